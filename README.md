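# varstate

Structure-informed prioritization of missense variants from
dual-conformation stability shifts and sequence-based pathogenicity
scores.

Many signaling proteins — the motivating case is the JAK1 tyrosine
kinase — are regulated by a conformational equilibrium between an
autoinhibited ("closed") and a catalytically active ("open") state.
Missense variants that destabilize the closed state, or stabilize the
open one, can produce constitutive gain-of-function activity even when
classical pathogenicity predictors are equivocal.  `varstate` implements a
reusable pipeline for screening such variants:

1. **Saturation enumeration** — all `19 × L` single-residue substitutions
   of an `L`-residue protein (for JAK1's 1154 residues, 21,926 variants).
2. **Feature assembly** — per-variant scores from heterogeneous predictor
   tables (CADD, AlphaMissense, ESM1b, PolyPhen2, SIFT, MutFunc,
   ClinPred) plus ingested ΔΔG values for the open and closed
   conformations, merged into one variants × features matrix with
   explicit missingness and per-feature z-scoring.
3. **Two-way clustering** — k-means (25 seeded restarts, default) or
   community detection on the k-nearest-neighbor graph (k = 6), yielding
   a *benign-like* and a *pathogenic-like* cluster.  The benign-like
   cluster is identified by its enrichment in population-catalog
   (gnomAD-style) variants — tested exactly on the 2×2
   catalog-by-cluster table, OR = (a·d)/(b·c) — and checked against known
   activating anchor variants.
4. **Query classification** — new variants are z-scored with the training
   statistics and assigned by nearest centroid, giving a ranked
   prioritization report.
5. **Dual-state stability profiles** — per-predictor ΔΔG_open/ΔΔG_closed
   records (SDM, mCSM, DUET, DDMut, Dynamut2 dialects) are normalized to
   a common sign convention (negative = destabilizing), classified
   (`destabilizes_both`, `destabilizes_closed_only`,
   `open_shift_stabilizing`, ...) and combined by strict-majority vote.
6. **Structure geometry** — Kabsch superposition with iterative pruning,
   domain-interface residue pairs, per-residue contacts with a
   donor/acceptor heavy-atom H-bond proxy, ligand-pocket centroid
   distances, and per-residue RMSF over coordinate ensembles.

A first-class synthetic-data generator reproduces the statistical
structure the pipeline assumes (two Gaussian populations at the
reported per-cluster feature means, catalog-flag rates, anchor variants,
toy structures and jittered ensembles), so every stage is testable
without external downloads.

## Worked example

`examples/02_cluster_and_prioritize.py` runs the full screen on a
generated matrix at the study scale:

```
feature matrix: 21926 variants x 9 features
Cluster 1 (benign_like):     7562 variants
Cluster 2 (pathogenic_like): 14364 variants
mean CADD        cluster1   20.96   cluster2   26.70
mean ESM1b       cluster1   -4.48   cluster2  -10.77
mean ddG_closed  cluster1   -2.02   cluster2   -6.37
catalog-flagged in cluster 1: 204/287  (OR = 4.77, p = 7.24e-37)
anchors in pathogenic_like:   4/4, conflicts: []
agreement with generator truth (ARI): 0.9987
query panel: 5/13 variants assigned pathogenic_like
```

The pathogenic-like cluster combines higher pathogenicity scores, a more
negative evolutionary score, and a markedly more destabilizing
closed-state ΔΔG; catalog-frequent variants concentrate in the
benign-like cluster; all four known activating anchors fall in the
pathogenic-like cluster, and 5 of the 13 query-panel variants — exactly
the panel's pathogenic-population members — are assigned to it.  The
other examples cover saturation enumeration, dual-state stability
classes and the geometry operations.

A thin CLI mirrors the library (`varstate enumerate | assemble |
stability | cluster | assign | simulate | structure | run`); `varstate
run --config run.yaml` executes the whole pipeline from a YAML config
and writes a ranked report, cluster summary and JSON manifest.

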