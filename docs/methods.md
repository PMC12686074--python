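# Methods

## Model and rationale

`varstate` treats missense-variant prioritization as unsupervised
structure in a feature space rather than supervised prediction.  Each
variant of an `L`-residue protein is a point in a variants × features
matrix whose columns combine sequence-based pathogenicity scores (CADD,
AlphaMissense, ESM1b, PolyPhen2, SIFT, MutFunc, ClinPred) with two
structure-derived features: the change in folding free energy (ΔΔG) of
the protein's open (active) and closed (autoinhibited) conformations upon
mutation.  The premise, drawn from kinase autoinhibition biology, is that
variants shifting the conformational equilibrium toward the open state —
by destabilizing the closed state and/or stabilizing the open one — form
a recognizable population distinct from the bulk of tolerated
substitutions.  Two-way clustering separates these populations; the
cluster enriched for population-catalog (gnomAD-style) variants is read
as benign-like, and known activating variants act as anchors for the
other.

All external predictor values (pathogenicity scores, ΔΔG from any of the
supported dialects, ligand-affinity changes as −log10(KD/Ki), interaction
ΔΔG) are *ingested*, never recomputed: the package's contribution is the
integration, classification and clustering machinery around them.

## Variant space

Variants are 1-based single-residue substitutions over the 20 canonical
amino acids, written in short HGVS-p form (`p.V464M`).  Saturation
enumeration produces exactly `19 × L` variants in a deterministic order
(position ascending, alternate alphabetical) so that every seeded
downstream stage is reproducible.  Stops, indels and ambiguity codes are
out of scope.  Domain boundaries are user configuration; the shipped
JAK1-style map (FERM/SH2/PK/TK) is explicitly approximate, for display
only, and is never used in tests.

## Feature matrix

Score tables are keyed by (position, ref, alt) and may arrive as a single
variant-label column or split position/ref/alt columns; duplicate keys
are an error.  Missing cells are imputed with the per-feature median of
observed values (robust, keeps all rows clusterable) and tracked in an
explicit mask.  Columns are standardized to mean 0, sd 1 using *observed*
values only, with the sample (n−1) standard deviation; imputed cells are
transformed with the same statistics, so they sit at the column's
imputation point.  Constant columns cannot be scaled and are dropped with
a warning.  Features are z-scored but not sign-reoriented: Euclidean
clustering is orientation-agnostic, and each score's damaging direction
is kept as metadata for reporting.  `ESM1b` accepts the `ESMb1`/`ESMb-1`
spellings on ingest.

## Clustering and labeling

Distances are Euclidean in z-space; unit variance makes the scale-free
choice defensible when no metric is prescribed.  Two partitioning routes
are implemented and recorded in every output:

- **kmeans2** (default): k-means, 2 clusters, 25 seeded restarts.
- **knn_community**: Louvain communities on the undirected k-nearest-
  neighbor graph (exact kNN, k = 6 default, ties broken toward the
  earlier variant key), merged to two groups by iteratively joining the
  closest community centroids.

Cluster ids are renumbered deterministically (lexicographically smaller
centroid first) before labeling.  The benign-like label goes to the
cluster with the higher fraction of catalog-flagged variants; an exact
tie falls back to the anchors and otherwise errors.  Anchors observed in
the benign-like cluster are reported as conflicts, never silently
re-labeled.  Reports print benign-like as "Cluster 1" and
pathogenic-like as "Cluster 2".

Catalog enrichment uses the exact (hypergeometric) two-sided test on the
2×2 flagged-by-cluster table; the odds ratio is (a·d)/(b·c) with a
Haldane–Anscombe +0.5 on all cells only when a cell is zero.

Query variants are z-scored with the stored training statistics and
assigned to the nearer labeled centroid; exact ties return
"unclassified".  The final report ranks pathogenic-like variants first,
ordered by distance to the benign-like centroid (descending).  Binary
cluster membership is the primary call; the within-cluster ordering is
this package's addition and is flagged as such in the run manifest.

## Dual-state stability

ΔΔG records carry an explicit sign convention per source; internally,
negative = destabilizing.  Classification at threshold τ (> 0; default
1.0 in the tabulated energy units, configurable because no canonical
cutoff exists) applies these rules in order, which are exhaustive and
mutually exclusive on ℝ²:

1. ΔΔG_open ≥ +τ → `open_shift_stabilizing`
2. both ≤ −τ → `destabilizes_both`
3. ΔΔG_closed ≤ −τ → `destabilizes_closed_only`
4. ΔΔG_open ≤ −τ → `destabilizes_open_only`
5. otherwise → `neutral`

Rule 1 takes precedence because a stabilized open state is the
functionally decisive signal for activation; when it co-occurs with
closed-state destabilization the detailed record reports the compound
pattern `closed_destab_open_shift` (both effects favor the active
state), while the enum class remains `open_shift_stabilizing`.  A
stabilized closed state with no other signal maps to `neutral`:
reinforcing autoinhibition is not a destabilization pattern.  Consensus
across predictors is a strict-majority vote; anything short of a
majority is `ambiguous`.  Ligand-affinity records are flagged as altered
at |value| ≥ τ_lig (inclusive; default 1.0, i.e. a ten-fold KD/Ki
change), and interaction ΔΔG values are flagged as destabilizing at
≤ −τ.

## Structure geometry

Structures are parsed with gemmi from PDB or mmCIF; multi-model files
become coordinate ensembles.  Hydrogens are ignored throughout (the
target models are predicted structures), so hydrogen-bond capability is
a donor/acceptor heavy-atom (N/O) criterion within 3.5 Å, without angle
terms — a deliberate proxy, not a full H-bond definition.

- **Superposition**: least-squares rigid fit (Kabsch, SVD with
  reflection guard), atoms paired by (chain, residue number, atom name);
  no sequence-alignment fallback.  With a prune cutoff (default 2.0 Å
  when requested), the worst residual pair is dropped and the fit
  repeated until all retained pairs fall under the cutoff — an emulation
  of pruned-atom superposition whose exact upstream settings are not
  standardized.  Collinear atom sets are flagged as degenerate.
- **Interfaces**: residue pairs across two disjoint ranges with any
  heavy-atom distance ≤ 5.0 Å (kd-tree accelerated; validated against
  brute force in the tests).
- **Pocket distances**: pocket center = centroid of the ligand's (or a
  residue set's) heavy atoms; the residue reference point is the
  side-chain heavy-atom centroid (CB outward), falling back to CA for
  glycine.
- **RMSF**: per-residue CA fluctuation sqrt(mean_t |r_i(t) − r̄_i|²).
  Whether frames are first rigidly fitted to frame 1 is a flag
  (`superpose_frames`, default on); the no-fit mode matches the reading
  of per-structure fluctuation "performed for each structure
  independently" and is what the closed-form σ√3 benchmark assumes.

## Synthetic data

The generator emulates the screen's feature space as two populations of
independent Gaussians.  Defaults are the study conditions: population
sizes 7559 (benign-like) and 14367 (pathogenic-like); per-population
means for ESM1b (−4.47 / −10.75), CADD (20.99 / 26.68) and ΔΔG_closed
(−2.05 / −6.36) taken from the reported per-cluster means; catalog-flag
probabilities 214/7559 and 75/14367, reproducing the reported flag
counts in expectation; and the four known activating variants planted as
pathogenic anchors.  Features without reported means (AlphaMissense,
PolyPhen2, SIFT, MutFunc, ClinPred, ΔΔG_open) use plausible values on
each score's native scale with the damaging direction consistent with
its orientation, and standard deviations chosen so that individual
features overlap substantially (≈ 1.5–2 sd mean separation) while the
joint 9-feature space is well separated — i.e., no single score decides
the split.  Missingness is off by default and configurable.

What the generator does *not* emulate: inter-score correlations (real
predictors are strongly correlated; the marginals reported for the
clusters do not constrain covariance, so independence is the documented
default), heavy tails, position-dependent structure along the sequence,
and any relationship between a variant's label and its feature values.
Passing the recovery tests therefore shows that the pipeline's
machinery — standardization, clustering, labeling, enrichment,
assignment — is correct under the assumed statistical structure, not
that real variant data separate this cleanly.

Toy structures are two residue groups at a configurable gap with an
optional ligand at a known centroid; ensembles add iid Gaussian jitter
(RMSF → σ√3).

## Numerical and reproducibility choices

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical inputs + seed give
  byte-identical outputs at every stage.
- Ties in kNN and cluster renumbering break on the lexicographically
  earlier variant key / smaller centroid; ordering is therefore total
  and stable.
- z-scoring uses the n−1 standard deviation so recomputation from the
  persisted column statistics is unambiguous.
- Degenerate inputs error loudly: all-identical matrices, all-missing
  columns, empty clusters, degenerate 2×2 margins, < 3 superposition
  pairs, collinear atom sets, inconsistent ensemble residue sets.
- The exact enrichment p-value comes from the conditional
  hypergeometric test (two-sided); the tests verify it against explicit
  enumeration of the hypergeometric support on small tables.

The test suite and the acceptance script run the full-scale clustering
at the study size (21,926 variants × 9 features) but keep structure
ensembles small (≈ 16 residues × 500 frames) and the recovery study at
n = 1000 + 2000 over 20 seeds — sizes chosen so the statistical bounds
they assert (CLT 3-SE bands, binomial 99% bands, 5% Monte-Carlo
tolerances) are meaningful while the whole suite runs in seconds.

## Known limitations

- No isoform/transcript mapping: positions are 1-based on the supplied
  canonical sequence, and the user must provide the matching FASTA.
- Exact reproduction of any externally published cluster membership
  depends on the original feature table and algorithm settings; with
  different tables, sizes and means will differ even if the qualitative
  two-cluster structure holds.
- The H-bond proxy ignores geometry beyond distance; interface and
  contact sets on predicted models inherit the models' local accuracy.
- Only two-way partitions are supported; display-style embeddings
  (UMAP and the like) are out of scope.
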