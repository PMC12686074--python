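"""End-to-end prioritization: enumerate, assemble, classify, cluster, rank.

A single seeded, configured run goes from raw inputs (sequence, score
tables, stability tables, catalog flags, anchors) to a per-variant report:
cluster label, centroid distances, consensus stability class, catalog flag
and rank.  Reports print the benign-like cluster as "Cluster 1" and the
pathogenic-like cluster as "Cluster 2".  Ranking puts pathogenic-like
variants first, ordered by distance to the benign-like centroid
(descending); the within-cluster ordering is this package's addition on
top of binary cluster membership and is labeled as such in the manifest.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import (
    BENIGN_LIKE,
    PATHOGENIC_LIKE,
    ClusterResult,
    enrichment_test,
    label_clusters,
    partition_two_way,
    summarize_clusters,
)
from .scores import (
    FeatureConfig,
    FeatureMatrix,
    ScoreTableError,
    apply_zscore,
    assemble_matrix,
    read_score_table,
    zscore,
)
from .stability import StabilityClass, build_profiles, classify_stability, read_ddg_table
from .variants import (
    DomainMap,
    VariantFormatError,
    annotate_domain,
    enumerate_saturation,
    load_fasta,
    parse_variant_label,
    read_variant_list,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated run configuration (usually loaded from YAML)."""

    score_tables: dict = field(default_factory=dict)  # feature -> spec dict
    fasta: Optional[str] = None
    variants: Optional[str] = None
    flags: Optional[str] = None
    anchors: Optional[str] = None
    query_table: Optional[str] = None
    stability_tables: list = field(default_factory=list)
    domains: list = field(default_factory=list)  # [start, end, label] triples
    features: Optional[list] = None
    method: str = "kmeans2"
    k: int = 6
    seed: int = 0
    tau: float = 1.0
    tau_lig: float = 1.0
    outdir: str = "varstate_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.score_tables:
            raise ValueError("no score tables configured")
        for name, spec in self.score_tables.items():
            p = Path(spec["path"])
            if not p.exists():
                raise ValueError(f"score table for {name} not found: {p}")
        for key in ("fasta", "variants", "flags", "anchors", "query_table"):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise ValueError(f"{key} file not found: {val}")
        if self.seed is None:
            raise ValueError("seed must be set")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PrioritizationReport:
    table: pd.DataFrame  # one row per variant, ranked
    manifest: dict
    cluster_result: ClusterResult
    summary_means: pd.DataFrame
    query: Optional[pd.DataFrame] = None


def _load_variant_universe(config: RunConfig):
    if config.fasta is not None:
        protein = load_fasta(config.fasta)
        if config.variants is not None:
            labels = read_variant_list(config.variants)
            return [parse_variant_label(lbl, protein) for lbl in labels]
        return list(enumerate_saturation(protein))
    if config.variants is not None:
        return [parse_variant_label(lbl) for lbl in read_variant_list(config.variants)]
    # fall back to the union of keys across all configured score tables
    keys: set = set()
    for name, spec in config.score_tables.items():
        default_value = "ddG" if name.startswith("ddG") else "value"
        table = read_score_table(
            spec["path"],
            name,
            spec.get("column_spec", {"variant": "variant", "value": default_value}),
            spec.get("orientation", "higher_is_damaging"),
        )
        keys |= set(table.records)
    return [parse_variant_label(f"p.{r}{p}{a}") for p, r, a in sorted(keys)]


def run_prioritization(config: RunConfig) -> PrioritizationReport:
    """Execute the full workflow; deterministic given config + seed."""
    try:
        config.validate()
    except ValueError as exc:
        raise PipelineError("validate", str(exc)) from exc

    try:
        variants = _load_variant_universe(config)
    except (VariantFormatError, ScoreTableError, ValueError) as exc:
        raise PipelineError("variants", str(exc)) from exc
    log.info("variant universe: %d variants", len(variants))

    try:
        tables = []
        for name, spec in config.score_tables.items():
            default_value = "ddG" if name.startswith("ddG") else "value"
            tables.append(
                read_score_table(
                    spec["path"],
                    name,
                    spec.get(
                        "column_spec", {"variant": "variant", "value": default_value}
                    ),
                    spec.get("orientation", "higher_is_damaging"),
                )
            )
        fconf = FeatureConfig(
            features=tuple(config.features)
            if config.features
            else tuple(t.feature_name for t in tables)
        )
        raw = assemble_matrix(variants, tables, config=fconf)
        z = zscore(raw)
    except (ScoreTableError, VariantFormatError) as exc:
        raise PipelineError("assemble", str(exc)) from exc
    log.info("feature matrix: %d x %d", raw.n_variants, len(raw.features))

    # stability classes: multi-predictor profiles when configured, else the
    # matrix's own dual-state columns
    stability_class: dict[str, str] = {}
    try:
        if config.stability_tables:
            records = []
            for spec in config.stability_tables:
                records.extend(
                    read_ddg_table(
                        spec["path"],
                        spec["predictor"],
                        spec["state"],
                        spec.get("convention", "negative_is_destabilizing"),
                    )
                )
            for key, prof in build_profiles(records, tau=config.tau).items():
                pos, r, a = key
                stability_class[f"p.{r}{pos}{a}"] = prof.consensus().value
        elif "ddG_open" in raw.features and "ddG_closed" in raw.features:
            for lbl, row in raw.values.iterrows():
                stability_class[str(lbl)] = classify_stability(
                    float(row["ddG_open"]), float(row["ddG_closed"]), config.tau
                ).value
    except Exception as exc:
        raise PipelineError("stability", str(exc)) from exc

    flags = pd.Series(False, index=raw.values.index)
    if config.flags is not None:
        fdf = pd.read_csv(config.flags, sep="\t")
        flagged = fdf.loc[fdf.iloc[:, 1].astype(bool), fdf.columns[0]]
        flags.loc[flags.index.intersection(flagged)] = True
    anchors = []
    if config.anchors is not None:
        anchors = [
            line.strip()
            for line in Path(config.anchors).read_text().splitlines()
            if line.strip()
        ]

    try:
        result = partition_two_way(z, method=config.method, seed=config.seed, k=config.k)
        result = label_clusters(result, flags, anchors)
        summary = summarize_clusters(result, raw, anchors)
        try:
            enrich = enrichment_test(result, flags)
        except ValueError:
            enrich = None  # degenerate 2x2 table (e.g. no catalog flags)
    except Exception as exc:
        raise PipelineError("cluster", str(exc)) from exc
    log.info("clusters: sizes=%s labels=%s", result.sizes, result.labels)

    domain_map = (
        DomainMap(intervals=tuple((int(s), int(e), str(l)) for s, e, l in config.domains))
        if config.domains
        else None
    )

    benign_cid = result.labels[BENIGN_LIKE]
    path_cid = result.labels[PATHOGENIC_LIKE]
    Z = z.values.to_numpy()
    cb = result.centroids[benign_cid]
    cp = result.centroids[path_cid]
    dist_b = np.linalg.norm(Z - cb, axis=1)
    dist_p = np.linalg.norm(Z - cp, axis=1)
    rows = pd.DataFrame(
        {
            "variant": z.values.index,
            # benign_like is printed as Cluster 1
            "cluster": [
                1 if result.assignment[v] == benign_cid else 2
                for v in z.values.index
            ],
            "label": [
                BENIGN_LIKE if result.assignment[v] == benign_cid else PATHOGENIC_LIKE
                for v in z.values.index
            ],
            "dist_benign_centroid": dist_b,
            "dist_pathogenic_centroid": dist_p,
            "consensus_stability": [
                stability_class.get(str(v), "") for v in z.values.index
            ],
            "gnomad_reported": flags.to_numpy(),
            "is_anchor": [v in set(anchors) for v in z.values.index],
        }
    )
    if domain_map is not None:
        rows["domain"] = [
            annotate_domain(parse_variant_label(str(v)), domain_map)
            for v in rows["variant"]
        ]
    # pathogenic-like first, farthest from the benign centroid first
    rows = rows.sort_values(
        by=["label", "dist_benign_centroid", "variant"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    rows.insert(0, "rank", np.arange(1, len(rows) + 1))

    query_block = None
    if config.query_table is not None:
        try:
            qdf = pd.read_csv(config.query_table, sep="\t", index_col=0)
            from .clustering import assign_new_variant

            qrows = []
            for lbl, row in qdf.iterrows():
                vec = apply_zscore(row.to_dict(), z.column_stats)
                qlabel, dists = assign_new_variant(vec, result)
                qrows.append(
                    {
                        "variant": lbl,
                        "assigned": qlabel,
                        "dist_benign_centroid": dists[BENIGN_LIKE],
                        "dist_pathogenic_centroid": dists[PATHOGENIC_LIKE],
                    }
                )
            query_block = pd.DataFrame(qrows)
        except Exception as exc:
            raise PipelineError("assign", str(exc)) from exc

    manifest = {
        "schema_version": 1,
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "method": result.method,
        "n_variants": int(len(rows)),
        "cluster_sizes_printed": {
            "Cluster 1 (benign_like)": result.sizes[benign_cid],
            "Cluster 2 (pathogenic_like)": result.sizes[path_cid],
        },
        "enrichment": (
            {
                "table": enrich.table.tolist(),
                "odds_ratio": enrich.odds_ratio,
                "p_value": enrich.p_value,
                "enriched_cluster": enrich.enriched_cluster,
            }
            if enrich is not None
            else None
        ),
        "anchor_conflicts": result.conflicts,
        "ranking_note": (
            "rank orders pathogenic_like variants first by distance to the "
            "benign-like centroid (descending); within-cluster ordering is "
            "an addition on top of binary cluster membership"
        ),
    }
    if query_block is not None:
        manifest["n_query"] = int(len(query_block))

    return PrioritizationReport(
        table=rows,
        manifest=manifest,
        cluster_result=result,
        summary_means=summary.means,
        query=query_block,
    )


def write_report(report: PrioritizationReport, outdir: str | Path) -> dict[str, Path]:
    """Persist the per-variant TSV, cluster summary and JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "report": outdir / "report.tsv",
        "summary": outdir / "cluster_summary.tsv",
        "manifest": outdir / "manifest.json",
    }
    report.table.to_csv(paths["report"], sep="\t", index=False)
    report.summary_means.to_csv(paths["summary"], sep="\t", index_label="cluster")
    paths["manifest"].write_text(json.dumps(report.manifest, indent=1))
    if report.query is not None:
        qp = outdir / "query_assignments.tsv"
        report.query.to_csv(qp, sep="\t", index=False)
        paths["query"] = qp
    return paths
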