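"""Per-variant score tables and the standardized feature matrix.

Heterogeneous predictor outputs (pathogenicity, evolutionary and functional
scores plus dual-state stability shifts) are read into :class:`ScoreTable`
objects keyed by (position, ref, alt), assembled into one variants x features
matrix with explicit missingness, and z-scored column-wise before any
distance-based analysis.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .variants import Variant, VariantSet, parse_variant_label

log = logging.getLogger(__name__)

#: Default feature panel: sequence-based pathogenicity / evolutionary /
#: functional scores plus the open- and closed-state stability shifts.
DEFAULT_FEATURES = (
    "CADD",
    "AlphaMissense",
    "ESM1b",
    "PolyPhen2",
    "SIFT",
    "MutFunc",
    "ClinPred",
    "ddG_open",
    "ddG_closed",
)

#: Accepted spellings for feature names (normalized on ingest).
FEATURE_ALIASES = {
    "ESMB1": "ESM1b",
    "ESMB-1": "ESM1b",
    "ESM-1B": "ESM1b",
    "ESM1B": "ESM1b",
    "POLYPHEN2": "PolyPhen2",
    "POLYPHEN-2": "PolyPhen2",
    "ALPHAMISSENSE": "AlphaMissense",
    "CADD": "CADD",
    "SIFT": "SIFT",
    "MUTFUNC": "MutFunc",
    "CLINPRED": "ClinPred",
    "DDG_OPEN": "ddG_open",
    "DDG_CLOSED": "ddG_closed",
}

VariantKey = tuple[int, str, str]


class ScoreTableError(ValueError):
    """Malformed or inconsistent score-table input."""


def canonical_feature_name(name: str) -> str:
    return FEATURE_ALIASES.get(name.strip().upper(), name.strip())


@dataclass
class ScoreTable:
    """One predictor's scores keyed by variant.

    ``orientation`` records whether larger values mean more damaging
    (``higher_is_damaging``) or less (``lower_is_damaging``, e.g. SIFT);
    it is metadata for reporting and never flips values.
    """

    feature_name: str
    orientation: str
    records: dict[VariantKey, float]

    def __post_init__(self) -> None:
        if self.orientation not in ("higher_is_damaging", "lower_is_damaging"):
            raise ScoreTableError(f"unknown orientation {self.orientation!r}")
        self.feature_name = canonical_feature_name(self.feature_name)


def _sniff_sep(path: Path) -> str:
    head = path.open().readline()
    return "\t" if "\t" in head else ","


def read_score_table(
    path: str | Path,
    feature_name: str,
    column_spec: Mapping[str, str],
    orientation: str = "higher_is_damaging",
) -> ScoreTable:
    """Read one predictor's table from TSV/CSV.

    ``column_spec`` maps roles to header names.  Two dialects are accepted:
    a single variant-label column (``{"variant": ..., "value": ...}``) or
    separate columns (``{"position": ..., "ref": ..., "alt": ...,
    "value": ...}``).  Duplicate variant keys are an error listing them.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    value_col = column_spec.get("value")
    if value_col is None or value_col not in df.columns:
        raise ScoreTableError(f"{path}: missing value column {value_col!r}")
    if "variant" in column_spec:
        vcol = column_spec["variant"]
        if vcol not in df.columns:
            raise ScoreTableError(f"{path}: missing variant column {vcol!r}")
        keys = [parse_variant_label(str(lbl)).key for lbl in df[vcol]]
    else:
        needed = ("position", "ref", "alt")
        for role in needed:
            if column_spec.get(role) not in df.columns:
                raise ScoreTableError(f"{path}: missing {role} column")
        keys = [
            (int(p), str(r).upper(), str(a).upper())
            for p, r, a in zip(
                df[column_spec["position"]],
                df[column_spec["ref"]],
                df[column_spec["alt"]],
            )
        ]
    values = pd.to_numeric(df[value_col], errors="coerce")
    bad = values.isna() & df[value_col].notna()
    if bad.any():
        rows = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())][:5]
        raise ScoreTableError(f"{path}: non-numeric values at file rows {rows}")
    records: dict[VariantKey, float] = {}
    dups: list[VariantKey] = []
    for key, val in zip(keys, values):
        if key in records:
            dups.append(key)
        records[key] = float(val)
    if dups:
        labels = sorted({f"p.{r}{p}{a}" for p, r, a in dups})
        raise ScoreTableError(f"{path}: duplicate variant keys: {labels}")
    return ScoreTable(feature_name=feature_name, orientation=orientation, records=records)


@dataclass
class FeatureConfig:
    """Which features to assemble and how to treat missing values."""

    features: tuple[str, ...] = DEFAULT_FEATURES
    missing_policy: str = "median"
    standardize: bool = True

    def __post_init__(self) -> None:
        feats = tuple(canonical_feature_name(f) for f in self.features)
        if len(feats) == 0:
            raise ScoreTableError("feature list is empty")
        if len(set(feats)) != len(feats):
            raise ScoreTableError("duplicate feature names")
        if self.missing_policy not in ("median", "mean", "error"):
            raise ScoreTableError(f"unknown missing policy {self.missing_policy!r}")
        self.features = feats


@dataclass
class FeatureMatrix:
    """Variants x features values with a missingness mask and z-score stats.

    ``mask`` is True where the value was imputed rather than observed.
    ``column_stats`` holds the per-feature (mean, sd) used for z-scoring,
    computed over observed values only with the n-1 sd denominator; it is
    None for a raw (unstandardized) matrix.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    column_stats: Optional[dict[str, tuple[float, float]]] = None
    orientations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.mask.index) or not self.values.columns.equals(
            self.mask.columns
        ):
            raise ScoreTableError("values and mask must share index and columns")

    @property
    def n_variants(self) -> int:
        return len(self.values)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        """Persist values as TSV with a sidecar JSON for mask and stats."""
        path = Path(path)
        self.values.to_csv(path, sep="\t", index_label="variant")
        sidecar = {
            "mask": {
                col: [str(i) for i in self.mask.index[self.mask[col]]]
                for col in self.mask.columns
            },
            "column_stats": self.column_stats,
            "orientations": self.orientations,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        values = pd.read_csv(path, sep="\t", index_col="variant")
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        mask = pd.DataFrame(False, index=values.index, columns=values.columns)
        for col, idx in sidecar["mask"].items():
            mask.loc[idx, col] = True
        stats = sidecar.get("column_stats")
        if stats is not None:
            stats = {k: (float(v[0]), float(v[1])) for k, v in stats.items()}
        return cls(
            values=values,
            mask=mask,
            column_stats=stats,
            orientations=sidecar.get("orientations", {}),
        )


def assemble_matrix(
    variant_set: VariantSet | Sequence[Variant],
    score_tables: Iterable[ScoreTable],
    ddg_open: Optional[Mapping[VariantKey, float]] = None,
    ddg_closed: Optional[Mapping[VariantKey, float]] = None,
    config: Optional[FeatureConfig] = None,
) -> FeatureMatrix:
    """Assemble one row per variant from per-feature score tables.

    Cells absent from a table are imputed per the config policy (default:
    per-feature median of the observed values) and flagged in the mask.
    Stability shifts, when given, fill the ``ddG_open`` / ``ddG_closed``
    columns.  Raises if a configured feature has no table or no table
    overlaps the variant set.
    """
    config = config or FeatureConfig()
    variants = list(variant_set)
    if not variants:
        raise ScoreTableError("empty variant set")
    keys = [v.key for v in variants]
    labels = [v.label for v in variants]

    by_name: dict[str, ScoreTable] = {}
    for t in score_tables:
        by_name[t.feature_name] = t
    if ddg_open is not None:
        by_name["ddG_open"] = ScoreTable("ddG_open", "lower_is_damaging", dict(ddg_open))
    if ddg_closed is not None:
        by_name["ddG_closed"] = ScoreTable(
            "ddG_closed", "lower_is_damaging", dict(ddg_closed)
        )

    missing_feats = [f for f in config.features if f not in by_name]
    if missing_feats:
        raise ScoreTableError(f"no table supplied for features: {missing_feats}")

    values = pd.DataFrame(index=pd.Index(labels, name="variant"), columns=list(config.features), dtype=float)
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    orientations: dict[str, str] = {}
    any_overlap = False
    for feat in config.features:
        table = by_name[feat]
        orientations[feat] = table.orientation
        col = np.array([table.records.get(k, np.nan) for k in keys], dtype=float)
        observed = ~np.isnan(col)
        if observed.any():
            any_overlap = True
        miss = ~observed
        if miss.any():
            if config.missing_policy == "error":
                raise ScoreTableError(
                    f"feature {feat}: {int(miss.sum())} variants missing"
                )
            if not observed.any():
                raise ScoreTableError(f"feature {feat}: all values missing")
            fill = (
                float(np.median(col[observed]))
                if config.missing_policy == "median"
                else float(np.mean(col[observed]))
            )
            col[miss] = fill
            mask.iloc[:, mask.columns.get_loc(feat)] = miss
        values[feat] = col
    if not any_overlap:
        raise ScoreTableError("no score table overlaps the variant set")
    return FeatureMatrix(values=values, mask=mask, orientations=orientations)


def zscore(matrix: FeatureMatrix) -> FeatureMatrix:
    """Standardize each column to mean 0, sd 1 over its observed values.

    Statistics use only non-imputed cells (sample sd, n-1 denominator);
    imputed cells are transformed with the same statistics so they stay at
    the column's imputation point.  Constant columns cannot be scaled and
    are dropped with a warning.
    """
    stats: dict[str, tuple[float, float]] = {}
    out = {}
    keep: list[str] = []
    for col in matrix.values.columns:
        vals = matrix.values[col].to_numpy(dtype=float)
        obs = ~matrix.mask[col].to_numpy()
        observed = vals[obs]
        if observed.size == 0:
            raise ScoreTableError(f"column {col}: no observed values")
        mu = float(np.mean(observed))
        sd = float(np.std(observed, ddof=1)) if observed.size > 1 else 0.0
        if sd == 0.0:
            warnings.warn(f"dropping constant feature column {col!r}")
            log.warning("dropping constant feature column %r", col)
            continue
        keep.append(col)
        stats[col] = (mu, sd)
        out[col] = (vals - mu) / sd
    if not keep:
        raise ScoreTableError("all columns constant; nothing to standardize")
    values = pd.DataFrame(out, index=matrix.values.index)[keep]
    return FeatureMatrix(
        values=values,
        mask=matrix.mask[keep].copy(),
        column_stats=stats,
        orientations={k: v for k, v in matrix.orientations.items() if k in keep},
    )


def apply_zscore(
    vector: Mapping[str, float], column_stats: Mapping[str, tuple[float, float]]
) -> np.ndarray:
    """Transform a raw feature vector with previously stored column stats."""
    out = []
    for feat, (mu, sd) in column_stats.items():
        if feat not in vector:
            raise ScoreTableError(f"feature {feat} missing from query vector")
        out.append((float(vector[feat]) - mu) / sd)
    return np.array(out, dtype=float)
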