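"""Dual-state stability shifts: ingestion, classification, consensus.

A variant's effect on the folding free energy is evaluated separately for
the open (catalytically active) and closed (autoinhibited) conformations.
Internally, negative ddG means destabilizing; predictors that tabulate the
opposite sign declare it and are flipped on ingest.  A positive shift on
the open state reads as stabilization of the active conformation — the
pattern seen for activating variants that tilt the conformational
equilibrium away from autoinhibition.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .scores import VariantKey, _sniff_sep
from .variants import parse_variant_label

PREDICTORS = ("pyrosetta_like", "SDM", "mCSM", "DUET", "DDMut", "Dynamut2", "other")
CONVENTIONS = ("negative_is_destabilizing", "positive_is_destabilizing")
STATES = ("open", "closed")


class StabilityError(ValueError):
    pass


class StabilityClass(enum.Enum):
    DESTABILIZES_BOTH = "destabilizes_both"
    DESTABILIZES_CLOSED_ONLY = "destabilizes_closed_only"
    DESTABILIZES_OPEN_ONLY = "destabilizes_open_only"
    OPEN_SHIFT_STABILIZING = "open_shift_stabilizing"
    NEUTRAL = "neutral"
    AMBIGUOUS = "ambiguous"


#: Detailed compound pattern reported when a stabilizing open-state shift
#: co-occurs with closed-state destabilization (both favor the open state).
CLOSED_DESTAB_OPEN_SHIFT = "closed_destab_open_shift"


@dataclass(frozen=True)
class DdgRecord:
    """One predictor's ddG for one variant in one conformational state,
    already normalized to the internal negative-is-destabilizing sign."""

    key: VariantKey
    predictor: str
    state: str
    value: float

    def __post_init__(self) -> None:
        if self.predictor not in PREDICTORS:
            raise StabilityError(f"unknown predictor {self.predictor!r}")
        if self.state not in STATES:
            raise StabilityError(f"unknown state {self.state!r}")
        if not math.isfinite(self.value):
            raise StabilityError(f"non-finite ddG for {self.key}")


def normalize_ddg(value: float, convention: str) -> float:
    """Map a tabulated ddG onto the internal sign (negative = destabilizing).

    Flipping the convention twice restores the original value.
    """
    if convention not in CONVENTIONS:
        raise StabilityError(f"unknown convention {convention!r}")
    return -value if convention == "positive_is_destabilizing" else value


def read_ddg_table(
    path: str | Path,
    predictor: str,
    state: str,
    convention: str = "negative_is_destabilizing",
    variant_column: str = "variant",
    value_column: str = "ddG",
) -> list[DdgRecord]:
    """Read a per-variant ddG TSV and normalize to the internal convention."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    for col in (variant_column, value_column):
        if col not in df.columns:
            raise StabilityError(f"{path}: missing column {col!r}")
    values = pd.to_numeric(df[value_column], errors="coerce")
    bad = values.isna() & df[value_column].notna()
    if bad.any():
        rows = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())][:5]
        raise StabilityError(f"{path}: non-numeric ddG at file rows {rows}")
    records = []
    for lbl, val in zip(df[variant_column], values):
        key = parse_variant_label(str(lbl)).key
        records.append(
            DdgRecord(
                key=key,
                predictor=predictor,
                state=state,
                value=normalize_ddg(float(val), convention),
            )
        )
    return records


def classify_stability(
    ddg_open: float, ddg_closed: float, tau: float = 1.0
) -> StabilityClass:
    """Classify a dual-state ddG pair at threshold ``tau`` (> 0).

    Precedence, checked in order (exhaustive and mutually exclusive):

    1. open >= +tau         -> OPEN_SHIFT_STABILIZING (open state favored)
    2. open and closed <= -tau -> DESTABILIZES_BOTH
    3. closed <= -tau       -> DESTABILIZES_CLOSED_ONLY
    4. open <= -tau         -> DESTABILIZES_OPEN_ONLY
    5. otherwise            -> NEUTRAL

    A stabilized closed state without other signal falls under NEUTRAL:
    reinforcing autoinhibition is not a destabilization pattern.
    """
    if tau <= 0:
        raise StabilityError(f"tau must be > 0, got {tau}")
    if not (math.isfinite(ddg_open) and math.isfinite(ddg_closed)):
        raise StabilityError("non-finite ddG input")
    if ddg_open >= tau:
        return StabilityClass.OPEN_SHIFT_STABILIZING
    if ddg_open <= -tau and ddg_closed <= -tau:
        return StabilityClass.DESTABILIZES_BOTH
    if ddg_closed <= -tau:
        return StabilityClass.DESTABILIZES_CLOSED_ONLY
    if ddg_open <= -tau:
        return StabilityClass.DESTABILIZES_OPEN_ONLY
    return StabilityClass.NEUTRAL


def stability_pattern(ddg_open: float, ddg_closed: float, tau: float = 1.0) -> str:
    """Detailed pattern label; reports the compound
    ``closed_destab_open_shift`` when a stabilizing open shift co-occurs
    with closed-state destabilization (maps to ``open_shift_stabilizing``
    in the class enum)."""
    cls = classify_stability(ddg_open, ddg_closed, tau)
    if cls is StabilityClass.OPEN_SHIFT_STABILIZING and ddg_closed <= -tau:
        return CLOSED_DESTAB_OPEN_SHIFT
    return cls.value


def consensus_stability(classes: Sequence[StabilityClass]) -> StabilityClass:
    """Strict-majority vote across predictors; no majority -> AMBIGUOUS."""
    if len(classes) == 0:
        raise StabilityError("no predictor classes to vote over")
    counts: dict[StabilityClass, int] = {}
    for c in classes:
        counts[c] = counts.get(c, 0) + 1
    best = max(counts.items(), key=lambda kv: kv[1])
    if best[1] * 2 > len(classes):
        return best[0]
    return StabilityClass.AMBIGUOUS


@dataclass
class DualStateProfile:
    """Per-variant, per-predictor open/closed ddG with classes."""

    key: VariantKey
    open_values: dict[str, float] = field(default_factory=dict)
    closed_values: dict[str, float] = field(default_factory=dict)
    tau: float = 1.0

    @property
    def predictors(self) -> list[str]:
        return sorted(set(self.open_values) & set(self.closed_values))

    def per_predictor_classes(self) -> dict[str, StabilityClass]:
        return {
            p: classify_stability(self.open_values[p], self.closed_values[p], self.tau)
            for p in self.predictors
        }

    def consensus(self) -> StabilityClass:
        classes = list(self.per_predictor_classes().values())
        if not classes:
            raise StabilityError(f"no dual-state predictor for {self.key}")
        return consensus_stability(classes)

    def mean_ddg(self, state: str) -> float:
        vals = self.open_values if state == "open" else self.closed_values
        if not vals:
            raise StabilityError(f"no {state}-state values for {self.key}")
        return float(np.mean(list(vals.values())))


def build_profiles(
    records: Iterable[DdgRecord], tau: float = 1.0
) -> dict[VariantKey, DualStateProfile]:
    """Group normalized ddG records into per-variant dual-state profiles."""
    profiles: dict[VariantKey, DualStateProfile] = {}
    for rec in records:
        prof = profiles.setdefault(rec.key, DualStateProfile(key=rec.key, tau=tau))
        target = prof.open_values if rec.state == "open" else prof.closed_values
        if rec.predictor in target:
            raise StabilityError(
                f"duplicate {rec.state}-state record for {rec.key} / {rec.predictor}"
            )
        target[rec.predictor] = rec.value
    return profiles


@dataclass(frozen=True)
class LigandAffinityRecord:
    """Predicted ligand-affinity change as -log10(KD/Ki); ``binding_altered``
    is an inclusive threshold on the magnitude."""

    key: VariantKey
    ligand_id: str
    value: float
    binding_altered: bool


def read_ligand_affinity(
    path: str | Path,
    tau_lig: float = 1.0,
    ligand_id: str = "ADP",
    variant_column: str = "variant",
    value_column: str = "value",
) -> list[LigandAffinityRecord]:
    """Read -log10(KD/Ki) affinity changes; flag |value| >= tau_lig."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    for col in (variant_column, value_column):
        if col not in df.columns:
            raise StabilityError(f"{path}: missing column {col!r}")
    values = pd.to_numeric(df[value_column], errors="coerce")
    if (values.isna() & df[value_column].notna()).any():
        raise StabilityError(f"{path}: non-numeric affinity values")
    out = []
    for lbl, val in zip(df[variant_column], values):
        if not math.isfinite(float(val)):
            raise StabilityError(f"{path}: non-finite affinity for {lbl}")
        out.append(
            LigandAffinityRecord(
                key=parse_variant_label(str(lbl)).key,
                ligand_id=ligand_id,
                value=float(val),
                binding_altered=bool(abs(float(val)) >= tau_lig),
            )
        )
    return out


@dataclass(frozen=True)
class InteractionDdg:
    """Ingested binding ddG for a protein-partner interaction (e.g. the
    SOCS1 KIR engaging the kinase domain)."""

    key: VariantKey
    partner_id: str
    value: float
    destabilizes_interaction: bool


def read_interaction_ddg(
    path: str | Path,
    partner_id: str,
    convention: str = "negative_is_destabilizing",
    tau: float = 1.0,
    variant_column: str = "variant",
    value_column: str = "ddG",
) -> list[InteractionDdg]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    for col in (variant_column, value_column):
        if col not in df.columns:
            raise StabilityError(f"{path}: missing column {col!r}")
    out = []
    for lbl, val in zip(df[variant_column], pd.to_numeric(df[value_column])):
        v = normalize_ddg(float(val), convention)
        if not math.isfinite(v):
            raise StabilityError(f"{path}: non-finite interaction ddG for {lbl}")
        out.append(
            InteractionDdg(
                key=parse_variant_label(str(lbl)).key,
                partner_id=partner_id,
                value=v,
                destabilizes_interaction=bool(v <= -tau),
            )
        )
    return out


def stability_report(
    profiles: Mapping[VariantKey, DualStateProfile],
    ligand: Optional[Sequence[LigandAffinityRecord]] = None,
    interaction: Optional[Sequence[InteractionDdg]] = None,
) -> pd.DataFrame:
    """Tabulate per-variant dual-state values, classes and flags."""
    lig_by_key = {r.key: r for r in (ligand or [])}
    int_by_key = {r.key: r for r in (interaction or [])}
    rows = []
    for key in sorted(profiles):
        prof = profiles[key]
        pos, ref, alt = key
        row: dict[str, object] = {"variant": f"p.{ref}{pos}{alt}"}
        for p in prof.predictors:
            row[f"{p}_open"] = prof.open_values[p]
            row[f"{p}_closed"] = prof.closed_values[p]
            row[f"{p}_class"] = classify_stability(
                prof.open_values[p], prof.closed_values[p], prof.tau
            ).value
            row[f"{p}_pattern"] = stability_pattern(
                prof.open_values[p], prof.closed_values[p], prof.tau
            )
        row["consensus_class"] = prof.consensus().value
        lig = lig_by_key.get(key)
        row["ligand_binding_altered"] = lig.binding_altered if lig else None
        inter = int_by_key.get(key)
        row["destabilizes_interaction"] = (
            inter.destabilizes_interaction if inter else None
        )
        rows.append(row)
    return pd.DataFrame(rows)
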