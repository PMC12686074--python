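"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates a saturation-mutagenesis feature space that splits
into a benign-like and a pathogenic-like population: independent Gaussian
features per population whose default means are the per-cluster means the
full-scale analysis reports (ESM1b -4.47 / -10.75, CADD 20.99 / 26.68,
closed-state ddG -2.05 / -6.36), population sizes 7559 / 14367, and
population-catalog flag probabilities reproducing 214 and 75 flagged
variants.  Known activating variants are planted as anchors in the
pathogenic population.  Toy structures and jittered coordinate ensembles
serve the geometry operations.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

from .scores import DEFAULT_FEATURES, FeatureMatrix
from .variants import AMINO_ACIDS, parse_variant_label


class SimulationError(ValueError):
    pass


#: Per-feature (mean, sd) for the benign-like and pathogenic-like
#: populations.  ESM1b, CADD and ddG_closed means are the reported
#: per-cluster means; the remaining features use plausible values on each
#: score's native scale with the damaging direction consistent with its
#: orientation.
DEFAULT_FEATURE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "CADD": {"benign": (20.99, 3.0), "pathogenic": (26.68, 3.0)},
    "AlphaMissense": {"benign": (0.25, 0.18), "pathogenic": (0.72, 0.18)},
    "ESM1b": {"benign": (-4.47, 3.0), "pathogenic": (-10.75, 3.0)},
    "PolyPhen2": {"benign": (0.30, 0.20), "pathogenic": (0.85, 0.20)},
    "SIFT": {"benign": (0.35, 0.12), "pathogenic": (0.05, 0.12)},
    "MutFunc": {"benign": (0.20, 0.15), "pathogenic": (0.60, 0.15)},
    "ClinPred": {"benign": (0.30, 0.20), "pathogenic": (0.80, 0.20)},
    "ddG_open": {"benign": (-1.00, 1.5), "pathogenic": (-3.50, 1.5)},
    "ddG_closed": {"benign": (-2.05, 2.0), "pathogenic": (-6.36, 2.0)},
}

#: Previously reported activating variants used as pathogenic anchors.
DEFAULT_ANCHORS = ("p.H596D", "p.A634D", "p.S703I", "p.C787F")


@dataclass
class SimConfig:
    """Two-population feature-matrix simulation parameters."""

    n_benign: int = 7559
    n_pathogenic: int = 14367
    feature_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FEATURE_PARAMS.items()}
    )
    flag_prob_benign: float = 214 / 7559
    flag_prob_pathogenic: float = 75 / 14367
    anchor_labels: tuple[str, ...] = DEFAULT_ANCHORS
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_benign < 1 or self.n_pathogenic < 1:
            raise SimulationError("population sizes must be >= 1")
        for feat, pops in self.feature_params.items():
            for pop, (mu, sd) in pops.items():
                if sd <= 0:
                    raise SimulationError(f"{feat}/{pop}: sd must be > 0")
        for p in (self.flag_prob_benign, self.flag_prob_pathogenic):
            if not 0.0 <= p <= 1.0:
                raise SimulationError("flag probabilities must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SimulationError("missing rate must be in [0, 1)")


@dataclass
class SimOutput:
    matrix: FeatureMatrix
    truth: pd.Series  # "benign" / "pathogenic" per variant
    flags: pd.Series  # catalog membership per variant
    anchors: list[str]
    manifest: dict


def _synthetic_labels(n: int, reserved: Sequence[str], rng: np.random.Generator) -> list[str]:
    """Unique synthetic variant labels p.<ref><pos><alt>, one position each,
    skipping positions used by reserved (anchor) labels."""
    taken = {parse_variant_label(lbl).position for lbl in reserved}
    labels = []
    pos = 1
    aas = np.array(list(AMINO_ACIDS))
    while len(labels) < n:
        if pos not in taken:
            ref, alt = rng.choice(20, size=2, replace=False)
            labels.append(f"p.{aas[ref]}{pos}{aas[alt]}")
        pos += 1
    return labels


def simulate_feature_matrix(config: Optional[SimConfig] = None) -> SimOutput:
    """Draw a two-population variants x features matrix.

    Features are independent Gaussians per population at the configured
    means/sds.  Catalog flags are Bernoulli per population.  Anchors are
    the first rows of the pathogenic population.  Missing cells (at
    ``missing_rate``) are median-imputed and masked, mirroring the
    assembly path.  Fully reproducible from the seed.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    nb, npath = config.n_benign, config.n_pathogenic
    n = nb + npath
    features = list(config.feature_params)

    anchors = list(config.anchor_labels[: npath])
    plain = _synthetic_labels(n - len(anchors), anchors, rng)
    # benign rows first, then pathogenic (anchors lead the pathogenic block)
    labels = plain[:nb] + anchors + plain[nb:]
    truth = pd.Series(
        ["benign"] * nb + ["pathogenic"] * npath, index=labels, name="truth"
    )

    values = np.empty((n, len(features)))
    for j, feat in enumerate(features):
        mu_b, sd_b = config.feature_params[feat]["benign"]
        mu_p, sd_p = config.feature_params[feat]["pathogenic"]
        values[:nb, j] = rng.normal(mu_b, sd_b, size=nb)
        values[nb:, j] = rng.normal(mu_p, sd_p, size=npath)

    mask = np.zeros((n, len(features)), dtype=bool)
    if config.missing_rate > 0:
        mask = rng.random((n, len(features))) < config.missing_rate
        mask &= mask.sum(axis=0) < n  # never blank a whole column
        for j in range(len(features)):
            col = values[:, j]
            med = float(np.median(col[~mask[:, j]]))
            col[mask[:, j]] = med

    flags = np.concatenate(
        [
            rng.random(nb) < config.flag_prob_benign,
            rng.random(npath) < config.flag_prob_pathogenic,
        ]
    )

    idx = pd.Index(labels, name="variant")
    matrix = FeatureMatrix(
        values=pd.DataFrame(values, index=idx, columns=features),
        mask=pd.DataFrame(mask, index=idx, columns=features),
        orientations={},
    )
    manifest = {
        "n_benign": nb,
        "n_pathogenic": npath,
        "features": features,
        "feature_params": {
            f: {p: list(v) for p, v in pops.items()}
            for f, pops in config.feature_params.items()
        },
        "flag_prob_benign": config.flag_prob_benign,
        "flag_prob_pathogenic": config.flag_prob_pathogenic,
        "missing_rate": config.missing_rate,
        "seed": config.seed,
        "anchors": anchors,
    }
    return SimOutput(
        matrix=matrix,
        truth=truth,
        flags=pd.Series(flags, index=idx, name="gnomad_reported"),
        anchors=anchors,
        manifest=manifest,
    )


def simulate_score_tables(sim: SimOutput, outdir: str | Path) -> dict[str, Path]:
    """Write one dialect-correct TSV per feature (masked cells omitted),
    plus catalog flags, anchors and the manifest.

    Reading the tables back through the score-ingestion path reconstructs
    the matrix exactly up to re-imputation of the masked cells.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if sim.matrix.n_variants == 0:
        raise SimulationError("empty variant set")
    paths: dict[str, Path] = {}
    for feat in sim.matrix.features:
        observed = ~sim.matrix.mask[feat]
        df = pd.DataFrame(
            {
                "variant": sim.matrix.values.index[observed],
                "value": sim.matrix.values.loc[observed, feat],
            }
        )
        # stability shifts use the ddG-table dialect
        if feat.startswith("ddG"):
            df = df.rename(columns={"value": "ddG"})
        p = outdir / f"{feat}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[feat] = p
    flags_path = outdir / "gnomad_flags.tsv"
    pd.DataFrame(
        {"variant": sim.flags.index, "gnomad_reported": sim.flags.astype(int)}
    ).to_csv(flags_path, sep="\t", index=False)
    paths["flags"] = flags_path
    anchors_path = outdir / "anchors.txt"
    anchors_path.write_text("\n".join(sim.anchors) + "\n")
    paths["anchors"] = anchors_path
    truth_path = outdir / "truth.tsv"
    pd.DataFrame({"variant": sim.truth.index, "truth": sim.truth}).to_csv(
        truth_path, sep="\t", index=False
    )
    paths["truth"] = truth_path
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(sim.manifest, indent=1))
    paths["manifest"] = manifest_path
    return paths


def simulate_query_panel(
    config: Optional[SimConfig] = None,
    pathogenic_labels: Sequence[str] = (
        "p.V464M",
        "p.P815S",
        "p.R879G",
        "p.N917D",
        "p.D1042Y",
    ),
    n_benign_like: int = 8,
    seed: int = 1,
) -> tuple[pd.DataFrame, pd.Series]:
    """A small query panel emulating a sequencing cohort: a handful of
    variants drawn from the pathogenic population (named after known
    activating candidates) among benign-like ones.

    Returns (features, truth) with truth in {"benign", "pathogenic"}.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    features = list(config.feature_params)
    rows, labels, truth = [], [], []
    for i in range(n_benign_like):
        rows.append(
            [rng.normal(*config.feature_params[f]["benign"]) for f in features]
        )
        labels.append(f"p.Q{2000 + i}L")
        truth.append("benign")
    for lbl in pathogenic_labels:
        rows.append(
            [rng.normal(*config.feature_params[f]["pathogenic"]) for f in features]
        )
        labels.append(lbl)
        truth.append("pathogenic")
    idx = pd.Index(labels, name="variant")
    return (
        pd.DataFrame(rows, index=idx, columns=features),
        pd.Series(truth, index=idx, name="truth"),
    )


# ---------------------------------------------------------------------------
# toy structures and ensembles


@dataclass
class ToyStructureSpec:
    """Two residue groups ("domains") separated by a configurable gap along
    y, with an optional ligand at a known centroid."""

    n_res_a: int = 5
    n_res_b: int = 5
    gap: float = 4.0
    spacing: float = 3.8
    start_res_a: int = 1
    start_res_b: int = 101
    ligand_center: Optional[tuple[float, float, float]] = None
    ligand_name: str = "ADP"

    def __post_init__(self) -> None:
        if self.n_res_a < 1 or self.n_res_b < 1:
            raise SimulationError("need >= 1 residue per group")
        if self.gap <= 0:
            raise SimulationError("gap must be positive")


# per-residue heavy-atom offsets in the (x, z) plane; y stays the group's
# plane so the inter-group minimum distance equals the configured gap
_RES_OFFSETS = (
    ("N", "N", (-0.9, 0.4)),
    ("CA", "C", (0.0, 0.0)),
    ("C", "C", (0.9, 0.4)),
    ("O", "O", (1.1, 1.5)),
    ("CB", "C", (0.0, -1.3)),
)


def _add_residue(chain: gemmi.Chain, num: int, name: str, atoms) -> None:
    res = gemmi.Residue()
    res.name = name
    res.seqid = gemmi.SeqId(num, " ")
    for atom_name, element, (x, y, z) in atoms:
        a = gemmi.Atom()
        a.name = atom_name
        a.element = gemmi.Element(element)
        a.pos = gemmi.Position(x, y, z)
        a.occ = 1.0
        res.add_atom(a)
    chain.add_residue(res)


def simulate_toy_structure(
    spec: Optional[ToyStructureSpec] = None, path: str | Path = "toy.pdb"
) -> Path:
    """Write a deterministic two-domain toy PDB (plus optional ligand)."""
    spec = spec or ToyStructureSpec()
    st = gemmi.Structure()
    st.name = "toy"
    model = gemmi.Model(1)
    chain = gemmi.Chain("A")
    for i in range(spec.n_res_a):
        x0 = i * spec.spacing
        atoms = [
            (nm, el, (x0 + dx, 0.0, dz)) for nm, el, (dx, dz) in _RES_OFFSETS
        ]
        _add_residue(chain, spec.start_res_a + i, "ALA", atoms)
    for i in range(spec.n_res_b):
        x0 = i * spec.spacing
        atoms = [
            (nm, el, (x0 + dx, spec.gap, dz)) for nm, el, (dx, dz) in _RES_OFFSETS
        ]
        _add_residue(chain, spec.start_res_b + i, "ALA", atoms)
    if spec.ligand_center is not None:
        cx, cy, cz = spec.ligand_center
        # three atoms whose centroid is exactly the requested center
        lig_atoms = [
            ("C1", "C", (cx + 1.0, cy, cz)),
            ("C2", "C", (cx - 0.5, cy + 0.866, cz)),
            ("C3", "C", (cx - 0.5, cy - 0.866, cz)),
        ]
        _add_residue(chain, 900, spec.ligand_name, lig_atoms)
    model.add_chain(chain)
    st.add_model(model)
    path = Path(path)
    st.write_pdb(str(path))
    return path


def simulate_single_residue_structure(
    ca_position: tuple[float, float, float],
    res_num: int = 1,
    path: str | Path = "residue.pdb",
    ligand_center: Optional[tuple[float, float, float]] = None,
    ligand_name: str = "ADP",
) -> Path:
    """A one-residue (glycine, CA-only) structure for pocket-distance
    fixtures; the CA is the residue reference point by fallback."""
    st = gemmi.Structure()
    st.name = "residue"
    model = gemmi.Model(1)
    chain = gemmi.Chain("A")
    _add_residue(chain, res_num, "GLY", [("CA", "C", ca_position)])
    if ligand_center is not None:
        cx, cy, cz = ligand_center
        lig_atoms = [
            ("C1", "C", (cx + 1.0, cy, cz)),
            ("C2", "C", (cx - 0.5, cy + 0.866, cz)),
            ("C3", "C", (cx - 0.5, cy - 0.866, cz)),
        ]
        _add_residue(chain, 900, ligand_name, lig_atoms)
    model.add_chain(chain)
    st.add_model(model)
    path = Path(path)
    st.write_pdb(str(path))
    return path


def simulate_ensemble(
    base_path: str | Path,
    jitter_sd: float,
    n_frames: int,
    seed: int = 0,
    path: str | Path = "ensemble.pdb",
) -> Path:
    """Multi-model PDB: each frame is the base structure plus iid Gaussian
    jitter (sd per coordinate axis).  With many frames the per-residue RMSF
    converges to jitter_sd * sqrt(3)."""
    if n_frames < 2:
        raise SimulationError("need >= 2 frames")
    if jitter_sd < 0:
        raise SimulationError("jitter sd must be >= 0")
    base = gemmi.read_structure(str(base_path))
    if len(base) == 0:
        raise SimulationError(f"no model in {base_path}")
    rng = np.random.default_rng(seed)
    st = gemmi.Structure()
    st.name = "ensemble"
    template = base[0]
    for f in range(n_frames):
        model = gemmi.Model(f + 1)
        for chain in template:
            new_chain = gemmi.Chain(chain.name)
            for res in chain:
                atoms = []
                for atom in res:
                    dx, dy, dz = rng.normal(0.0, jitter_sd, size=3)
                    atoms.append(
                        (
                            atom.name,
                            atom.element.name,
                            (atom.pos.x + dx, atom.pos.y + dy, atom.pos.z + dz),
                        )
                    )
                _add_residue(new_chain, res.seqid.num, res.name, atoms)
            model.add_chain(new_chain)
        st.add_model(model)
    path = Path(path)
    st.write_pdb(str(path))
    return path
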