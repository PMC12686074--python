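"""Geometry on atomic models: superposition, interfaces, contacts,
pocket distances and ensemble fluctuation.

Models come from PDB or mmCIF files (parsed with gemmi).  Hydrogens are
ignored throughout: the models these operations target are predicted
structures whose heavy-atom positions are the reliable signal.  Hydrogen-
bond capability is therefore a donor/acceptor heavy-atom (N/O) distance
criterion without angle terms — a deliberate proxy.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class AtomRecord:
    chain: str
    res_seq: int
    res_name: str
    atom_name: str
    element: str
    pos: tuple[float, float, float]

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class StructureModel:
    """One conformer: a flat list of atom records plus lookup helpers."""

    model_id: str
    atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise GeometryError(f"model {self.model_id!r} has no atoms")
        for a in self.atoms:
            if not np.all(np.isfinite(a.pos)):
                raise GeometryError(f"non-finite coordinates in {self.model_id!r}")

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def coords(self, atoms: Optional[Sequence[AtomRecord]] = None) -> np.ndarray:
        atoms = self.atoms if atoms is None else atoms
        return np.array([a.pos for a in atoms], dtype=float)

    def residue_atoms(
        self, res_seq: int, chain: Optional[str] = None, heavy_only: bool = True
    ) -> list[AtomRecord]:
        out = [
            a
            for a in self.atoms
            if a.res_seq == res_seq
            and (chain is None or a.chain == chain)
            and (not heavy_only or not a.is_hydrogen)
        ]
        return out

    def residue_numbers(self, chain: Optional[str] = None) -> list[int]:
        seen = []
        prev = None
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            if (a.chain, a.res_seq) != prev:
                seen.append(a.res_seq)
                prev = (a.chain, a.res_seq)
        return sorted(set(seen))

    def ca_coords(self) -> dict[tuple[str, int], np.ndarray]:
        return {
            (a.chain, a.res_seq): np.array(a.pos)
            for a in self.atoms
            if a.atom_name == "CA"
        }


def _atoms_from_gemmi_model(model: gemmi.Model) -> list[AtomRecord]:
    atoms = []
    for chain in model:
        for res in chain:
            for atom in res:
                atoms.append(
                    AtomRecord(
                        chain=chain.name,
                        res_seq=res.seqid.num,
                        res_name=res.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        pos=(atom.pos.x, atom.pos.y, atom.pos.z),
                    )
                )
    return atoms


def load_structure(path: str | Path) -> list[StructureModel]:
    """Parse a PDB/mmCIF file into an ensemble of :class:`StructureModel`.

    Single-model files yield a one-element list; NMR/trajectory-style
    multi-model files yield one entry per MODEL block.
    """
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on parse failure
        raise GeometryError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise GeometryError(f"no models in {path}")
    models = []
    for m in st:
        atoms = _atoms_from_gemmi_model(m)
        if not atoms:
            raise GeometryError(f"empty model in {path}")
        models.append(StructureModel(model_id=str(m.num), atoms=atoms))
    return models


@dataclass
class SuperpositionResult:
    rmsd: float
    n_atoms_used: int
    n_pruned: int
    rotation: np.ndarray  # 3x3
    translation: np.ndarray  # 3


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of P onto Q; returns (R, t, rmsd)."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return R, t, rmsd


def superpose(
    model_a: StructureModel,
    model_b: StructureModel,
    atom_selector: str = "CA",
    prune_cutoff: Optional[float] = None,
    max_rounds: int = 50,
) -> SuperpositionResult:
    """Rigid-body superposition of A onto B by paired atoms.

    Atoms are paired by (chain, residue number, atom name); the selector
    restricts to one atom name ("CA" default; "*" keeps all).  With
    ``prune_cutoff`` set, pairs whose residual exceeds the cutoff are
    iteratively dropped (worst first) and the fit repeated until stable.
    """
    def index(m: StructureModel):
        return {
            (a.chain, a.res_seq, a.atom_name): np.array(a.pos)
            for a in m.atoms
            if (atom_selector == "*" or a.atom_name == atom_selector)
            and not a.is_hydrogen
        }

    ia, ib = index(model_a), index(model_b)
    keys = sorted(set(ia) & set(ib))
    if len(keys) < 3:
        raise GeometryError(f"only {len(keys)} paired atoms; need >= 3")
    P = np.array([ia[k] for k in keys])
    Q = np.array([ib[k] for k in keys])
    n_initial = len(keys)
    active = np.ones(n_initial, dtype=bool)
    R, t, rmsd = _kabsch(P, Q)
    if prune_cutoff is not None:
        for _ in range(max_rounds):
            resid = np.linalg.norm((P @ R.T + t) - Q, axis=1)
            over = active & (resid > prune_cutoff)
            if not over.any() or active.sum() <= 3:
                break
            worst = np.argmax(np.where(over, resid, -np.inf))
            active[worst] = False
            R, t, rmsd = _kabsch(P[active], Q[active])
    n_used = int(active.sum())
    # degenerate (collinear) atom sets have a rank-deficient covariance
    if np.linalg.matrix_rank(P[active] - P[active].mean(axis=0), tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) atom set for superposition")
    return SuperpositionResult(
        rmsd=rmsd,
        n_atoms_used=n_used,
        n_pruned=n_initial - n_used,
        rotation=R,
        translation=t,
    )


def interface_residues(
    model: StructureModel,
    range_a: tuple[int, int],
    range_b: tuple[int, int],
    cutoff: float = 5.0,
) -> list[tuple[int, int, float]]:
    """Residue pairs across two disjoint residue ranges with any heavy-atom
    distance <= cutoff; each pair reported once as (res_a, res_b, min_dist).
    """
    a0, a1 = range_a
    b0, b1 = range_b
    if max(a0, b0) <= min(a1, b1):
        raise GeometryError(f"overlapping ranges {range_a} and {range_b}")
    heavy = model.heavy_atoms()
    atoms_a = [a for a in heavy if a0 <= a.res_seq <= a1]
    atoms_b = [a for a in heavy if b0 <= a.res_seq <= b1]
    if not atoms_a or not atoms_b:
        return []
    xa, xb = model.coords(atoms_a), model.coords(atoms_b)
    tree = cKDTree(xb)
    pairs: dict[tuple[int, int], float] = {}
    for i, atom in enumerate(atoms_a):
        for j in tree.query_ball_point(xa[i], cutoff):
            d = float(np.linalg.norm(xa[i] - xb[j]))
            key = (atom.res_seq, atoms_b[j].res_seq)
            if d <= cutoff and d < pairs.get(key, np.inf):
                pairs[key] = d
    return sorted((ra, rb, d) for (ra, rb), d in pairs.items())


@dataclass
class ContactReport:
    focal_residue: int
    partners: list[tuple[int, float, bool]]  # (res, min heavy dist, hbond_capable)


def residue_contacts(
    model: StructureModel,
    position: int,
    cutoff_hbond: float = 3.5,
    cutoff_contact: float = 5.0,
    chain: Optional[str] = None,
) -> ContactReport:
    """Contacts of one residue: partners with min heavy-atom distance <=
    ``cutoff_contact``, sorted by distance; ``hbond_capable`` when an N/O
    pair sits within ``cutoff_hbond``."""
    focal = model.residue_atoms(position, chain=chain)
    if not focal:
        raise GeometryError(f"residue {position} not in model")
    others: dict[int, list[AtomRecord]] = {}
    for a in model.heavy_atoms():
        if a.res_seq != position:
            others.setdefault(a.res_seq, []).append(a)
    xf = model.coords(focal)
    partners = []
    for res, atoms in others.items():
        xo = model.coords(atoms)
        d = np.sqrt(((xf[:, None, :] - xo[None, :, :]) ** 2).sum(axis=2))
        dmin = float(d.min())
        if dmin <= cutoff_contact:
            hb = False
            for i, fa in enumerate(focal):
                for j, oa in enumerate(atoms):
                    if (
                        fa.element in ("N", "O")
                        and oa.element in ("N", "O")
                        and d[i, j] <= cutoff_hbond
                    ):
                        hb = True
            partners.append((res, dmin, hb))
    partners.sort(key=lambda p: (p[1], p[0]))
    return ContactReport(focal_residue=position, partners=partners)


@dataclass
class PocketSpec:
    """A binding pocket defined by the centroid of a set of heavy atoms
    (typically a bound ligand)."""

    center: np.ndarray
    defining_atoms: list[AtomRecord]


def pocket_center(
    model: StructureModel,
    ligand_id: Optional[str] = None,
    residue_set: Optional[Iterable[int]] = None,
) -> PocketSpec:
    """Pocket center = centroid of the ligand's (or residue set's) heavy atoms."""
    if ligand_id is not None:
        atoms = [a for a in model.heavy_atoms() if a.res_name == ligand_id]
        if not atoms:
            raise GeometryError(f"ligand {ligand_id!r} absent from model")
    elif residue_set is not None:
        wanted = set(residue_set)
        atoms = [a for a in model.heavy_atoms() if a.res_seq in wanted]
        if not atoms:
            raise GeometryError("no atoms in the pocket residue set")
    else:
        raise GeometryError("give a ligand id or a residue set")
    coords = model.coords(atoms)
    return PocketSpec(center=coords.mean(axis=0), defining_atoms=atoms)


def sidechain_centroid(model: StructureModel, position: int) -> np.ndarray:
    """Heavy-atom centroid of the side chain (CB outward); CA fallback for
    glycine or missing side chains."""
    backbone = {"N", "CA", "C", "O", "OXT"}
    atoms = [
        a for a in model.residue_atoms(position) if a.atom_name not in backbone
    ]
    if not atoms:
        atoms = [a for a in model.residue_atoms(position) if a.atom_name == "CA"]
        if not atoms:
            raise GeometryError(f"residue {position} has no usable atoms")
    return model.coords(atoms).mean(axis=0)


def distance_to_pocket(
    model: StructureModel, position: int, pocket: PocketSpec
) -> float:
    """Distance (A) from a residue's side-chain centroid to the pocket center."""
    return float(np.linalg.norm(sidechain_centroid(model, position) - pocket.center))


def ensemble_rmsf(
    ensemble: Sequence[StructureModel],
    superpose_frames: bool = True,
) -> dict[tuple[str, int], float]:
    """Per-residue RMSF over an ensemble, on CA atoms.

    RMSF_i = sqrt(mean_t |r_i(t) - mean_t r_i|^2).  With
    ``superpose_frames`` each frame is first rigidly fitted to frame 1 on
    shared CA atoms; disable it to fluctuate in the file's raw frame,
    treating each structure's coordinates as already aligned.
    """
    if len(ensemble) < 2:
        raise GeometryError("need an ensemble of >= 2 conformations")
    cas = [m.ca_coords() for m in ensemble]
    keys = sorted(set(cas[0]).intersection(*cas[1:]))
    if set(cas[0]) != set(keys) or any(set(c) != set(cas[0]) for c in cas):
        raise GeometryError("inconsistent residue sets across frames")
    if not keys:
        raise GeometryError("no shared CA atoms across frames")
    ref = np.array([cas[0][k] for k in keys])
    stacks = []
    for c in cas:
        X = np.array([c[k] for k in keys])
        if superpose_frames and len(keys) >= 3:
            R, t, _ = _kabsch(X, ref)
            X = X @ R.T + t
        stacks.append(X)
    traj = np.stack(stacks)  # frames x residues x 3
    mean = traj.mean(axis=0)
    sq = ((traj - mean) ** 2).sum(axis=2).mean(axis=0)
    rmsf = np.sqrt(sq)
    return {k: float(r) for k, r in zip(keys, rmsf)}
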