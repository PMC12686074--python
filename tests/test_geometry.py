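"""Superposition, interfaces, contacts, pocket distances, ensemble RMSF."""
import numpy as np
import pytest

import varstate as vs
from varstate.geometry import AtomRecord, GeometryError, StructureModel


def _random_rotation(rng):
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


def _transformed(model, R, t):
    atoms = [
        AtomRecord(
            a.chain,
            a.res_seq,
            a.res_name,
            a.atom_name,
            a.element,
            tuple(R @ np.array(a.pos) + t),
        )
        for a in model.atoms
    ]
    return StructureModel("moved", atoms)


def test_load_minimal_pdb(tmp_path):
    p = tmp_path / "min.pdb"
    p.write_text(
        "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
        "ATOM      2  CA  ALA A   1       1.450   0.000   0.000  1.00  0.00           C\n"
        "ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C\n"
        "END\n"
    )
    (model,) = vs.load_structure(p)
    assert len(model.atoms) == 3
    assert model.atoms[0].chain == "A"
    assert model.residue_numbers() == [1]


def test_load_multimodel_yields_ensemble(tmp_path):
    base = vs.simulate_toy_structure(vs.ToyStructureSpec(), tmp_path / "b.pdb")
    ens_path = vs.simulate_ensemble(base, jitter_sd=0.1, n_frames=5, seed=0,
                                    path=tmp_path / "e.pdb")
    ens = vs.load_structure(ens_path)
    assert len(ens) == 5
    assert len(ens[0].atoms) == len(ens[4].atoms)


def test_load_mmcif_matches_pdb(tmp_path):
    import gemmi

    pdb_path = vs.simulate_toy_structure(vs.ToyStructureSpec(), tmp_path / "t.pdb")
    st = gemmi.read_structure(str(pdb_path))
    st.setup_entities()
    cif_path = tmp_path / "t.cif"
    st.make_mmcif_document().write_file(str(cif_path))
    m_pdb = vs.load_structure(pdb_path)[0]
    m_cif = vs.load_structure(cif_path)[0]
    np.testing.assert_allclose(m_pdb.coords(), m_cif.coords(), atol=1e-3)


def test_load_rejects_garbage(tmp_path):
    p = tmp_path / "x.pdb"
    p.write_text("this is not a structure\n")
    with pytest.raises(GeometryError):
        vs.load_structure(p)


def test_superpose_identity(toy_structure):
    res = vs.superpose(toy_structure, toy_structure)
    assert res.rmsd == pytest.approx(0.0, abs=1e-12)
    assert res.n_pruned == 0


def test_superpose_rigid_invariance(toy_structure):
    rng = np.random.default_rng(0)
    for _ in range(5):
        R = _random_rotation(rng)
        t = rng.normal(scale=10, size=3)
        moved = _transformed(toy_structure, R, t)
        res = vs.superpose(toy_structure, moved, atom_selector="*")
        assert res.rmsd < 1e-6


def test_superpose_pruning_removes_outlier(toy_structure):
    rng = np.random.default_rng(1)
    R, t = _random_rotation(rng), rng.normal(size=3)
    moved = _transformed(toy_structure, R, t)
    # displace one CA far from its true position
    atoms = list(moved.atoms)
    for i, a in enumerate(atoms):
        if a.atom_name == "CA":
            atoms[i] = AtomRecord(
                a.chain, a.res_seq, a.res_name, a.atom_name, a.element,
                (a.pos[0] + 30.0, a.pos[1], a.pos[2]),
            )
            break
    outlier = StructureModel("outlier", atoms)
    res = vs.superpose(toy_structure, outlier, prune_cutoff=2.0)
    assert res.n_pruned == 1
    assert res.rmsd < 1e-6
    assert res.n_atoms_used + res.n_pruned == 10  # initial CA pairing count


def test_superpose_noise_rmsd_matches_monte_carlo_oracle(toy_structure):
    """With iid Gaussian noise (sd per axis) on N paired atoms the expected
    post-fit RMSD is estimated by an independent Monte-Carlo oracle."""
    rng = np.random.default_rng(2)
    sigma = 0.3
    P = toy_structure.coords(
        [a for a in toy_structure.atoms if a.atom_name == "CA"]
    )
    from varstate.geometry import _kabsch

    def trial(r):
        Q = P + r.normal(0, sigma, size=P.shape)
        return _kabsch(P, Q)[2]

    oracle = np.mean([trial(rng) for _ in range(300)])
    measured = []
    rng2 = np.random.default_rng(7)
    for _ in range(100):
        noisy_atoms = []
        for a in toy_structure.atoms:
            jitter = rng2.normal(0, sigma, size=3) if a.atom_name == "CA" else (0, 0, 0)
            noisy_atoms.append(
                AtomRecord(a.chain, a.res_seq, a.res_name, a.atom_name, a.element,
                           tuple(np.array(a.pos) + np.array(jitter)))
            )
        res = vs.superpose(toy_structure, StructureModel("n", noisy_atoms))
        measured.append(res.rmsd)
    assert np.mean(measured) == pytest.approx(oracle, rel=0.05)


def test_superpose_too_few_pairs():
    atoms = [
        AtomRecord("A", i, "GLY", "CA", "C", (float(i), 0.0, 0.0)) for i in range(2)
    ]
    m = StructureModel("m", atoms)
    with pytest.raises(GeometryError, match="paired"):
        vs.superpose(m, m)


def test_superpose_collinear_flagged():
    atoms = [
        AtomRecord("A", i, "GLY", "CA", "C", (float(i), 0.0, 0.0)) for i in range(5)
    ]
    m = StructureModel("m", atoms)
    with pytest.raises(GeometryError, match="collinear"):
        vs.superpose(m, m)


def brute_force_interface(model, range_a, range_b, cutoff):
    pairs = {}
    heavy = model.heavy_atoms()
    for a in heavy:
        if not (range_a[0] <= a.res_seq <= range_a[1]):
            continue
        for b in heavy:
            if not (range_b[0] <= b.res_seq <= range_b[1]):
                continue
            d = float(np.linalg.norm(np.array(a.pos) - np.array(b.pos)))
            key = (a.res_seq, b.res_seq)
            if d <= cutoff and d < pairs.get(key, np.inf):
                pairs[key] = d
    return sorted((ra, rb, d) for (ra, rb), d in pairs.items())


def test_interface_matches_brute_force(toy_structure):
    got = vs.interface_residues(toy_structure, (1, 5), (101, 105), cutoff=5.0)
    expected = brute_force_interface(toy_structure, (1, 5), (101, 105), 5.0)
    assert [(a, b) for a, b, _ in got] == [(a, b) for a, b, _ in expected]
    np.testing.assert_allclose([d for *_, d in got], [d for *_, d in expected])
    assert got  # helices 4 A apart do touch at a 5 A cutoff


def test_interface_symmetric(toy_structure):
    ab = vs.interface_residues(toy_structure, (1, 5), (101, 105))
    ba = vs.interface_residues(toy_structure, (101, 105), (1, 5))
    assert {(a, b) for a, b, _ in ab} == {(b, a) for a, b, _ in ba}


def test_interface_empty_at_large_gap(tmp_path):
    p = vs.simulate_toy_structure(vs.ToyStructureSpec(gap=20.0), tmp_path / "far.pdb")
    m = vs.load_structure(p)[0]
    assert vs.interface_residues(m, (1, 5), (101, 105), cutoff=5.0) == []


def test_interface_rejects_overlapping_ranges(toy_structure):
    with pytest.raises(GeometryError, match="overlap"):
        vs.interface_residues(toy_structure, (1, 10), (5, 20))


def test_contacts_hbond_criterion():
    atoms = [
        AtomRecord("A", 1, "SER", "N", "N", (0.0, 0.0, 0.0)),
        AtomRecord("A", 1, "SER", "CA", "C", (1.5, 0.0, 0.0)),
        AtomRecord("A", 2, "SER", "O", "O", (0.0, 2.9, 0.0)),
        AtomRecord("A", 3, "ALA", "CB", "C", (1.5, 2.9, 0.0)),
    ]
    m = StructureModel("m", atoms)
    rep = vs.residue_contacts(m, 1)
    partners = {res: (d, hb) for res, d, hb in rep.partners}
    assert partners[2][1] is True       # N...O at 2.9 A
    assert partners[3][1] is False      # C...C at 2.9 A: contact only
    assert partners[3][0] == pytest.approx(2.9)
    # sorted ascending by distance
    assert [d for _, d, _ in rep.partners] == sorted(d for _, d, _ in rep.partners)
    with pytest.raises(GeometryError):
        vs.residue_contacts(m, 99)


def test_pocket_distance_pythagorean(tmp_path):
    p = vs.simulate_single_residue_structure(
        (3.0, 4.0, 0.0), path=tmp_path / "r.pdb", ligand_center=(0.0, 0.0, 0.0)
    )
    m = vs.load_structure(p)[0]
    pocket = vs.pocket_center(m, ligand_id="ADP")
    np.testing.assert_allclose(pocket.center, [0.0, 0.0, 0.0], atol=1e-6)
    assert vs.distance_to_pocket(m, 1, pocket) == pytest.approx(5.0, abs=1e-6)


def test_pocket_center_from_residue_set(toy_structure):
    pocket = vs.pocket_center(toy_structure, residue_set=[1, 2])
    atoms = [a for a in toy_structure.heavy_atoms() if a.res_seq in (1, 2)]
    oracle = np.mean([a.pos for a in atoms], axis=0)
    np.testing.assert_allclose(pocket.center, oracle, atol=1e-9)
    d = vs.distance_to_pocket(toy_structure, 1, pocket)
    assert d >= 0


def test_pocket_missing_ligand(toy_structure):
    with pytest.raises(GeometryError, match="absent"):
        vs.pocket_center(toy_structure, ligand_id="ATP")


def test_rmsf_static_ensemble_is_zero(tmp_path):
    base = vs.simulate_toy_structure(vs.ToyStructureSpec(), tmp_path / "b.pdb")
    ens_path = vs.simulate_ensemble(base, jitter_sd=0.0, n_frames=4, seed=0,
                                    path=tmp_path / "static.pdb")
    prof = vs.ensemble_rmsf(vs.load_structure(ens_path))
    assert all(v == pytest.approx(0.0, abs=1e-9) for v in prof.values())


def test_rmsf_alternating_displacement_closed_form():
    """Residue j displaced +/- d alternately along one axis has RMSF d."""
    d = 0.7
    frames = []
    for sign in (+1, -1, +1, -1):
        atoms = [
            AtomRecord("A", i, "GLY", "CA", "C",
                       (i * 3.8, sign * d if i == 2 else 0.0, 0.0))
            for i in range(5)
        ]
        frames.append(StructureModel("f", atoms))
    prof = vs.ensemble_rmsf(frames, superpose_frames=False)
    assert prof[("A", 2)] == pytest.approx(d)
    assert prof[("A", 0)] == pytest.approx(0.0, abs=1e-12)


def test_rmsf_gaussian_jitter_matches_closed_form(tmp_path):
    """iid jitter of sd sigma per axis gives RMSF -> sigma*sqrt(3)."""
    sigma = 0.4
    base = vs.simulate_toy_structure(vs.ToyStructureSpec(n_res_a=8, n_res_b=8),
                                     tmp_path / "b.pdb")
    ens_path = vs.simulate_ensemble(base, jitter_sd=sigma, n_frames=500, seed=5,
                                    path=tmp_path / "j.pdb")
    prof = vs.ensemble_rmsf(vs.load_structure(ens_path), superpose_frames=False)
    mean_rmsf = np.mean(list(prof.values()))
    assert mean_rmsf == pytest.approx(sigma * np.sqrt(3), rel=0.05)


def test_rmsf_rejects_inconsistent_frames():
    a = [AtomRecord("A", i, "GLY", "CA", "C", (i * 3.8, 0, 0)) for i in range(4)]
    b = [AtomRecord("A", i, "GLY", "CA", "C", (i * 3.8, 0, 0)) for i in range(3)]
    with pytest.raises(GeometryError, match="inconsistent"):
        vs.ensemble_rmsf([StructureModel("a", a), StructureModel("b", b)])
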