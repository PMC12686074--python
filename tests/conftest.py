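import numpy as np
import pytest

import varstate as vs


@pytest.fixture(scope="session")
def small_sim():
    """A small, well-separated two-population simulation (shared, read-only)."""
    config = vs.SimConfig(n_benign=200, n_pathogenic=400, seed=11)
    return config, vs.simulate_feature_matrix(config)


@pytest.fixture()
def toy_protein():
    return vs.ProteinSequence("toy", "ACDEFGHIKL")


@pytest.fixture(scope="session")
def toy_structure(tmp_path_factory):
    """Two 5-residue groups 4 A apart with a ligand centered at the origin."""
    path = tmp_path_factory.mktemp("struct") / "toy.pdb"
    vs.simulate_toy_structure(
        vs.ToyStructureSpec(gap=4.0, ligand_center=(0.0, 0.0, 0.0)), path
    )
    return vs.load_structure(path)[0]


def brute_force_knn(X, keys, k):
    """Independent O(N^2) nearest-neighbor oracle with the documented
    tie rule (earlier row order wins)."""
    n = len(X)
    out = {}
    for i in range(n):
        dists = []
        for j in range(n):
            if j != i:
                dists.append((float(np.linalg.norm(X[i] - X[j])), j))
        dists.sort()
        out[keys[i]] = [keys[j] for _, j in dists[: min(k, n - 1)]]
    return out
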