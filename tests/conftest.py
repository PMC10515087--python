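import numpy as np
import pytest

from thermevol.phylo import Phylogeny, parse_newick
from thermevol.simulate import simulate_yule_tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def two_tip_tree():
    return parse_newick("(A:1,B:3);")


def star_tree(n: int, depth: float = 1.0) -> Phylogeny:
    labels = [f"s{i:03d}" for i in range(n)]
    return parse_newick(
        "(" + ",".join(f"{l}:{depth}" for l in labels) + ");")


@pytest.fixture
def yule_factory():
    def make(n, seed, birth_rate=1.0):
        return simulate_yule_tree(n, birth_rate, seed)
    return make


def brute_force_mrca_depths(tree: Phylogeny) -> np.ndarray:
    """O(n^2) oracle: pairwise MRCA depth via explicit ancestor paths."""
    depth = tree.depths()
    leaf_order = tree._leaf_order()
    paths = []
    for v in leaf_order:
        anc = []
        u = int(v)
        while u >= 0:
            anc.append(u)
            u = int(tree.parent[u])
        paths.append(anc)
    n = len(leaf_order)
    C = np.zeros((n, n))
    for i in range(n):
        C[i, i] = depth[leaf_order[i]]
        for j in range(i + 1, n):
            shared = set(paths[i]) & set(paths[j])
            m = max(depth[u] for u in shared)
            C[i, j] = C[j, i] = m
    return C
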