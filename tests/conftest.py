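import numpy as np
import pytest

import floralevo as fe


@pytest.fixture
def five_taxon_tree():
    """Fixed 5-taxon fixture used for frozen cross-package oracle values."""
    return fe.parse_newick("((A:1.2,B:0.7):0.6,((C:0.9,D:1.4):0.3,E:2.0):0.4);")


@pytest.fixture
def five_taxon_values():
    return {"A": 1.3, "B": 0.2, "C": -0.5, "D": 2.2, "E": 0.9}


def random_tree(seed: int, n_tips: int = 8) -> fe.PhyloTree:
    return fe.sim_tree(n_tips, birth_rate=1.0, seed=seed)


def laplacian_states_oracle(tree, tip_values):
    """Joint-ML ancestral states by solving the graph-Laplacian normal
    equations (minimize sum of squared length-weighted edge changes with the
    tips clamped) — an independent route to the GLS states."""
    internals = list(tree.internal_nodes)
    idx = {n: i for i, n in enumerate(internals)}
    n = len(internals)
    A = np.zeros((n, n))
    b = np.zeros(n)
    for parent, child, ln in tree.edge_list():
        w = 1.0 / max(ln, 1e-8)
        i = idx[parent]
        if child in idx:
            j = idx[child]
            A[i, i] += w
            A[j, j] += w
            A[i, j] -= w
            A[j, i] -= w
        else:
            A[i, i] += w
            b[i] += w * tip_values[child]
    return dict(zip(internals, np.linalg.solve(A, b)))


def two_distant_clades(tree, lo=3, hi=5, min_gap=4):
    """A disjoint pair of moderate clades whose MRCA covers >= min_gap
    background tips (so one shift cannot explain both)."""
    subtree = {}
    for nd in tree.internal_nodes:
        if nd == tree.root:
            continue
        s = {t for t in tree.tips if nd in ([t] + tree.ancestors(t))}
        if lo <= len(s) <= hi:
            subtree[nd] = s
    best = None
    for n1, s1 in subtree.items():
        for n2, s2 in subtree.items():
            if n1 >= n2 or (s1 & s2):
                continue
            if n1 in tree.ancestors(n2) or n2 in tree.ancestors(n1):
                continue
            m = tree.mrca(n1, n2)
            cover = sum(1 for t in tree.tips if m in ([t] + tree.ancestors(t)))
            gap = cover - len(s1) - len(s2)
            if gap >= min_gap and (best is None or gap > best[0]):
                best = (gap, n1, n2)
    return None if best is None else (best[1], best[2])
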