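"""Maximum-likelihood ancestral state reconstruction under Brownian motion.

The model: a continuous trait evolves as a Brownian random walk with rate
sigma^2 from an unknown root state. Tip values are then jointly multivariate
normal with mean ``root_state * 1`` and covariance ``sigma2 * C``, where
``C[i, j]`` is the shared root-to-MRCA path length of tips i and j.

The ML root state is the GLS mean, sigma^2 has the usual closed form, and the
ML internal states equal the conditional expectations ``E[state | tips]``,
which do not depend on sigma^2. Branch lengths of zero are floored at a small
epsilon so the covariance stays positive definite; flooring is reported on
the fit object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .tree import PhyloTree, prune_tips, diploid_view
from .tables import PolyploidRegistry, TRAIT_COLUMNS

__all__ = [
    "BMFit",
    "ReconstructionResult",
    "ProgenitorReconstruction",
    "bm_loglik",
    "fit_bm_asr",
    "interpolate_on_branch",
    "reconstructed_progenitors",
]

#: floor applied to zero / near-zero branch lengths (tree units)
LENGTH_EPS = 1e-8


@dataclass(frozen=True)
class BMFit:
    sigma2: float
    root_state: float
    loglik: float
    degenerate: bool = False  # tip values had zero variance
    floored_edges: int = 0  # edges whose length was floored at LENGTH_EPS


@dataclass(frozen=True)
class ReconstructionResult:
    node_states: dict[str, float]  # every internal node -> ML state
    fit: BMFit


@dataclass(frozen=True)
class ProgenitorReconstruction:
    """Reconstructed progenitor trait vectors at an allopolyploid's origin."""

    accession: str
    traits: tuple[str, ...]
    maternal_state: np.ndarray
    paternal_state: np.ndarray

    @property
    def reconstructed_midpoint(self) -> np.ndarray:
        return 0.5 * (self.maternal_state + self.paternal_state)


def _floored_vcv(tree: PhyloTree) -> tuple[np.ndarray, list[str], int]:
    lengths = {n: tree.length[n] for n in tree.parent}
    floored = sum(
        1 for n, ln in lengths.items() if n != tree.root and 0 <= ln < LENGTH_EPS
    )
    if floored:
        edges = [
            (p, c, max(ln, LENGTH_EPS)) for p, c, ln in tree.edge_list()
        ]
        tree = PhyloTree.from_edges(tree.root, edges)
    C, taxa = tree.vcv()
    return C, taxa, floored


def _as_vector(tip_values, taxa: list[str]) -> np.ndarray:
    if isinstance(tip_values, pd.Series):
        missing = [t for t in taxa if t not in tip_values.index]
        if missing:
            raise ValueError(f"missing tip values for: {missing}")
        return tip_values.reindex(taxa).to_numpy(dtype=float)
    tip_values = dict(tip_values)
    missing = [t for t in taxa if t not in tip_values]
    if missing:
        raise ValueError(f"missing tip values for: {missing}")
    return np.array([float(tip_values[t]) for t in taxa])


def bm_loglik(
    tree: PhyloTree, tip_values, sigma2: float, root_state: float
) -> float:
    """Log-likelihood of tip data under BM(sigma2) from ``root_state``."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    C, taxa, _ = _floored_vcv(tree)
    x = _as_vector(tip_values, taxa)
    n = len(taxa)
    V = sigma2 * C
    cf = cho_factor(V, lower=True)
    resid = x - root_state
    quad = float(resid @ cho_solve(cf, resid))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)


def fit_bm_asr(tree: PhyloTree, tip_values) -> ReconstructionResult:
    """Jointly ML-optimal sigma^2, root state, and all internal node states.

    Internal states are the GLS conditional expectations given the tips; they
    are independent of sigma^2 and equal the branch-length-weighted harmonic
    averaging solution at the optimum.
    """
    if tree.n_tips < 2:
        raise ValueError("need >= 2 tips")
    C, taxa, floored = _floored_vcv(tree)
    x = _as_vector(tip_values, taxa)
    n = len(taxa)

    if np.ptp(x) == 0.0:
        warnings.warn("zero trait variance across tips; states set to common value")
        states = {node: float(x[0]) for node in tree.internal_nodes}
        fit = BMFit(
            sigma2=LENGTH_EPS,
            root_state=float(x[0]),
            loglik=float("nan"),
            degenerate=True,
            floored_edges=floored,
        )
        return ReconstructionResult(node_states=states, fit=fit)

    cf = cho_factor(C, lower=True)
    ones = np.ones(n)
    Ci1 = cho_solve(cf, ones)
    mu = float(ones @ cho_solve(cf, x) / (ones @ Ci1))
    resid = x - mu
    a = cho_solve(cf, resid)
    sigma2 = float(resid @ a) / n
    logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    loglik = -0.5 * (
        n * np.log(2.0 * np.pi * sigma2) + logdetC + n
    )

    # E[state_a | tips] = mu + cov(a, tips) C^{-1} (x - mu):
    # cov(a, tip_i) (in sigma2 units) = depth of MRCA(a, tip_i)
    depths = tree.depths()
    anc_sets = {t: set([t, *tree.ancestors(t)]) for t in taxa}
    states: dict[str, float] = {}
    for node in tree.internal_nodes:
        lineage = [node, *tree.ancestors(node)]
        v = np.array(
            [depths[next(u for u in lineage if u in anc_sets[t])] for t in taxa]
        )
        states[node] = mu + float(v @ a)
    fit = BMFit(
        sigma2=sigma2, root_state=mu, loglik=loglik, floored_edges=floored
    )
    return ReconstructionResult(node_states=states, fit=fit)


def interpolate_on_branch(
    parent_state: float, child_state: float, d_parent: float, d_child: float
) -> float:
    """Brownian-bridge conditional mean at a point on a branch.

    The point sits ``d_parent`` below the parent and ``d_child`` above the
    child; the conditional mean weights each endpoint by the *opposite*
    distance.
    """
    if d_parent < 0 or d_child < 0:
        raise ValueError("distances must be nonnegative")
    total = d_parent + d_child
    if total == 0:
        raise ValueError("both distances are zero")
    return (parent_state * d_child + child_state * d_parent) / total


def reconstructed_progenitors(
    full_tree: PhyloTree,
    registry: PolyploidRegistry,
    diploid_traits: pd.DataFrame,
    traits: tuple[str, ...] = TRAIT_COLUMNS,
) -> dict[str, ProgenitorReconstruction]:
    """Progenitor trait vectors at each allopolyploid's origin anchor points.

    The anchor of a homeolog copy is the node where the copy's tip attaches to
    its progenitor lineage in the full (diploid + polyploid) tree. States are
    reconstructed on the diploid-only view using diploid morphology, then the
    anchor point is evaluated either directly (anchor retained in the diploid
    view) or by Brownian-bridge interpolation on the edge the pruning
    collapsed it onto.

    ``diploid_traits`` must be a species-level table covering all diploid tips.
    """
    dip = diploid_view(full_tree, registry)
    copies = set(registry.copy_tips())
    _, placement = prune_tips(full_tree, copies)
    dip_nodes = set(dip.nodes)

    table = diploid_traits.set_index("species") if "species" in diploid_traits else diploid_traits
    recon: dict[str, ReconstructionResult] = {}
    tipvals: dict[str, pd.Series] = {}
    for trait in traits:
        series = table[trait]
        recon[trait] = fit_bm_asr(dip, series)
        tipvals[trait] = series

    def node_state(trait: str, node: str) -> float:
        if dip.is_tip(node):
            return float(tipvals[trait][node])
        return recon[trait].node_states[node]

    def anchor_state(trait: str, copy_tip: str) -> float:
        attach = full_tree.parent[copy_tip]
        assert attach is not None
        # walk up through nodes that were themselves pruned away entirely
        while attach not in dip_nodes and attach not in placement:
            attach = full_tree.parent[attach]
            if attach is None:
                raise ValueError(f"copy {copy_tip!r} attaches at the root")
        if attach in dip_nodes:
            return node_state(trait, attach)
        below, d_above = placement[attach]
        par = dip.parent[below]
        if par is None:
            raise ValueError(
                f"anchor for copy {copy_tip!r} lies above the diploid root"
            )
        d_child = d_above
        d_parent = dip.length[below] - d_above
        return interpolate_on_branch(
            node_state(trait, par), node_state(trait, below), d_parent, d_child
        )

    out: dict[str, ProgenitorReconstruction] = {}
    for e in registry:
        mat = np.array([anchor_state(t, e.maternal_tip) for t in traits])
        pat = np.array([anchor_state(t, e.paternal_tip) for t in traits])
        out[e.accession] = ProgenitorReconstruction(
            accession=e.accession,
            traits=tuple(traits),
            maternal_state=mat,
            paternal_state=pat,
        )
    return out
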