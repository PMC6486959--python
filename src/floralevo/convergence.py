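"""Convergent-regime search under a multi-peak Hansen (OU) model.

Traits evolve by an Ornstein-Uhlenbeck process pulled with strength alpha
toward a regime-specific optimum theta; a *regime painting* assigns every
edge of the tree to a regime. The search is a simplified stepwise procedure
in the style of SURFACE:

* forward phase — starting from a single regime, greedily add one shift at a
  time (a new regime originating on one edge and inherited by its subtree)
  while the corrected Akaike score (AICc) improves;
* backward phase — greedily merge pairs of regimes while AICc improves.
  Regimes reached by two or more independent shifts after merging are the
  convergent regimes.

All traits share the painting; alpha, sigma^2 and the thetas are fit per
trait. The parameter count is k = n_traits * (2 + n_regimes) and the AICc
sample size is the number of tips (traits share the same phylogenetic
replicates). Trees need not be ultrametric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .tree import PhyloTree

__all__ = [
    "RegimePainting",
    "HansenFit",
    "SurfaceResult",
    "hansen_loglik",
    "fit_hansen",
    "surface_search",
]


@dataclass(frozen=True)
class RegimePainting:
    """Shift-based painting: each shift edge starts a new regime that is
    inherited by its whole subtree unless overridden deeper down."""

    shifts: tuple[tuple[str, int], ...]  # (child-end node of shift edge, regime id)
    root_regime: int = 0

    def edge_regimes(self, tree: PhyloTree) -> dict[str, int]:
        """Regime of the edge *above* each non-root node."""
        shift_map = dict(self.shifts)
        regime: dict[str, int] = {}
        for node in tree.preorder():
            if node == tree.root:
                regime[node] = self.root_regime
            else:
                regime[node] = shift_map.get(node, regime[tree.parent[node]])
        del regime[tree.root]
        return regime

    def regime_ids(self) -> tuple[int, ...]:
        ids = {self.root_regime, *(r for _n, r in self.shifts)}
        return tuple(sorted(ids))

    @property
    def n_regimes(self) -> int:
        return len(self.regime_ids())


@dataclass(frozen=True)
class TraitFit:
    alpha: float
    sigma2: float
    thetas: dict[int, float]
    loglik: float


@dataclass(frozen=True)
class HansenFit:
    painting: RegimePainting
    per_trait: dict[str, TraitFit]
    loglik: float
    n_params: int
    aicc: float


@dataclass(frozen=True)
class SurfaceResult:
    forward: HansenFit
    final: HansenFit
    convergent_regimes: dict[int, int]  # regime id -> number of independent origins
    aicc_trace: tuple[float, ...]


# ---------------------------------------------------------------------------
# geometry shared by every fit on one tree


class _TreeGeometry:
    def __init__(self, tree: PhyloTree):
        self.tree = tree
        self.tips = list(tree.tips)
        self.depths = tree.depths()
        self.T = np.array([self.depths[t] for t in self.tips])
        n = len(self.tips)
        anc = {t: [t, *tree.ancestors(t)] for t in self.tips}
        anc_sets = {t: set(a) for t, a in anc.items()}
        self.t_mrca = np.empty((n, n))
        for i, a in enumerate(self.tips):
            self.t_mrca[i, i] = self.T[i]
            for j in range(i + 1, n):
                b = self.tips[j]
                m = next(u for u in anc[a] if u in anc_sets[b])
                self.t_mrca[i, j] = self.t_mrca[j, i] = self.depths[m]
        self.d = self.T[:, None] + self.T[None, :] - 2.0 * self.t_mrca
        # flattened (tip, path-edge) segments for vectorized mean computation
        seg_tip, seg_child, seg_a, seg_b = [], [], [], []
        for i, t in enumerate(self.tips):
            for node in reversed([t, *[u for u in tree.ancestors(t) if u != tree.root]]):
                seg_tip.append(i)
                seg_child.append(node)
                seg_a.append(self.T[i] - self.depths[node])
                seg_b.append(self.T[i] - self.depths[tree.parent[node]])
        self.seg_tip = np.array(seg_tip)
        self.seg_child = seg_child
        self.seg_a = np.array(seg_a)
        self.seg_b = np.array(seg_b)
        self.height = float(self.T.max())

    def unit_cov(self, alpha: float) -> np.ndarray:
        """OU tip covariance at sigma^2 = 1; continuous BM limit at alpha=0.

        A tiny ridge keeps the matrix factorizable when polytomies place
        several accession tips at the same point (zero-length tip edges).
        """
        t, d = self.t_mrca, self.d
        if alpha <= 0:
            V = t.copy()
        else:
            V = (-np.expm1(-2.0 * alpha * t) / (2.0 * alpha)) * np.exp(-alpha * d)
        return V + 1e-9 * self.height * np.eye(len(self.tips))

    def design(self, alpha: float, edge_regime: dict[str, int], regimes) -> np.ndarray:
        """W with E[x_tip] = W @ theta (root state = root-regime optimum)."""
        idx = {r: k for k, r in enumerate(regimes)}
        W = np.zeros((len(self.tips), len(regimes)))
        # root contribution e^{-alpha T}
        W[:, idx[edge_regime["__root__"]]] += np.exp(-alpha * self.T)
        w = np.exp(-alpha * self.seg_a) - np.exp(-alpha * self.seg_b)
        regs = np.fromiter(
            (idx[edge_regime[c]] for c in self.seg_child), dtype=int, count=len(w)
        )
        np.add.at(W, (self.seg_tip, regs), w)
        return W


def _mean_vector(
    geom: _TreeGeometry, painting: RegimePainting, alpha: float, thetas: dict[int, float]
) -> np.ndarray:
    edge_regime = painting.edge_regimes(geom.tree)
    edge_regime["__root__"] = painting.root_regime
    regimes = painting.regime_ids()
    W = geom.design(alpha, edge_regime, regimes)
    th = np.array([thetas[r] for r in regimes])
    return W @ th


def hansen_loglik(
    tree: PhyloTree,
    painting: RegimePainting,
    tip_values,
    alpha: float,
    sigma2: float,
    thetas: dict[int, float],
) -> float:
    """Multivariate-normal log-density of tip data under the painted OU
    model; reduces to the BM likelihood as alpha -> 0."""
    if not np.isfinite(alpha) or not np.isfinite(sigma2) or sigma2 <= 0 or alpha < 0:
        raise ValueError("invalid parameters")
    geom = _TreeGeometry(tree)
    x = np.asarray(
        [tip_values[t] for t in geom.tips]
        if not isinstance(tip_values, pd.Series)
        else tip_values.reindex(geom.tips).to_numpy(dtype=float)
    )
    mean = _mean_vector(geom, painting, alpha, thetas)
    V = sigma2 * geom.unit_cov(alpha)
    cf = cho_factor(V, lower=True)
    resid = x - mean
    quad = float(resid @ cho_solve(cf, resid))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    n = len(x)
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)


def _profile_fit_trait(
    geom: _TreeGeometry,
    painting: RegimePainting,
    x: np.ndarray,
    alpha_max: float,
) -> TraitFit:
    """Per-trait ML fit: thetas and sigma^2 are GLS-profiled given alpha;
    alpha by bounded scalar optimization (deterministic)."""
    edge_regime = painting.edge_regimes(geom.tree)
    edge_regime["__root__"] = painting.root_regime
    regimes = painting.regime_ids()
    n = len(x)

    def profile(alpha: float) -> tuple[float, np.ndarray, float]:
        V0 = geom.unit_cov(alpha)
        cf = cho_factor(V0, lower=True)
        W = geom.design(alpha, edge_regime, regimes)
        WtVi = cho_solve(cf, W).T
        A = WtVi @ W
        b = WtVi @ x
        th, *_ = np.linalg.lstsq(A, b, rcond=None)
        resid = x - W @ th
        q = float(resid @ cho_solve(cf, resid))
        sigma2 = max(q / n, 1e-12)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
        return ll, th, sigma2

    def neg(alpha: float) -> float:
        return -profile(alpha)[0]

    res = minimize_scalar(
        neg,
        bounds=(1e-8, alpha_max),
        method="bounded",
        options={"xatol": 1e-3 * alpha_max, "maxiter": 60},
    )
    alpha = float(res.x)
    ll, th, sigma2 = profile(alpha)
    # near-zero alpha (BM-like) can beat the interior optimum
    ll0, th0, s0 = profile(1e-8)
    if ll0 > ll:
        alpha, ll, th, sigma2 = 1e-8, ll0, th0, s0
    return TraitFit(
        alpha=alpha,
        sigma2=float(sigma2),
        thetas={r: float(v) for r, v in zip(regimes, th)},
        loglik=float(ll),
    )


def _aicc(loglik: float, k: int, n: int, n_shifts: int, n_edges: int) -> float:
    """AICc plus a positional cost of 2 ln(E) per shift.

    Each shift's edge is chosen by search over all E candidate edges, so its
    cost is the log-cardinality of the choice set (the standard
    changepoint-selection penalty), not a single smooth parameter.
    """
    if n - k - 1 <= 0:
        return np.inf
    aicc = -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
    return aicc + 2.0 * np.log(n_edges) * n_shifts


def fit_hansen(
    tree: PhyloTree,
    traits: pd.DataFrame,
    painting: RegimePainting,
    geom: _TreeGeometry | None = None,
    alpha_max: float | None = None,
) -> HansenFit:
    """Fit the painted Hansen model to every trait column independently."""
    geom = geom or _TreeGeometry(tree)
    alpha_max = alpha_max or 50.0 / geom.height
    table = traits.set_index("species") if "species" in traits else traits
    per_trait: dict[str, TraitFit] = {}
    total = 0.0
    for col in table.columns:
        x = table[col].reindex(geom.tips).to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"missing tip values in trait {col!r}")
        tf = _profile_fit_trait(geom, painting, x, alpha_max)
        per_trait[col] = tf
        total += tf.loglik
    # AICc sample size: tips are the independent phylogenetic units; traits
    # are measured on the same species and do not multiply them
    k = len(per_trait) * (2 + painting.n_regimes)
    n = len(geom.tips)
    n_edges = len(geom.tips) + len(tree.internal_nodes) - 1
    return HansenFit(
        painting=painting,
        per_trait=per_trait,
        loglik=total,
        n_params=k,
        aicc=_aicc(total, k, n, len(painting.shifts), n_edges),
    )


def _merge(painting: RegimePainting, a: int, b: int) -> RegimePainting:
    """Collapse regime b into regime a."""
    shifts = tuple(
        (node, a if r == b else r) for node, r in painting.shifts
    )
    root = a if painting.root_regime == b else painting.root_regime
    return RegimePainting(shifts=shifts, root_regime=root)


def _simplify(painting: RegimePainting, tree: PhyloTree) -> RegimePainting:
    """Drop no-op shifts (regime equal to the regime just above them) and
    renumber regimes contiguously. Edge regimes are unchanged."""
    shift_map = dict(painting.shifts)
    regime: dict[str, int] = {tree.root: painting.root_regime}
    kept: list[tuple[str, int]] = []
    for node in tree.preorder():
        if node == tree.root:
            continue
        above = regime[tree.parent[node]]
        r = shift_map.get(node, above)
        regime[node] = r
        if node in shift_map and r != above:
            kept.append((node, r))
    ids = sorted({painting.root_regime, *(r for _n, r in kept)})
    relabel = {r: i for i, r in enumerate(ids)}
    return RegimePainting(
        shifts=tuple((n, relabel[r]) for n, r in kept),
        root_regime=relabel[painting.root_regime],
    )


def surface_search(
    tree: PhyloTree,
    traits: pd.DataFrame,
    max_shifts: int | None = None,
    alpha_max: float | None = None,
    verbose: bool = False,
) -> SurfaceResult:
    """Stepwise forward shift addition and backward regime collapse.

    Every accepted step strictly decreases AICc; the AICc trace is returned.
    Convergent regimes are those whose final membership unites two or more
    independently arising shifts.
    """
    geom = _TreeGeometry(tree)
    non_root = [n for n in tree.preorder() if n != tree.root]
    painting = RegimePainting(shifts=())
    current = fit_hansen(tree, traits, painting, geom=geom, alpha_max=alpha_max)
    trace = [current.aicc]
    max_shifts = max_shifts if max_shifts is not None else len(non_root)

    # forward phase
    next_id = 1
    while len(painting.shifts) < max_shifts:
        shifted = {n for n, _r in painting.shifts}
        best = None
        for node in non_root:
            if node in shifted:
                continue
            cand = RegimePainting(
                shifts=(*painting.shifts, (node, next_id)),
                root_regime=painting.root_regime,
            )
            fit = fit_hansen(tree, traits, cand, geom=geom, alpha_max=alpha_max)
            if np.isfinite(fit.aicc) and (best is None or fit.aicc < best.aicc):
                best = fit
        if best is None or best.aicc >= current.aicc:
            break
        current, painting = best, best.painting
        trace.append(current.aicc)
        next_id += 1
        if verbose:  # pragma: no cover
            print(f"forward: +shift -> AICc {current.aicc:.3f}")
    forward_fit = current

    # backward phase: merge regime pairs while AICc improves; merged
    # paintings are simplified (no-op shifts dropped) before scoring
    while True:
        ids = painting.regime_ids()
        best = None
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                cand = _simplify(_merge(painting, a, b), tree)
                fit = fit_hansen(tree, traits, cand, geom=geom, alpha_max=alpha_max)
                if np.isfinite(fit.aicc) and (best is None or fit.aicc < best.aicc):
                    best = fit
        if best is None or best.aicc >= current.aicc:
            break
        current, painting = best, best.painting
        trace.append(current.aicc)
        if verbose:  # pragma: no cover
            print(f"backward: merge -> AICc {current.aicc:.3f}")

    origins: dict[int, int] = {}
    for _node, r in painting.shifts:
        origins[r] = origins.get(r, 0) + 1
    convergent = {r: c for r, c in origins.items() if c >= 2}
    return SurfaceResult(
        forward=forward_fit,
        final=current,
        convergent_regimes=convergent,
        aicc_trace=tuple(trace),
    )
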