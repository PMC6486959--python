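"""Phylogenetic signal: Blomberg's K and Pagel's lambda.

K compares the observed ratio of tip variance to phylogenetically corrected
variance with its Brownian-motion expectation on the same tree; K = 1 under
BM, K < 1 means less signal than BM predicts. Significance comes from a
tip-label randomization test on the variance of phylogenetically independent
contrasts (PICs).

lambda multiplies the off-diagonal phylogenetic covariance; lambda = 0 is an
iid (star) model, lambda = 1 is plain BM. It is estimated by profile ML on
[0, 1] and tested against lambda = 0 with a chi-square(1) likelihood-ratio
test (boundary estimates are reported as such).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .asr import _as_vector, _floored_vcv, LENGTH_EPS
from .tree import PhyloTree

__all__ = ["SignalResult", "blomberg_k", "pagel_lambda", "pic_variance"]


@dataclass(frozen=True)
class SignalResult:
    kappa: float | None = None
    k_pvalue: float | None = None
    lambda_hat: float | None = None
    lambda_pvalue: float | None = None
    n_permutations: int | None = None
    seed: int | None = None


def pic_variance(tree: PhyloTree, tip_values) -> float:
    """Variance of Felsenstein's standardized independent contrasts.

    Polytomies are resolved internally by pairing children sequentially with
    zero-length connecting branches (an arbitrary resolution; the contrast
    variance is what the randomization test permutes, so only exchangeability
    matters). Zero branch-length sums are floored.
    """
    order = list(tree.postorder())
    x = dict(zip(*_tips_and_values(tree, tip_values)))
    # (value, extra branch length) per processed node
    st: dict[str, tuple[float, float]] = {}
    contrasts: list[float] = []
    for node in order:
        kids = tree.children[node]
        if not kids:
            st[node] = (x[node], tree.length[node])
            continue
        vals = [st[k] for k in kids]
        va, ta = vals[0]
        for vb, tb in vals[1:]:
            t_sum = max(ta + tb, LENGTH_EPS)
            contrasts.append((va - vb) / np.sqrt(t_sum))
            # nodal value and extra length after combining the pair
            va = (va / ta + vb / tb) / (1 / ta + 1 / tb) if ta > 0 and tb > 0 else (
                va if tb > 0 else vb if ta > 0 else 0.5 * (va + vb)
            )
            ta = ta * tb / t_sum
        st[node] = (va, ta + tree.length[node])
    c = np.asarray(contrasts)
    return float(np.mean(c**2))


def _tips_and_values(tree: PhyloTree, tip_values) -> tuple[list[str], np.ndarray]:
    taxa = list(tree.tips)
    return taxa, _as_vector(tip_values, taxa)


def blomberg_k(
    tree: PhyloTree,
    tip_values,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> SignalResult:
    """Blomberg's K with a PIC-variance randomization test.

    The p-value is the +1-corrected fraction of tip-label permutations whose
    contrast variance is <= the observed one (signal concentrates variation
    between clades, deflating contrasts).
    """
    if tree.n_tips < 4:
        raise ValueError("need >= 4 tips")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value")
    C, taxa, _ = _floored_vcv(tree)
    x = _as_vector(tip_values, taxa)
    if np.ptp(x) == 0:
        raise ValueError("constant tip values")
    n = len(x)
    cf = cho_factor(C, lower=True)
    ones = np.ones(n)
    Ci1 = cho_solve(cf, ones)
    mu = float(ones @ cho_solve(cf, x) / (ones @ Ci1))
    d = x - mu
    mse0 = float(d @ d) / (n - 1)
    mse = float(d @ cho_solve(cf, d)) / (n - 1)
    expected = (float(np.trace(C)) - n / float(ones @ Ci1)) / (n - 1)
    kappa = (mse0 / mse) / expected

    rng = np.random.default_rng(seed)
    obs = pic_variance(tree, dict(zip(taxa, x)))
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(x)
        if pic_variance(tree, dict(zip(taxa, perm))) <= obs:
            hits += 1
    pval = (1 + hits) / (n_permutations + 1)
    return SignalResult(
        kappa=kappa, k_pvalue=pval, n_permutations=n_permutations, seed=seed
    )


def _lambda_profile_loglik(C: np.ndarray, x: np.ndarray, lam: float) -> float:
    n = len(x)
    Cl = lam * C + (1.0 - lam) * np.diag(np.diag(C))
    cf = cho_factor(Cl, lower=True)
    ones = np.ones(n)
    mu = float(ones @ cho_solve(cf, x) / (ones @ cho_solve(cf, ones)))
    resid = x - mu
    sigma2 = float(resid @ cho_solve(cf, resid)) / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)


def pagel_lambda(tree: PhyloTree, tip_values) -> SignalResult:
    """Profile-ML lambda on [0, 1] and a LRT against lambda = 0."""
    if tree.n_tips < 4:
        raise ValueError("need >= 4 tips")
    C, taxa, _ = _floored_vcv(tree)
    x = _as_vector(tip_values, taxa)
    if np.ptp(x) == 0:
        raise ValueError("constant tip values")

    res = minimize_scalar(
        lambda lam: -_lambda_profile_loglik(C, x, lam),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:  # pragma: no cover - bounded Brent rarely fails
        raise RuntimeError(f"lambda optimization failed: {res.message}")
    # bounded Brent never evaluates the exact endpoints; check them too
    cands = [(float(res.x), -float(res.fun))]
    for lam in (0.0, 1.0):
        cands.append((lam, _lambda_profile_loglik(C, x, lam)))
    lam_hat, ll_hat = max(cands, key=lambda t: t[1])
    ll0 = _lambda_profile_loglik(C, x, 0.0)
    lrt = max(0.0, 2.0 * (ll_hat - ll0))
    pval = float(chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    return SignalResult(lambda_hat=lam_hat, lambda_pvalue=pval)
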