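"""Landmark-based floral limb shape: generalized Procrustes analysis + PCA.

Each photograph contributes a configuration of 15 two-dimensional landmarks.
GPA removes position (centering), size (unit centroid size), and orientation
(least-squares rotation, reflections disallowed — flowers are photographed
consistently), leaving shape. A covariance PCA of the aligned, flattened
coordinates yields the PC1/PC2 shape scores that feed the downstream
comparative analyses. Tangent-space projection is omitted: at the small
shape variances involved the aligned coordinates are already effectively
tangent-plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .spectra import _fix_signs

__all__ = ["N_LANDMARKS", "ProcrustesResult", "gpa_align", "shape_pca", "procrustes_distance"]

N_LANDMARKS = 15


def _validate(configs: np.ndarray) -> np.ndarray:
    arr = np.asarray(configs, dtype=float)
    if arr.ndim != 3 or arr.shape[1:] != (N_LANDMARKS, 2):
        raise ValueError(f"expected (m, {N_LANDMARKS}, 2) landmark array")
    if np.isnan(arr).any():
        raise ValueError("landmarks contain NaN")
    return arr


def _center_scale(config: np.ndarray) -> np.ndarray:
    c = config - config.mean(axis=0)
    size = np.linalg.norm(c)
    if size == 0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return c / size


def _rotate_to(config: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rotation of ``config`` onto ``target`` (no reflection)."""
    u, _s, vt = np.linalg.svd(config.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.diag([1.0, d])
    return config @ (u @ s @ vt)


@dataclass(frozen=True)
class ProcrustesResult:
    aligned: np.ndarray  # (m, 15, 2), centered, unit centroid size
    mean_shape: np.ndarray  # (15, 2), unit centroid size
    n_iterations: int


def gpa_align(
    configs, tol: float = 1e-10, max_iter: int = 1000
) -> ProcrustesResult:
    """Iterative generalized Procrustes alignment.

    Center and scale every configuration to unit centroid size, then
    alternate rotating all configurations to the current mean and
    re-estimating the (renormalized) mean until it moves less than ``tol``.
    """
    arr = _validate(configs)
    if arr.shape[0] < 2:
        raise ValueError("need >= 2 configurations")
    aligned = np.stack([_center_scale(c) for c in arr])
    mean = aligned[0].copy()
    it = 0
    for it in range(1, max_iter + 1):
        aligned = np.stack([_rotate_to(c, mean) for c in aligned])
        new_mean = _center_scale(aligned.mean(axis=0))
        if np.linalg.norm(new_mean - mean) < tol:
            mean = new_mean
            break
        mean = new_mean
    aligned = np.stack([_rotate_to(c, mean) for c in aligned])
    return ProcrustesResult(aligned=aligned, mean_shape=mean, n_iterations=it)


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations (closed form)."""
    a = _center_scale(np.asarray(a, dtype=float))
    b = _center_scale(np.asarray(b, dtype=float))
    return float(np.linalg.norm(_rotate_to(a, b) - b))


def shape_pca(
    result: ProcrustesResult, keys: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Covariance PCA of the aligned, flattened 30-coordinate vectors.

    Returns a score table (provenance keys, if given, plus pc1, pc2, ...)
    and the variance fractions. Component signs follow the same
    largest-|loading|-positive convention as the spectral PCA so that
    downstream quadrant labels are stable.
    """
    m = result.aligned.shape[0]
    if m < 3:
        raise ValueError("need >= 3 configurations")
    X = result.aligned.reshape(m, -1)
    pca = PCA()
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    _fix_signs(loadings, scores)
    n_pc = scores.shape[1]
    df = pd.DataFrame(scores, columns=[f"pc{i+1}" for i in range(n_pc)])
    if keys is not None:
        if len(keys) != m:
            raise ValueError("keys length does not match configurations")
        df = pd.concat([keys.reset_index(drop=True), df], axis=1)
    return df, pca.explained_variance_ratio_
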