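"""Floral reflectance spectra: smoothing, area normalization, and PCA.

Spectra are smoothed with repeated centered rolling averages (default: three
passes of a 9-nm window), then scaled so the trapezoidal area under the curve
over 300-700 nm is a common constant — normalization compares spectra by
shape (hue) rather than overall intensity (brightness). Color axes come from
a covariance PCA of the normalized values sampled on a 25-nm grid
(300, 325, ..., 700 nm: 17 values); components explaining more than 5% of
the variance are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = ["Spectrum", "SpectraPCA", "smooth", "normalize_area", "spectra_pca", "PCA_GRID"]

#: the PCA sampling grid in nm
PCA_GRID = np.arange(300.0, 701.0, 25.0)
NORM_LO, NORM_HI = 300.0, 700.0


@dataclass(frozen=True)
class Spectrum:
    wavelengths: np.ndarray  # nm, strictly increasing
    reflectance: np.ndarray  # nonnegative; fraction or percent
    label: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "reflectance", r)
        if w.ndim != 1 or w.shape != r.shape:
            raise ValueError("wavelengths and reflectance must be 1-D and equal length")
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(r < 0):
            raise ValueError("reflectance must be nonnegative")

    def covers(self, lo: float = NORM_LO, hi: float = NORM_HI) -> bool:
        return self.wavelengths[0] <= lo and self.wavelengths[-1] >= hi


def _window_samples(wavelengths: np.ndarray, window_nm: float) -> int:
    """Nearest odd sample count spanning ``window_nm`` on the instrument grid."""
    step = float(np.median(np.diff(wavelengths)))
    k = max(1, int(round(window_nm / step)))
    if k % 2 == 0:
        k += 1
    return k


def smooth(spec: Spectrum, window_nm: float = 9.0, passes: int = 3) -> Spectrum:
    """Centered rolling average, applied ``passes`` times.

    Edges use shrunken (truncated) windows, so a constant spectrum is exactly
    invariant. The window is given in nm and converted to the nearest odd
    sample count for the spectrum's own grid.
    """
    k = _window_samples(spec.wavelengths, window_nm)
    n = len(spec.wavelengths)
    if k > n:
        raise ValueError(f"window of {k} samples wider than spectrum ({n})")
    half = k // 2
    r = spec.reflectance
    for _ in range(passes):
        c = np.concatenate(([0.0], np.cumsum(r)))
        lo = np.maximum(np.arange(n) - half, 0)
        hi = np.minimum(np.arange(n) + half + 1, n)
        r = (c[hi] - c[lo]) / (hi - lo)
    return Spectrum(spec.wavelengths, r, label=spec.label)


def _band_area(spec: Spectrum) -> float:
    if not spec.covers():
        raise ValueError(
            f"spectrum must cover {NORM_LO:g}-{NORM_HI:g} nm for normalization"
        )
    w, r = spec.wavelengths, spec.reflectance
    inside = (w > NORM_LO) & (w < NORM_HI)
    grid = np.concatenate(([NORM_LO], w[inside], [NORM_HI]))
    vals = np.interp(grid, w, r)
    return float(np.trapezoid(vals, grid))


def normalize_area(spec: Spectrum, target_area: float = 1.0) -> Spectrum:
    """Scale reflectance so the 300-700 nm trapezoidal area equals
    ``target_area``; idempotent and invariant to overall intensity."""
    area = _band_area(spec)
    if area <= 0:
        raise ValueError("spectrum has zero area over the normalization band")
    return Spectrum(
        spec.wavelengths, spec.reflectance * (target_area / area), label=spec.label
    )


@dataclass(frozen=True)
class SpectraPCA:
    grid: np.ndarray
    loadings: np.ndarray  # (n_components, len(grid)) orthonormal rows
    scores: np.ndarray  # (n_spectra, n_components)
    variance_fractions: np.ndarray
    retained: int
    labels: tuple[str, ...]
    mean: np.ndarray

    def retained_scores(self) -> np.ndarray:
        return self.scores[:, : self.retained]


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    # sign convention: the largest-|loading| element of each component positive
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] *= -1.0
            scores[:, i] *= -1.0


def spectra_pca(
    specs: list[Spectrum], retention: float = 0.05
) -> SpectraPCA:
    """Covariance PCA of normalized spectra resampled to the 25-nm grid.

    ``retained`` counts components whose variance fraction strictly exceeds
    ``retention``; zero-variance input retains nothing.
    """
    if len(specs) < 3:
        raise ValueError("need >= 3 spectra")
    X = np.vstack(
        [np.interp(PCA_GRID, s.wavelengths, s.reflectance) for s in specs]
    )
    if np.allclose(X, X[0]):
        import warnings

        warnings.warn("identical spectra: zero variance, nothing retained")
        zero = np.zeros((0, len(PCA_GRID)))
        return SpectraPCA(
            grid=PCA_GRID.copy(),
            loadings=zero,
            scores=np.zeros((len(specs), 0)),
            variance_fractions=np.zeros(0),
            retained=0,
            labels=tuple(s.label for s in specs),
            mean=X.mean(axis=0),
        )
    pca = PCA()
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    _fix_signs(loadings, scores)
    frac = pca.explained_variance_ratio_
    retained = int(np.sum(frac > retention))
    return SpectraPCA(
        grid=PCA_GRID.copy(),
        loadings=loadings,
        scores=scores,
        variance_fractions=frac,
        retained=retained,
        labels=tuple(s.label for s in specs),
        mean=pca.mean_,
    )
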