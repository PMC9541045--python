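"""Spectral preprocessing chain.

The chain runs, in this fixed order, per spectrum:

1. linear interpolation onto a uniform grid restricted to the biological
   fingerprint window (default 900–1800 cm^-1, 1 cm^-1 step) — below
   900 cm^-1 the optical fiber's silica background dominates and above
   1800 cm^-1 there is no biological signal;
2. Savitzky-Golay smoothing (default second order, 9-point window);
3. airPLS baseline estimation and subtraction (adaptive iteratively
   reweighted penalized least squares) to remove the broad tissue
   fluorescence;
4. standard normal variate (SNV) normalization, removing multiplicative
   intensity/scatter differences between acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solveh_banded
from scipy.signal import savgol_coeffs

from .io import Cohort, RamanSpectrum, SpectrumMetadata

__all__ = [
    "PreprocessConfig",
    "SpectralMatrix",
    "interpolate_window",
    "savitzky_golay",
    "airpls_baseline",
    "snv",
    "preprocess_cohort",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Hyperparameters of the preprocessing chain.

    ``airpls_lambda`` is the Whittaker smoothness penalty (larger = stiffer
    baseline); ``airpls_tol`` stops the reweighting once the 1-norm of the
    below-baseline residual drops under ``tol * ||x||_1``.
    """

    window: tuple[float, float] = (900.0, 1800.0)
    grid_step: float = 1.0
    sg_order: int = 2
    sg_window: int = 9
    airpls_lambda: float = 1e5
    airpls_max_iter: int = 30
    airpls_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.window[0] >= self.window[1]:
            raise ValueError("window low must be < high")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and > sg_order")
        if self.airpls_lambda < 0:
            raise ValueError("airpls_lambda must be >= 0")

    def wavenumbers(self) -> np.ndarray:
        low, high = self.window
        n = int(round((high - low) / self.grid_step)) + 1
        return low + self.grid_step * np.arange(n)


@dataclass
class SpectralMatrix:
    """Processed spectra on a shared grid: one row per acquisition."""

    grid: np.ndarray
    intensities: np.ndarray  # (n_spectra, n_wavenumbers)
    meta: list[SpectrumMetadata]

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D")
        if self.intensities.shape[0] != len(self.meta):
            raise ValueError("row count must equal metadata count")
        if self.intensities.shape[1] != self.grid.size:
            raise ValueError("column count must equal grid length")
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("axis error: grid must be strictly increasing")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def group_labels(self) -> np.ndarray:
        return np.array([m.group for m in self.meta])

    @property
    def subject_ids(self) -> np.ndarray:
        return np.array([m.subject_id for m in self.meta])

    @property
    def covariates(self) -> np.ndarray:
        return np.array(
            [np.nan if m.covariate is None else m.covariate for m in self.meta]
        )

    def rows(self, group: str) -> np.ndarray:
        return self.intensities[self.group_labels == group]

    def subset(self, groups) -> "SpectralMatrix":
        mask = np.isin(self.group_labels, list(groups))
        return SpectralMatrix(
            self.grid,
            self.intensities[mask],
            [m for m, keep in zip(self.meta, mask) if keep],
        )


def interpolate_window(
    spectrum: RamanSpectrum, cfg: PreprocessConfig = PreprocessConfig()
) -> RamanSpectrum:
    """Linearly interpolate onto the uniform fingerprint-window grid.

    The native axis must cover the window; values are never extrapolated.
    """
    low, high = cfg.window
    if spectrum.wavenumber[0] > low or spectrum.wavenumber[-1] < high:
        raise ValueError(
            "insufficient spectral range: native axis "
            f"[{spectrum.wavenumber[0]:g}, {spectrum.wavenumber[-1]:g}] does not "
            f"cover window [{low:g}, {high:g}]"
        )
    grid = cfg.wavenumbers()
    values = np.interp(grid, spectrum.wavenumber, spectrum.intensity)
    return RamanSpectrum(grid, values, spectrum.meta)


def savitzky_golay(values: np.ndarray, order: int = 2, window: int = 9) -> np.ndarray:
    """Savitzky-Golay smoothing with truncated one-sided edge fits.

    Interior points use the standard sliding least-squares polynomial of
    the given order; the first and last ``window//2`` points are smoothed
    by refitting the polynomial on the window truncated at the array edge
    and evaluating at the point itself.  Exact on polynomials of degree
    <= ``order``.
    """
    values = np.asarray(values, dtype=float)
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and > order")
    n = values.size
    if n < window:
        raise ValueError(f"too short to smooth: length {n} < window {window}")
    coeffs = savgol_coeffs(window, order)
    out = np.convolve(values, coeffs[::-1], mode="same")
    half = window // 2
    idx = np.arange(n)
    for i in range(half):
        for j in (i, n - 1 - i):
            lo, hi = max(0, j - half), min(n, j + half + 1)
            deg = min(order, hi - lo - 1)
            c = np.polynomial.polynomial.polyfit(idx[lo:hi] - j, values[lo:hi], deg)
            out[j] = c[0]
    return out


def _whittaker_solve(x: np.ndarray, w: np.ndarray, lam: float) -> np.ndarray:
    """Solve (diag(w) + lam D2'D2) z = w*x with a banded Cholesky solver."""
    n = x.size
    main = np.full(n, 6.0)
    main[[0, -1]] = 1.0
    main[[1, -2]] = 5.0
    off1 = np.full(n, -4.0)
    off1[0] = off1[-2] = -2.0
    off2 = np.full(n, 1.0)
    ab = np.zeros((3, n))
    ab[0] = w + lam * main
    ab[1] = lam * off1  # ab[1, i] = A[i+1, i]
    ab[2] = lam * off2
    return solveh_banded(ab, w * x, lower=True)


def airpls_baseline(
    values: np.ndarray,
    lam: float = 1e5,
    max_iter: int = 30,
    tol: float = 1e-3,
) -> np.ndarray:
    """Estimate the fluorescence baseline by airPLS.

    Iteratively solves the weighted Whittaker problem
    ``min sum_i w_i (x_i - z_i)^2 + lam * sum (d2 z)^2``; after each solve
    points above the baseline (Raman peaks) get weight 0 while points below
    get exponentially growing weights, so the baseline settles under the
    peaks.  Stops when the 1-norm of the negative residuals falls below
    ``tol * ||x||_1`` or after ``max_iter`` sweeps.  Returns the baseline;
    the caller subtracts it.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    if x.size < 3:
        raise ValueError("too short for baseline estimation")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    w = np.ones_like(x)
    x_norm = np.abs(x).sum()
    z = x
    for t in range(1, max_iter + 1):
        z = _whittaker_solve(x, w, lam)
        d = x - z
        neg = d < 0
        dssn = np.abs(d[neg]).sum()
        if dssn < tol * x_norm or not neg.any():
            break
        w[~neg] = 0.0
        w[neg] = np.exp(t * np.abs(d[neg]) / dssn)
        # anchor the endpoints so the baseline cannot drift up at the edges
        w[0] = w[-1] = np.exp(t * np.abs(d[neg]).max() / dssn)
    return z


def snv(values: np.ndarray) -> np.ndarray:
    """Standard normal variate: center to mean 0, scale to sample sd 1 (ddof=1)."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    # relative threshold: a constant vector can have sd ~ eps*|x| in floats
    if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, float(np.abs(x).max())):
        raise ValueError("degenerate spectrum: zero spread")
    return (x - x.mean()) / sd


def preprocess_cohort(
    cohort: Cohort, cfg: PreprocessConfig = PreprocessConfig()
) -> SpectralMatrix:
    """Run the full chain (window -> smooth -> airPLS subtract -> SNV).

    Metadata order is preserved; any stage failure is re-raised annotated
    with the offending acquisition id.
    """
    rows = []
    meta = []
    grid = cfg.wavenumbers()
    for i, spectrum in enumerate(cohort.spectra):
        acq = spectrum.meta.acquisition_id or f"#{i}"
        try:
            windowed = interpolate_window(spectrum, cfg)
            smoothed = savitzky_golay(windowed.intensity, cfg.sg_order, cfg.sg_window)
            baseline = airpls_baseline(
                smoothed, cfg.airpls_lambda, cfg.airpls_max_iter, cfg.airpls_tol
            )
            rows.append(snv(smoothed - baseline))
        except ValueError as exc:
            raise ValueError(f"acquisition {acq}: {exc}") from exc
        meta.append(spectrum.meta)
    return SpectralMatrix(grid, np.vstack(rows), meta)
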