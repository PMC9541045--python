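"""Windowed cosine similarity between cohort mean spectra.

Raman spectra are long, structured vectors; a single global similarity
number hides where two tissues differ.  Splitting the fingerprint region
into fixed-width intervals (default 100 cm^-1) and computing the cosine of
the angle between the two mean spectra inside each interval localizes the
comparison — e.g. exercised-mouse muscle resembling human dystrophic
muscle most in the lower-wavenumber windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import SpectralMatrix

__all__ = ["SimilarityProfile", "mean_spectrum", "cosine", "windowed_cosine", "cohort_similarity"]


@dataclass
class SimilarityProfile:
    """Per-window cosine similarity between two mean spectra."""

    window_edges: list[tuple[float, float]]  # half-open, final window closed
    values: np.ndarray                       # one cosine per window, in [-1, 1]
    names: tuple[str, str] = ("A", "B")

    def mean_over(self, low: float, high: float) -> float:
        """Mean cosine over the windows whose span lies within [low, high]."""
        vals = [
            v
            for (lo, hi), v in zip(self.window_edges, self.values)
            if lo >= low and hi <= high
        ]
        if not vals:
            raise ValueError(f"no windows inside [{low}, {high}]")
        return float(np.mean(vals))


def mean_spectrum(matrix: SpectralMatrix, group: str) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and standard deviation of a group's processed rows."""
    rows = matrix.rows(group)
    if rows.shape[0] == 0:
        raise ValueError(f"empty group {group!r}")
    return rows.mean(axis=0), rows.std(axis=0, ddof=1 if rows.shape[0] > 1 else 0)


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two vectors: a.b / (||a|| ||b||)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have the same length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("undefined similarity: zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def windowed_cosine(
    mean_a: np.ndarray,
    mean_b: np.ndarray,
    grid: np.ndarray,
    width: float = 100.0,
    names: tuple[str, str] = ("A", "B"),
) -> SimilarityProfile:
    """Cosine similarity inside consecutive wavenumber intervals.

    Windows are half-open ``[low, low+width)`` starting at the grid origin;
    the final window is closed so the last grid point is included.
    """
    grid = np.asarray(grid, dtype=float)
    mean_a = np.asarray(mean_a, dtype=float)
    mean_b = np.asarray(mean_b, dtype=float)
    if not (grid.size == mean_a.size == mean_b.size):
        raise ValueError("grid and mean spectra must align")
    span = grid[-1] - grid[0]
    if span < width:
        raise ValueError("grid span smaller than one window")
    n_windows = int(np.floor(span / width + 1e-9))
    edges = []
    values = []
    for k in range(n_windows):
        low = grid[0] + k * width
        high = low + width
        last = k == n_windows - 1
        mask = (grid >= low) & ((grid <= grid[-1]) if last else (grid < high))
        edges.append((float(low), float(grid[-1]) if last else float(high)))
        values.append(cosine(mean_a[mask], mean_b[mask]))
    return SimilarityProfile(edges, np.asarray(values), names)


def cohort_similarity(
    matrix: SpectralMatrix, group_a: str, group_b: str, width: float = 100.0
) -> SimilarityProfile:
    """Windowed cosine similarity between two groups' mean processed spectra."""
    mean_a, _ = mean_spectrum(matrix, group_a)
    mean_b, _ = mean_spectrum(matrix, group_b)
    return windowed_cosine(mean_a, mean_b, matrix.grid, width, names=(group_a, group_b))
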