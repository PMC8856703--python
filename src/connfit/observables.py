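"""Functional connectivity observables and goodness-of-fit metrics.

Static FC is the regions x regions Pearson correlation matrix of the BOLD
series. FC dynamics (FCD) are summarized as a windows x windows matrix whose
(t1, t2) entry is the Pearson correlation between the vectorized strict
upper triangles of the windowed FC matrices at window positions t1 and t2;
the distribution of the FCD matrix's own upper-triangle values characterizes
how much connectivity reconfigures over time.

Two fit metrics compare simulation to data: the uncentered Pearson
correlation (cosine) of FC upper triangles, which is sensitive to
differences in mean FC level, and the Kolmogorov-Smirnov distance between
the FCD upper-triangle distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .bold import BoldSeries

__all__ = [
    "FCMatrix",
    "FCDMatrix",
    "upper_triangle",
    "fc_matrix",
    "fcd_matrix",
    "uncentered_corr",
    "ks_distance",
]


@dataclass
class FCMatrix:
    """Symmetric correlation matrix with unit diagonal, entries in [-1, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("FC matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("FC matrix must have unit diagonal")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class FCDMatrix:
    """Window x window FC-similarity matrix plus the windowing metadata."""

    values: np.ndarray
    window_length: float
    window_step: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


def upper_triangle(matrix: np.ndarray | FCMatrix | FCDMatrix) -> np.ndarray:
    """Vectorized strict upper triangle (diagonal excluded), row-major."""
    m = matrix.values if isinstance(matrix, (FCMatrix, FCDMatrix)) else np.asarray(matrix)
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _pearson_matrix(x: np.ndarray, context: str) -> np.ndarray:
    dead = np.flatnonzero(np.ptp(x, axis=1) == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance region(s) {dead.tolist()} in {context}; "
            "correlation undefined"
        )
    c = np.corrcoef(x)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


def fc_matrix(series: BoldSeries | np.ndarray) -> FCMatrix:
    """Pairwise Pearson correlation of regional time series."""
    x = series.values if isinstance(series, BoldSeries) else np.asarray(series, float)
    if x.shape[1] < 3:
        raise ValueError("need at least 3 time points for FC")
    return FCMatrix(values=_pearson_matrix(x, "FC computation"))


def fcd_matrix(
    series: BoldSeries,
    window_length: float = 30.0,
    window_step: float = 4.0,
) -> FCDMatrix:
    """Sliding-window FCD matrix.

    Windows are rectangular, sample-aligned and left-closed; lengths are
    converted to samples via round(x / tr). Entry (t1, t2) is the Pearson
    correlation of the strict upper triangles of FC(t1) and FC(t2).
    """
    if window_step <= 0:
        raise ValueError("window step must be positive")
    if window_length >= series.duration:
        raise ValueError("window length must be shorter than the series")
    L = int(round(window_length / series.tr))
    step = int(round(window_step / series.tr))
    if L < 3:
        raise ValueError("window too short: fewer than 3 samples")
    if step < 1:
        raise ValueError("window step shorter than one TR")
    T = series.n_volumes
    n_windows = (T - L) // step + 1
    if n_windows < 2:
        raise ValueError(
            f"only {n_windows} window(s) fit; need at least 2 for an FCD matrix"
        )
    triangles = np.empty((n_windows, series.n_regions * (series.n_regions - 1) // 2))
    for w in range(n_windows):
        seg = series.values[:, w * step : w * step + L]
        triangles[w] = upper_triangle(_pearson_matrix(seg, f"FCD window {w}"))
    fcd = np.corrcoef(triangles)
    fcd = np.clip((fcd + fcd.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(fcd, 1.0)
    return FCDMatrix(values=fcd, window_length=window_length, window_step=window_step)


def uncentered_corr(
    fc_a: FCMatrix | np.ndarray, fc_b: FCMatrix | np.ndarray
) -> float:
    """Cosine similarity of the strict upper triangles, without centering.

    Unlike the ordinary Pearson correlation this is sensitive to the overall
    FC level, penalizing simulations whose mean connectivity is off even if
    the pattern matches.
    """
    x = upper_triangle(fc_a)
    y = upper_triangle(fc_b)
    if x.shape != y.shape:
        raise ValueError("FC matrices have different dimensions")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("zero-norm upper triangle; uncentered correlation undefined")
    return float(np.dot(x, y) / (nx * ny))


def ks_distance(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Kolmogorov-Smirnov distance: sup-norm between the two empirical CDFs."""
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("KS distance needs non-empty samples")
    return float(stats.ks_2samp(a, b).statistic)
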