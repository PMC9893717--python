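"""Recurrence quantification of ensemble firing-rate dynamics.

The firing-rate series of an ensemble (events per second of all member
neurons inside a 1-s sliding window) is treated as the orbit of a
dynamical system. The recurrence plot ``P`` marks every pair of time
points whose states lie within a fixed radius epsilon (Euclidean
distance, optional delay embedding; the default embedding dimension 1
compares scalar rates by absolute difference):

    P_ij = 1  iff  ||x_i - x_j|| <= epsilon.

Five scalar measures summarize ``P``:

* RR  -- recurrence rate, the density ``sum P / n^2``;
* DET -- fraction of recurrence points on diagonal lines of length >=
  ``min_line`` (predictability / rigidity);
* DIV -- inverse length of the longest diagonal line (chaoticity proxy);
* LAM -- like DET but over vertical lines (laminarity / intermittency);
* W   -- mean length of maximal vertical runs of zeros (white lines), an
  estimator of recurrence times.

The line of identity (main diagonal) is included by default, matching a
recurrence-rate definition that sums every ``P_ij``; set
``include_loi=False`` for the convention that excludes it (its points are
then removed from both the line counts and the recurrence-point totals).
:class:`RecurrenceQuantifier` packages the chain as a scikit-learn style
estimator (``fit`` on a rate series, fitted ``measures_``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from sklearn.base import BaseEstimator

from .raster import Raster

__all__ = [
    "RateSeries",
    "RecurrencePlot",
    "RQAMeasures",
    "RecurrenceQuantifier",
    "firing_rate",
    "recurrence_matrix",
    "rqa_measures",
]


@dataclass(frozen=True)
class RateSeries:
    """Sliding-window event rate (events/s) of a set of neurons."""

    rates: np.ndarray
    window_seconds: float
    fps: float

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        if rates.ndim != 1:
            raise ValueError("rates must be 1-D")
        if (rates < 0).any():
            raise ValueError("rates must be non-negative")
        object.__setattr__(self, "rates", rates)

    @property
    def n_points(self) -> int:
        return int(self.rates.shape[0])


@dataclass(frozen=True)
class RecurrencePlot:
    """Binary recurrence matrix with its construction parameters."""

    P: np.ndarray
    epsilon: float
    embedding_dimension: int = 1
    embedding_delay: int = 1
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        p = np.asarray(self.P)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("P must be square")
        if not np.array_equal(p, p.T):
            raise ValueError("P must be symmetric")
        object.__setattr__(self, "P", p.astype(np.uint8))

    @property
    def n(self) -> int:
        return int(self.P.shape[0])


@dataclass(frozen=True)
class RQAMeasures:
    """The five recurrence measures plus their audit histograms.

    Histograms map line length -> number of maximal lines of that length
    (all lengths >= 1, before the ``min_line`` cut).
    """

    RR: float
    DET: float
    DIV: float
    LAM: float
    W_mean: float
    diagonal_histogram: Dict[int, int]
    vertical_histogram: Dict[int, int]
    white_vertical_histogram: Dict[int, int]
    min_line: int
    include_loi: bool


def firing_rate(subraster: Raster, window_seconds: float = 1.0) -> RateSeries:
    """Summed event rate of all neurons in a sliding window.

    ``rate[t]`` is the total number of events of all neurons in frames
    ``[t, t + w - 1]`` divided by ``window_seconds``, where
    ``w = round(window_seconds * fps)``; the window slides one frame at a
    time, giving ``F - w + 1`` points.
    """
    w = int(round(window_seconds * subraster.fps))
    if w < 1:
        raise ValueError(
            f"window of {window_seconds} s is shorter than one frame at "
            f"{subraster.fps} fps"
        )
    if w > subraster.n_frames:
        raise ValueError("window longer than the recording")
    total = subraster.matrix.sum(axis=0).astype(float)
    csum = np.concatenate(([0.0], np.cumsum(total)))
    counts = csum[w:] - csum[:-w]
    return RateSeries(counts / window_seconds, window_seconds, subraster.fps)


def recurrence_matrix(series, epsilon: float = 1.5,
                      embedding_dimension: int = 1,
                      embedding_delay: int = 1) -> RecurrencePlot:
    """Fixed-radius recurrence plot of a scalar series.

    With ``embedding_dimension > 1`` the series is delay-embedded into
    vectors ``(x_t, x_{t+tau}, ..., x_{t+(d-1)tau})`` before the pairwise
    Euclidean comparison.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    x = series.rates if isinstance(series, RateSeries) else np.asarray(series, dtype=float)
    d, tau = int(embedding_dimension), int(embedding_delay)
    if d < 1 or tau < 1:
        raise ValueError("embedding dimension and delay must be >= 1")
    n = x.shape[0] - (d - 1) * tau
    if n < 2:
        raise ValueError("fewer than two points after delay embedding")
    if d == 1:
        diff = np.abs(x[:, None] - x[None, :])
    else:
        emb = np.stack([x[i * tau : i * tau + n] for i in range(d)], axis=1)
        diff = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(axis=2))
    return RecurrencePlot((diff <= epsilon).astype(np.uint8), epsilon, d, tau)


def _run_length_histogram(mask: np.ndarray) -> Dict[int, int]:
    """Histogram of maximal runs of True in a 1-D boolean array."""
    hist: Dict[int, int] = {}
    if mask.size == 0:
        return hist
    padded = np.concatenate(([False], mask, [False]))
    changes = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = changes[::2], changes[1::2]
    for length in ends - starts:
        hist[int(length)] = hist.get(int(length), 0) + 1
    return hist


def _merge_hist(total: Dict[int, int], part: Dict[int, int]) -> None:
    for length, count in part.items():
        total[length] = total.get(length, 0) + count


def rqa_measures(plot: RecurrencePlot, min_line: int = 2,
                 include_loi: bool = True) -> RQAMeasures:
    """Compute RR, DET, DIV, LAM and the mean white vertical line length.

    ``min_line`` applies to both the diagonal (DET) and vertical (LAM)
    line counts. With ``include_loi=False`` the main diagonal is removed
    before any counting, from the recurrence-point totals as well.
    """
    if min_line < 1:
        raise ValueError("min_line must be >= 1")
    p = plot.P.astype(bool)
    n = plot.n

    p_counted = p.copy()
    if not include_loi:
        np.fill_diagonal(p_counted, False)
    n_points = int(p_counted.sum())
    rr = p_counted.sum() / float(n * n)

    diag_hist: Dict[int, int] = {}
    for offset in range(-(n - 1), n):
        _merge_hist(diag_hist, _run_length_histogram(np.diagonal(p_counted, offset)))
    vert_hist: Dict[int, int] = {}
    white_hist: Dict[int, int] = {}
    for j in range(n):
        col = p_counted[:, j]
        _merge_hist(vert_hist, _run_length_histogram(col))
        _merge_hist(white_hist, _run_length_histogram(~p[:, j]))

    def line_fraction(hist: Dict[int, int]) -> float:
        if n_points == 0:
            return 0.0
        on_lines = sum(l * c for l, c in hist.items() if l >= min_line)
        return on_lines / n_points

    det = line_fraction(diag_hist)
    lam = line_fraction(vert_hist)
    longest = max(diag_hist) if diag_hist else 0
    div = 1.0 / longest if longest else float("nan")
    n_white = sum(white_hist.values())
    w_mean = (
        sum(l * c for l, c in white_hist.items()) / n_white if n_white else 0.0
    )
    return RQAMeasures(
        RR=float(rr), DET=float(det), DIV=float(div), LAM=float(lam),
        W_mean=float(w_mean), diagonal_histogram=diag_hist,
        vertical_histogram=vert_hist, white_vertical_histogram=white_hist,
        min_line=min_line, include_loi=include_loi,
    )


class RecurrenceQuantifier(BaseEstimator):
    """Recurrence analysis of a rate series (scikit-learn style).

    Parameters mirror :func:`recurrence_matrix` and :func:`rqa_measures`.
    After ``fit(series)`` the fitted attributes ``plot_`` and
    ``measures_`` hold the recurrence plot and the five measures.
    """

    def __init__(self, epsilon: float = 1.5, embedding_dimension: int = 1,
                 embedding_delay: int = 1, min_line: int = 2,
                 include_loi: bool = True):
        self.epsilon = epsilon
        self.embedding_dimension = embedding_dimension
        self.embedding_delay = embedding_delay
        self.min_line = min_line
        self.include_loi = include_loi

    def fit(self, X, y=None) -> "RecurrenceQuantifier":
        self.plot_ = recurrence_matrix(
            X, epsilon=self.epsilon,
            embedding_dimension=self.embedding_dimension,
            embedding_delay=self.embedding_delay,
        )
        self.measures_ = rqa_measures(
            self.plot_, min_line=self.min_line, include_loi=self.include_loi
        )
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        """Fit and return the five measures as a 1-D array."""
        self.fit(X)
        m = self.measures_
        return np.array([m.RR, m.DET, m.DIV, m.LAM, m.W_mean])
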