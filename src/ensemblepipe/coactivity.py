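"""Coactivity series, the runs test, surrogate calibration, peak detection.

The coactivity series of a raster is the per-frame count of simultaneously
active neurons (the column sums). Whether that series could have arisen by
chance is tested with the Wald-Wolfowitz runs test: dichotomize around the
mean, count maximal same-sign runs T, and compare with the expectation
under randomness,

    T_bar = 2 n1 n2 / (n1 + n2) + 1
    s_T^2 = 2 n1 n2 (2 n1 n2 - n1 - n2) / ((n1 + n2)^2 (n1 + n2 - 1))
    Z     = (T - T_bar) / s_T,

with a two-tailed normal p-value. Values exactly equal to the mean are
dropped before run counting (classical convention).

The test's error rates are calibrated empirically with two surrogate
classes that both preserve each neuron's event count:

* type-1 (null-true): each neuron's active frames are redrawn uniformly
  without replacement -- the rejection fraction estimates alpha-hat;
* type-2 (null-false): each neuron keeps its multiset of inter-event
  intervals (order permuted, start offset uniform), preserving the bursty
  temporal structure -- the non-rejection fraction estimates beta-hat.

Significant coactivity peaks are frames whose count strictly exceeds a
sliding-window local mean + n_sd local standard deviations (population
SD; window centered with edge truncation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.stats import norm

from .raster import Raster, subraster
from .ensembles import EnsembleAssignment

__all__ = [
    "CoactivitySeries",
    "RunsTestResult",
    "SurrogateErrorReport",
    "PeakSet",
    "DegenerateSeriesError",
    "coactivity_series",
    "runs_test",
    "surrogate_type1",
    "surrogate_type2",
    "estimate_error_rates",
    "detect_peaks",
    "significant_peaks_per_ensemble",
]


class DegenerateSeriesError(ValueError):
    """Series constant relative to its mean: the runs test is undefined."""


@dataclass(frozen=True)
class CoactivitySeries:
    """Per-frame count of simultaneously active neurons."""

    counts: np.ndarray
    source: str = "raster"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_frames(self) -> int:
        return int(self.counts.shape[0])


@dataclass(frozen=True)
class RunsTestResult:
    """Outcome of the Wald-Wolfowitz runs test around the mean."""

    T: int
    T_bar: float
    s_T: float
    n1: int
    n2: int
    Z: float
    p_value: float

    def rejects(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


@dataclass(frozen=True)
class SurrogateErrorReport:
    """Monte-Carlo estimates of the runs test's type-I/II error rates."""

    M: int
    alpha_hat: float
    beta_hat: float
    alpha_level: float
    seed: int
    n_degenerate_type1: int = 0
    n_degenerate_type2: int = 0


@dataclass(frozen=True)
class PeakSet:
    """Per-frame significance flags from the dynamic-threshold detector."""

    flags: np.ndarray
    window_fraction: float
    n_sd: float
    ensemble_id: Optional[int] = None
    threshold: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        flags = np.asarray(self.flags, dtype=bool)
        if not 0 < self.window_fraction <= 1:
            raise ValueError("window_fraction must lie in (0, 1]")
        if self.n_sd <= 0:
            raise ValueError("n_sd must be positive")
        object.__setattr__(self, "flags", flags)

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    @property
    def flagged_frames(self) -> np.ndarray:
        return np.flatnonzero(self.flags)


def coactivity_series(raster: Raster, source: str = "raster") -> CoactivitySeries:
    """Column sums of the raster: active-neuron count per frame."""
    return CoactivitySeries(raster.matrix.sum(axis=0), source=source)


def runs_test(series) -> RunsTestResult:
    """Wald-Wolfowitz runs test of randomness around the series mean.

    Raises :class:`DegenerateSeriesError` when every retained value lies
    on one side of the mean (n1 or n2 = 0).
    """
    counts = series.counts if isinstance(series, CoactivitySeries) else np.asarray(series)
    counts = np.asarray(counts, dtype=float)
    # compare n*x with sum(x) rather than x with the rounded mean: exact
    # for integer-valued series, so mean-relative dichotomization is
    # invariant under constant shifts
    signs = np.sign(counts * counts.size - counts.sum())
    signs = signs[signs != 0]  # values equal to the mean are dropped
    n1 = int((signs > 0).sum())
    n2 = int((signs < 0).sum())
    if n1 == 0 or n2 == 0:
        raise DegenerateSeriesError(
            "series is constant relative to its mean; runs test undefined"
        )
    t = int(1 + (np.diff(signs) != 0).sum())
    n = n1 + n2
    t_bar = 2.0 * n1 * n2 / n + 1.0
    s_t2 = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n1 - n2) / (n**2 * (n - 1))
    s_t = float(np.sqrt(s_t2))
    z = (t - t_bar) / s_t
    p = float(2.0 * norm.sf(abs(z)))
    return RunsTestResult(T=t, T_bar=t_bar, s_T=s_t, n1=n1, n2=n2, Z=float(z),
                          p_value=min(max(p, np.nextafter(0, 1)), 1.0))


def surrogate_type1(raster: Raster, seed: int = 0,
                    rng: Optional[np.random.Generator] = None) -> Raster:
    """Null-true surrogate: per-neuron event times redrawn uniformly.

    Each neuron's active frames are resampled uniformly without
    replacement from all frames, preserving its event count.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    n, f = raster.n_neurons, raster.n_frames
    out = np.zeros((n, f), dtype=np.uint8)
    counts = raster.matrix.sum(axis=1)
    for i in range(n):
        c = int(counts[i])
        if c:
            out[i, rng.choice(f, size=c, replace=False)] = 1
    return Raster(out, fps=raster.fps, neuron_ids=raster.neuron_ids)


def surrogate_type2(raster: Raster, seed: int = 0,
                    rng: Optional[np.random.Generator] = None) -> Raster:
    """Structure-preserving surrogate: inter-event intervals conserved.

    Per neuron, the multiset of intervals between successive events is
    kept, their order permuted, and the first event placed uniformly in
    the feasible offset range. Neurons with fewer than two events are
    placed uniformly.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    n, f = raster.n_neurons, raster.n_frames
    out = np.zeros((n, f), dtype=np.uint8)
    for i in range(n):
        frames = np.flatnonzero(raster.matrix[i])
        if frames.size < 2:
            if frames.size == 1:
                out[i, rng.integers(0, f)] = 1
            continue
        intervals = np.diff(frames)
        rng.shuffle(intervals)
        span = int(intervals.sum())
        start = int(rng.integers(0, f - span))
        positions = start + np.concatenate(([0], np.cumsum(intervals)))
        out[i, positions] = 1
    return Raster(out, fps=raster.fps, neuron_ids=raster.neuron_ids)


def estimate_error_rates(raster: Raster, M: int = 1000,
                         alpha_level: float = 0.05,
                         seed: int = 0) -> SurrogateErrorReport:
    """Estimate the runs test's type-I and type-II error rates.

    alpha-hat is the fraction of M type-1 surrogates whose coactivity the
    test rejects at ``alpha_level``; beta-hat the fraction of M type-2
    surrogates it fails to reject. Degenerate surrogate series count as
    non-rejections for alpha-hat and as failures for beta-hat
    (conservative on both rates). One independent seed-derived RNG
    substream is used per surrogate index.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(2 * M)
    rejections = 0
    deg1 = 0
    for i in range(M):
        surr = surrogate_type1(raster, rng=np.random.default_rng(streams[i]))
        try:
            if runs_test(coactivity_series(surr)).rejects(alpha_level):
                rejections += 1
        except DegenerateSeriesError:
            deg1 += 1  # counted as a non-rejection
    failures = 0
    deg2 = 0
    for i in range(M):
        surr = surrogate_type2(raster, rng=np.random.default_rng(streams[M + i]))
        try:
            if not runs_test(coactivity_series(surr)).rejects(alpha_level):
                failures += 1
        except DegenerateSeriesError:
            deg2 += 1
            failures += 1  # counted as a failure to reject
    return SurrogateErrorReport(
        M=M,
        alpha_hat=rejections / M,
        beta_hat=failures / M,
        alpha_level=alpha_level,
        seed=seed,
        n_degenerate_type1=deg1,
        n_degenerate_type2=deg2,
    )


def _sliding_mean_sd(counts: np.ndarray, window: int) -> Tuple[np.ndarray, np.ndarray]:
    """Centered sliding mean and population SD with edge truncation."""
    f = counts.shape[0]
    x = counts.astype(float)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    csum2 = np.concatenate(([0.0], np.cumsum(x * x)))
    half_lo = window // 2
    half_hi = window - half_lo  # window covers [t - half_lo, t + half_hi)
    lo = np.clip(np.arange(f) - half_lo, 0, f)
    hi = np.clip(np.arange(f) + half_hi, 0, f)
    n = (hi - lo).astype(float)
    mean = (csum[hi] - csum[lo]) / n
    var = (csum2[hi] - csum2[lo]) / n - mean**2
    return mean, np.sqrt(np.maximum(var, 0.0))


def detect_peaks(series, window_fraction: float = 0.20, n_sd: float = 2.0,
                 ensemble_id: Optional[int] = None) -> PeakSet:
    """Flag frames strictly above the local mean + n_sd local SD.

    The window spans ``round(window_fraction * F)`` frames, slides one
    frame at a time, is centered on the evaluated frame, and truncates at
    the series edges. The SD is the population SD of the window.
    """
    counts = series.counts if isinstance(series, CoactivitySeries) else np.asarray(series)
    counts = np.asarray(counts, dtype=float)
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must lie in (0, 1]")
    window = int(round(window_fraction * counts.shape[0]))
    if window < 2:
        raise ValueError(
            f"window of {window} frame(s) after rounding; need >= 2"
        )
    mean, sd = _sliding_mean_sd(counts, window)
    threshold = mean + n_sd * sd
    flags = counts > threshold
    return PeakSet(flags, window_fraction, n_sd, ensemble_id=ensemble_id,
                   threshold=threshold)


def significant_peaks_per_ensemble(
    raster: Raster,
    assignment: EnsembleAssignment,
    window_fraction: float = 0.20,
    n_sd: float = 2.0,
    alpha_level: float = 0.05,
) -> Dict[int, PeakSet]:
    """Per-ensemble significant coactivity peaks, gated by the runs test.

    For each ensemble the subraster's coactivity must be declared
    non-random by the runs test at ``alpha_level``; otherwise the ensemble
    yields an empty :class:`PeakSet` and a warning.
    """
    if assignment.labels.shape[0] != raster.n_neurons:
        raise ValueError("assignment does not cover this raster")
    peaksets: Dict[int, PeakSet] = {}
    for cid in range(assignment.n_ensembles):
        members = assignment.members(cid)
        sub = subraster(raster, members)
        series = coactivity_series(sub, source=f"ensemble-{cid}")
        try:
            result = runs_test(series)
            significant = result.rejects(alpha_level)
        except DegenerateSeriesError:
            significant = False
        if not significant:
            warnings.warn(
                f"ensemble {cid}: coactivity not distinguishable from "
                f"random at alpha={alpha_level}; empty peak set",
                stacklevel=2,
            )
            peaksets[cid] = PeakSet(
                np.zeros(raster.n_frames, dtype=bool), window_fraction, n_sd,
                ensemble_id=cid,
            )
            continue
        peaksets[cid] = detect_peaks(series, window_fraction, n_sd,
                                     ensemble_id=cid)
    return peaksets
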