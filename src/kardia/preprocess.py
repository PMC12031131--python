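"""Segment selection, artifact handling, and tachogram resampling.

A 10-min supine recording yields more beats than the 5-min analysis window;
:func:`select_segment` slides a window beat-by-beat and keeps the candidate
with the most stable mean RR (lowest coefficient of variation of 30-s block
means).  Artifact beats are flagged against a local median and repaired by
cubic-spline interpolation; the repaired series is then resampled onto a
uniform 4 Hz grid (the tachogram) for Welch spectral analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .io import RRSeries

__all__ = [
    "UniformTachogram",
    "ArtifactMask",
    "InsufficientDataError",
    "SegmentQualityError",
    "select_segment",
    "detect_artifacts",
    "correct_artifacts",
    "resample_tachogram",
]


class InsufficientDataError(ValueError):
    """The recording is too short for the requested operation."""


class SegmentQualityError(ValueError):
    """Too many artifacts: the segment should be re-selected, not repaired."""


@dataclass(frozen=True)
class UniformTachogram:
    """RR values (ms) resampled on a uniform time grid."""

    values: np.ndarray
    fs: float
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs


@dataclass(frozen=True)
class ArtifactMask:
    """Per-beat artifact flags (True = artifact) and the threshold used."""

    flags: np.ndarray
    threshold_used: float

    @property
    def fraction(self) -> float:
        return float(np.mean(self.flags)) if self.flags.size else 0.0


def _window_cv(intervals: np.ndarray, block_s: float = 30.0) -> float:
    """Coefficient of variation of block-mean RR inside one candidate segment."""
    times = np.cumsum(intervals) / 1000.0
    blocks = np.floor((times - times[0]) / block_s).astype(int)
    means = pd.Series(intervals).groupby(blocks).mean().to_numpy()
    overall = float(np.mean(intervals))
    if overall == 0:
        return np.inf
    # population SD: a single-block degenerate case then scores 0, not NaN
    return float(np.std(means) / overall)


def select_segment(series: RRSeries, duration_s: float = 300.0) -> RRSeries:
    """Select the most stable contiguous sub-series of ``duration_s`` seconds.

    Candidate windows start at every beat; each is extended until its summed
    intervals first reach ``duration_s``.  The stability score is the
    coefficient of variation of 30-s-block mean RR within the candidate
    (lower = more stable); ties go to the earliest start.

    Raises
    ------
    InsufficientDataError
        If the recording spans less than ``duration_s``.
    """
    intervals = series.intervals
    total_s = float(np.sum(intervals) / 1000.0)
    if total_s < duration_s:
        raise InsufficientDataError(
            f"{series.subject_id}: recording spans {total_s:.1f} s "
            f"< required {duration_s:.0f} s"
        )
    cum = np.concatenate([[0.0], np.cumsum(intervals) / 1000.0])
    best_score, best_slice = np.inf, (0, len(intervals))
    for start in range(len(intervals)):
        # first end index whose summed duration reaches duration_s
        end = int(np.searchsorted(cum, cum[start] + duration_s, side="left"))
        if end > len(intervals):
            break
        score = _window_cv(intervals[start:end])
        if score < best_score - 1e-15:
            best_score, best_slice = score, (start, end)
    return series.slice_beats(*best_slice)


def detect_artifacts(series: RRSeries, threshold: float = 0.20) -> ArtifactMask:
    """Flag beats deviating from the local median by more than ``threshold``.

    The local median is taken over an 11-beat centred window, shrunk at the
    edges.  A beat is an artifact iff
    ``|RR_k − median_k| > threshold · median_k``.
    """
    rr = pd.Series(series.intervals)
    if rr.size < 11:
        raise InsufficientDataError(
            f"{series.subject_id}: artifact detection needs ≥ 11 beats, got {rr.size}"
        )
    local_median = rr.rolling(window=11, center=True, min_periods=1).median()
    flags = (rr - local_median).abs() > threshold * local_median
    return ArtifactMask(flags=flags.to_numpy(), threshold_used=threshold)


def correct_artifacts(series: RRSeries, mask: ArtifactMask,
                      max_fraction: float = 0.05) -> RRSeries:
    """Replace flagged intervals by cubic-spline interpolation over beat index.

    Refuses (raises :class:`SegmentQualityError`) when the flagged fraction
    reaches ``max_fraction``: such a segment should be re-selected rather
    than synthesised.  Unflagged beats are never modified and the beat count
    is preserved.
    """
    flags = np.asarray(mask.flags, dtype=bool)
    if flags.size != len(series):
        raise ValueError("mask length does not match series length")
    if not flags.any():
        return series
    if mask.fraction >= max_fraction:
        raise SegmentQualityError(
            f"{series.subject_id}: {100 * mask.fraction:.1f}% of beats flagged "
            f"(limit {100 * max_fraction:.0f}%); re-select the segment"
        )
    idx = np.arange(flags.size)
    good = ~flags
    spline = CubicSpline(idx[good], series.intervals[good])
    repaired = series.intervals.copy()
    repaired[flags] = spline(idx[flags])
    return series.replace_intervals(repaired)


def resample_tachogram(series: RRSeries, fs: float = 4.0) -> UniformTachogram:
    """Resample RR-vs-time onto a uniform grid by cubic-spline interpolation.

    The RR value at a beat is attached to that beat's (end) time; the grid
    spans ``[t_first_beat, t_last_beat]`` with spacing exactly ``1/fs`` and
    ``floor(span·fs)`` points.
    """
    if len(series) < 4:
        raise InsufficientDataError(
            f"{series.subject_id}: cubic resampling needs ≥ 4 beats, got {len(series)}"
        )
    beat_t = series.beat_times[1:]  # time of each interval's closing beat
    spline = CubicSpline(beat_t, series.intervals)
    span = beat_t[-1] - beat_t[0]
    n = int(np.floor(span * fs))
    grid = beat_t[0] + np.arange(n) / fs
    return UniformTachogram(values=spline(grid), fs=fs, t0=float(beat_t[0]))
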