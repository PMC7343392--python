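"""Pulse-oximeter beat cleaning, HRV series, rMSSD, ΔsAA and arousal regressors.

The cleaning stage mirrors standard adaptive HRV artifact filters: beats
implying a physiologically implausible instantaneous rate (outside 25-200
beats per minute) are handled first, then beats whose inter-beat interval
falls too far below the running mean of recently accepted intervals are
rejected as spurious detections.  Overly long intervals are *gaps* (missed
beats), not artifacts: the beat that ends a gap is genuine, so it is kept and
the gap is flagged instead.  This asymmetry is what makes cleaning
idempotent.

The HRV series proper is the sequence of successive R-R interval differences
(ms), cubic-spline interpolated onto an equidistant grid for spectral
analysis.  rMSSD is always computed on the raw accepted intervals, never on
the interpolated series, because interpolation distorts successive
differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.stats import gamma as gamma_dist

from lcmem.config import SAA_SCHEDULE


class PhysioError(ValueError):
    pass


@dataclass
class BeatTimeline:
    """Strictly increasing beat timestamps (s) for one acquisition stage.

    ``clean_times`` optionally retains the artifact-free ground truth when the
    timeline came from the synthetic generator.  ``gap_after`` flags indices
    ``i`` such that the interval (times[i], times[i+1]) is a suspected gap.
    """

    times: np.ndarray
    stage: str = ""
    clean_times: np.ndarray | None = None
    gap_after: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        if self.times.ndim != 1:
            raise PhysioError("beat timestamps must be one-dimensional")
        if np.any(np.diff(self.times) <= 0):
            raise PhysioError("beat timestamps must be strictly increasing")

    @property
    def intervals(self) -> np.ndarray:
        """Inter-beat intervals in ms."""
        return np.diff(self.times) * 1000.0


@dataclass
class RejectionReport:
    n_beats: int
    n_rate_rejected: int = 0
    n_adaptive_rejected: int = 0
    n_gaps: int = 0
    usable: bool = True

    @property
    def n_rejected(self) -> int:
        return self.n_rate_rejected + self.n_adaptive_rejected


@dataclass
class HRVSeries:
    """Equidistant successive R-R-difference series (ms) for one stage."""

    times: np.ndarray
    values: np.ndarray
    sampling_interval: float
    percent_missing: float = 0.0
    stage: str = ""


def clean_beats(
    beats: BeatTimeline,
    bpm_bounds: tuple[float, float] = (25.0, 200.0),
    rel_threshold: float = 0.13,
    running_window: int = 10,
) -> tuple[BeatTimeline, RejectionReport]:
    """Reject implausible beats; flag gaps.

    Rules, applied to each interval ``rr`` between consecutive original
    beats:

    * ``rr`` shorter than the high-rate bound (60/bpm_high s) — reject the
      beat (spurious detection).
    * ``rr`` longer than the low-rate bound (60/bpm_low s) — keep the beat but
      flag the interval as a gap (missed beats).
    * ``rr`` more than ``rel_threshold`` *below* the running mean of the last
      ``running_window`` accepted intervals — reject the beat (adaptive
      cumulative-mean rule).  Intervals deviating far *above* the running mean
      are kept but excluded from the running mean.
    """
    t = beats.times
    report = RejectionReport(n_beats=len(t))
    if len(t) < 2:
        report.usable = False
        return beats, report
    rr_min = 60.0 / bpm_bounds[1]
    rr_max = 60.0 / bpm_bounds[0]

    kept = [0]
    gap_flags = [False]
    recent: list[float] = []
    last_kept = t[0]
    for i in range(1, len(t)):
        # intervals are measured from the last *kept* beat, so a second pass
        # sees exactly the interval sequence this pass produced (idempotence)
        rr = t[i] - last_kept
        if rr < rr_min:
            report.n_rate_rejected += 1
            continue
        if rr > rr_max:
            kept.append(i)
            gap_flags[-1] = True  # the interval *into* this beat is a gap
            gap_flags.append(False)
            report.n_gaps += 1
            last_kept = t[i]
            continue
        mean_rr = float(np.mean(recent[-running_window:])) if recent else None
        if mean_rr is not None and (mean_rr - rr) / mean_rr > rel_threshold:
            report.n_adaptive_rejected += 1
            continue
        kept.append(i)
        gap_flags.append(False)
        last_kept = t[i]
        if mean_rr is None or abs(rr - mean_rr) / mean_rr <= rel_threshold:
            recent.append(rr)

    if len(kept) < 2:
        report.usable = False
        return (
            BeatTimeline(times=t[kept], stage=beats.stage, clean_times=beats.clean_times),
            report,
        )
    cleaned = BeatTimeline(
        times=t[kept],
        stage=beats.stage,
        clean_times=beats.clean_times,
        gap_after=np.array(gap_flags[:-1] + [False], bool)[: len(kept)],
    )
    return cleaned, report


def _regular_interval_mask(timeline: BeatTimeline, tolerance: float = 0.3) -> np.ndarray:
    """True for intervals that are neither gaps nor large outliers.

    An interval is irregular when flagged as a gap during cleaning or when it
    deviates from the median interval by more than ``tolerance`` (fraction).
    Differences touching irregular intervals are excluded from rMSSD and from
    the HRV spline knots, since they reflect rejected beats, not physiology.
    """
    rr = np.diff(timeline.times)
    ok = np.ones(len(rr), bool)
    if timeline.gap_after is not None:
        ok &= ~timeline.gap_after[:-1] if len(timeline.gap_after) == len(rr) + 1 else ~timeline.gap_after[: len(rr)]
    med = np.median(rr)
    if med > 0:
        ok &= np.abs(rr - med) / med <= tolerance
    return ok


def rmssd(intervals: np.ndarray) -> float:
    """Root mean square of successive R-R interval differences (ms).

    ``intervals`` are R-R intervals in ms; returns NaN for fewer than two
    intervals.
    """
    intervals = np.asarray(intervals, float)
    if len(intervals) < 2:
        return float("nan")
    d = np.diff(intervals)
    return float(np.sqrt(np.mean(d**2)))


def stage_rmssd(timeline: BeatTimeline) -> float:
    """rMSSD over a cleaned timeline, skipping differences across irregular intervals."""
    rr = np.diff(timeline.times) * 1000.0
    if len(rr) < 2:
        return float("nan")
    ok = _regular_interval_mask(timeline)
    pair_ok = ok[:-1] & ok[1:]
    d = np.diff(rr)[pair_ok]
    if len(d) == 0:
        return float("nan")
    return float(np.sqrt(np.mean(d**2)))


def percent_missing(
    timeline: BeatTimeline,
    sampling_interval: float,
    duration: float | None = None,
    gap_threshold: float = 2.4,
) -> float:
    """Fraction of equidistant grid points falling inside beat gaps."""
    t = timeline.times
    if duration is None:
        duration = t[-1]
    grid = np.arange(0.0, duration, sampling_interval)
    if len(grid) == 0:
        return 1.0
    missing = np.zeros(len(grid), bool)
    missing |= grid < t[0]
    missing |= grid > t[-1]
    rr = np.diff(t)
    gap_after = timeline.gap_after[: len(rr)] if timeline.gap_after is not None else np.zeros(len(rr), bool)
    for i in np.nonzero((rr > gap_threshold) | gap_after)[0]:
        missing |= (grid > t[i]) & (grid < t[i + 1])
    return float(np.mean(missing))


def interpolate_hrv(
    beats: BeatTimeline,
    sampling_interval: float,
    duration: float | None = None,
) -> HRVSeries:
    """Cubic-spline successive R-R differences onto an equidistant grid.

    Knots sit at the later beat of each difference pair; differences touching
    irregular intervals (gaps, outliers) are dropped before fitting.
    """
    t = beats.times
    if len(t) < 4:
        raise PhysioError("need at least 4 beats for cubic interpolation")
    rr_ms = np.diff(t) * 1000.0
    ok = _regular_interval_mask(beats)
    pair_ok = ok[:-1] & ok[1:]
    knot_t = t[2:][pair_ok]
    knot_v = np.diff(rr_ms)[pair_ok]
    if len(knot_t) < 4:
        raise PhysioError("too few regular beats for cubic interpolation")
    if duration is None:
        duration = t[-1]
    grid = np.arange(0.0, duration, sampling_interval)
    spline = CubicSpline(knot_t, knot_v, extrapolate=False)
    values = spline(grid)
    values[np.isnan(values)] = 0.0
    pm = percent_missing(beats, sampling_interval, duration)
    return HRVSeries(
        times=grid,
        values=values,
        sampling_interval=sampling_interval,
        percent_missing=pm,
        stage=beats.stage,
    )


def exclusion_check(series: HRVSeries, missing_cutoff: float = 0.10) -> bool:
    """Stage usable iff no more than ``missing_cutoff`` of time points are missing."""
    return series.percent_missing <= missing_cutoff


# --- saliva alpha-amylase -------------------------------------------------

#: Stage -> (beginning sample, end sample) on the seven-sample schedule.
DEFAULT_SAA_STAGE_MAP: dict[str, tuple[str, str]] = {
    "baseline": ("pre_baseline", "pre_encoding"),
    "encoding": ("pre_encoding", "post_encoding"),
    "consolidation": ("post_encoding", "pre_recollection"),
    "recollection": ("pre_recollection", "post_recollection"),
}


def delta_saa(
    samples: pd.DataFrame,
    stage_map: dict[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """ΔsAA = sAA at stage end − sAA at stage beginning, per subject × stage.

    ``samples`` must have columns ``subject``, ``label``, ``value``; a missing
    endpoint propagates to a missing ΔsAA (never treated as zero).
    """
    stage_map = stage_map or DEFAULT_SAA_STAGE_MAP
    unknown = set(samples["label"]) - set(SAA_SCHEDULE)
    if unknown:
        raise PhysioError(f"unknown sAA schedule labels: {sorted(unknown)}")
    rows = []
    for subject, group in samples.groupby("subject"):
        levels = group.set_index("label")["value"]
        for stage, (start, end) in stage_map.items():
            v0 = levels.get(start, np.nan)
            v1 = levels.get(end, np.nan)
            rows.append(
                {"subject": subject, "stage": stage, "measure": "delta_saa", "value": float(v1) - float(v0)}
            )
    return pd.DataFrame(rows)


# --- arousal events and regressors ---------------------------------------

def local_minima_events(series: HRVSeries, window: float = 15.0) -> np.ndarray:
    """Times of strict local minima of the HRV series over a centered rolling window.

    A sample is an event iff it is the unique minimum of its ``window``-second
    centered window; when several samples tie for the minimum, only the
    earliest is flagged.
    """
    half = int(round(window / 2.0 / series.sampling_interval))
    if 2 * half + 1 < 3:
        raise PhysioError("window must span at least 3 samples")
    v = series.values
    if np.allclose(v, v[0]):
        warnings.warn("constant HRV series: no arousal events", stacklevel=2)
        return np.array([])
    events = []
    for i in range(len(v)):
        lo, hi = max(0, i - half), min(len(v), i + half + 1)
        win = v[lo:hi]
        if v[i] == win.min() and lo + int(np.argmin(win)) == i:
            events.append(series.times[i])
    return np.asarray(events)


def double_gamma_hrf(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response (peak 6 s, undershoot 16 s)."""
    t = np.asarray(t, float)
    h = gamma_dist.pdf(t, peak_delay) - gamma_dist.pdf(t, undershoot_delay) / ratio
    h[t < 0] = 0.0
    return h


def hrf_regressor(
    events: np.ndarray,
    series_length: int,
    sampling_interval: float,
) -> np.ndarray:
    """Unit impulses at event times convolved with the double-gamma HRF."""
    events = np.asarray(events, float)
    impulses = np.zeros(series_length)
    for e in events:
        k = int(round(e / sampling_interval))
        if 0 <= k < series_length:
            impulses[k] += 1.0
    kernel_t = np.arange(0, 32.0 + sampling_interval, sampling_interval)
    kernel = double_gamma_hrf(kernel_t)
    return np.convolve(impulses, kernel)[:series_length]
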