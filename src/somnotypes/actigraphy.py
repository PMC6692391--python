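"""Wrist-accelerometer sleep detection and sleep/circadian metrics.

Implements a heuristic sleep-period-time (SPT) window detector for wrist-worn
triaxial accelerometers that needs no sleep diary: posture is tracked through
the z-angle (the dorsal-ventral tilt of the wrist), sustained postural
inactivity is found by thresholding a rolling median of the absolute z-angle
change, and the longest inactivity block in each noon-to-noon analysis day is
taken as the night's sleep opportunity.  Within the SPT-window, sleep episodes
are runs of posture stability (angle change < 5 degrees) lasting at least
5 minutes; their total gives sleep duration, their count sleep fragmentation,
and their ratio to the SPT duration sleep efficiency.  L5/M10 timing (least
active 5-h / most active 10-h window) summarise circadian rest-activity phase.

All epoch intervals are half-open ``[start, end)`` with 0-based indexing.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "AccelEpochSeries",
    "SptWindow",
    "SleepDayMetrics",
    "PersonSleepSummary",
    "z_angle_from_triaxial",
    "rolling_median_abs_change",
    "movement_threshold",
    "detect_inactivity_bouts",
    "merge_bouts_to_blocks",
    "detect_spt_window",
    "detect_sleep_episodes",
    "compute_day_metrics",
    "summarize_person",
    "SleepWindowAnalyzer",
]


def z_angle_from_triaxial(ax, ay, az):
    """Dorsal-ventral tilt angle in degrees from raw triaxial acceleration.

    z_angle = arctan(az / sqrt(ax^2 + ay^2)), in [-90, 90] degrees.
    """
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    az = np.asarray(az, dtype=float)
    return np.degrees(np.arctan2(az, np.hypot(ax, ay)))


@dataclass
class AccelEpochSeries:
    """Uniformly sampled z-angle + activity trace for one person.

    Parameters
    ----------
    person_id : str
    epoch_seconds : float
        Epoch length; 5 s by default upstream.
    start_time : pandas.Timestamp
        Wall-clock time of the first epoch.
    z_angle : ndarray of degrees in [-90, 90]
    activity : ndarray of nonnegative movement magnitudes (e.g. ENMO in mg)
    """

    person_id: str
    epoch_seconds: float
    start_time: pd.Timestamp
    z_angle: np.ndarray
    activity: np.ndarray

    def __post_init__(self):
        self.z_angle = np.asarray(self.z_angle, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")
        if self.z_angle.shape != self.activity.shape or self.z_angle.ndim != 1:
            raise ValueError("z_angle and activity must be 1-D and equal length")
        if np.nanmax(np.abs(self.z_angle)) > 90 + 1e-9:
            raise ValueError("z-angle outside [-90, 90] degrees")
        if np.nanmin(self.activity) < 0:
            raise ValueError("activity must be nonnegative")
        self.start_time = pd.Timestamp(self.start_time)

    @property
    def n_epochs(self) -> int:
        return self.z_angle.shape[0]

    def epochs_per_day(self) -> int:
        return int(round(86400.0 / self.epoch_seconds))

    def day_slices(self) -> list[tuple[int, int]]:
        """Half-open epoch ranges of the full noon-to-noon analysis days.

        The analysis day starts at noon so a nocturnal sleep window is never
        split across days.  Only days fully covered by the trace are returned.
        """
        n_day = self.epochs_per_day()
        first_noon = self.start_time.normalize() + pd.Timedelta(hours=12)
        if first_noon < self.start_time:
            first_noon += pd.Timedelta(days=1)
        offset = (first_noon - self.start_time).total_seconds() / self.epoch_seconds
        start = int(math.ceil(offset - 1e-9))
        out = []
        while start + n_day <= self.n_epochs:
            out.append((start, start + n_day))
            start += n_day
        return out


@dataclass(frozen=True)
class SptWindow:
    """Sleep-period-time window: half-open epoch interval [onset, wake)."""

    day_index: int
    onset_epoch: int
    wake_epoch: int

    def __post_init__(self):
        if self.onset_epoch >= self.wake_epoch:
            raise ValueError("SPT onset must precede wake")

    @property
    def n_epochs(self) -> int:
        return self.wake_epoch - self.onset_epoch


@dataclass
class SleepDayMetrics:
    day_index: int
    sleep_duration_min: float
    spt_duration_min: float
    sleep_efficiency: float
    n_sleep_bouts: int
    sleep_midpoint_min: float  # minutes from day start (noon)
    l5_timing_hours: float     # hours since previous midnight
    m10_timing_hours: float    # hours since previous midday
    diurnal_inactivity_min: float


@dataclass
class PersonSleepSummary:
    person_id: str
    n_days: int
    sleep_duration_mean_min: float
    sleep_duration_sd_min: float
    sleep_efficiency_mean: float
    n_sleep_bouts_mean: float
    sleep_midpoint_mean_min: float
    l5_timing_mean_hours: float
    m10_timing_mean_hours: float
    diurnal_inactivity_mean_min: float


def _window_epochs(window_min: float, epoch_seconds: float) -> int:
    w = int(round(window_min * 60.0 / epoch_seconds))
    if w < 1:
        raise ValueError("window shorter than one epoch")
    return w


def rolling_median_abs_change(z_angle, window_min: float = 5.0,
                              epoch_seconds: float = 5.0) -> np.ndarray:
    """Centered rolling median of the absolute change in z-angle.

    The per-epoch absolute change |z[i] - z[i-1]| (leading value repeated so
    the series keeps the input length) is smoothed with a centered median
    window of ``window_min`` minutes; edge windows are truncated to the
    available epochs.
    """
    z = np.asarray(z_angle, dtype=float)
    if z.size < 2:
        raise ValueError("need at least 2 epochs")
    w = _window_epochs(window_min, epoch_seconds)
    if w % 2 == 0:
        w += 1  # odd count so the window is symmetric about each epoch
    d = np.abs(np.diff(z))
    d = np.concatenate([d[:1], d])
    if w == 1:
        return d
    return (
        pd.Series(d).rolling(w, center=True, min_periods=1).median().to_numpy()
    )


def movement_threshold(rolled, percentile: float = 10.0,
                       multiplier: float = 15.0) -> float:
    """Movement/non-movement threshold for one analysis day.

    The given percentile (linear-interpolation quantile) of the rolled
    |z-angle change| series, scaled by ``multiplier``.  The multiplier of 15
    follows the upstream open-source heuristic; ``multiplier=1`` uses the bare
    percentile.
    """
    rolled = np.asarray(rolled, dtype=float)
    if rolled.size == 0:
        raise ValueError("empty series")
    return multiplier * float(np.quantile(rolled, percentile / 100.0))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean mask, as half-open intervals."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    edges = np.flatnonzero(np.diff(m.astype(np.int8)))
    starts = list(edges[m[edges + 1]] + 1)
    ends = list(edges[~m[edges + 1]] + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(m.size)
    return list(zip(starts, ends))


def detect_inactivity_bouts(nonmovement_mask, min_duration_min: float = 30.0,
                            epoch_seconds: float = 5.0) -> list[tuple[int, int]]:
    """Maximal non-movement runs of at least ``min_duration_min`` minutes."""
    min_epochs = _window_epochs(min_duration_min, epoch_seconds)
    return [(s, e) for s, e in _runs(nonmovement_mask) if e - s >= min_epochs]


def merge_bouts_to_blocks(bouts, max_gap_min: float = 60.0,
                          epoch_seconds: float = 5.0) -> list[tuple[int, int]]:
    """Combine inactivity bouts separated by gaps < ``max_gap_min`` minutes.

    Merging is transitive (strictly-less-than gap rule); a block spans the
    first onset to the last end of its member bouts.
    """
    bouts = list(bouts)
    for (s0, e0), (s1, e1) in zip(bouts, bouts[1:]):
        if s1 < e0 or s0 >= e0 or s1 >= e1:
            raise ValueError("bouts must be sorted, disjoint half-open intervals")
    if not bouts:
        return []
    gap_epochs = max_gap_min * 60.0 / epoch_seconds
    blocks = [list(bouts[0])]
    for s, e in bouts[1:]:
        if s - blocks[-1][1] < gap_epochs:
            blocks[-1][1] = e
        else:
            blocks.append([s, e])
    return [tuple(b) for b in blocks]


def detect_spt_window(blocks, day_index: int = 0) -> SptWindow | None:
    """Longest inactivity block in the day (ties -> earliest onset).

    Returns None when the day has no blocks (SPT flagged missing).
    """
    blocks = list(blocks)
    if not blocks:
        return None
    s, e = max(blocks, key=lambda b: (b[1] - b[0], -b[0]))
    return SptWindow(day_index=day_index, onset_epoch=int(s), wake_epoch=int(e))


def detect_sleep_episodes(z_angle, spt: SptWindow, angle_change_deg: float = 5.0,
                          min_duration_min: float = 5.0,
                          window_min: float = 5.0,
                          epoch_seconds: float = 5.0,
                          rolled=None) -> list[tuple[int, int]]:
    """Posture-stable runs >= ``min_duration_min`` inside the SPT-window.

    An epoch is posture-stable when the rolling |z-angle change| metric is
    below ``angle_change_deg``.  Pass ``rolled`` to reuse a precomputed
    metric; otherwise it is computed from ``z_angle``.
    """
    z = np.asarray(z_angle, dtype=float)
    if spt.onset_epoch < 0 or spt.wake_epoch > z.size:
        raise ValueError("SPT-window outside trace")
    if rolled is None:
        rolled = rolling_median_abs_change(z, window_min, epoch_seconds)
    stable = np.asarray(rolled)[spt.onset_epoch:spt.wake_epoch] < angle_change_deg
    min_epochs = _window_epochs(min_duration_min, epoch_seconds)
    return [
        (s + spt.onset_epoch, e + spt.onset_epoch)
        for s, e in _runs(stable)
        if e - s >= min_epochs
    ]


def _extreme_activity_window(activity: np.ndarray, window_epochs: int,
                             find_min: bool) -> int:
    """Start epoch of the extreme moving-average window (ties -> earliest)."""
    if window_epochs > activity.size:
        raise ValueError("window longer than the day")
    c = np.concatenate([[0.0], np.cumsum(activity, dtype=float)])
    sums = c[window_epochs:] - c[:-window_epochs]
    return int(np.argmin(sums) if find_min else np.argmax(sums))


def compute_day_metrics(trace: AccelEpochSeries, spt: SptWindow, episodes,
                        bouts, day_slice: tuple[int, int] | None = None,
                        l5_window_h: float = 5.0,
                        m10_window_h: float = 10.0) -> SleepDayMetrics:
    """Per-day sleep, fragmentation, and circadian metrics.

    ``bouts`` are the day's unmerged inactivity bouts; those falling outside
    the SPT-window contribute to diurnal inactivity.  ``day_slice`` is the
    day's half-open epoch range (defaults to the ``spt.day_index``-th full
    analysis day of the trace).
    """
    if spt.n_epochs == 0:
        raise ValueError("SPT duration zero")
    if day_slice is None:
        day_slice = trace.day_slices()[spt.day_index]
    d0, d1 = day_slice
    eps_min = trace.epoch_seconds / 60.0

    sleep_epochs = sum(e - s for s, e in episodes)
    spt_min = spt.n_epochs * eps_min
    sleep_min = sleep_epochs * eps_min

    # inactivity bouts outside the SPT-window, clipped to the analysis day
    diurnal_epochs = 0
    for s, e in bouts:
        s, e = max(s, d0), min(e, d1)
        if s >= e:
            continue
        overlap = max(0, min(e, spt.wake_epoch) - max(s, spt.onset_epoch))
        diurnal_epochs += (e - s) - overlap

    activity_day = trace.activity[d0:d1]
    l5_epochs = int(round(l5_window_h * 3600.0 / trace.epoch_seconds))
    m10_epochs = int(round(m10_window_h * 3600.0 / trace.epoch_seconds))
    l5_start = _extreme_activity_window(activity_day, l5_epochs, find_min=True)
    m10_start = _extreme_activity_window(activity_day, m10_epochs, find_min=False)
    eps_h = trace.epoch_seconds / 3600.0
    # window midpoints in hours from the day's start (noon)
    l5_mid_h = (l5_start + l5_epochs / 2.0) * eps_h
    m10_mid_h = (m10_start + m10_epochs / 2.0) * eps_h

    return SleepDayMetrics(
        day_index=spt.day_index,
        sleep_duration_min=sleep_min,
        spt_duration_min=spt_min,
        sleep_efficiency=sleep_min / spt_min,
        n_sleep_bouts=len(episodes),
        sleep_midpoint_min=((spt.onset_epoch + spt.wake_epoch) / 2.0 - d0) * eps_min,
        l5_timing_hours=(l5_mid_h + 12.0) % 24.0,  # hours since previous midnight
        m10_timing_hours=m10_mid_h,                # hours since previous midday
        diurnal_inactivity_min=diurnal_epochs * eps_min,
    )


def summarize_person(days, person_id: str = "") -> PersonSleepSummary:
    """Across-day means (and the sample SD of sleep duration, n-1 denominator).

    Days without an SPT-window (None entries) are excluded; a single valid day
    reports the SD as missing (NaN).
    """
    days = [d for d in days if d is not None]
    if not days:
        raise ValueError("no valid days to summarize")
    dur = np.array([d.sleep_duration_min for d in days], dtype=float)
    sd = float(np.std(dur, ddof=1)) if dur.size > 1 else float("nan")
    mean = lambda attr: float(np.mean([getattr(d, attr) for d in days]))
    return PersonSleepSummary(
        person_id=person_id,
        n_days=len(days),
        sleep_duration_mean_min=float(dur.mean()),
        sleep_duration_sd_min=sd,
        sleep_efficiency_mean=mean("sleep_efficiency"),
        n_sleep_bouts_mean=mean("n_sleep_bouts"),
        sleep_midpoint_mean_min=mean("sleep_midpoint_min"),
        l5_timing_mean_hours=mean("l5_timing_hours"),
        m10_timing_mean_hours=mean("m10_timing_hours"),
        diurnal_inactivity_mean_min=mean("diurnal_inactivity_min"),
    )


class SleepWindowAnalyzer(BaseEstimator):
    """SPT-window detector and sleep/circadian metric extractor.

    Estimator over :class:`AccelEpochSeries` traces.  ``fit`` runs the full
    heuristic per noon-to-noon analysis day; the fitted attributes expose the
    per-day audit trail (thresholds, bouts, blocks, windows, episodes) plus
    tidy per-day and per-person tables.

    Parameters
    ----------
    rolling_window_min : float, default 5
        Length of the centered rolling-median window (minutes).
    percentile : float, default 10
        Percentile of the rolled series that seeds the movement threshold.
    threshold_multiplier : float, default 15
        Scale factor on the percentile (1 = bare percentile).
    bout_min_min : float, default 30
        Minimum inactivity-bout duration (minutes).
    block_gap_min : float, default 60
        Bouts closer than this gap (minutes) are merged into blocks.
    episode_angle_deg : float, default 5
        Posture-stability threshold on the rolled metric (degrees).
    episode_min_min : float, default 5
        Minimum sleep-episode duration (minutes).
    threshold_scope : {'day', 'recording'}, default 'day'
        Whether the movement threshold is computed per analysis day or once
        over the whole recording.

    Attributes
    ----------
    rolled_ : ndarray            rolled |z-angle change| over the whole trace
    thresholds_ : list of float  per-day movement thresholds
    bouts_, blocks_ : list of list of (start, end) epoch intervals per day
    spt_windows_ : list of SptWindow or None per day
    episodes_ : list of list of (start, end) per day
    day_metrics_ : DataFrame     one row per valid day
    summary_ : PersonSleepSummary
    """

    def __init__(self, rolling_window_min=5.0, percentile=10.0,
                 threshold_multiplier=15.0, bout_min_min=30.0,
                 block_gap_min=60.0, episode_angle_deg=5.0,
                 episode_min_min=5.0, l5_window_h=5.0, m10_window_h=10.0,
                 threshold_scope="day"):
        self.rolling_window_min = rolling_window_min
        self.percentile = percentile
        self.threshold_multiplier = threshold_multiplier
        self.bout_min_min = bout_min_min
        self.block_gap_min = block_gap_min
        self.episode_angle_deg = episode_angle_deg
        self.episode_min_min = episode_min_min
        self.l5_window_h = l5_window_h
        self.m10_window_h = m10_window_h
        self.threshold_scope = threshold_scope

    def fit(self, trace: AccelEpochSeries, y=None):
        if self.threshold_scope not in ("day", "recording"):
            raise ValueError("threshold_scope must be 'day' or 'recording'")
        eps = trace.epoch_seconds
        days = trace.day_slices()
        if not days:
            raise ValueError("trace shorter than one full noon-to-noon day")
        self.rolled_ = rolling_median_abs_change(
            trace.z_angle, self.rolling_window_min, eps)
        rec_thr = movement_threshold(
            self.rolled_, self.percentile, self.threshold_multiplier)

        self.thresholds_, self.bouts_, self.blocks_ = [], [], []
        self.spt_windows_, self.episodes_ = [], []
        metrics = []
        for day_index, (d0, d1) in enumerate(days):
            rolled_day = self.rolled_[d0:d1]
            thr = (rec_thr if self.threshold_scope == "recording" else
                   movement_threshold(rolled_day, self.percentile,
                                      self.threshold_multiplier))
            # <= so the degenerate all-still (threshold 0) day still detects
            mask = rolled_day <= thr
            bouts = [(s + d0, e + d0) for s, e in
                     detect_inactivity_bouts(mask, self.bout_min_min, eps)]
            blocks = merge_bouts_to_blocks(bouts, self.block_gap_min, eps)
            spt = detect_spt_window(blocks, day_index)
            self.thresholds_.append(thr)
            self.bouts_.append(bouts)
            self.blocks_.append(blocks)
            self.spt_windows_.append(spt)
            if spt is None:
                self.episodes_.append([])
                continue
            episodes = detect_sleep_episodes(
                trace.z_angle, spt, self.episode_angle_deg,
                self.episode_min_min, self.rolling_window_min, eps,
                rolled=self.rolled_)
            self.episodes_.append(episodes)
            metrics.append(compute_day_metrics(
                trace, spt, episodes, bouts, (d0, d1),
                self.l5_window_h, self.m10_window_h))

        self.day_metrics_ = pd.DataFrame(
            [dataclasses.asdict(m) for m in metrics])
        self.summary_ = summarize_person(metrics, trace.person_id) \
            if metrics else None
        return self

    def fit_transform(self, trace: AccelEpochSeries, y=None) -> pd.DataFrame:
        """Fit and return the per-day metrics table."""
        return self.fit(trace).day_metrics_
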