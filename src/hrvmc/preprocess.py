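"""RR-interval preprocessing: outlier handling, quality gating, resampling.

The chain mirrors standard frequency-domain HRV practice: flag physiologically
implausible intervals and interpolate over them, rate the beat detections by
cross-detector agreement (SQI), cut the recording into 5-minute segments and
keep only high-quality ones, then resample the tachogram onto a uniform 4 Hz
grid and band-limit it to 0.03-0.9 Hz with a zero-phase Butterworth filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline, interp1d

logger = logging.getLogger(__name__)

__all__ = [
    "RRSeries",
    "PeakAnnotations",
    "SegmentQuality",
    "UniformSeries",
    "detect_outliers",
    "interpolate_outliers",
    "compute_sqi",
    "segment_and_gate",
    "resample_uniform",
    "bandpass",
]


@dataclass
class RRSeries:
    """Beat times (s, strictly increasing) and the RR interval ending at each."""

    beat_times: np.ndarray
    intervals: np.ndarray
    outlier_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.beat_times.shape != self.intervals.shape:
            raise ValueError("beat_times and intervals must have equal length")
        if self.beat_times.size and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if self.outlier_flags is not None:
            self.outlier_flags = np.asarray(self.outlier_flags, dtype=bool)
            if self.outlier_flags.shape != self.intervals.shape:
                raise ValueError("outlier_flags length mismatch")

    def __len__(self) -> int:
        return self.intervals.size


@dataclass
class PeakAnnotations:
    """R-peak sample indices from one QRS detector."""

    sample_indices: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.sample_indices = np.asarray(self.sample_indices, dtype=np.int64)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.sample_indices.size and np.any(np.diff(self.sample_indices) <= 0):
            raise ValueError("sample indices must be strictly increasing")

    @property
    def times_s(self) -> np.ndarray:
        return self.sample_indices / self.sampling_rate_hz


@dataclass
class SegmentQuality:
    segment_index: int
    mean_sqi: float
    is_high_quality: bool


@dataclass
class UniformSeries:
    """Tachogram values (s) on a uniform time grid."""

    values: np.ndarray
    start_time_s: float
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.values.size) / self.sampling_rate_hz


def detect_outliers(
    rr: RRSeries,
    min_rr_s: float = 0.3,
    max_rr_s: float = 2.0,
    rel_jump: float = 0.2,
    window: int = 5,
) -> np.ndarray:
    """Flag implausible RR intervals.

    An interval is an outlier if it is shorter than ``min_rr_s`` (beats too
    close together, e.g. a double detection), longer than ``max_rr_s`` (a gap
    from missed beats), or deviates from the local running median by more
    than the relative fraction ``rel_jump``.
    """
    if len(rr) == 0:
        raise ValueError("empty RR series")
    x = rr.intervals
    flags = (x < min_rr_s) | (x > max_rr_s)
    if x.size >= window:
        med = signal.medfilt(x, kernel_size=window if window % 2 else window + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(x - med) / med
        flags |= np.nan_to_num(rel, nan=np.inf) > rel_jump
    return flags


def interpolate_outliers(
    rr: RRSeries, flags: np.ndarray, mode: str = "linear"
) -> RRSeries:
    """Replace flagged intervals by interpolating the clean ones over time.

    Flags at the edges of the series are filled by nearest-neighbour
    extrapolation.  ``mode`` is ``"linear"`` (default, no overshoot) or
    ``"cubic"``.
    """
    flags = np.asarray(flags, dtype=bool)
    good = ~flags
    if good.sum() < 2:
        raise ValueError("fewer than two unflagged intervals; series unrecoverable")
    if not flags.any():
        return RRSeries(rr.beat_times.copy(), rr.intervals.copy(),
                        outlier_flags=flags.copy())
    t_good = rr.beat_times[good]
    x_good = rr.intervals[good]
    if mode == "cubic" and good.sum() >= 4:
        interp = CubicSpline(t_good, x_good)
        filled = interp(rr.beat_times)
    else:
        interp = interp1d(
            t_good, x_good, kind="linear", bounds_error=False,
            fill_value=(x_good[0], x_good[-1]),
        )
        filled = interp(rr.beat_times)
    out = rr.intervals.copy()
    out[flags] = filled[flags]
    logger.debug("interpolated %d flagged intervals", int(flags.sum()))
    return RRSeries(rr.beat_times.copy(), out, outlier_flags=flags.copy())


def compute_sqi(
    ann_a: PeakAnnotations,
    ann_b: PeakAnnotations,
    tol_s: float = 0.15,
) -> tuple[np.ndarray, float]:
    """Beat-level agreement between two independent QRS detectors.

    Peaks are matched greedily one-to-one within +/- ``tol_s`` seconds.  The
    signal quality index is n_matched / (n_a + n_b - n_matched), the fraction
    of the union of detections on which the detectors agree; 1 means perfect
    agreement.  Returns per-beat match flags for ``ann_a`` and the SQI.
    """
    if tol_s <= 0:
        raise ValueError("tol_s must be positive")
    ta, tb = ann_a.times_s, ann_b.times_s
    if ta.size == 0 and tb.size == 0:
        raise ValueError("SQI undefined: both annotation lists are empty")
    matched = np.zeros(ta.size, dtype=bool)
    i = j = n_match = 0
    while i < ta.size and j < tb.size:
        dt = ta[i] - tb[j]
        if abs(dt) <= tol_s:
            matched[i] = True
            n_match += 1
            i += 1
            j += 1
        elif dt < 0:
            i += 1
        else:
            j += 1
    denom = ta.size + tb.size - n_match
    return matched, (n_match / denom if denom else 0.0)


def segment_and_gate(
    rr: RRSeries,
    sqi_per_beat: np.ndarray,
    window_s: float = 300.0,
    threshold: float = 0.9,
) -> list[tuple[RRSeries, SegmentQuality]]:
    """Cut the series into consecutive non-overlapping windows and rate each.

    A segment is high quality when the mean per-beat SQI strictly exceeds
    ``threshold`` (0.9 by default); low-quality segments are returned with
    ``is_high_quality=False`` so callers can exclude them from the matrix.
    Returns an empty list (with a logged warning) for recordings shorter
    than one window.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    sqi_per_beat = np.asarray(sqi_per_beat, dtype=float)
    if sqi_per_beat.shape != rr.intervals.shape:
        raise ValueError("sqi_per_beat length mismatch")
    t0, t_end = rr.beat_times[0], rr.beat_times[-1]
    n_seg = int((t_end - t0) // window_s)
    if n_seg == 0:
        logger.warning(
            "recording span %.1f s shorter than one %.0f s window; no segments",
            t_end - t0, window_s,
        )
        return []
    out = []
    for k in range(n_seg):
        lo, hi = t0 + k * window_s, t0 + (k + 1) * window_s
        sel = (rr.beat_times >= lo) & (rr.beat_times < hi)
        if not sel.any():
            continue
        mean_sqi = float(sqi_per_beat[sel].mean())
        quality = SegmentQuality(
            segment_index=k, mean_sqi=mean_sqi,
            is_high_quality=mean_sqi > threshold,
        )
        seg = RRSeries(rr.beat_times[sel], rr.intervals[sel])
        out.append((seg, quality))
    n_low = sum(not q.is_high_quality for _, q in out)
    if n_low:
        logger.info("rejected %d/%d segments below SQI %.2f", n_low, len(out), threshold)
    return out


def resample_uniform(rr: RRSeries, fs: float = 4.0) -> UniformSeries:
    """Cubic interpolation of the tachogram onto a uniform grid at ``fs`` Hz.

    The grid spans [first beat time, last beat time]; the interpolant passes
    through the original (beat time, interval) nodes.
    """
    if len(rr) < 4:
        raise ValueError("need at least 4 beats to resample")
    spline = CubicSpline(rr.beat_times, rr.intervals)
    t0, t_end = rr.beat_times[0], rr.beat_times[-1]
    n = int(np.floor((t_end - t0) * fs)) + 1
    grid = t0 + np.arange(n) / fs
    return UniformSeries(values=spline(grid), start_time_s=t0, sampling_rate_hz=fs)


def bandpass(
    series: UniformSeries,
    low: float = 0.03,
    high: float = 0.9,
    order: int = 4,
) -> UniformSeries:
    """Zero-phase Butterworth band-pass of the resampled tachogram.

    ``order`` is the overall band-pass order (an order-4 band-pass uses a
    2nd-order low/high prototype).  Applied forward-backward (filtfilt) so
    LF/HF peak positions are not phase-shifted; length is preserved.
    """
    nyq = series.sampling_rate_hz / 2.0
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {nyq} Hz")
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    sos = signal.butter(
        max(order // 2, 1), [low, high], btype="bandpass",
        fs=series.sampling_rate_hz, output="sos",
    )
    filtered = signal.sosfiltfilt(sos, series.values)
    return UniformSeries(
        values=filtered, start_time_s=series.start_time_s,
        sampling_rate_hz=series.sampling_rate_hz,
    )
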