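"""Smoothing, breath-event detection and respiration-rate conversion.

The raw ROI trace carries ripple from sensor noise and mask jitter, so it is
smoothed with a normalized Gaussian window before peak counting.  Exhaled air
is warmer than the nostril rim, so each breath shows as a warm peak; the
respiration rate follows the observer protocol: the time taken to complete
five breaths (first to sixth detected peak) is converted to breaths per
minute.  When fewer than six peaks are available the estimator falls back to
the reciprocal mean inter-peak interval.

Kernel defaults: window length = 2 s of samples rounded up to odd, sigma =
window/6 (so the window spans ±3 sigma).  Both are exposed because no single
setting suits every frame rate and rate band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .exceptions import EstimationError, InvalidParameterError
from .extraction import RoiSeries

#: Default smoothing window duration, seconds.
DEFAULT_WINDOW_S = 2.0
#: Gaps of missing frames up to this duration are linearly interpolated;
#: longer gaps split the trace and the longest segment is analysed.
MAX_INTERP_GAP_S = 1.0

DEFAULT_MIN_PROMINENCE = 0.3
DEFAULT_MIN_DISTANCE_S = 0.5


@dataclass(frozen=True)
class BreathTrace:
    """Smoothed breathing trace plus provenance of its smoothing."""

    values: np.ndarray
    fps: float
    method: str
    kernel_params: dict = field(default_factory=dict)
    frame_offset: int = 0  # first frame of the analysed segment

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if not np.isfinite(arr).all():
            raise InvalidParameterError("breath trace must be finite everywhere")
        object.__setattr__(self, "values", arr)

    @property
    def times(self) -> np.ndarray:
        return (self.frame_offset + np.arange(self.values.size)) / self.fps


@dataclass(frozen=True)
class RrEstimate:
    """Respiration-rate estimate with the rule and events that produced it."""

    rate_bpm: float
    n_events: int
    window_duration: float  # seconds spanned by the events used
    event_indices: np.ndarray  # absolute frame indices, strictly increasing
    rule: str  # "five_breaths" or "mean_interval"


def gaussian_kernel(window_len: int, sigma: float) -> np.ndarray:
    """Symmetric Gaussian weights ∝ exp(−k²/(2σ²)), normalized to sum to 1."""
    if window_len < 3 or window_len % 2 == 0:
        raise InvalidParameterError(f"window_len must be odd and >= 3, got {window_len}")
    if sigma <= 0:
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    k = np.arange(window_len) - (window_len - 1) / 2
    w = np.exp(-(k**2) / (2.0 * sigma**2))
    return w / w.sum()


def default_kernel(fps: float, window_s: float = DEFAULT_WINDOW_S) -> np.ndarray:
    """Kernel for ``window_s`` seconds at ``fps``: odd length, sigma = len/6."""
    n = max(3, int(math.ceil(window_s * fps)))
    if n % 2 == 0:
        n += 1
    return gaussian_kernel(n, n / 6.0)


def fill_missing(series: RoiSeries, max_gap_s: float = MAX_INTERP_GAP_S) -> tuple[np.ndarray, int]:
    """Resolve missing frames: interpolate short gaps, else keep the longest run.

    Interior NaN gaps no longer than ``max_gap_s`` are linearly interpolated;
    longer gaps (and NaN at either edge) split the trace, and the longest
    contiguous finite segment is returned together with its start index.
    """
    values = np.asarray(series.values, dtype=float).copy()
    finite = np.isfinite(values)
    if not finite.any():
        raise EstimationError("series has no non-missing frames")
    max_gap = int(round(max_gap_s * series.fps))
    # interpolate short interior gaps
    idx = np.arange(values.size)
    gap_start = None
    for i in range(values.size):
        if not finite[i] and gap_start is None:
            gap_start = i
        elif finite[i] and gap_start is not None:
            if gap_start > 0 and (i - gap_start) <= max_gap:
                values[gap_start:i] = np.interp(
                    idx[gap_start:i], idx[finite], values[finite]
                )
            gap_start = None
    finite = np.isfinite(values)
    # longest finite run
    best_start, best_len, start = 0, 0, None
    for i in range(values.size + 1):
        if i < values.size and finite[i]:
            if start is None:
                start = i
        elif start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    return values[best_start : best_start + best_len], best_start


def smooth(series: RoiSeries, kernel: np.ndarray | None = None) -> BreathTrace:
    """Convolve the ROI series with a Gaussian window (reflected boundaries).

    A constant segment is returned unchanged, keeping the unit DC gain exact
    rather than subject to rounding.
    """
    if kernel is None:
        kernel = default_kernel(series.fps)
    kernel = np.asarray(kernel, dtype=float)
    segment, offset = fill_missing(series)
    if segment.size < kernel.size:
        raise EstimationError(
            f"series has {segment.size} usable samples, fewer than the "
            f"window length {kernel.size}"
        )
    if np.ptp(segment) == 0:
        smoothed = segment
    else:
        smoothed = ndimage.convolve1d(segment, kernel, mode="reflect")
    params = {"window_len": int(kernel.size), "sigma_equivalent": _sigma_of(kernel)}
    return BreathTrace(
        values=smoothed,
        fps=series.fps,
        method=series.method,
        kernel_params=params,
        frame_offset=offset,
    )


def _sigma_of(kernel: np.ndarray) -> float:
    k = np.arange(kernel.size) - (kernel.size - 1) / 2
    return float(np.sqrt(np.sum(kernel * k**2)))


def detect_peaks(
    trace: BreathTrace,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_distance_s: float = DEFAULT_MIN_DISTANCE_S,
    invert: bool = False,
) -> np.ndarray:
    """Breath events: prominent local maxima of the smoothed trace.

    ``min_prominence`` is a fraction of the trace's robust range (the
    5th–95th percentile span, which ignores brief boundary transients of the
    smoothing while spanning essentially the full swing of a periodic
    signal); ``min_distance_s`` suppresses secondary maxima closer than that
    many seconds.  With ``invert=True`` troughs are counted instead (for
    conventions where the inhale dominates the signal).  A flat trace yields
    zero events.
    """
    if not 0.0 < min_prominence < 1.0:
        raise InvalidParameterError(
            f"min_prominence must lie in (0, 1), got {min_prominence}"
        )
    if min_distance_s <= 0:
        raise InvalidParameterError(f"min_distance_s must be positive, got {min_distance_s}")
    values = -trace.values if invert else trace.values
    vrange = float(np.ptp(values))
    if vrange == 0:
        return np.array([], dtype=int)
    span = float(np.percentile(values, 95) - np.percentile(values, 5))
    if span == 0:
        span = vrange
    distance = max(1, int(round(min_distance_s * trace.fps)))
    peaks, _ = signal.find_peaks(
        values, prominence=min_prominence * span, distance=distance
    )
    return peaks.astype(int)


def rr_from_five_breaths(duration_s: float) -> float:
    """Convert the time taken to complete five breaths into breaths/minute.

    Ten seconds for five breaths is a rate of 30 per minute.
    """
    if duration_s <= 0:
        raise InvalidParameterError(f"duration_s must be positive, got {duration_s}")
    return 5.0 / duration_s * 60.0


def estimate_rr(
    trace: BreathTrace,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_distance_s: float = DEFAULT_MIN_DISTANCE_S,
    invert: bool = False,
) -> RrEstimate:
    """Respiration rate from detected breath events.

    Primary rule: the span from the first to the sixth peak covers exactly
    five breaths and is converted with :func:`rr_from_five_breaths`.  With
    fewer than six peaks the rate falls back to 60 / mean inter-peak
    interval.  Fewer than two peaks is an error (no breathing signal).
    """
    peaks = detect_peaks(trace, min_prominence, min_distance_s, invert)
    if peaks.size < 2:
        raise EstimationError("no breathing signal: fewer than two breath events")
    times = peaks / trace.fps
    if peaks.size >= 6:
        duration = float(times[5] - times[0])
        rate = rr_from_five_breaths(duration)
        rule = "five_breaths"
    else:
        duration = float(times[-1] - times[0])
        rate = 60.0 / float(np.mean(np.diff(times)))
        rule = "mean_interval"
    return RrEstimate(
        rate_bpm=rate,
        n_events=int(peaks.size),
        window_duration=duration,
        event_indices=peaks + trace.frame_offset,
        rule=rule,
    )
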