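"""Mask-thermal fusion and per-frame ROI aggregation.

Multiplying the binary mask with the co-registered temperature frame selects
exactly the nostril pixels; three rival statistics then condense each frame's
ROI to a scalar:

* ``max``  — maximum in-mask temperature (°C), the classic IRT statistic;
* ``mean`` — in-mask sum divided by the mask pixel count (°C);
* ``sum``  — raw in-mask integral (units °C·pixels, tracked explicitly so
  the trace is never compared 1:1 against the °C methods).

The mean is invariant to how many pixels the ROI occupies (camera distance,
one vs two visible nostrils), while the sum scales with ROI area and the max
ignores spatial extent entirely — the crux of the method comparison.

Frames whose mask is empty (no detection) become missing values; the
breathing module later interpolates short gaps and splits the trace at long
ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import EmptyRoiError, InvalidParameterError
from .thermal_io import MaskSequence, ThermalSequence, require_aligned

METHODS = ("max", "mean", "sum")


@dataclass(frozen=True)
class RoiSeries:
    """Per-frame aggregated ROI temperature — the raw breathing trace.

    ``values[i]`` is NaN exactly for the frame indices in ``missing``.
    """

    values: np.ndarray
    pixel_counts: np.ndarray
    method: str
    fps: float
    missing: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "pixel_counts", np.asarray(self.pixel_counts, dtype=np.int64))
        if self.method not in METHODS:
            raise InvalidParameterError(f"method must be one of {METHODS}, got {self.method!r}")

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


def roi_values(frame, mask) -> np.ndarray:
    """Temperatures at the mask-positive pixels (empty array if mask is empty)."""
    frame = np.asarray(frame, dtype=float)
    mask = np.asarray(mask)
    if frame.shape != mask.shape:
        raise InvalidParameterError(
            f"frame shape {frame.shape} does not match mask shape {mask.shape}"
        )
    return frame[mask == 1]


def aggregate(values, method: str) -> float:
    """Condense a collection of ROI temperatures with one of the three statistics."""
    if method not in METHODS:
        raise InvalidParameterError(f"method must be one of {METHODS}, got {method!r}")
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise EmptyRoiError("cannot aggregate an empty ROI (missing frame)")
    if method == "max":
        return float(values.max())
    if method == "mean":
        return float(values.sum() / values.size)
    return float(values.sum())


def extract_series(thermal: ThermalSequence, masks: MaskSequence, method: str) -> RoiSeries:
    """Aggregate every frame's ROI; empty-mask frames are recorded as missing."""
    require_aligned(thermal, masks)
    n = thermal.n_frames
    values = np.full(n, np.nan)
    counts = masks.pixel_counts
    missing = []
    for i in range(n):
        if counts[i] == 0:
            missing.append(i)
            continue
        values[i] = aggregate(thermal.frames[i][masks.frames[i] == 1], method)
    return RoiSeries(
        values=values,
        pixel_counts=counts,
        method=method,
        fps=thermal.fps,
        missing=frozenset(missing),
    )


def value_count(n_frames: int, height: int, width: int) -> int:
    """Total number of temperature values in a recording, T·H·W."""
    for name, v in (("n_frames", n_frames), ("height", height), ("width", width)):
        if int(v) != v or v <= 0:
            raise InvalidParameterError(f"{name} must be a positive integer, got {v!r}")
    return int(n_frames) * int(height) * int(width)


def value_count_from_rate(height: int, width: int, fps: float, duration_s: float) -> int:
    """Value count for ``duration_s`` seconds at ``fps``: (fps·s)·H·W."""
    if fps <= 0 or duration_s <= 0:
        raise InvalidParameterError("fps and duration_s must be positive")
    n_frames = fps * duration_s
    if abs(n_frames - round(n_frames)) > 1e-9:
        raise InvalidParameterError(
            f"fps × duration = {n_frames} is not a whole number of frames"
        )
    return value_count(int(round(n_frames)), height, width)
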