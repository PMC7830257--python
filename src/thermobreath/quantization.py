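"""Optimal quantization of temperature frames for display and detection.

Skin temperature drifts with the ambient, so a fixed colour map loses the
facial morphology.  Quantization remaps each frame's continuous temperatures
onto display intensities through a dynamically chosen threshold that best
separates the warm object (the nose) from the cooler background and thereby
maximizes contrast.  The separation criterion used here is maximal
between-class variance over a histogram of the frame — Otsu's criterion, the
standard operationalisation of "best separates object from background".

Pixels below the threshold map to intensity 0; the remaining temperature
range [threshold, max] maps linearly onto [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError, InvalidParameterError
from .thermal_io import ThermalSequence

DEFAULT_N_BINS = 256


@dataclass(frozen=True)
class QuantizedFrame:
    """8-bit display frame plus the separating temperature that produced it."""

    pixels: np.ndarray  # H × W uint8
    threshold: float  # °C

    @property
    def object_mask(self) -> np.ndarray:
        """Boolean map of pixels assigned to the object (above threshold)."""
        return self.pixels > 0


def otsu_threshold(values, n_bins: int = DEFAULT_N_BINS) -> float:
    """Temperature threshold maximizing between-class variance.

    The value range is divided into ``n_bins`` equal-width histogram bins and
    every interior bin edge is scored as a candidate threshold; the edge with
    maximal between-class variance wins, ties broken toward the lower
    threshold.  Pixels strictly below the returned temperature belong to the
    background class.

    Raises
    ------
    DegenerateInputError
        If the input holds fewer than two distinct values.
    """
    if n_bins < 2:
        raise InvalidParameterError(f"n_bins must be >= 2, got {n_bins}")
    vals = np.asarray(values, dtype=float).ravel()
    if vals.size < 2 or np.ptp(vals) == 0:
        raise DegenerateInputError("constant input: no threshold separates two classes")
    hist, edges = np.histogram(vals, bins=n_bins, range=(vals.min(), vals.max()))
    p = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    # split after bin k-1 <=> threshold at edges[k], k = 1 .. n_bins-1
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    cum_mean = np.cumsum(p * centers)[:-1]
    total_mean = float(np.sum(p * centers))
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = cum_mean / w0
        m1 = (total_mean - cum_mean) / w1
        var_between = w0 * w1 * (m0 - m1) ** 2
    var_between = np.where((w0 > 0) & (w1 > 0), var_between, -np.inf)
    # ties (to within relative rounding noise) break toward the lower threshold:
    # empty-bin plateaus between well-separated modes are exact ties analytically
    best = var_between.max()
    k = int(np.argmax(var_between >= best - abs(best) * 1e-12)) + 1
    return float(edges[k])


def apply_quantization(frame, threshold: float, upper: float | None = None) -> np.ndarray:
    """Map temperatures to intensities at a fixed threshold.

    Sub-threshold pixels become 0; [threshold, upper] maps linearly onto
    [0, 255] (``upper`` defaults to the frame maximum).  The map is monotone
    in temperature for a fixed threshold.
    """
    frame = np.asarray(frame, dtype=float)
    if upper is None:
        upper = float(frame.max())
    out = np.zeros(frame.shape, dtype=np.uint8)
    above = frame >= threshold
    if upper > threshold:
        scaled = np.clip((frame[above] - threshold) / (upper - threshold), 0.0, 1.0)
        out[above] = np.rint(scaled * 255).astype(np.uint8)
    else:
        out[above] = 255
    return out


def optimal_quantize(frame, n_bins: int = DEFAULT_N_BINS) -> QuantizedFrame:
    """Quantize one temperature frame with a per-frame dynamic threshold."""
    frame = np.asarray(frame, dtype=float)
    threshold = otsu_threshold(frame, n_bins=n_bins)
    return QuantizedFrame(pixels=apply_quantization(frame, threshold), threshold=threshold)


def quantize_sequence(
    seq: ThermalSequence,
    n_bins: int = DEFAULT_N_BINS,
    per_recording: bool = False,
) -> list[QuantizedFrame]:
    """Quantize every frame of a sequence.

    With ``per_recording=True`` a single threshold is computed from the
    pooled values of the whole recording and applied to every frame;
    otherwise each frame is thresholded dynamically on its own.
    """
    if per_recording:
        threshold = otsu_threshold(seq.frames, n_bins=n_bins)
        return [
            QuantizedFrame(pixels=apply_quantization(f, threshold), threshold=threshold)
            for f in seq.frames
        ]
    return [optimal_quantize(f, n_bins=n_bins) for f in seq.frames]
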