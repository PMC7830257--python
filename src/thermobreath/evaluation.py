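"""Agreement statistics and the aggregation-method comparison experiment.

Two questions close the pipeline.  First, do algorithm-derived respiration
rates agree with reference rates?  That is answered by ordinary least
squares of estimated on true rate over a batch of simulated recordings
(:func:`recovery_experiment`), summarized by slope, intercept, R² and the
two-sided p-value for zero slope.  Second, how do the three ROI statistics
behave under the confounds that plague real recordings?
:func:`method_comparison` extracts all three traces from one scene and flags
artifacts: an abrupt level shift co-timed with a change in mask pixel count
(the signature of a distance change or a one-vs-two-nostril switch, which
corrupt the sum but not the mean), and a trace whose dynamic range is too
small to carry a breathing signal (the failure mode of the max statistic on
shallow breaths).

A level shift is declared when the ratio of the trailing to leading 5 s
trace medians around a pixel-count change-point leaves [1/1.25, 1.25];
change-points are read off the pixel-count series, which is exact for
synthetic scenes.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .breathing import BreathTrace, RrEstimate, estimate_rr, smooth
from .exceptions import DegenerateInputError, EstimationError, InvalidParameterError
from .extraction import METHODS, RoiSeries, extract_series
from .synthetic_scene import SceneBundle, SceneConfig, generate_scene

logger = logging.getLogger(__name__)

#: Default geometry for batch experiments: quarter-scale frames with the
#: nostril geometry scaled 1:4.  The aggregation statistics are computed on
#: exact masks, so they do not depend on the rendering resolution.
EXPERIMENT_TEMPLATE = SceneConfig(
    frame_height=160,
    frame_width=120,
    fps=10.0,
    duration_s=60.0,
    amplitude=2.0,
    baseline_temp=33.0,
    ambient_temp=20.0,
    nostril_radii=(5.0, 3.5),
    nostril_separation=22.0,
    motion_amplitude=2.0,
    render_rgb=False,
)

LEVEL_SHIFT_RATIO = 1.25
LEVEL_SHIFT_WINDOW_S = 5.0
CHANGE_POINT_REL_JUMP = 0.2
LOW_AMPLITUDE_RANGE = 0.2  # °C peak-to-trough below which a trace is flagged


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of one rate series on another."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares of ``y`` on ``x`` with intercept.

    R² = 1 − SSres/SStot; the p-value is the two-sided test of zero slope.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise InvalidParameterError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise InvalidParameterError(f"need n >= 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("x is constant; the slope is undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=int(x.size),
    )


def run_pipeline(scene: SceneBundle, method: str = "mean") -> RrEstimate:
    """Ground-truth-mask pipeline: extract → smooth → estimate rate."""
    series = extract_series(scene.thermal, scene.gt_masks, method)
    return estimate_rr(smooth(series))


def recovery_experiment(
    n_recordings: int = 50,
    rate_range: tuple[float, float] = (10.0, 60.0),
    noise_sd: float = 0.07,
    seed: int = 0,
    scene_template: SceneConfig | None = None,
) -> tuple[pd.DataFrame, RegressionResult]:
    """True-vs-estimated rate agreement over a batch of simulated recordings.

    ``n_recordings`` scenes are generated with true rates drawn uniformly
    from ``rate_range`` (seeded); each runs the full ground-truth-mask,
    mean-method pipeline; estimated is regressed on true.  Scenes whose rate
    estimation fails are recorded as missing, excluded from the regression
    and counted in the log.
    """
    if n_recordings < 3:
        raise InvalidParameterError(f"need n_recordings >= 3, got {n_recordings}")
    template = EXPERIMENT_TEMPLATE if scene_template is None else scene_template
    rng = np.random.default_rng(seed)
    rates = rng.uniform(rate_range[0], rate_range[1], size=n_recordings)
    scene_seeds = rng.integers(0, 2**31 - 1, size=n_recordings)
    rows = []
    for k in range(n_recordings):
        config = dataclasses.replace(
            template,
            rate_bpm=float(rates[k]),
            noise_sd=noise_sd,
            seed=int(scene_seeds[k]),
        )
        scene = generate_scene(config)
        try:
            est = run_pipeline(scene, method="mean")
            rows.append(
                {
                    "recording": k,
                    "true_rate_bpm": config.rate_bpm,
                    "estimated_rate_bpm": est.rate_bpm,
                    "n_events": est.n_events,
                    "rule": est.rule,
                }
            )
        except EstimationError as exc:
            logger.warning("recording %d (%.1f bpm) failed: %s", k, config.rate_bpm, exc)
            rows.append(
                {
                    "recording": k,
                    "true_rate_bpm": config.rate_bpm,
                    "estimated_rate_bpm": np.nan,
                    "n_events": 0,
                    "rule": "failed",
                }
            )
    table = pd.DataFrame(rows)
    ok = table["estimated_rate_bpm"].notna()
    n_failed = int((~ok).sum())
    if n_failed:
        logger.warning("%d of %d recordings failed rate estimation", n_failed, n_recordings)
    regression = linear_regression(
        table.loc[ok, "true_rate_bpm"], table.loc[ok, "estimated_rate_bpm"]
    )
    return table, regression


# ---------------------------------------------------------------------------
# Method comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LevelShift:
    """Trace level ratio around one pixel-count change-point."""

    frame_index: int
    ratio: float
    flagged: bool


@dataclass(frozen=True)
class MethodReport:
    """One aggregation method's trace, artifact flags and rate estimate."""

    method: str
    series: RoiSeries
    trace: BreathTrace
    level_shifts: tuple[LevelShift, ...]
    low_amplitude: bool
    rr: RrEstimate | None

    @property
    def flagged(self) -> bool:
        return self.low_amplitude or any(s.flagged for s in self.level_shifts)


@dataclass(frozen=True)
class MethodComparisonReport:
    """Side-by-side behaviour of max/mean/sum on one scene."""

    methods: dict[str, MethodReport]
    change_points: tuple[int, ...]


def pixel_count_change_points(
    pixel_counts: np.ndarray, rel_jump: float = CHANGE_POINT_REL_JUMP
) -> tuple[int, ...]:
    """Frames where the mask pixel count jumps by more than ``rel_jump``."""
    counts = np.asarray(pixel_counts, dtype=float)
    prev = counts[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(np.diff(counts)) / np.where(prev > 0, prev, np.nan)
    return tuple(int(i) + 1 for i in np.nonzero(rel > rel_jump)[0])


def level_shift_ratio(
    values: np.ndarray,
    change_point: int,
    fps: float,
    window_s: float = LEVEL_SHIFT_WINDOW_S,
) -> float:
    """Ratio of trailing to leading window medians around a change-point."""
    w = max(1, int(round(window_s * fps)))
    leading = values[max(0, change_point - w) : change_point]
    trailing = values[change_point : change_point + w]
    leading = leading[np.isfinite(leading)]
    trailing = trailing[np.isfinite(trailing)]
    if leading.size == 0 or trailing.size == 0:
        raise InvalidParameterError(
            f"change-point {change_point} leaves an empty comparison window"
        )
    return float(np.median(trailing) / np.median(leading))


def method_comparison(
    scene: SceneBundle,
    window_s: float = LEVEL_SHIFT_WINDOW_S,
    shift_ratio: float = LEVEL_SHIFT_RATIO,
    low_amplitude_range: float = LOW_AMPLITUDE_RANGE,
) -> MethodComparisonReport:
    """Extract all three traces from one scene and flag their artifacts."""
    counts = scene.gt_masks.pixel_counts
    change_points = pixel_count_change_points(counts)
    reports: dict[str, MethodReport] = {}
    for method in METHODS:
        series = extract_series(scene.thermal, scene.gt_masks, method)
        trace = smooth(series)
        shifts = []
        for cp in change_points:
            ratio = level_shift_ratio(series.values, cp, series.fps, window_s)
            shifts.append(
                LevelShift(
                    frame_index=cp,
                    ratio=ratio,
                    flagged=not (1.0 / shift_ratio <= ratio <= shift_ratio),
                )
            )
        low_amplitude = float(np.ptp(trace.values)) < low_amplitude_range
        try:
            rr = estimate_rr(trace)
        except EstimationError:
            rr = None
        reports[method] = MethodReport(
            method=method,
            series=series,
            trace=trace,
            level_shifts=tuple(shifts),
            low_amplitude=low_amplitude,
            rr=rr,
        )
    return MethodComparisonReport(methods=reports, change_points=change_points)
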