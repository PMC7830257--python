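"""Synthetic paired RGB/thermal scenes with ground truth.

Real recordings of hospitalized calves come as co-registered RGB video plus
per-pixel temperature streams; none are redistributable, so this module
renders a controllable stand-in: two elliptical nostrils on a uniform
ambient background whose interior temperature oscillates with breathing
(warm exhale, cool inhale), plus the confounds that matter for comparing
aggregation statistics —

* slow sinusoidal translation of the nose (animal/camera sway),
* a per-frame distance scale factor multiplying the apparent nostril radii
  (camera moved closer or further), which changes ROI *area* but not the
  interior temperature values,
* a per-frame visible-nostril count in {1, 2} (the head turns and one
  nostril leaves view), which with equal per-nostril geometry doubles the
  ROI area,
* i.i.d. Gaussian sensor noise, default sd 0.07 °C (the stated sensitivity
  of the handheld camera class being emulated).

The breathing waveform is a pure sinusoid, baseline + amplitude·sin(2πft):
no waveform is dictated by the physiology at this fidelity and the sinusoid
makes analytic expectations (peak count, mean ROI temperature) available in
closed form.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from skimage.draw import ellipse as draw_ellipse

from .exceptions import GenerationError, InvalidParameterError, ValidationError
from .segmentation import AnnotationSet
from .thermal_io import MaskSequence, RgbSequence, ThermalSequence


def thermal_signal(t: float, rate_bpm: float, baseline: float, amplitude: float):
    """Nostril interior temperature at time ``t`` seconds.

    baseline + amplitude·sin(2π·(rate_bpm/60)·t); the warm peak is the
    exhale.  Periodic with period 60/rate_bpm seconds.  Accepts scalar or
    array ``t``.
    """
    if not rate_bpm > 0:
        raise InvalidParameterError(f"rate_bpm must be positive, got {rate_bpm}")
    return baseline + amplitude * np.sin(2.0 * np.pi * (rate_bpm / 60.0) * np.asarray(t, float))


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic recording.

    Geometry defaults follow the emulated stream: 640 (height) × 480 (width)
    pixels at 10 frames per second.  ``nostril_radii`` are the (row, col)
    semi-axes of each elliptical nostril at distance scale 1;
    ``nostril_separation`` is the centre-to-centre distance at scale 1.
    ``nostril_schedule`` / ``distance_schedule`` may be a scalar (constant)
    or one entry per frame.
    """

    frame_height: int = 640
    frame_width: int = 480
    fps: float = 10.0
    duration_s: float = 60.0
    rate_bpm: float = 30.0
    baseline_temp: float = 33.0  # °C at mid-breath
    amplitude: float = 2.0  # °C, half peak-to-trough
    ambient_temp: float = 20.0  # °C background
    noise_sd: float = 0.07  # °C, sensor sensitivity
    nostril_schedule: object = 2  # per-frame count in {1, 2}, or scalar
    distance_schedule: object = 1.0  # per-frame scale > 0, or scalar
    motion_amplitude: float = 5.0  # px, sinusoidal nose translation
    motion_period_s: float = 20.0  # s, period of that translation
    nostril_radii: tuple[float, float] = (20.0, 14.0)  # (row, col) semi-axes, px
    nostril_separation: float = 90.0  # px at scale 1
    seed: int = 0
    render_rgb: bool = True

    def __post_init__(self) -> None:
        if self.frame_height < 1 or self.frame_width < 1:
            raise InvalidParameterError("frame dimensions must be >= 1")
        if self.fps <= 0 or self.duration_s <= 0:
            raise InvalidParameterError("fps and duration_s must be positive")
        if self.rate_bpm <= 0:
            raise InvalidParameterError("rate_bpm must be positive")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise InvalidParameterError("amplitude and noise_sd must be >= 0")
        ns = self.resolved_nostril_schedule()
        if not np.isin(ns, (1, 2)).all():
            raise InvalidParameterError("nostril_schedule entries must be 1 or 2")
        ds = self.resolved_distance_schedule()
        if not (ds > 0).all():
            raise InvalidParameterError("distance_schedule entries must be > 0")

    @property
    def n_frames(self) -> int:
        n = self.fps * self.duration_s
        if abs(n - round(n)) > 1e-9:
            raise InvalidParameterError(
                f"fps × duration = {n} is not a whole number of frames"
            )
        return int(round(n))

    def _resolve(self, sched, dtype) -> np.ndarray:
        arr = np.asarray(sched)
        if arr.ndim == 0:
            return np.full(self.n_frames, arr[()], dtype=dtype)
        if arr.size != self.n_frames:
            raise InvalidParameterError(
                f"schedule length {arr.size} does not match {self.n_frames} frames"
            )
        return arr.astype(dtype)

    def resolved_nostril_schedule(self) -> np.ndarray:
        return self._resolve(self.nostril_schedule, int)

    def resolved_distance_schedule(self) -> np.ndarray:
        return self._resolve(self.distance_schedule, float)

    def to_yaml(self, path) -> Path:
        doc = asdict(self)
        for key in ("nostril_schedule", "distance_schedule"):
            v = doc[key]
            doc[key] = v.tolist() if isinstance(v, np.ndarray) else v
        doc["nostril_radii"] = list(doc["nostril_radii"])
        path = Path(path)
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "SceneConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if "nostril_radii" in doc:
            doc["nostril_radii"] = tuple(doc["nostril_radii"])
        return cls(**doc)


@dataclass(frozen=True)
class SceneBundle:
    """Everything one synthetic recording produces, with ground truth."""

    thermal: ThermalSequence
    gt_masks: MaskSequence
    gt_annotations: AnnotationSet
    true_rate_bpm: float
    config: SceneConfig
    rgb: RgbSequence | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.thermal.frames.shape != self.gt_masks.frames.shape:
            raise ValidationError("thermal and gt_masks must share shape")
        if self.rgb is not None and (
            self.rgb.n_frames != self.thermal.n_frames
            or self.rgb.frame_shape != self.thermal.frame_shape
        ):
            raise ValidationError("rgb must match the thermal grid and frame count")
        if self.true_rate_bpm != self.config.rate_bpm:
            raise ValidationError("true_rate_bpm must equal config.rate_bpm")


def _nostril_centers(config: SceneConfig, frame: int, t: float, scale: float, count: int):
    cr = config.frame_height / 2.0
    cc = config.frame_width / 2.0 + config.motion_amplitude * np.sin(
        2.0 * np.pi * t / config.motion_period_s
    )
    if count == 2:
        half = config.nostril_separation * scale / 2.0
        return [(cr, cc - half), (cr, cc + half)]
    return [(cr, cc)]


def _check_inside(config: SceneConfig, frame: int, centers, radii) -> None:
    r_rad, c_rad = radii
    for cr, cc in centers:
        if (
            cr - r_rad < 0
            or cr + r_rad > config.frame_height - 1
            or cc - c_rad < 0
            or cc + c_rad > config.frame_width - 1
        ):
            raise GenerationError(
                f"nostril ellipse leaves the frame bounds at frame {frame} "
                f"(center ({cr:.1f}, {cc:.1f}), radii ({r_rad:.1f}, {c_rad:.1f}))"
            )


def generate_scene(config: SceneConfig) -> SceneBundle:
    """Render a full synthetic recording from its config.

    Thermal frames are ``ambient_temp`` everywhere except the nostril
    ellipse interiors, which carry ``thermal_signal(t)``; Gaussian noise of
    sd ``noise_sd`` is then added over the whole frame.  Ground-truth masks
    mark exactly the nostril interiors.  Identical configs (including seed)
    render bit-identical bundles; the noise is the only stochastic element.
    """
    H, W, T = config.frame_height, config.frame_width, config.n_frames
    rng = np.random.default_rng(config.seed)
    n_sched = config.resolved_nostril_schedule()
    d_sched = config.resolved_distance_schedule()

    thermal = np.full((T, H, W), config.ambient_temp, dtype=float)
    masks = np.zeros((T, H, W), dtype=np.uint8)
    rgb = np.zeros((T, H, W, 3), dtype=np.uint8) if config.render_rgb else None

    for i in range(T):
        t = i / config.fps
        scale = d_sched[i]
        radii = (config.nostril_radii[0] * scale, config.nostril_radii[1] * scale)
        centers = _nostril_centers(config, i, t, scale, n_sched[i])
        _check_inside(config, i, centers, radii)
        temp = float(thermal_signal(t, config.rate_bpm, config.baseline_temp, config.amplitude))
        for cr, cc in centers:
            rr, cc_px = draw_ellipse(cr, cc, radii[0], radii[1], shape=(H, W))
            masks[i, rr, cc_px] = 1
        inside = masks[i] == 1
        thermal[i][inside] = temp
        if config.noise_sd > 0:
            thermal[i] += rng.normal(0.0, config.noise_sd, size=(H, W))
        if rgb is not None:
            rgb[i] = _render_rgb_frame(config, centers, radii, (H, W))

    bundle = SceneBundle(
        thermal=ThermalSequence(frames=thermal, fps=config.fps),
        gt_masks=MaskSequence(frames=masks),
        gt_annotations=AnnotationSet.from_mask_sequence(MaskSequence(frames=masks)),
        true_rate_bpm=config.rate_bpm,
        config=config,
        rgb=RgbSequence(frames=rgb) if rgb is not None else None,
    )
    return bundle


def _render_rgb_frame(config, centers, radii, shape) -> np.ndarray:
    # Cosmetic: flat background, darker muzzle ellipse, darkest nostrils.
    frame = np.full(shape + (3,), 150, dtype=np.uint8)
    mean_c = float(np.mean([c for _, c in centers]))
    mean_r = float(np.mean([r for r, _ in centers]))
    muzzle_r = radii[0] * 2.5
    muzzle_c = (config.nostril_separation / 2.0 + radii[1]) * 1.6 + radii[1]
    rr, cc = draw_ellipse(mean_r, mean_c, muzzle_r, muzzle_c, shape=shape)
    frame[rr, cc] = 90
    for cr, cc_ in centers:
        rr, cc2 = draw_ellipse(cr, cc_, radii[0], radii[1], shape=shape)
        frame[rr, cc2] = 35
    return frame


def render_breath_extent(config: SceneConfig, extent_fraction: float) -> tuple[ThermalSequence, MaskSequence]:
    """Scene variant where only part of each nostril participates in the breath.

    A shallow breath warms a small core of the nostril; a deep breath warms
    (nearly) all of it.  ``extent_fraction`` is the area fraction of each
    nostril that oscillates with :func:`thermal_signal`; the rest of the
    nostril stays at ``baseline_temp``.  Peak temperature is therefore equal
    across extents while the ROI mean amplitude scales with the extent —
    this is the pair of scenes on which the max statistic cannot tell a
    shallow breath from a deep one.

    Note the baseline rim also clamps the ROI *maximum* during the cool
    inhale half-cycle, so two extents strictly below 1 share an identical
    max trace; at extent 1 there is no rim and the max follows the trough.
    """
    if not 0.0 < extent_fraction <= 1.0:
        raise InvalidParameterError(
            f"extent_fraction must lie in (0, 1], got {extent_fraction}"
        )
    H, W, T = config.frame_height, config.frame_width, config.n_frames
    rng = np.random.default_rng(config.seed)
    n_sched = config.resolved_nostril_schedule()
    d_sched = config.resolved_distance_schedule()
    shrink = float(np.sqrt(extent_fraction))

    thermal = np.full((T, H, W), config.ambient_temp, dtype=float)
    masks = np.zeros((T, H, W), dtype=np.uint8)
    for i in range(T):
        t = i / config.fps
        scale = d_sched[i]
        radii = (config.nostril_radii[0] * scale, config.nostril_radii[1] * scale)
        centers = _nostril_centers(config, i, t, scale, n_sched[i])
        _check_inside(config, i, centers, radii)
        temp = float(thermal_signal(t, config.rate_bpm, config.baseline_temp, config.amplitude))
        for cr, cc in centers:
            rr, cc_px = draw_ellipse(cr, cc, radii[0], radii[1], shape=(H, W))
            masks[i, rr, cc_px] = 1
            thermal[i, rr, cc_px] = config.baseline_temp
            rr2, cc2 = draw_ellipse(cr, cc, radii[0] * shrink, radii[1] * shrink, shape=(H, W))
            thermal[i, rr2, cc2] = temp
        if config.noise_sd > 0:
            thermal[i] += rng.normal(0.0, config.noise_sd, size=(H, W))
    return ThermalSequence(frames=thermal, fps=config.fps), MaskSequence(frames=masks)
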