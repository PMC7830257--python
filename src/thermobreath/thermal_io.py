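"""Sequence containers and file I/O for the thermography pipeline.

The pipeline works on three co-registered per-frame stacks: radiometric
temperature frames (°C), optional RGB frames, and binary region-of-interest
masks selecting the nostril pixels.  All three share one pixel grid and one
frame clock; co-registration is assumed, not computed.

On-disk layout
--------------
* Thermal sequences: HDF5 file with a 3-D float dataset ``temperature`` of
  shape (T, H, W) and attributes ``fps``, ``emissivity``, ``units``;
  alternatively a directory of per-frame CSV files (``frame_000000.csv`` ...)
  with a ``metadata.json`` sidecar — intended for small text fixtures only.
* Mask sequences: HDF5 dataset ``mask`` (T, H, W, uint8 in {0, 1}) or a
  directory of PNG frames where pixel 0 maps to mask 0 and 255 maps to 1;
  any other PNG value is rejected.
* RGB sequences: a directory of zero-padded PNG frames.
* Detections/annotations: JSON of the form
  ``{"frames": [{"index": i, "objects": [{"box": [r0, c0, r1, c1],
  "score": s, "mask_ref": null}]}]}`` with half-open pixel boxes; the
  readers and writers live in :mod:`thermobreath.segmentation`.

Temperatures are validated against the device range −20..400 °C on
construction and on load.  Emissivity is carried as metadata only; no
radiometric correction is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np

from .exceptions import AlignmentError, FormatError, ValidationError

#: Radiometric range of the supported sensor class, °C.
TEMP_MIN = -20.0
TEMP_MAX = 400.0

#: Default emissivity carried as metadata (typical handheld-camera setting).
DEFAULT_EMISSIVITY = 0.95


def _as_3d_float(frames) -> np.ndarray:
    arr = np.asarray(frames, dtype=float)
    if arr.ndim != 3:
        raise ValidationError(f"expected a (T, H, W) stack, got shape {arr.shape}")
    if min(arr.shape) < 1:
        raise ValidationError(f"all of T, H, W must be >= 1, got {arr.shape}")
    return arr


@dataclass(frozen=True)
class ThermalSequence:
    """Ordered stack of temperature frames in °C with frame-rate metadata."""

    frames: np.ndarray
    fps: float
    emissivity: float = DEFAULT_EMISSIVITY
    units: str = "°C"

    def __post_init__(self) -> None:
        arr = _as_3d_float(self.frames)
        object.__setattr__(self, "frames", arr)
        if not self.fps > 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        bad = ~np.isfinite(arr) | (arr < TEMP_MIN) | (arr > TEMP_MAX)
        if bad.any():
            t, r, c = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"temperature {arr[t, r, c]!r} °C at frame {t}, pixel ({r}, {c}) "
                f"outside the device range [{TEMP_MIN:g}, {TEMP_MAX:g}] °C"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]

    @property
    def value_count(self) -> int:
        """Total number of temperature values, T·H·W."""
        return int(self.frames.size)

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds from the start of the recording."""
        return np.arange(self.n_frames) / self.fps


@dataclass(frozen=True)
class MaskSequence:
    """Per-frame binary ROI masks aligned to a thermal sequence."""

    frames: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValidationError(f"expected a (T, H, W) mask stack, got shape {arr.shape}")
        if not np.isin(arr, (0, 1)).all():
            bad = arr[~np.isin(arr, (0, 1))]
            raise ValidationError(f"mask values must be strictly 0/1, found {bad.flat[0]!r}")
        object.__setattr__(self, "frames", arr.astype(np.uint8))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]

    @property
    def pixel_counts(self) -> np.ndarray:
        """Number of ROI pixels in each frame."""
        return self.frames.sum(axis=(1, 2)).astype(np.int64)


@dataclass(frozen=True)
class RgbSequence:
    """Stack of 8-bit RGB frames recorded alongside the thermal stream."""

    frames: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames)
        if arr.ndim != 4 or arr.shape[-1] != 3:
            raise ValidationError(f"expected a (T, H, W, 3) stack, got shape {arr.shape}")
        if arr.min() < 0 or arr.max() > 255:
            raise ValidationError("RGB intensities must lie in [0, 255]")
        object.__setattr__(self, "frames", arr.astype(np.uint8))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]


def require_aligned(thermal: ThermalSequence, masks: MaskSequence) -> None:
    """Raise :class:`AlignmentError` unless the stacks share grid and clock."""
    if thermal.frames.shape != masks.frames.shape:
        raise AlignmentError(
            f"thermal shape {thermal.frames.shape} does not match "
            f"mask shape {masks.frames.shape}"
        )


# ---------------------------------------------------------------------------
# Thermal sequence I/O
# ---------------------------------------------------------------------------

def write_thermal_sequence(seq: ThermalSequence, path) -> Path:
    """Write a thermal sequence to HDF5 (canonical container)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("temperature", data=seq.frames)
        ds.attrs["fps"] = seq.fps
        ds.attrs["emissivity"] = seq.emissivity
        ds.attrs["units"] = seq.units
    return path


def write_thermal_csv_dir(seq: ThermalSequence, path) -> Path:
    """Write a thermal sequence as per-frame CSVs with a JSON sidecar.

    Text container for small fixtures; values round-trip to the printed
    precision (%.10g), not bit-exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        np.savetxt(path / f"frame_{i:06d}.csv", frame, delimiter=",", fmt="%.10g")
    meta = {
        "fps": seq.fps,
        "emissivity": seq.emissivity,
        "units": seq.units,
        "n_frames": seq.n_frames,
        "frame_shape": list(seq.frame_shape),
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))
    return path


def read_thermal_sequence(path) -> ThermalSequence:
    """Read a thermal sequence from HDF5 or a per-frame CSV directory."""
    path = Path(path)
    if path.is_dir():
        return _read_thermal_csv_dir(path)
    with h5py.File(path, "r") as f:
        if "temperature" not in f:
            raise FormatError(f"{path}: missing 'temperature' dataset")
        ds = f["temperature"]
        if "fps" not in ds.attrs:
            raise FormatError(f"{path}: missing required 'fps' attribute")
        frames = ds[...]
        declared = ds.shape
        fps = float(ds.attrs["fps"])
        emissivity = float(ds.attrs.get("emissivity", DEFAULT_EMISSIVITY))
        units = str(ds.attrs.get("units", "°C"))
    if frames.size != int(np.prod(declared)):
        raise FormatError(f"{path}: value count disagrees with declared shape {declared}")
    return ThermalSequence(frames=frames, fps=fps, emissivity=emissivity, units=units)


def _read_thermal_csv_dir(path: Path) -> ThermalSequence:
    sidecar = path / "metadata.json"
    if not sidecar.exists():
        raise FormatError(f"{path}: missing metadata.json sidecar")
    meta = json.loads(sidecar.read_text())
    if "fps" not in meta:
        raise FormatError(f"{path}: sidecar missing required 'fps' entry")
    files = sorted(path.glob("frame_*.csv"))
    if not files:
        raise FormatError(f"{path}: no frame_*.csv files found")
    frames = np.stack([np.atleast_2d(np.loadtxt(f, delimiter=",")) for f in files])
    expected = meta.get("n_frames")
    if expected is not None and frames.shape[0] != expected:
        raise FormatError(
            f"{path}: sidecar declares {expected} frames, found {frames.shape[0]}"
        )
    shape = meta.get("frame_shape")
    if shape is not None and list(frames.shape[1:]) != list(shape):
        raise FormatError(
            f"{path}: sidecar declares frame shape {shape}, found {frames.shape[1:]}"
        )
    return ThermalSequence(
        frames=frames,
        fps=float(meta["fps"]),
        emissivity=float(meta.get("emissivity", DEFAULT_EMISSIVITY)),
        units=str(meta.get("units", "°C")),
    )


# ---------------------------------------------------------------------------
# Mask sequence I/O
# ---------------------------------------------------------------------------

def write_mask_sequence(masks: MaskSequence, path) -> Path:
    """Write masks to HDF5 (``.h5``/``.hdf5`` suffix) or a PNG directory."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("mask", data=masks.frames.astype(np.uint8))
        return path
    path.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(masks.frames):
        iio.imwrite(path / f"mask_{i:06d}.png", (frame * 255).astype(np.uint8))
    return path


def read_mask_sequence(path) -> MaskSequence:
    """Read masks from HDF5 or a PNG directory (0 ↔ 0, 255 ↔ 1)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("mask_*.png"))
        if not files:
            raise FormatError(f"{path}: no mask_*.png files found")
        frames = []
        for f in files:
            img = np.asarray(iio.imread(f))
            if img.ndim == 3:
                img = img[..., 0]
            if not np.isin(img, (0, 255)).all():
                bad = img[~np.isin(img, (0, 255))].flat[0]
                raise ValidationError(f"{f}: mask PNG value {bad} is neither 0 nor 255")
            frames.append((img == 255).astype(np.uint8))
        return MaskSequence(frames=np.stack(frames))
    with h5py.File(path, "r") as f:
        if "mask" not in f:
            raise FormatError(f"{path}: missing 'mask' dataset")
        frames = f["mask"][...]
    return MaskSequence(frames=frames)


# ---------------------------------------------------------------------------
# RGB sequence I/O
# ---------------------------------------------------------------------------

def write_rgb_sequence(rgb: RgbSequence, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(rgb.frames):
        iio.imwrite(path / f"frame_{i:06d}.png", frame)
    return path


def read_rgb_sequence(path) -> RgbSequence:
    path = Path(path)
    files = sorted(path.glob("frame_*.png"))
    if not files:
        raise FormatError(f"{path}: no frame_*.png files found")
    return RgbSequence(frames=np.stack([np.asarray(iio.imread(f)) for f in files]))
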