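"""ROI mask providers and detection-quality metrics.

The pipeline needs one binary nose mask per frame.  In production those come
from an external instance-segmentation system and enter through the JSON
importer; for controlled experiments this module provides an *oracle*
provider (perturbed ground truth) and a classical threshold detector built
on optimal quantization plus connected components.

Detection quality is scored the standard way for object detectors: a
detection is a true positive iff its IoU with a not-yet-matched ground truth
strictly exceeds the IoU threshold (default 0.5); precision = TP / detections,
recall = TP / ground truths; AP integrates the precision envelope over
recall (all-point interpolation); with a single class, mAP = AP.

Matching is greedy in descending score order, score ties broken by frame
index and then by input order, so results are independent of how equal-score
detections are permuted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.measure import label, regionprops
from skimage import morphology

from .exceptions import InvalidParameterError, UndefinedMetricError, DegenerateInputError
from .quantization import optimal_quantize
from .thermal_io import MaskSequence, ThermalSequence

logger = logging.getLogger(__name__)

Box = tuple[int, int, int, int]  # half-open (r0, c0, r1, c1)


def _validate_box(box) -> Box:
    r0, c0, r1, c1 = (int(v) for v in box)
    if r1 <= r0 or c1 <= c0:
        raise InvalidParameterError(f"degenerate box {box!r}: needs r1 > r0 and c1 > c0")
    return (r0, c0, r1, c1)


def mask_bbox(mask: np.ndarray) -> Box:
    """Tight half-open bounding box of a binary mask."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise InvalidParameterError("empty mask has no bounding box")
    return (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)


@dataclass(frozen=True)
class Detection:
    """One scored detection: half-open box, optional mask, confidence."""

    frame_index: int
    box: Box
    score: float = 1.0
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "box", _validate_box(self.box))
        if not 0.0 <= self.score <= 1.0:
            raise InvalidParameterError(f"score must lie in [0, 1], got {self.score}")
        if self.mask is not None:
            r0, c0, r1, c1 = self.box
            rows, cols = np.nonzero(self.mask)
            if rows.size and (
                rows.min() < r0 or rows.max() >= r1 or cols.min() < c0 or cols.max() >= c1
            ):
                raise InvalidParameterError("box does not contain all mask-positive pixels")


@dataclass(frozen=True)
class Annotation:
    """One ground-truth object (no score)."""

    box: Box
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "box", _validate_box(self.box))


@dataclass(frozen=True)
class AnnotationSet:
    """Ground-truth objects grouped by frame index."""

    frames: dict[int, tuple[Annotation, ...]]

    def __post_init__(self) -> None:
        clean = {
            int(i): tuple(objs) for i, objs in self.frames.items() if len(objs) > 0
        }
        object.__setattr__(self, "frames", clean)

    @property
    def n_objects(self) -> int:
        return sum(len(objs) for objs in self.frames.values())

    @classmethod
    def from_mask_sequence(cls, masks: MaskSequence) -> "AnnotationSet":
        """One annotation per 8-connected component of each frame's mask."""
        frames: dict[int, tuple[Annotation, ...]] = {}
        for i, frame in enumerate(masks.frames):
            objs = []
            for prop in regionprops(label(frame, connectivity=2)):
                comp = np.zeros(frame.shape, dtype=np.uint8)
                comp[tuple(prop.coords.T)] = 1
                objs.append(Annotation(box=mask_bbox(comp), mask=comp))
            if objs:
                frames[i] = tuple(objs)
        return cls(frames=frames)


@dataclass(frozen=True)
class DetectionEvaluation:
    """Precision/recall/AP summary at one IoU threshold (single class)."""

    precision: float
    recall: float
    ap: float
    map: float
    iou_threshold: float


# ---------------------------------------------------------------------------
# Overlap measures
# ---------------------------------------------------------------------------

def iou_box(a, b) -> float:
    """Intersection-over-union of two half-open pixel boxes; symmetric."""
    ar0, ac0, ar1, ac1 = _validate_box(a)
    br0, bc0, br1, bc1 = _validate_box(b)
    ih = max(0, min(ar1, br1) - max(ar0, br0))
    iw = max(0, min(ac1, bc1) - max(ac0, bc0))
    inter = ih * iw
    union = (ar1 - ar0) * (ac1 - ac0) + (br1 - br0) * (bc1 - bc0) - inter
    return inter / union


def iou_mask(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks on a shared grid."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise InvalidParameterError("both masks are empty; IoU is undefined")
    return float(np.logical_and(a, b).sum() / union)


# ---------------------------------------------------------------------------
# Matching and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchResult:
    """Greedy one-to-one assignment of detections to ground truths."""

    detections: tuple[Detection, ...]  # sorted by descending score
    is_tp: np.ndarray  # bool per sorted detection
    matched_gt: tuple[tuple[int, int] | None, ...]  # (frame, gt index) or None
    n_gt: int

    @property
    def n_tp(self) -> int:
        return int(self.is_tp.sum())


def _sorted_detections(dets) -> list[Detection]:
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, dets[i].frame_index, i))
    return [dets[i] for i in order]


def match_detections(
    dets,
    gts: AnnotationSet,
    iou_threshold: float = 0.5,
    use_mask_iou: bool = False,
) -> MatchResult:
    """Greedily match detections to ground truths frame by frame.

    Detections are visited in descending score order; each is matched to the
    highest-IoU still-unmatched ground truth of its frame, and counts as a
    true positive iff that IoU strictly exceeds ``iou_threshold``.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise InvalidParameterError(f"iou_threshold must lie in (0, 1), got {iou_threshold}")
    sorted_dets = _sorted_detections(list(dets))
    taken: set[tuple[int, int]] = set()
    is_tp = np.zeros(len(sorted_dets), dtype=bool)
    matched: list[tuple[int, int] | None] = []
    for d_idx, det in enumerate(sorted_dets):
        frame_gts = gts.frames.get(det.frame_index, ())
        best_iou, best_g = 0.0, None
        for g_idx, gt in enumerate(frame_gts):
            if (det.frame_index, g_idx) in taken:
                continue
            if use_mask_iou and det.mask is not None and gt.mask is not None:
                iou = iou_mask(det.mask, gt.mask)
            else:
                iou = iou_box(det.box, gt.box)
            if iou > best_iou:
                best_iou, best_g = iou, g_idx
        if best_g is not None and best_iou > iou_threshold:
            taken.add((det.frame_index, best_g))
            is_tp[d_idx] = True
            matched.append((det.frame_index, best_g))
        else:
            matched.append(None)
    return MatchResult(
        detections=tuple(sorted_dets),
        is_tp=is_tp,
        matched_gt=tuple(matched),
        n_gt=gts.n_objects,
    )


def precision_recall(tp: int, n_det: int, n_gt: int) -> tuple[float, float]:
    """Precision = TP / detections (0 when none); recall = TP / ground truths."""
    if n_gt == 0:
        raise UndefinedMetricError("recall is undefined with zero ground truths")
    if tp > min(n_det, n_gt):
        raise InvalidParameterError(f"tp={tp} exceeds min(n_det={n_det}, n_gt={n_gt})")
    precision = tp / n_det if n_det > 0 else 0.0
    return (precision, tp / n_gt)


def average_precision(
    dets,
    gts: AnnotationSet,
    iou_threshold: float = 0.5,
    use_mask_iou: bool = False,
) -> float:
    """All-point interpolated AP: integral of the precision envelope over recall."""
    if gts.n_objects == 0:
        raise UndefinedMetricError("AP is undefined with zero ground truths")
    result = match_detections(dets, gts, iou_threshold, use_mask_iou)
    if len(result.detections) == 0:
        return 0.0
    cum_tp = np.cumsum(result.is_tp)
    recall = cum_tp / result.n_gt
    precision = cum_tp / np.arange(1, len(cum_tp) + 1)
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recall, envelope):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def evaluate_detections(
    dets,
    gts: AnnotationSet,
    iou_threshold: float = 0.5,
    use_mask_iou: bool = False,
) -> DetectionEvaluation:
    """Precision, recall and AP at one IoU threshold; single class so mAP = AP."""
    result = match_detections(dets, gts, iou_threshold, use_mask_iou)
    precision, recall = precision_recall(result.n_tp, len(result.detections), result.n_gt)
    ap = average_precision(dets, gts, iou_threshold, use_mask_iou)
    return DetectionEvaluation(
        precision=precision, recall=recall, ap=ap, map=ap, iou_threshold=iou_threshold
    )


# ---------------------------------------------------------------------------
# Mask providers
# ---------------------------------------------------------------------------

def oracle_provider(
    gt_masks: MaskSequence,
    dilation: int = 0,
    drop_rate: float = 0.0,
    seed: int = 0,
) -> list[Detection]:
    """Detections derived from ground truth, optionally perturbed.

    Each 8-connected component becomes one detection with score 1.0.  With
    ``dilation`` > 0 every component is dilated by a disk of that radius
    (degrading IoU in a controlled way); with ``drop_rate`` > 0 each
    component is independently dropped with that probability, seeded.
    """
    if not 0.0 <= drop_rate < 1.0:
        raise InvalidParameterError(f"drop_rate must lie in [0, 1), got {drop_rate}")
    rng = np.random.default_rng(seed)
    footprint = morphology.disk(dilation) if dilation > 0 else None
    dets: list[Detection] = []
    for i, frame in enumerate(gt_masks.frames):
        for prop in regionprops(label(frame, connectivity=2)):
            if drop_rate > 0 and rng.random() < drop_rate:
                continue
            comp = np.zeros(frame.shape, dtype=np.uint8)
            comp[tuple(prop.coords.T)] = 1
            if footprint is not None:
                comp = morphology.dilation(comp.astype(bool), footprint).astype(np.uint8)
            dets.append(Detection(frame_index=i, box=mask_bbox(comp), score=1.0, mask=comp))
    return dets


def threshold_detector(
    thermal: ThermalSequence,
    min_area: int,
    max_area: int,
    n_bins: int = 256,
) -> list[Detection]:
    """Classical detector: optimal quantization → connected components.

    Each frame is quantized with a dynamic threshold; above-threshold pixels
    form the object map, whose 8-connected components within
    [``min_area``, ``max_area``] pixels are emitted as detections scored by
    their mean quantized intensity / 255.  Constant frames yield no
    detections (logged, not fatal).
    """
    if min_area <= 0 or max_area <= 0 or min_area >= max_area:
        raise InvalidParameterError(
            f"need 0 < min_area < max_area, got ({min_area}, {max_area})"
        )
    dets: list[Detection] = []
    for i, frame in enumerate(thermal.frames):
        try:
            q = optimal_quantize(frame, n_bins=n_bins)
        except DegenerateInputError:
            logger.warning("frame %d is constant; no detections emitted", i)
            continue
        for prop in regionprops(label(q.object_mask, connectivity=2)):
            if not min_area <= prop.area <= max_area:
                continue
            comp = np.zeros(frame.shape, dtype=np.uint8)
            comp[tuple(prop.coords.T)] = 1
            score = float(q.pixels[comp == 1].mean() / 255.0)
            dets.append(
                Detection(
                    frame_index=i,
                    box=mask_bbox(comp),
                    score=min(score, 1.0),
                    mask=comp,
                )
            )
    return dets


# ---------------------------------------------------------------------------
# JSON import/export (schema documented in thermal_io)
# ---------------------------------------------------------------------------

def write_detections(dets, path) -> Path:
    """Write scored detections to the per-frame JSON schema."""
    by_frame: dict[int, list[Detection]] = {}
    for d in dets:
        by_frame.setdefault(d.frame_index, []).append(d)
    doc = {
        "frames": [
            {
                "index": i,
                "objects": [
                    {"box": list(d.box), "score": d.score, "mask_ref": None}
                    for d in by_frame[i]
                ],
            }
            for i in sorted(by_frame)
        ]
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1))
    return path


def read_detections(path) -> list[Detection]:
    """Import detections (e.g. from an external instance-segmentation run)."""
    doc = json.loads(Path(path).read_text())
    dets: list[Detection] = []
    for frame in doc["frames"]:
        for obj in frame["objects"]:
            score = obj.get("score")
            dets.append(
                Detection(
                    frame_index=int(frame["index"]),
                    box=tuple(obj["box"]),
                    score=1.0 if score is None else float(score),
                )
            )
    return dets


def write_annotations(gts: AnnotationSet, path) -> Path:
    doc = {
        "frames": [
            {
                "index": i,
                "objects": [{"box": list(a.box), "score": None, "mask_ref": None} for a in objs],
            }
            for i, objs in sorted(gts.frames.items())
        ]
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1))
    return path


def read_annotations(path) -> AnnotationSet:
    doc = json.loads(Path(path).read_text())
    frames = {
        int(frame["index"]): tuple(Annotation(box=tuple(o["box"])) for o in frame["objects"])
        for frame in doc["frames"]
    }
    return AnnotationSet(frames=frames)
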