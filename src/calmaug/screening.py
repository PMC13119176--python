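"""Teacher-guided accept–reject screening of augmented samples.

Copy-paste augmentation inevitably produces some implausible composites
(lesions on non-host regions, jarring blends, over-occluded targets).
Screening treats a teacher detector as an acceptance oracle: a pasted box
is kept only if the teacher re-detects it with sufficient confidence and
localization agreement. Filtering the augmented stream p̃(x, y) this way
yields the quality-controlled distribution p̃_keep(x, y) actually used
for training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np

Box = tuple[float, float, float, float]  # (cx, cy, w, h), normalized


@dataclass(frozen=True)
class Detection:
    """One teacher prediction: class, normalized box, confidence in [0, 1]."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float
    confidence: float

    @property
    def box(self) -> Box:
        return (self.cx, self.cy, self.w, self.h)


class TeacherModel(Protocol):
    """Any detector usable as a screening teacher.

    ``predict`` receives an object exposing ``image`` (H×W×3 raster) and
    ``annotations``; real detector adapters use only the raster, while the
    synthetic oracle teacher reads the ground-truth annotations.
    """

    def predict(self, sample) -> list[Detection]: ...


@dataclass
class ScreeningConfig:
    """Accept–reject thresholds.

    conf_min (τ) and iou_min (θ) are the teacher-confidence and
    localization-consistency thresholds; min_visible_fraction rejects
    pastes whose box was excessively occluded by the environment stage.
    """

    conf_min: float = 0.25
    iou_min: float = 0.5
    require_class_match: bool = True
    min_visible_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("conf_min", "iou_min", "min_visible_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


REASONS = ("ok", "low_confidence", "poor_localization", "class_mismatch", "over_occluded")


@dataclass
class BoxVerdict:
    annotation_index: int
    reason: str
    iou: float = 0.0
    confidence: float = 0.0


@dataclass
class ScreeningResult:
    """Whole-sample decision: accepted iff every pasted box verdict is ok."""

    accepted: bool
    verdicts: list[BoxVerdict]


def iou(a: Box | Sequence[float], b: Box | Sequence[float]) -> float:
    """Intersection over union of two (cx, cy, w, h) boxes; 0 for degenerate boxes."""
    ax0, ay0 = a[0] - a[2] / 2, a[1] - a[3] / 2
    ax1, ay1 = a[0] + a[2] / 2, a[1] + a[3] / 2
    bx0, by0 = b[0] - b[2] / 2, b[1] - b[3] / 2
    bx1, by1 = b[0] + b[2] / 2, b[1] + b[3] / 2
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    # areas from the same edge arithmetic so identical boxes give exactly 1
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    if union <= 0:
        return 0.0
    return float(inter / union)


def _greedy_match(
    boxes: list[Box], detections: list[Detection]
) -> dict[int, Detection]:
    """One-to-one matching by descending IoU; unmatched boxes are absent."""
    pairs = sorted(
        (
            (iou(box, det.box), bi, di)
            for bi, box in enumerate(boxes)
            for di, det in enumerate(detections)
        ),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    matched: dict[int, Detection] = {}
    used: set[int] = set()
    for score, bi, di in pairs:
        if score <= 0.0:
            break
        if bi in matched or di in used:
            continue
        matched[bi] = detections[di]
        used.add(di)
    return matched


def screen_sample(sample, teacher: TeacherModel, cfg: ScreeningConfig) -> ScreeningResult:
    """Screen the pasted boxes of one augmented sample.

    Each pasted box is matched one-to-one to the highest-IoU teacher
    detection; a box is ok iff it kept enough visible area, the match's
    IoU ≥ iou_min, the class matches (if required) and confidence ≥
    conf_min. Original (non-pasted) boxes are never screened; the sample
    is never mutated.
    """
    pasted_idx = list(range(sample.n_original, len(sample.annotations)))
    if not pasted_idx:
        raise ValueError(f"sample {sample.image_id!r} has no pasted boxes to screen")
    detections = teacher.predict(sample)
    boxes = [sample.annotations[i].box for i in pasted_idx]
    matched = _greedy_match(boxes, detections)
    visible = sample.visible_fractions
    verdicts = []
    for j, ann_index in enumerate(pasted_idx):
        vis = 1.0 if visible is None else visible[ann_index]
        det = matched.get(j)
        score = iou(boxes[j], det.box) if det is not None else 0.0
        conf = det.confidence if det is not None else 0.0
        if vis < cfg.min_visible_fraction:
            reason = "over_occluded"
        elif det is None or score < cfg.iou_min:
            reason = "poor_localization"
        elif cfg.require_class_match and det.class_id != sample.annotations[ann_index].class_id:
            reason = "class_mismatch"
        elif conf < cfg.conf_min:
            reason = "low_confidence"
        else:
            reason = "ok"
        verdicts.append(BoxVerdict(ann_index, reason, score, conf))
    return ScreeningResult(all(v.reason == "ok" for v in verdicts), verdicts)


def screen_batch(
    samples: Iterable, teacher: TeacherModel, cfg: ScreeningConfig
) -> tuple[list, list, dict[str, int]]:
    """Split a batch into kept and rejected samples plus reason counts.

    The kept stream realizes p̃_keep. ``summary`` counts rejected samples by
    the first failing reason and records totals under ``kept``/``rejected``.
    """
    kept, rejected = [], []
    summary = {r: 0 for r in REASONS if r != "ok"}
    for sample in samples:
        result = screen_sample(sample, teacher, cfg)
        if result.accepted:
            kept.append(sample)
        else:
            rejected.append(sample)
            first_bad = next(v.reason for v in result.verdicts if v.reason != "ok")
            summary[first_bad] += 1
    summary["kept"] = len(kept)
    summary["rejected"] = len(rejected)
    return kept, rejected, summary
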