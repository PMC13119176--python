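"""Category-aware copy-paste: planning, placement, pasting.

The engine raises every deficit class to a per-class target floor T:
``pastes_i = max(0, T_i - N_i)`` donor instances are pasted onto
backgrounds drawn uniformly from the whole dataset (so a rare lesion is
seen in diverse scenes, not only its source image). Placement is uniform
over all positions keeping the scaled box inside the frame and below an
IoU ceiling against existing boxes — deliberately not center-biased, which
spreads object centers toward the frame edges and corners. Each emitted
sample then passes through the environment-simulation stack and is flagged
for teacher screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

from .dist_stats import ClassDistribution
from .env_sim import EnvProfile, apply_env
from .lesion_bank import LesionBank, LesionInstance, sample_instance, EmptyClassError
from .screening import iou
from .yolo_io import Annotation, DetectionDataset

logger = logging.getLogger(__name__)


class PlacementError(RuntimeError):
    """No admissible position found within the retry budget."""


@dataclass
class AugPolicy:
    """Copy-paste policy.

    ``target_count`` is the post-augmentation per-class floor (scalar or a
    per-class vector); only classes below it are augmented. ``scale_jitter``
    multiplies the donor's native scale (clipped so the scaled box stays in
    (0, 1]).
    """

    target_count: int | Sequence[int] = 54
    scale_jitter: tuple[float, float] = (0.5, 2.0)
    max_paste_per_image: int = 5
    max_overlap_iou: float = 0.1
    blend_mode: str = "feathered"
    retry_budget: int = 50

    def __post_init__(self) -> None:
        if self.scale_jitter[0] <= 0 or self.scale_jitter[0] > self.scale_jitter[1]:
            raise ValueError(f"bad scale_jitter range {self.scale_jitter}")
        if not (0.0 <= self.max_overlap_iou < 1.0):
            raise ValueError("max_overlap_iou must be in [0, 1)")
        if self.blend_mode not in ("feathered", "hard"):
            raise ValueError(f"unknown blend_mode {self.blend_mode!r}")

    def targets(self, num_classes: int) -> np.ndarray:
        if np.isscalar(self.target_count):
            return np.full(num_classes, int(self.target_count), dtype=np.int64)
        t = np.asarray(self.target_count, dtype=np.int64)
        if len(t) != num_classes:
            raise ValueError(
                f"per-class target vector has {len(t)} entries for {num_classes} classes"
            )
        return t


@dataclass
class AugmentedSample:
    """An augmented image, its annotations and per-paste provenance."""

    image_id: str
    image: np.ndarray
    annotations: list[Annotation]
    n_original: int
    provenance: list[dict] = field(default_factory=list)
    effects: list[dict] = field(default_factory=list)
    visible_fractions: list[float] | None = None
    pending_screen: bool = True


def class_deficits(d: ClassDistribution, target: int | Sequence[int]) -> np.ndarray:
    """Per-class paste quota ``max(0, T_i - N_i)``."""
    t = (
        np.full(d.num_classes, int(target), dtype=np.int64)
        if np.isscalar(target)
        else np.asarray(target, dtype=np.int64)
    )
    if np.any(t <= 0):
        raise ValueError("targets must be positive")
    return np.maximum(0, t - d.counts)


def sample_placement(
    frame_size: tuple[int, int],
    box_size: tuple[float, float],
    existing_boxes: Sequence[tuple[float, float, float, float]],
    max_overlap_iou: float,
    rng: np.random.Generator,
    retries: int = 50,
) -> tuple[float, float]:
    """Uniformly sample a normalized center for a (w, h) box.

    Admissible centers keep the full box inside the frame and its IoU with
    every existing box at or below ``max_overlap_iou``; rejection sampling
    with a bounded budget, raising :class:`PlacementError` on exhaustion.
    """
    w, h = box_size
    lox, hix = w / 2, 1 - w / 2
    loy, hiy = h / 2, 1 - h / 2
    if lox > hix + 1e-9 or loy > hiy + 1e-9:
        raise PlacementError(f"box {box_size} does not fit in frame")
    for _ in range(retries):
        cx = float(rng.uniform(lox, hix)) if hix > lox else lox
        cy = float(rng.uniform(loy, hiy)) if hiy > loy else loy
        cand = (cx, cy, w, h)
        if all(iou(cand, b) <= max_overlap_iou for b in existing_boxes):
            return cx, cy
    raise PlacementError(
        f"no admissible placement for box {box_size} after {retries} tries"
    )


def _resize(arr: np.ndarray, size: tuple[int, int], mode) -> np.ndarray:
    return np.asarray(Image.fromarray(arr).resize(size, mode))


def paste(
    image: np.ndarray,
    annotations: list[Annotation],
    instance: LesionInstance,
    center: tuple[float, float],
    scale_factor: float,
    blend_mode: str = "feathered",
    image_id: str = "augmented",
) -> AugmentedSample:
    """Paste one donor crop onto a background at a normalized center.

    The donor's crop is resized so its normalized scale becomes
    ``native_scale * scale_factor`` in the target frame, then alpha-blended
    (or copied bit-exactly outside the alpha support in hard mode). The new
    annotation's box is the extent of alpha > 0.5. Original annotations are
    untouched.
    """
    height, width = image.shape[:2]
    ch, cw = instance.pixels.shape[:2]
    # resize the crop so its normalized scale sqrt(w*h) in this frame
    # becomes native_scale * scale_factor
    crop_scale = np.sqrt((cw / width) * (ch / height))
    resize_factor = scale_factor * instance.native_scale / max(1e-9, crop_scale)
    tw = max(2, int(round(cw * resize_factor)))
    th = max(2, int(round(ch * resize_factor)))
    pixels = _resize(instance.pixels, (tw, th), Image.BILINEAR)
    alpha = np.asarray(
        Image.fromarray((np.clip(instance.alpha, 0, 1) * 255).astype(np.uint8)).resize(
            (tw, th), Image.BILINEAR
        ),
        dtype=np.float64,
    ) / 255.0
    if blend_mode == "hard":
        alpha = (alpha >= 0.5).astype(np.float64)
    cx, cy = center
    x0 = int(round(cx * width - tw / 2))
    y0 = int(round(cy * height - th / 2))
    if x0 < 0 or y0 < 0 or x0 + tw > width or y0 + th > height:
        raise PlacementError(
            f"scaled crop ({tw}x{th}) out of frame at center {center}"
        )
    out = image.copy()
    region = out[y0 : y0 + th, x0 : x0 + tw].astype(np.float64)
    blended = region * (1 - alpha[..., None]) + pixels.astype(np.float64) * alpha[..., None]
    out[y0 : y0 + th, x0 : x0 + tw] = np.clip(np.rint(blended), 0, 255).astype(np.uint8)
    ys, xs = np.nonzero(alpha > 0.5)
    if len(xs) == 0:
        raise PlacementError("resized alpha has no support above 0.5")
    bx0, bx1 = x0 + xs.min(), x0 + xs.max() + 1
    by0, by1 = y0 + ys.min(), y0 + ys.max() + 1
    new_ann = Annotation(
        instance.class_id,
        (bx0 + bx1) / 2 / width,
        (by0 + by1) / 2 / height,
        (bx1 - bx0) / width,
        (by1 - by0) / height,
    )
    sample = AugmentedSample(
        image_id=image_id,
        image=out,
        annotations=list(annotations) + [new_ann],
        n_original=len(annotations),
    )
    sample.provenance.append(
        {
            "donor_image": instance.source[0],
            "donor_index": instance.source[1],
            "class_id": instance.class_id,
            "center": [cx, cy],
            "scale_factor": scale_factor,
            "blend_mode": blend_mode,
        }
    )
    return sample


def _paste_onto_sample(
    sample: AugmentedSample,
    instance: LesionInstance,
    policy: AugPolicy,
    rng: np.random.Generator,
) -> bool:
    """Attempt one scale-jittered paste onto an in-progress sample."""
    for _ in range(5):  # a few scale draws; placement retries nest inside
        jitter = float(np.exp(rng.uniform(*np.log(policy.scale_jitter))))
        scale = float(np.clip(jitter * instance.native_scale, 0.02, 0.9))
        scale_factor = scale / instance.native_scale
        ch, cw = instance.pixels.shape[:2]
        height, width = sample.image.shape[:2]
        crop_scale = np.sqrt((cw / width) * (ch / height))
        resize_factor = scale_factor * instance.native_scale / max(1e-9, crop_scale)
        w = min(0.95, cw * resize_factor / width)
        h = min(0.95, ch * resize_factor / height)
        try:
            center = sample_placement(
                (width, height),
                (w, h),
                [a.box for a in sample.annotations],
                policy.max_overlap_iou,
                rng,
                policy.retry_budget,
            )
        except PlacementError:
            continue
        try:
            pasted = paste(
                sample.image,
                sample.annotations,
                instance,
                center,
                scale_factor,
                policy.blend_mode,
                sample.image_id,
            )
        except PlacementError:
            continue
        sample.image = pasted.image
        sample.annotations = pasted.annotations
        sample.provenance.extend(pasted.provenance)
        return True
    return False


def plan_and_augment(
    ds: DetectionDataset,
    bank: LesionBank,
    policy: AugPolicy,
    env_profile: EnvProfile | None,
    rng: np.random.Generator,
) -> tuple[list[AugmentedSample], ClassDistribution]:
    """Generate augmented samples raising every class to its target floor.

    Returns the emitted samples (each already passed through the
    environment stack when a profile is given, and flagged
    ``pending_screen``) plus the planned post-augmentation distribution
    (original counts + scheduled pastes, i.e. before any screening loss).
    Deficit classes are processed in descending-deficit order; donors are
    sampled with replacement; backgrounds uniformly over the whole dataset.
    """
    dist = ClassDistribution.from_dataset(ds)
    deficits = class_deficits(dist, policy.target_count)
    missing = [
        int(c)
        for c in np.nonzero(deficits)[0]
        if not bank.per_class.get(int(c))
    ]
    if missing:
        raise EmptyClassError(
            f"deficit classes with no donor instances in the bank: {missing}"
        )
    queue: list[int] = []
    for cid in np.argsort(-deficits, kind="stable"):
        queue.extend([int(cid)] * int(deficits[cid]))
    samples: list[AugmentedSample] = []
    n_emitted = 0
    budget = max(1, 10 * len(queue))
    attempts = 0
    pos = 0
    while pos < len(queue):
        if attempts > budget:
            raise PlacementError(
                f"could not schedule all pastes ({len(queue) - pos} left) "
                f"within the global retry budget"
            )
        bg = ds.items[int(rng.integers(len(ds.items)))]
        sample = AugmentedSample(
            image_id=f"{bg.image_id}_aug{n_emitted:05d}",
            image=bg.load_image().copy(),
            annotations=list(bg.annotations),
            n_original=len(bg.annotations),
        )
        placed_here = 0
        while pos < len(queue) and placed_here < policy.max_paste_per_image:
            cid = queue[pos]
            instance = sample_instance(bank, cid, rng)
            attempts += 1
            if _paste_onto_sample(sample, instance, policy, rng):
                pos += 1
                placed_here += 1
            else:
                logger.info(
                    "paste of class %d failed on %s; retrying on a new background",
                    cid,
                    sample.image_id,
                )
                break
        if placed_here == 0:
            continue
        if env_profile is not None:
            apply_env(sample, env_profile, rng)
        else:
            sample.visible_fractions = [1.0] * len(sample.annotations)
        samples.append(sample)
        n_emitted += 1
    planned = ClassDistribution(dist.counts + deficits, list(dist.class_names))
    return samples, planned
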