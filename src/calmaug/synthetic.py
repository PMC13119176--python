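"""Procedurally drawn leaf/lesion detection fixtures with known ground truth.

The generator emulates the statistical structure of a long-tailed field
dataset — ~30 classes whose instance counts span two orders of magnitude,
object centers biased toward the frame center, and a narrow band of object
scales — on synthetic imagery: a vein-textured leaf ellipse over soil-toned
noise, with per-class colored elliptical lesion blobs. Classes are visually
separable (distinct hues) but the images make no attempt at photorealism.

Everything is a pure function of the :class:`FixtureSpec` (seed included),
so fixtures are regenerated identically anywhere. An
:class:`OracleTeacher` test double stands in for a trained detector during
screening: it reads a sample's ground-truth boxes and re-emits each with a
configurable detection probability, confidence law and localization jitter.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .screening import Detection
from .yolo_io import Annotation, DatasetItem, DetectionDataset

#: Frozen 30-class long-tail instance-count vector used as the default study
#: condition: min 2, max 755 (imbalance ratio 377.5), 17/30 classes with at
#: least 200 instances, log-count dispersion ~1.20. A two-regime exponential
#: decay — a slow head and a steep final tail — reproduces those extremes.
PLANTDOC_LIKE_COUNTS: tuple[int, ...] = (
    755, 696, 642, 593, 547, 504, 465, 429, 396, 365,
    337, 311, 286, 264, 244, 225, 207, 191, 176, 163,
    150, 138, 128, 118, 109, 100, 59, 34, 20, 2,
)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset.

    center_bias b mixes placement laws: centers are drawn from
    (1-b)·Uniform + b·truncated-Gaussian at the frame center (sd 0.12),
    so b=0 is uniform and b=1 is tightly central. scale_range bounds the
    normalized object scale sqrt(w*h). Counts are realized exactly.
    """

    class_counts: tuple[int, ...] = PLANTDOC_LIKE_COUNTS
    image_size: int = 256
    center_bias: float = 0.6
    scale_range: tuple[float, float] = (0.08, 0.22)
    max_per_image: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.class_counts):
            raise ValueError("class counts must be non-negative")
        lo, hi = self.scale_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"scale_range must be within (0, 1], got {self.scale_range}")
        if not (0.0 <= self.center_bias <= 1.0):
            raise ValueError("center_bias must be in [0, 1]")

    @property
    def num_classes(self) -> int:
        return len(self.class_counts)


@dataclass
class GeneratedFixture:
    """A generated dataset plus per-object soft masks.

    ``masks[image_id][i]`` is the alpha raster (crop-local, float in
    [0, 1]) of annotation ``i`` of that image, aligned with
    ``item.annotations``.
    """

    dataset: DetectionDataset
    masks: dict[str, list[np.ndarray]]


def class_color(class_id: int) -> tuple[float, float, float]:
    """Deterministic, well-separated RGB lesion color for a class (floats in [0,1])."""
    hue = (class_id * 0.3819660113) % 1.0  # golden-ratio spacing
    sat = 0.65 + 0.25 * ((class_id * 7) % 3) / 2
    val = 0.55 + 0.35 * ((class_id * 5) % 4) / 3
    return colorsys.hsv_to_rgb(hue, sat, val)


def sample_center_biased(
    half_w: float, half_h: float, center_bias: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw a normalized box center keeping the box fully inside the frame.

    Mixture law: with probability ``center_bias`` a Gaussian at (0.5, 0.5)
    with sd 0.12 truncated to the feasible rectangle, else uniform over it.
    """
    lox, hix = half_w, 1.0 - half_w
    loy, hiy = half_h, 1.0 - half_h
    if lox > hix or loy > hiy:
        raise ValueError("box does not fit in the frame")
    if rng.random() >= center_bias:
        return float(rng.uniform(lox, hix)), float(rng.uniform(loy, hiy))
    for _ in range(100):  # truncation by rejection
        cx, cy = rng.normal(0.5, 0.12, size=2)
        if lox <= cx <= hix and loy <= cy <= hiy:
            return float(cx), float(cy)
    return float(np.clip(0.5, lox, hix)), float(np.clip(0.5, loy, hiy))


def _boxes_iou(a: tuple, b: tuple) -> float:
    from .screening import iou

    return iou(a, b)


def _draw_background(size: int, rng: np.random.Generator) -> np.ndarray:
    """Soil-toned noise with a vein-textured leaf ellipse, float RGB in [0,1]."""
    yy, xx = np.mgrid[0:size, 0:size] / size
    soil = np.empty((size, size, 3))
    noise = gaussian_filter(rng.standard_normal((size, size)), 3.0)
    for c, base in enumerate((0.38, 0.28, 0.18)):
        soil[..., c] = np.clip(base + 0.35 * noise, 0.02, 1.0)
    # leaf ellipse, random orientation and mild eccentricity
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - 0.5) * ct + (yy - 0.5) * st
    v = -(xx - 0.5) * st + (yy - 0.5) * ct
    a, b = rng.uniform(0.40, 0.48), rng.uniform(0.30, 0.40)
    leaf_mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    veins = 0.08 * np.cos(2 * np.pi * v / 0.08) + 0.10 * np.exp(-((v / 0.02) ** 2))
    shade = gaussian_filter(rng.standard_normal((size, size)), 8.0) * 0.25
    green = np.stack(
        [
            np.clip(0.16 + veins * 0.4 + shade * 0.4, 0, 1),
            np.clip(0.45 + veins + shade, 0, 1),
            np.clip(0.14 + veins * 0.3 + shade * 0.3, 0, 1),
        ],
        axis=-1,
    )
    img = np.where(leaf_mask[..., None], green, soil)
    return img


def _draw_lesion(
    bw: int, bh: int, class_id: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Render a lesion blob on a (bh, bw) crop; returns (rgb float, alpha).

    The alpha ≥ 0.5 region is an ellipse inscribed in the crop, so the
    mask's bounding rectangle matches the crop box to within a pixel.
    """
    yy, xx = np.mgrid[0:bh, 0:bw] + 0.5
    a, b = bw / 2.0, bh / 2.0
    r = np.sqrt(((xx - a) / a) ** 2 + ((yy - b) / b) ** 2)
    feather = 0.25
    alpha = np.clip((1.0 + feather - r) / (2 * feather), 0.0, 1.0)
    base = np.array(class_color(class_id))
    speckle = gaussian_filter(rng.standard_normal((bh, bw)), 1.0)
    rgb = np.clip(base[None, None, :] * (1.0 + 0.35 * speckle[..., None]), 0, 1)
    # darker rim to mimic necrotic lesion borders
    rim = np.clip(1.0 - np.abs(r - 0.85) / 0.15, 0, 1)
    rgb *= 1.0 - 0.35 * rim[..., None]
    return rgb, alpha


def _mask_to_annotation(
    alpha: np.ndarray, x0: int, y0: int, size: int, class_id: int
) -> Annotation:
    ys, xs = np.nonzero(alpha >= 0.5)
    bx0, bx1 = x0 + xs.min(), x0 + xs.max() + 1
    by0, by1 = y0 + ys.min(), y0 + ys.max() + 1
    return Annotation(
        class_id,
        (bx0 + bx1) / 2 / size,
        (by0 + by1) / 2 / size,
        (bx1 - bx0) / size,
        (by1 - by0) / size,
    )


def generate_dataset(spec: FixtureSpec) -> GeneratedFixture:
    """Generate a dataset realizing ``spec.class_counts`` exactly.

    Instances are packed into images (up to ``max_per_image`` each, ground
    truth overlap limited to IoU ≤ 0.1); centers follow the center-bias
    mixture law; scales are uniform over ``scale_range``. Raises when an
    instance cannot be placed even alone in a fresh frame.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    pool: list[int] = [
        cid for cid, n in enumerate(spec.class_counts) for _ in range(int(n))
    ]
    rng.shuffle(pool)
    class_names = [f"class_{i:02d}" for i in range(spec.num_classes)]
    items: list[DatasetItem] = []
    masks: dict[str, list[np.ndarray]] = {}
    img_index = 0
    cursor = 0
    while cursor < len(pool):
        image_id = f"fixture_{img_index:05d}"
        img = _draw_background(size, rng)
        k_target = int(rng.integers(1, spec.max_per_image + 1))
        annotations: list[Annotation] = []
        item_masks: list[np.ndarray] = []
        placed_boxes: list[tuple] = []
        fresh_frame_failure = False
        while cursor < len(pool) and len(annotations) < k_target:
            cid = pool[cursor]
            placed = False
            for _ in range(60):
                s = rng.uniform(*spec.scale_range)
                aspect = rng.uniform(0.7, 1.4)
                w = s * np.sqrt(aspect)
                h = s / np.sqrt(aspect)
                if w >= 1.0 or h >= 1.0:
                    continue
                try:
                    cx, cy = sample_center_biased(w / 2, h / 2, spec.center_bias, rng)
                except ValueError:
                    continue
                cand = (cx, cy, w, h)
                if all(_boxes_iou(cand, pb) <= 0.1 for pb in placed_boxes):
                    x0 = int(round((cx - w / 2) * size))
                    y0 = int(round((cy - h / 2) * size))
                    bw = max(2, int(round(w * size)))
                    bh = max(2, int(round(h * size)))
                    x0 = min(max(0, x0), size - bw)
                    y0 = min(max(0, y0), size - bh)
                    rgb, alpha = _draw_lesion(bw, bh, cid, rng)
                    region = img[y0 : y0 + bh, x0 : x0 + bw]
                    img[y0 : y0 + bh, x0 : x0 + bw] = (
                        region * (1 - alpha[..., None]) + rgb * alpha[..., None]
                    )
                    annotations.append(_mask_to_annotation(alpha, x0, y0, size, cid))
                    item_masks.append(alpha)
                    placed_boxes.append(cand)
                    placed = True
                    break
            if placed:
                cursor += 1
            else:
                if not placed_boxes:
                    fresh_frame_failure = True
                break  # frame too crowded; remaining instances go to the next image
        if fresh_frame_failure:
            raise ValueError(
                f"cannot place a class-{pool[cursor]} instance even in an empty "
                f"{size}px frame; use larger images or a smaller scale_range"
            )
        items.append(
            DatasetItem(
                image_id,
                annotations,
                image=(np.clip(img, 0, 1) * 255).astype(np.uint8),
            )
        )
        masks[image_id] = item_masks
        img_index += 1
    return GeneratedFixture(DetectionDataset(items, class_names), masks)


@dataclass
class OracleTeacher:
    """Ground-truth-reading teacher test double for screening.

    Emits each ground-truth box of the sample under screening with
    probability ``detection_probability``, confidence
    ``confidence_mean`` perturbed by ``confidence_jitter``-scaled Gaussian
    noise (clipped to [0, 1]) and box corners jittered by
    ``localization_noise`` pixels. With probability 1, zero jitter and
    confidence 1, predictions equal ground truth exactly.
    """

    detection_probability: float = 1.0
    confidence_mean: float = 1.0
    confidence_jitter: float = 0.0
    localization_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.detection_probability <= 1.0):
            raise ValueError("detection_probability must be in [0, 1]")
        self._rng = np.random.default_rng(self.seed)

    def predict(self, sample) -> list[Detection]:
        image = getattr(sample, "image", None)
        if image is None:
            image = sample.load_image()
        height, width = image.shape[:2]
        out: list[Detection] = []
        for ann in sample.annotations:
            if self._rng.random() >= self.detection_probability:
                continue
            cx, cy, w, h = ann.box
            if self.localization_noise > 0:
                jit = self._rng.normal(0, self.localization_noise, size=4)
                cx = float(np.clip(cx + jit[0] / width, 0, 1))
                cy = float(np.clip(cy + jit[1] / height, 0, 1))
                w = float(np.clip(w + jit[2] / width, 1e-3, 1))
                h = float(np.clip(h + jit[3] / height, 1e-3, 1))
            conf = self.confidence_mean
            if self.confidence_jitter > 0:
                conf += self._rng.normal(0, self.confidence_jitter)
            out.append(Detection(ann.class_id, cx, cy, w, h, float(np.clip(conf, 0, 1))))
        return out


def make_oracle_teacher(ds: DetectionDataset, **params) -> OracleTeacher:
    """Build an oracle teacher for samples derived from ``ds``.

    The teacher reads ground truth from whatever sample it is asked to
    predict, so the dataset argument only asserts that ground truth exists;
    an adversarial variant is ``detection_probability=0``.
    """
    if ds.num_annotations == 0:
        raise ValueError("oracle teacher needs a dataset with ground truth")
    return OracleTeacher(**params)
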