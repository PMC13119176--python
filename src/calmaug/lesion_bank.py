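"""Object-level crop extraction and the class-indexed donor bank.

Every annotated box becomes a :class:`LesionInstance` — the pixel crop
(padded slightly to retain boundary context), an alpha mask for blending,
and provenance back to its source image. Instances are stored at source
resolution and indexed by class so the augmentation engine can sample
donors for any deficit class.

Hard overlap of pasted crops produces visible seams that a detector can
latch onto, so the default alpha is a cosine-feathered rectangle; a binary
("hard") alpha is available for tests needing exact pixel locality, and
ground-truth soft masks (e.g. from the synthetic generator) are used
verbatim when supplied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio

from .yolo_io import DetectionDataset

logger = logging.getLogger(__name__)

#: Feathered border width as a fraction of the smaller crop side.
FEATHER_FRACTION = 0.08


class EmptyClassError(KeyError):
    """Requested a donor instance for a class with no entries in the bank."""


@dataclass
class LesionInstance:
    """One extracted object crop.

    ``alpha`` is a blending mask in [0, 1] matching ``pixels`` spatially;
    ``native_scale`` is the annotation's normalized sqrt(w*h) in the source
    frame, used to reproduce realistic paste sizes.
    """

    pixels: np.ndarray
    alpha: np.ndarray
    class_id: int
    source: tuple[str, int]
    native_scale: float

    def __post_init__(self) -> None:
        if self.pixels.shape[0] < 2 or self.pixels.shape[1] < 2:
            raise ValueError("crop must be at least 2x2 pixels")
        if self.alpha.shape != self.pixels.shape[:2]:
            raise ValueError("alpha mask must match crop shape")


def feathered_alpha(height: int, width: int) -> np.ndarray:
    """Rectangle mask with a raised-cosine border ramp.

    Feather width is ``FEATHER_FRACTION`` of the smaller side (at least one
    pixel); the interior is exactly 1.
    """
    f = max(1, int(round(FEATHER_FRACTION * min(height, width))))

    def ramp(n: int) -> np.ndarray:
        edge = 0.5 - 0.5 * np.cos(np.pi * (np.arange(n) + 0.5) / f)
        out = np.ones(n)
        out[:f] = edge[:f]
        out[n - f :] = edge[:f][::-1]
        return out

    return np.outer(ramp(height), ramp(width))


def extract_instances(
    ds: DetectionDataset,
    pad_fraction: float = 0.05,
    masks: dict[str, list[np.ndarray]] | None = None,
    alpha_mode: str = "feathered",
) -> list[LesionInstance]:
    """Extract one instance per annotation whose clipped box is ≥ 2×2 px.

    The box is padded by ``pad_fraction`` of its size on every side, then
    clipped to the frame; degenerate boxes are skipped with a warning.
    ``masks`` (keyed by image id, aligned with annotations) supplies
    ground-truth alpha crops; otherwise a feathered (or, with
    ``alpha_mode='hard'``, binary) rectangle mask is synthesized.
    """
    if pad_fraction < 0:
        raise ValueError("pad_fraction must be non-negative")
    if alpha_mode not in ("feathered", "hard"):
        raise ValueError(f"unknown alpha_mode {alpha_mode!r}")
    instances: list[LesionInstance] = []
    for item in ds.items:
        img = item.load_image()
        height, width = img.shape[:2]
        gt_masks = (masks or {}).get(item.image_id)
        for idx, ann in enumerate(item.annotations):
            x0, y0, x1, y1 = ann.to_pixels(width, height)
            pad_x = int(round(pad_fraction * (x1 - x0)))
            pad_y = int(round(pad_fraction * (y1 - y0)))
            px0, py0 = max(0, x0 - pad_x), max(0, y0 - pad_y)
            px1, py1 = min(width, x1 + pad_x), min(height, y1 + pad_y)
            if px1 - px0 < 2 or py1 - py0 < 2:
                logger.warning(
                    "skipping sub-2px box %d of %s", idx, item.image_id
                )
                continue
            crop = np.ascontiguousarray(img[py0:py1, px0:px1])
            if gt_masks is not None:
                gm = gt_masks[idx]
                alpha = np.zeros(crop.shape[:2])
                # ground-truth mask covers the unpadded box region of the crop
                alpha[y0 - py0 : y0 - py0 + gm.shape[0], x0 - px0 : x0 - px0 + gm.shape[1]] = gm
            elif alpha_mode == "hard":
                alpha = np.zeros(crop.shape[:2])
                alpha[y0 - py0 : y1 - py0, x0 - px0 : x1 - px0] = 1.0
            else:
                alpha = np.zeros(crop.shape[:2])
                alpha[y0 - py0 : y1 - py0, x0 - px0 : x1 - px0] = feathered_alpha(
                    y1 - y0, x1 - x0
                )
            instances.append(
                LesionInstance(crop, alpha, ann.class_id, (item.image_id, idx), ann.scale)
            )
    return instances


@dataclass
class LesionBank:
    """Per-class donor lists with O(1) availability lookup."""

    per_class: dict[int, list[LesionInstance]]

    def availability(self) -> dict[int, int]:
        return {cid: len(v) for cid, v in self.per_class.items()}

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.per_class.values())

    def get(self, class_id: int, index: int) -> LesionInstance:
        return self.per_class[class_id][index]


def build_bank(instances: list[LesionInstance]) -> LesionBank:
    """Index instances by class; lossless (total availability = input length)."""
    per_class: dict[int, list[LesionInstance]] = {}
    for inst in instances:
        per_class.setdefault(inst.class_id, []).append(inst)
    return LesionBank(per_class)


def sample_instance(
    bank: LesionBank, class_id: int, rng: np.random.Generator
) -> LesionInstance:
    """Uniformly sample a donor of ``class_id``; deterministic under a seeded rng."""
    entries = bank.per_class.get(class_id)
    if not entries:
        raise EmptyClassError(f"no donor instances for class {class_id}")
    return entries[int(rng.integers(len(entries)))]


def save_bank(bank: LesionBank, root: str | Path) -> Path:
    """Persist crops as PNG pairs plus a JSON index; returns the index path."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    index = []
    for cid in sorted(bank.per_class):
        for i, inst in enumerate(bank.per_class[cid]):
            stem = f"c{cid:03d}_{i:05d}"
            iio.imwrite(root / f"{stem}.png", inst.pixels)
            iio.imwrite(
                root / f"{stem}_alpha.png",
                (np.clip(inst.alpha, 0, 1) * 255).astype(np.uint8),
            )
            index.append(
                {
                    "stem": stem,
                    "class_id": cid,
                    "source_image": inst.source[0],
                    "source_index": inst.source[1],
                    "native_scale": inst.native_scale,
                }
            )
    index_path = root / "bank_index.json"
    index_path.write_text(json.dumps(index, indent=1))
    return index_path


def load_bank(root: str | Path) -> LesionBank:
    root = Path(root)
    index = json.loads((root / "bank_index.json").read_text())
    instances = []
    for rec in index:
        pixels = iio.imread(root / f"{rec['stem']}.png")
        alpha = iio.imread(root / f"{rec['stem']}_alpha.png").astype(float) / 255.0
        instances.append(
            LesionInstance(
                pixels,
                alpha,
                rec["class_id"],
                (rec["source_image"], rec["source_index"]),
                rec["native_scale"],
            )
        )
    return build_bank(instances)
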