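"""Reading, writing and splitting object-detection datasets in YOLO layout.

The YOLO label dialect is one object per line::

    <class_id> <cx> <cy> <w> <h>

with center coordinates and box sizes normalized to the image frame.
Datasets are a directory of images with same-stem ``.txt`` label files
(either flat, or split into ``images/`` and ``labels/`` subdirectories)
plus a class-name table (``classes.txt``, one name per line, or a
``data.yaml`` with a ``names`` entry).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import imageio.v3 as iio
import yaml

logger = logging.getLogger(__name__)

#: Tolerance on box-edge overshoot after clipping to the frame.
EPS = 1e-6

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg", ".bmp")


class LabelParseError(ValueError):
    """A label line that cannot be interpreted as a YOLO annotation."""


@dataclass(frozen=True)
class Annotation:
    """One normalized YOLO bounding box.

    Attributes
    ----------
    class_id : int
        Non-negative index into the dataset's class-name table.
    cx, cy : float
        Box center, normalized to [0, 1].
    w, h : float
        Box width and height, normalized to (0, 1].
    """

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.class_id < 0:
            raise LabelParseError(f"negative class id: {self.class_id}")
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise LabelParseError(f"center out of range: ({self.cx}, {self.cy})")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise LabelParseError(f"size out of range: ({self.w}, {self.h})")
        if (
            self.cx - self.w / 2 < -EPS
            or self.cx + self.w / 2 > 1 + EPS
            or self.cy - self.h / 2 < -EPS
            or self.cy + self.h / 2 > 1 + EPS
        ):
            raise LabelParseError(
                f"box extends past the frame: center=({self.cx},{self.cy}) "
                f"size=({self.w},{self.h})"
            )

    @property
    def box(self) -> tuple[float, float, float, float]:
        """(cx, cy, w, h) tuple."""
        return (self.cx, self.cy, self.w, self.h)

    @property
    def scale(self) -> float:
        """Normalized object scale sqrt(w*h)."""
        return float(np.sqrt(self.w * self.h))

    def to_pixels(self, width: int, height: int) -> tuple[int, int, int, int]:
        """Denormalize to half-open pixel extents (x0, y0, x1, y1), origin top-left."""
        x0 = int(np.floor((self.cx - self.w / 2) * width))
        y0 = int(np.floor((self.cy - self.h / 2) * height))
        x1 = int(np.ceil((self.cx + self.w / 2) * width))
        y1 = int(np.ceil((self.cy + self.h / 2) * height))
        return (max(0, x0), max(0, y0), min(width, x1), min(height, y1))


def parse_label_line(line: str) -> Annotation:
    """Parse one YOLO label line into an :class:`Annotation`.

    Raises :class:`LabelParseError` naming the offending content for a wrong
    token count, non-numeric tokens, or out-of-range coordinates.
    """
    tokens = line.split()
    if len(tokens) < 5:
        raise LabelParseError(f"expected 5 whitespace-separated tokens, got {line!r}")
    try:
        class_id = int(tokens[0])
        cx, cy, w, h = (float(t) for t in tokens[1:5])
    except ValueError as exc:
        raise LabelParseError(f"non-numeric token in {line!r}") from exc
    try:
        return Annotation(class_id, cx, cy, w, h)
    except LabelParseError as exc:
        raise LabelParseError(f"{exc} in line {line!r}") from None


def format_label_line(ann: Annotation) -> str:
    """Format an annotation as a YOLO label line with 6-decimal coordinates."""
    return f"{ann.class_id} {ann.cx:.6f} {ann.cy:.6f} {ann.w:.6f} {ann.h:.6f}"


@dataclass
class DatasetItem:
    """One image and its annotations.

    ``image`` may hold the raster directly (synthetic data) or be loaded
    lazily from ``path`` on first access via :meth:`load_image`.
    """

    image_id: str
    annotations: list[Annotation]
    image: np.ndarray | None = None
    path: Path | None = None

    def load_image(self) -> np.ndarray:
        """Return the H×W×3 uint8 raster, reading from disk if needed."""
        if self.image is not None:
            return self.image
        if self.path is None:
            raise ValueError(f"item {self.image_id!r} has neither raster nor path")
        arr = iio.imread(self.path)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        if arr.shape[-1] == 4:
            arr = arr[..., :3]
        return np.ascontiguousarray(arr, dtype=np.uint8)


@dataclass
class DetectionDataset:
    """A detection dataset: items plus an ordered class-name table."""

    items: list[DatasetItem]
    class_names: list[str]
    split_tag: str | None = None

    def __post_init__(self) -> None:
        k = len(self.class_names)
        for item in self.items:
            for ann in item.annotations:
                if ann.class_id >= k:
                    raise ValueError(
                        f"class id {ann.class_id} out of range for "
                        f"{k} classes (image {item.image_id!r})"
                    )

    def __len__(self) -> int:
        return len(self.items)

    def iter_annotations(self) -> Iterator[tuple[DatasetItem, Annotation]]:
        for item in self.items:
            for ann in item.annotations:
                yield item, ann

    @property
    def num_annotations(self) -> int:
        return sum(len(it.annotations) for it in self.items)


def _read_class_names(root: Path) -> list[str]:
    txt = root / "classes.txt"
    if txt.exists():
        return [ln.strip() for ln in txt.read_text().splitlines() if ln.strip()]
    for yml in (root / "data.yaml", root / "data.yml"):
        if yml.exists():
            data = yaml.safe_load(yml.read_text())
            names = data.get("names")
            if isinstance(names, dict):
                return [names[k] for k in sorted(names)]
            if isinstance(names, list):
                return list(names)
    raise FileNotFoundError(
        f"no class-name file (classes.txt or data.yaml with 'names') under {root}"
    )


def _locate_images(root: Path) -> list[Path]:
    img_dir = root / "images" if (root / "images").is_dir() else root
    paths = sorted(
        p for p in img_dir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES
    )
    stems = [p.stem for p in paths]
    dupes = {s for s in stems if stems.count(s) > 1}
    if dupes:
        raise ValueError(f"duplicate image stems under {img_dir}: {sorted(dupes)}")
    return paths


def read_dataset(root: str | Path) -> DetectionDataset:
    """Read a YOLO-layout dataset rooted at ``root``.

    Images without a label file are kept as background items with an empty
    annotation list (logged), never dropped.
    """
    root = Path(root)
    class_names = _read_class_names(root)
    label_dir = root / "labels" if (root / "labels").is_dir() else root
    items: list[DatasetItem] = []
    for img_path in _locate_images(root):
        label_path = label_dir / f"{img_path.stem}.txt"
        annotations: list[Annotation] = []
        if label_path.exists():
            for raw in label_path.read_text().splitlines():
                if raw.strip():
                    annotations.append(parse_label_line(raw))
        else:
            logger.info("no label file for %s; kept as background", img_path.name)
        items.append(DatasetItem(img_path.stem, annotations, path=img_path))
    return DetectionDataset(items, class_names)


def write_dataset(
    ds: DetectionDataset, root: str | Path, overwrite: bool = False
) -> list[Path]:
    """Write ``ds`` in YOLO layout under ``root`` and return the file manifest.

    Coordinates are printed with 6 decimal places so read→write→read is a
    fixed point. An empty dataset writes nothing and returns an empty
    manifest. Existing files raise unless ``overwrite`` is set.
    """
    root = Path(root)
    if not ds.items:
        return []
    img_dir, lbl_dir = root / "images", root / "labels"
    img_dir.mkdir(parents=True, exist_ok=True)
    lbl_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []
    for item in ds.items:
        img_path = img_dir / f"{item.image_id}.png"
        lbl_path = lbl_dir / f"{item.image_id}.txt"
        for p in (img_path, lbl_path):
            if p.exists() and not overwrite:
                raise FileExistsError(f"{p} exists (pass overwrite=True)")
        iio.imwrite(img_path, item.load_image())
        lbl_path.write_text(
            "".join(format_label_line(a) + "\n" for a in item.annotations)
        )
        manifest += [img_path, lbl_path]
    cls_path = root / "classes.txt"
    cls_path.write_text("".join(n + "\n" for n in ds.class_names))
    manifest.append(cls_path)
    return manifest


def _stratum(item: DatasetItem) -> int:
    """Majority class of an image's boxes; ties -> lowest class id; -1 if empty."""
    if not item.annotations:
        return -1
    ids = [a.class_id for a in item.annotations]
    counts = np.bincount(ids)
    return int(np.argmax(counts))  # argmax returns the lowest index on ties


def stratified_split(
    ds: DetectionDataset,
    ratios: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[DetectionDataset, DetectionDataset, DetectionDataset]:
    """Stratified train/val/test partition by each image's majority class.

    The partition is exhaustive and disjoint, deterministic for a given
    seed, and per-stratum proportions match ``ratios`` to within one image
    (largest-remainder apportionment inside each stratum).
    """
    if len(ratios) != 3 or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must be 3 fractions summing to 1, got {ratios}")
    if not ds.items:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(seed)
    strata: dict[int, list[int]] = {}
    for idx, item in enumerate(ds.items):
        strata.setdefault(_stratum(item), []).append(idx)
    parts: tuple[list[int], list[int], list[int]] = ([], [], [])
    for key in sorted(strata):
        members = np.array(strata[key])
        rng.shuffle(members)
        n = len(members)
        exact = np.asarray(ratios) * n
        sizes = np.floor(exact).astype(int)
        remainder_order = np.argsort(-(exact - sizes), kind="stable")
        for j in remainder_order[: n - sizes.sum()]:
            sizes[j] += 1
        offsets = np.concatenate([[0], np.cumsum(sizes)])
        for part, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            part.extend(int(i) for i in members[lo:hi])
    tags = ("train", "val", "test")
    return tuple(  # type: ignore[return-value]
        DetectionDataset(
            [replace(ds.items[i]) for i in sorted(part)],
            list(ds.class_names),
            split_tag=tag,
        )
        for part, tag in zip(parts, tags)
    )
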