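"""Class-distribution diagnostics for long-tailed detection datasets.

All statistics operate on the per-class instance-count vector
N = (N_1, ..., N_k) — counts of annotated boxes, not images. The
diagnostics quantify the three axes an augmentation pass reshapes:

* class balance — imbalance ratio ``max N_i / min N_i`` and the standard
  deviation of log counts (multiplicative dispersion, invariant to the
  total volume);
* learnability — "effective categories" with at least ``n0`` instances,
  and the fraction of all instances those categories hold;
* geometry — normalized histograms of box centers and of object scale
  sqrt(w*h).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .yolo_io import DetectionDataset

logger = logging.getLogger(__name__)


@dataclass
class ClassDistribution:
    """Per-class instance counts with their class names."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or len(self.counts) == 0:
            raise ValueError("counts must be a non-empty 1-D vector")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.class_names) != len(self.counts):
            raise ValueError("class_names and counts must be parallel")

    @classmethod
    def from_dataset(cls, ds: DetectionDataset) -> "ClassDistribution":
        counts = np.zeros(len(ds.class_names), dtype=np.int64)
        for _, ann in ds.iter_annotations():
            counts[ann.class_id] += 1
        return cls(counts, list(ds.class_names))

    @property
    def num_classes(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _positive(d: ClassDistribution, what: str) -> np.ndarray:
    pos = d.counts[d.counts > 0]
    if len(pos) < len(d.counts):
        logger.info(
            "%s: excluding %d zero-count classes", what, len(d.counts) - len(pos)
        )
    return pos


def imbalance_ratio(d: ClassDistribution) -> float:
    """Ratio of the largest to the smallest positive per-class count (IR ≥ 1).

    Zero-count classes are excluded from the minimum (and logged) rather
    than producing an infinite ratio.
    """
    pos = _positive(d, "imbalance_ratio")
    if len(pos) == 0:
        raise ValueError("imbalance_ratio undefined: all counts are zero")
    return float(pos.max() / pos.min())


def log_dispersion(d: ClassDistribution, base: float | None = None) -> float:
    """Population standard deviation of log per-class counts.

    Natural log by default (``base`` overrides). Invariant to scaling all
    counts by a common factor, so it measures multiplicative dispersion
    independently of dataset volume. Zero-count classes are excluded.
    """
    pos = _positive(d, "log_dispersion")
    if len(pos) < 2:
        raise ValueError("log_dispersion needs at least 2 positive classes")
    logs = np.log(pos.astype(float))
    if base is not None:
        logs = logs / np.log(base)
    return float(np.std(logs))  # population SD


def effective_coverage(d: ClassDistribution, n0: int) -> tuple[int, float]:
    """Number and fraction of classes with at least ``n0`` instances."""
    if n0 < 0:
        raise ValueError("n0 must be non-negative")
    count = int(np.count_nonzero(d.counts >= n0))
    return count, count / d.num_classes


def effective_sample_proportion(d: ClassDistribution, n0: int) -> float:
    """Fraction of all instances held by classes with at least ``n0`` of them."""
    if d.total == 0:
        raise ValueError("effective_sample_proportion undefined on empty distribution")
    return float(d.counts[d.counts >= n0].sum() / d.total)


def _bin_index(values: np.ndarray, bins: int) -> np.ndarray:
    # half-open [l, u) bins, final bin closed; interior-edge values go up
    return np.clip((values * bins).astype(int), 0, bins - 1)


def center_histogram(ds: DetectionDataset, bins: int = 8) -> np.ndarray:
    """Normalized bins×bins frequency grid of box centers (cx, cy).

    Rows index cy, columns cx. Returns an all-zero grid as the sentinel for
    a dataset with no boxes; otherwise the grid sums to 1.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    grid = np.zeros((bins, bins), dtype=float)
    cxs, cys = [], []
    for _, ann in ds.iter_annotations():
        cxs.append(ann.cx)
        cys.append(ann.cy)
    if not cxs:
        return grid
    ix = _bin_index(np.array(cxs), bins)
    iy = _bin_index(np.array(cys), bins)
    np.add.at(grid, (iy, ix), 1.0)
    return grid / grid.sum()


def scale_histogram(ds: DetectionDataset, bins: int = 10) -> np.ndarray:
    """Normalized 1-D frequency grid of object scales sqrt(w*h) over (0, 1].

    All-zero sentinel when the dataset has no boxes.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    grid = np.zeros(bins, dtype=float)
    scales = np.array([ann.scale for _, ann in ds.iter_annotations()])
    if len(scales) == 0:
        return grid
    np.add.at(grid, _bin_index(scales, bins), 1.0)
    return grid / grid.sum()


@dataclass
class DistributionReport:
    """Snapshot of every distribution diagnostic at threshold ``n0``."""

    class_names: list[str]
    counts: list[int]
    imbalance_ratio: float
    log_dispersion: float
    n0: int
    effective_count: int
    effective_fraction: float
    effective_sample_fraction: float
    center_histogram: list[list[float]]
    scale_histogram: list[float]

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)

    def to_markdown(self) -> str:
        lines = [
            "| statistic | value |",
            "| --- | --- |",
            f"| classes | {len(self.class_names)} |",
            f"| instances | {sum(self.counts)} |",
            f"| imbalance ratio | {self.imbalance_ratio:.1f} |",
            f"| log dispersion | {self.log_dispersion:.2f} |",
            f"| effective classes (N0={self.n0}) | "
            f"{self.effective_count}/{len(self.class_names)} "
            f"({100 * self.effective_fraction:.1f}%) |",
            f"| effective-sample fraction | "
            f"{100 * self.effective_sample_fraction:.1f}% |",
        ]
        return "\n".join(lines)


def build_report(
    ds: DetectionDataset, n0: int = 200, bins: int = 8
) -> DistributionReport:
    """Compute a full :class:`DistributionReport` for a dataset."""
    dist = ClassDistribution.from_dataset(ds)
    count, frac = effective_coverage(dist, n0)
    return DistributionReport(
        class_names=list(dist.class_names),
        counts=[int(c) for c in dist.counts],
        imbalance_ratio=imbalance_ratio(dist),
        log_dispersion=log_dispersion(dist),
        n0=n0,
        effective_count=count,
        effective_fraction=frac,
        effective_sample_fraction=effective_sample_proportion(dist, n0),
        center_histogram=center_histogram(ds, bins).tolist(),
        scale_histogram=scale_histogram(ds, bins).tolist(),
    )


@dataclass
class AugReportDelta:
    """Per-statistic before→after differences plus direction flags."""

    imbalance_ratio_delta: float
    log_dispersion_delta: float
    effective_count_delta: int
    effective_sample_fraction_delta: float
    ir_decreased: bool
    coverage_increased: bool


def compare(before: DistributionReport, after: DistributionReport) -> AugReportDelta:
    """Before→after deltas of the headline statistics.

    Requires both reports to share the class table and threshold.
    """
    if before.class_names != after.class_names:
        raise ValueError("reports have mismatched class tables")
    if before.n0 != after.n0:
        raise ValueError("reports use different thresholds n0")
    return AugReportDelta(
        imbalance_ratio_delta=after.imbalance_ratio - before.imbalance_ratio,
        log_dispersion_delta=after.log_dispersion - before.log_dispersion,
        effective_count_delta=after.effective_count - before.effective_count,
        effective_sample_fraction_delta=(
            after.effective_sample_fraction - before.effective_sample_fraction
        ),
        ir_decreased=after.imbalance_ratio < before.imbalance_ratio,
        coverage_increased=after.effective_count > before.effective_count,
    )
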