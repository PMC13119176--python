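"""End-to-end orchestration: stats → bank → paste → environment → screen → write.

The pipeline is a pure function of (input dataset, config, seed): a single
global seed fans out to independent per-stage generators (stage names
hashed into the seed) so that inserting or reordering stages never
silently reshuffles another stage's randomness. The input dataset is never
mutated in place; the output root receives a standard YOLO layout holding
the originals plus every augmented sample the teacher kept, next to
``report.json``, ``report.md`` and ``provenance.json``.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .augment import AugPolicy, AugmentedSample, plan_and_augment
from .dist_stats import (
    ClassDistribution,
    DistributionReport,
    build_report,
    compare,
)
from .env_sim import EnvProfile
from .lesion_bank import build_bank, extract_instances
from .screening import ScreeningConfig, TeacherModel, screen_batch
from .synthetic import OracleTeacher
from .yolo_io import DatasetItem, DetectionDataset, read_dataset, write_dataset

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Everything one augmentation run needs.

    ``teacher`` holds :class:`OracleTeacher` constructor parameters; pass a
    ready-made detector adapter to :func:`run_calm_aug` instead to screen
    with an external model. ``rejected_mode`` is ``drop`` (default) or
    ``resample`` — re-plan replacements for rejected samples for up to
    ``max_resample_rounds`` rounds.
    """

    input_root: str | Path | None = None
    output_root: str | Path | None = None
    policy: AugPolicy = field(default_factory=AugPolicy)
    env: EnvProfile | None = field(default_factory=EnvProfile)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    teacher: dict = field(default_factory=dict)
    n0: int = 200
    bins: int = 8
    seed: int = 0
    rejected_mode: str = "drop"
    max_resample_rounds: int = 10
    pad_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.rejected_mode not in ("drop", "resample"):
            raise ValueError(f"unknown rejected_mode {self.rejected_mode!r}")
        if (
            self.input_root is not None
            and self.output_root is not None
            and Path(self.input_root).resolve() == Path(self.output_root).resolve()
        ):
            raise ValueError("output root must differ from input root")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file mirroring its fields."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(data)
    if "policy" in kwargs:
        kwargs["policy"] = AugPolicy(**_tupled(kwargs["policy"]))
    if "env" in kwargs:
        env = kwargs["env"]
        kwargs["env"] = None if env is None else EnvProfile(**_tupled(env))
    if "screening" in kwargs:
        kwargs["screening"] = ScreeningConfig(**kwargs["screening"])
    return PipelineConfig(**kwargs)


def _tupled(mapping: dict) -> dict:
    return {
        k: tuple(tuple(e) if isinstance(e, list) else e for e in v)
        if isinstance(v, list)
        else v
        for k, v in mapping.items()
    }


def _samples_to_items(samples: list[AugmentedSample]) -> list[DatasetItem]:
    return [
        DatasetItem(s.image_id, list(s.annotations), image=s.image) for s in samples
    ]


def run_calm_aug(
    cfg: PipelineConfig,
    dataset: DetectionDataset | None = None,
    masks: dict | None = None,
    teacher: TeacherModel | None = None,
) -> tuple[Path | None, dict]:
    """Run the full augmentation pipeline.

    ``dataset``/``masks``/``teacher`` override the config's disk input and
    oracle-teacher parameters for library use. Returns the output dataset
    path (None when no ``output_root`` is configured) and the report dict
    with before/after distribution reports, deltas, the screening summary
    and per-sample provenance.
    """
    if dataset is None:
        if cfg.input_root is None:
            raise ValueError("either cfg.input_root or a dataset is required")
        dataset = read_dataset(cfg.input_root)
    before = build_report(dataset, cfg.n0, cfg.bins)
    instances = extract_instances(dataset, cfg.pad_fraction, masks=masks)
    bank = build_bank(instances)
    if teacher is None:
        teacher = OracleTeacher(
            seed=stage_seed(cfg.seed, "teacher"), **cfg.teacher
        )
    rng = np.random.default_rng(stage_seed(cfg.seed, "augment"))
    samples, planned = plan_and_augment(dataset, bank, cfg.policy, cfg.env, rng)
    kept, rejected, summary = screen_batch(samples, teacher, cfg.screening)
    if cfg.rejected_mode == "resample" and rejected:
        kept, summary = _resample_rounds(
            dataset, bank, cfg, teacher, kept, summary, rng
        )
    out_items = [
        DatasetItem(it.image_id, list(it.annotations), image=it.image, path=it.path)
        for it in dataset.items
    ] + _samples_to_items(kept)
    out_ds = DetectionDataset(out_items, list(dataset.class_names))
    after = build_report(out_ds, cfg.n0, cfg.bins)
    report = {
        "seed": cfg.seed,
        "before": asdict(before),
        "after": asdict(after),
        "planned_counts": [int(c) for c in planned.counts],
        "delta": asdict(compare(before, after)),
        "screening": summary,
        "n_augmented_emitted": len(samples),
        "n_augmented_kept": len(kept),
        "provenance": {s.image_id: s.provenance for s in kept},
    }
    out_path: Path | None = None
    if cfg.output_root is not None:
        out_path = Path(cfg.output_root)
        write_dataset(out_ds, out_path, overwrite=True)
        (out_path / "report.json").write_text(json.dumps(report, indent=1))
        (out_path / "report.md").write_text(_report_md(before, after, summary))
        (out_path / "provenance.json").write_text(
            json.dumps(report["provenance"], indent=1)
        )
    return out_path, report


def _resample_rounds(dataset, bank, cfg, teacher, kept, summary, rng):
    """Top up screening losses by re-planning residual deficits."""
    base = ClassDistribution.from_dataset(dataset)
    targets = cfg.policy.targets(base.num_classes)
    for round_idx in range(cfg.max_resample_rounds):
        kept_counts = base.counts.copy()
        for s in kept:
            for ann in s.annotations[s.n_original :]:
                kept_counts[ann.class_id] += 1
        residual = np.maximum(0, targets - kept_counts)
        if residual.sum() == 0:
            break
        logger.info("resample round %d: %d residual pastes", round_idx, residual.sum())
        # one paste per replacement sample: whole-sample rejection then costs
        # at most one paste, so residuals shrink geometrically across rounds
        sub_policy = AugPolicy(
            target_count=(base.counts + residual).tolist(),
            scale_jitter=cfg.policy.scale_jitter,
            max_paste_per_image=1,
            max_overlap_iou=cfg.policy.max_overlap_iou,
            blend_mode=cfg.policy.blend_mode,
            retry_budget=cfg.policy.retry_budget,
        )
        extra, _ = plan_and_augment(dataset, bank, sub_policy, cfg.env, rng)
        new_kept, _, round_summary = screen_batch(extra, teacher, cfg.screening)
        kept = kept + new_kept
        for key, val in round_summary.items():
            summary[key] = summary.get(key, 0) + val
    return kept, summary


def _report_md(
    before: DistributionReport, after: DistributionReport, summary: dict
) -> str:
    delta = compare(before, after)
    parts = [
        "# Augmentation report",
        "",
        "## Before",
        before.to_markdown(),
        "",
        "## After",
        after.to_markdown(),
        "",
        "## Delta",
        f"- imbalance ratio: {delta.imbalance_ratio_delta:+.1f}"
        f" ({'decreased' if delta.ir_decreased else 'not decreased'})",
        f"- effective classes: {delta.effective_count_delta:+d}",
        f"- effective-sample fraction: "
        f"{100 * delta.effective_sample_fraction_delta:+.1f}%",
        "",
        "## Screening",
        *(f"- {k}: {v}" for k, v in summary.items()),
        "",
    ]
    return "\n".join(parts)
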