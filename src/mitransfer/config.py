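"""Run configuration and the end-to-end pipeline.

A :class:`RunConfig` (usually loaded from YAML) wires every stage together:
simulate a cohort, preprocess, pre-train on the pooled source subjects,
fine-tune each transfer plan per target subject over repeated splits, run
the classical baselines on the same splits, and emit a summary table plus a
complexity report.  One global seed fans out to per-stage seeds through a
stable hash of the stage name, so stages can be re-run in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import (EvalResult, baseline_classify, compare_methods,
                         evaluate_subject, make_split_sequence)
from .model import EEGNetConfig, complexity_report
from .preprocessing import FilterSpec
from .synth import SynthConfig, generate_cohort, pooled_source_trials
from .transfer import FINETUNE_EPOCHS, TrainConfig, TransferPlan, pretrain


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2 in the CLI)."""


class DataError(RuntimeError):
    """Missing or inconsistent data artifact (exit code 3 in the CLI)."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: hash of the stage name mixed with the
    global seed, reduced below 2**31."""
    return (global_seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass(frozen=True)
class CohortSettings:
    n_source_subjects: int = 5
    n_target_subjects: int = 1
    difficulty_profile: str = "easy"

    def __post_init__(self) -> None:
        if self.difficulty_profile not in ("easy", "hard"):
            raise ConfigError(
                f"cohort.difficulty_profile: expected easy|hard, "
                f"got {self.difficulty_profile!r}"
            )
        if self.n_source_subjects < 0 or self.n_target_subjects < 1:
            raise ConfigError("cohort: need n_target_subjects >= 1")


@dataclass(frozen=True)
class EvalSettings:
    n_repeats: int = 10
    n_train: int = 40
    plans: tuple[str, ...] = ("EEGNet_0", "EEGNet_1", "EEGNet_2")
    baselines: tuple[str, ...] = ("svm", "lda")
    finetune_epochs: int = FINETUNE_EPOCHS

    def __post_init__(self) -> None:
        for p in self.plans:
            try:
                TransferPlan.from_name(p)
            except ValueError as exc:
                raise ConfigError(f"evaluation.plans: {exc}") from exc
        for b in self.baselines:
            if b not in ("svm", "lda"):
                raise ConfigError(
                    f"evaluation.baselines: unknown baseline {b!r}"
                )


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of one reproducible run."""

    seed: int = 0
    out_dir: str = "runs/demo"
    target_fs: float = 100.0
    synth: SynthConfig = field(default_factory=SynthConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    model: EEGNetConfig | None = None  # None -> derived from synth/target_fs
    train: TrainConfig = field(default_factory=TrainConfig)
    cohort: CohortSettings = field(default_factory=CohortSettings)
    evaluation: EvalSettings = field(default_factory=EvalSettings)

    def resolved_model(self) -> EEGNetConfig:
        if self.model is not None:
            return self.model
        t = int(round(self.synth.trial_len_s * self.target_fs))
        return EEGNetConfig(n_channels=self.synth.n_channels, n_samples=t)


_SECTIONS = {
    "synth": SynthConfig,
    "filter": FilterSpec,
    "model": EEGNetConfig,
    "train": TrainConfig,
    "cohort": CohortSettings,
    "evaluation": EvalSettings,
}


def _build_section(name: str, cls, payload) -> object:
    if not isinstance(payload, dict):
        raise ConfigError(f"{name}: expected a mapping, got {type(payload).__name__}")
    valid = {f.name for f in fields(cls)}
    for key in payload:
        if key not in valid:
            raise ConfigError(f"{name}.{key}: unknown field")
    if cls in (EvalSettings,):
        payload = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in payload.items()}
    try:
        return cls(**payload)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{name}: {exc}") from exc


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Raises :class:`ConfigError` naming the offending field path.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level: expected a mapping")
    kwargs = {}
    for key, value in raw.items():
        if key in ("seed", "out_dir", "target_fs"):
            kwargs[key] = value
        elif key in _SECTIONS:
            kwargs[key] = _build_section(key, _SECTIONS[key], value)
        else:
            raise ConfigError(f"{key}: unknown section")
    try:
        return RunConfig(**kwargs)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def run_pipeline(config: RunConfig, log=print) -> pd.DataFrame:
    """Execute simulate -> preprocess -> pretrain -> fine-tune plans ->
    baselines -> summary.  Returns the summary table (percent accuracies)
    and writes all artifacts under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    synth_cfg = replace(config.synth, seed=stage_seed(config.seed, "simulate"))
    specs, manifest = generate_cohort(
        config.cohort.n_source_subjects, config.cohort.n_target_subjects,
        synth_cfg, config.cohort.difficulty_profile,
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    log(f"[simulate] cohort of {len(specs)} subjects written to manifest.csv")

    model_cfg = config.resolved_model()
    needs_pretrain = any(
        TransferPlan.from_name(p).uses_source_weights for p in config.evaluation.plans
    )
    weights = None
    if needs_pretrain:
        if config.cohort.n_source_subjects < 1:
            raise DataError("transfer plans need source subjects for pre-training")
        source = pooled_source_trials(specs, config.target_fs)
        tc_pre = replace(config.train, seed=stage_seed(config.seed, "pretrain"))
        weights, history = pretrain(source, model_cfg, tc_pre)
        pd.DataFrame({"epoch": range(1, len(history.loss) + 1),
                      "loss": history.loss,
                      "accuracy": history.accuracy}).to_csv(
            out / "pretrain_history.csv", index=False)
        log(f"[pretrain] {source.n_trials} pooled source trials, "
            f"final loss {history.loss[-1]:.4f}")

    rows: list[EvalResult] = []
    records = []
    for spec in (s for s in specs if s.role == "target"):
        trials = spec.trials(config.target_fs)
        base_seed = stage_seed(config.seed, f"evaluate:{spec.subject_id}")
        splits = make_split_sequence(
            trials, config.evaluation.n_repeats, config.evaluation.n_train,
            base_seed)
        for plan_name in config.evaluation.plans:
            plan = TransferPlan.from_name(plan_name)
            tc = replace(config.train,
                         epochs=(config.train.epochs if plan.name == "EEGNet_0"
                                 else config.evaluation.finetune_epochs))
            res = evaluate_subject(
                trials, plan, model_cfg, tc,
                n_train=config.evaluation.n_train,
                source_weights=weights if plan.uses_source_weights else None,
                subject_id=spec.subject_id, splits=splits)
            rows.append(res)
            log(f"[evaluate] {spec.subject_id} {plan.name}: {100 * res.mean:.1f}%")
        for baseline in config.evaluation.baselines:
            res = baseline_classify(trials, baseline, splits,
                                    subject_id=spec.subject_id)
            rows.append(res)
            log(f"[evaluate] {spec.subject_id} {baseline}: {100 * res.mean:.1f}%")
        for res in rows:
            if res.subject_id == spec.subject_id:
                for seed, acc in zip(res.seeds, res.accuracies):
                    records.append({"subject": res.subject_id,
                                    "method": res.method,
                                    "split_seed": seed, "accuracy": acc})

    pd.DataFrame(records).to_csv(out / "results.csv", index=False)
    comparison = compare_methods(rows)
    comparison.table.to_csv(out / "summary.csv")
    (out / "comparison.txt").write_text(comparison.render() + "\n")

    report = complexity_report(model_cfg)
    (out / "complexity.txt").write_text(report.render() + "\n")
    log(f"[complexity] {report.total_params} params, "
        f"{report.total_flops} FLOPs ({report.convention})")
    return comparison.table


__all__ = [
    "ConfigError", "DataError", "RunConfig", "CohortSettings", "EvalSettings",
    "stage_seed", "load_run_config", "run_pipeline",
]
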