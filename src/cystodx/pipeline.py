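"""End-to-end orchestration: fixtures -> IQR rejection -> three branch
trainings -> ensemble vote -> metrics, from one config, fully seeded."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cnn import TrainedClassifier, train_classifier
from .config import RunConfig, save_config
from .data import DatasetManifest, load_manifest, save_manifest
from .fixtures import FixtureConfig, generate_dataset
from .gan import train_gan_branch
from .metrics import MetricsReport, evaluate_predictions
from .outliers import RejectionReport, filter_outliers
from .voting import ensemble_predict, vote_summary
from .xdl import train_xdl

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    rejection: RejectionReport
    members: dict[str, TrainedClassifier]
    predictions: "object"  # pandas DataFrame
    vote_summary: dict
    metrics: dict[str, MetricsReport]
    timings: dict[str, float] = field(default_factory=dict)
    config_hash: str = ""
    seed: int = 0

    @property
    def ensemble_accuracy(self) -> float:
        return self.metrics["EDL"].accuracy

    def summary(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "rejection": {"n_kept": len(self.rejection.kept),
                          "n_rejected": len(self.rejection.rejected)},
            "members": {
                name: {"validation_accuracy": m.validation_accuracy,
                       "epochs": len(m.history)}
                for name, m in self.members.items()
            },
            "vote_summary": self.vote_summary,
            "metrics": {name: r.to_dict() for name, r in self.metrics.items()},
            "timings_s": {k: round(v, 2) for k, v in self.timings.items()},
        }


def load_pipeline_config(path: str | Path) -> tuple[RunConfig, FixtureConfig | None]:
    """One YAML file: RunConfig keys at the top level plus an optional
    ``fixtures`` section for synthetic-data generation."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    raw = dict(raw)
    fx = raw.pop("fixtures", None)
    cfg = RunConfig.from_dict(raw)
    fixture_cfg = None
    if fx is not None:
        fx = dict(fx)
        fx.setdefault("seed", cfg.seed)
        for key in ("image_size", "lesion_radius_range", "split_fractions"):
            if key in fx:
                fx[key] = tuple(fx[key])
        fixture_cfg = FixtureConfig(**fx)
    return cfg, fixture_cfg


def run_all(
    config: RunConfig,
    out_dir: str | Path,
    fixture_config: FixtureConfig | None = None,
    manifest: DatasetManifest | None = None,
) -> PipelineResult:
    """Execute every stage in order under ``out_dir``.

    Either a fixture config (synthetic data is generated) or an existing
    manifest must be provided. Re-running with the same config and seed
    reproduces manifests, sidecar accuracies and the predictions table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    config_hash = hashlib.sha256(cfg_text.encode()).hexdigest()[:16]
    save_config(config, out_dir / "config.yaml")
    timings: dict[str, float] = {}

    def stage(name):
        log.info("stage: %s", name)
        return _StageTimer(name, timings)

    try:
        if manifest is None:
            if fixture_config is None:
                raise ValueError("need either a manifest or a fixture config")
            with stage("fixtures"):
                manifest = generate_dataset(fixture_config, out_dir / "fixtures")

        with stage("outlier_rejection"):
            report = filter_outliers(manifest, config.outlier_feature,
                                     config.iqr_multiplier)
            save_manifest(report.kept, out_dir / "kept_manifest.csv")
            (out_dir / "rejection_report.json").write_text(
                json.dumps(report.summary(), indent=1))

        kept = report.kept
        ckpt_dir = out_dir / "checkpoints"
        ckpt_dir.mkdir(exist_ok=True)
        members: dict[str, TrainedClassifier] = {}
        with stage("train_cnn"):
            members["CNN"] = train_classifier(kept, config, branch="CNN")
            members["CNN"].save(ckpt_dir / "cnn")
        with stage("train_gan"):
            gan_member, augmented, _ = train_gan_branch(kept, config, out_dir)
            members["GAN"] = gan_member
            members["GAN"].save(ckpt_dir / "gan")
            save_manifest(augmented, out_dir / "augmented_manifest.csv")
        with stage("train_xdl"):
            members["XDL"] = train_xdl(kept, config)
            members["XDL"].save(ckpt_dir / "xdl")

        with stage("vote"):
            table = ensemble_predict(
                [members["CNN"], members["GAN"], members["XDL"]],
                kept, mode=config.voting_mode, split="test")
            table.to_csv(out_dir / "predictions.csv", index=False)
            summary = vote_summary(table)

        with stage("evaluate"):
            metrics = {"EDL": evaluate_predictions(
                table["label"], table["final_label"], config.class_names)}
            for name in ("CNN", "GAN", "XDL"):
                metrics[name] = evaluate_predictions(
                    table["label"], table[f"pred_{name}"], config.class_names)
    except Exception as exc:
        log.error("pipeline aborted during stage %s: %s",
                  timings.get("_current", "?"), exc)
        raise

    result = PipelineResult(
        rejection=report, members=members, predictions=table,
        vote_summary=summary, metrics=metrics, timings=timings,
        config_hash=config_hash, seed=config.seed)
    (out_dir / "result.json").write_text(json.dumps(result.summary(), indent=1))
    return result


class _StageTimer:
    def __init__(self, name: str, sink: dict) -> None:
        self.name = name
        self.sink = sink

    def __enter__(self):
        self.sink["_current"] = self.name
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.sink[self.name] = time.perf_counter() - self.t0
        self.sink.pop("_current", None)
        return False
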