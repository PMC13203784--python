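"""Configuration-driven experiment suites.

A suite is a YAML file naming the variants to run (architecture x loss x
augmentation), the dataset manifest, and the shared hyperparameters. The
hyperparameter block uses the training-protocol names verbatim (base
channel multiplier, input size, scheduler factor/patience, ...) so a
config file doubles as the experiment record. Each variant trains,
evaluates on the validation and test splits, and writes its artifacts
(config snapshot, training log, best/last checkpoints, metric tables,
confusion-matrix and ROC plots) under its own run directory; a
consolidated variant x split x metric table with confidence intervals is
assembled at the end and can be regenerated from the artifacts alone.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from .data import AugmentationConfig, DatasetSplit, read_manifest, split_by_patient
from .metrics import MetricReport
from .model import ArchitectureConfig, HybridUNet
from .training import (
    ExperimentVariant,
    TrainConfig,
    evaluate_split,
    load_checkpoint,
    train,
)

__all__ = ["ExperimentSuite", "run_suite", "regenerate_report", "load_suite"]

# YAML keys for the shared hyperparameter block -> internal config fields
_HYPER_KEYS = {
    "Base (channels multiplier)": ("arch", "base_channels"),
    "Input size": ("both", "input_size"),
    "Batch size": ("train", "batch_size"),
    "Learning rate": ("train", "learning_rate"),
    "Epochs": ("train", "max_epochs"),
    "Early stopping patience": ("train", "early_stop_patience"),
    "Scheduler factor": ("train", "plateau_factor"),
    "Scheduler patience": ("train", "plateau_patience"),
    "Gradient clipping": ("train", "clip_max_norm"),
    "Transformer layers": ("arch", "transformer_layers"),
    "Transformer heads": ("arch", "attention_heads"),
}


@dataclass
class ExperimentSuite:
    variants: list[ExperimentVariant]
    manifest: str
    output_root: str
    train_cfg: TrainConfig = field(default_factory=TrainConfig)
    arch_overrides: dict = field(default_factory=dict)
    seed: int = 0
    resume: bool = True
    bootstrap_resamples: int = 1000

    def __post_init__(self):
        names = [v.name for v in self.variants]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate variant names: {names}")


def load_suite(path: str | Path) -> ExperimentSuite:
    with open(path) as f:
        raw = yaml.safe_load(f)
    train_kwargs: dict = {}
    arch_kwargs: dict = {}
    for key, value in (raw.get("hyperparameters") or {}).items():
        if key not in _HYPER_KEYS:
            continue  # descriptive entries like Optimizer/Loss are informational
        target, name = _HYPER_KEYS[key]
        if target in ("train", "both"):
            train_kwargs[name] = value
        if target in ("arch", "both"):
            arch_kwargs[name] = value
    seed = int(raw.get("seed", 0))
    train_kwargs.setdefault("seed", seed)
    return ExperimentSuite(
        variants=[ExperimentVariant.from_name(n) for n in raw["variants"]],
        manifest=str(raw["data"]),
        output_root=str(raw["output"]),
        train_cfg=TrainConfig(**train_kwargs),
        arch_overrides=arch_kwargs,
        seed=seed,
        resume=bool(raw.get("resume", True)),
        bootstrap_resamples=int(raw.get("bootstrap_resamples", 1000)),
    )


def _arch_for(variant: ExperimentVariant, suite: ExperimentSuite) -> ArchitectureConfig:
    kwargs = dict(suite.arch_overrides)
    kwargs["use_transformer"] = variant.architecture == "hybrid"
    kwargs.setdefault("input_size", suite.train_cfg.input_size)
    kwargs["input_size"] = suite.train_cfg.input_size
    return ArchitectureConfig(**kwargs)


def _report_to_json(report: MetricReport) -> dict:
    out = {
        "n_images": report.n_images,
        "point": report.point,
        "ci_lower": report.ci_lower,
        "ci_upper": report.ci_upper,
        "auc": report.auc,
    }
    if report.classwise is not None:
        cw = report.classwise
        out["confusion"] = {"tp": cw.counts.tp, "fp": cw.counts.fp,
                            "fn": cw.counts.fn, "tn": cw.counts.tn}
        out["per_class"] = cw.per_class
        out["macro"] = cw.macro
        out["weighted"] = cw.weighted
        out["pixel_accuracy"] = cw.accuracy
    return out


def _plot_confusion(report: MetricReport, path: Path) -> None:
    cw = report.classwise
    if cw is None:
        return
    mat = np.array([[cw.counts.tn, cw.counts.fp], [cw.counts.fn, cw.counts.tp]])
    fig, ax = plt.subplots(figsize=(3.2, 3))
    ax.imshow(mat, cmap="Blues")
    for i in range(2):
        for j in range(2):
            ax.text(j, i, f"{mat[i, j]:,}", ha="center", va="center", fontsize=8)
    ax.set_xticks([0, 1], ["BG", "FG"])
    ax.set_yticks([0, 1], ["BG", "FG"])
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _plot_roc(model: HybridUNet, records, input_size: int, path: Path,
              max_images: int = 8, seed: int = 0) -> None:
    from .data import load_pair
    from .autodiff import no_grad

    scores, labels = [], []
    model.eval()
    with no_grad():
        for r in records[:max_images]:
            img, msk = load_pair(r, target_size=input_size)
            scores.append(model(img[None]).data.ravel())
            labels.append(msk.ravel())
    s = np.concatenate(scores)
    y = np.concatenate(labels) > 0
    if y.all() or not y.any():
        return
    order = np.argsort(-s)
    tpr = np.cumsum(y[order]) / y.sum()
    fpr = np.cumsum(~y[order]) / (~y).sum()
    fig, ax = plt.subplots(figsize=(3.4, 3))
    ax.plot(fpr, tpr)
    ax.plot([0, 1], [0, 1], "--", color="gray", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


EXPECTED_ARTIFACTS = (
    "config.yaml",
    "train_log.csv",
    "best.npz",
    "last.npz",
    "metrics.json",
    "metrics.csv",
    "confusion.png",
    "roc.png",
)


def run_suite(suite: ExperimentSuite) -> pd.DataFrame:
    """Execute every variant; failures are recorded, not fatal.

    Returns the consolidated variant x split x metric table (also written
    to ``suite_report.csv`` under the output root).
    """
    root = Path(suite.output_root)
    root.mkdir(parents=True, exist_ok=True)
    records = read_manifest(suite.manifest)
    splits = split_by_patient(records, seed=suite.seed)
    rows: list[dict] = []
    failures: dict[str, str] = {}
    for variant in suite.variants:
        run_dir = root / variant.name
        try:
            rows.extend(_run_variant(variant, suite, splits, run_dir))
        except Exception as e:  # keep remaining variants alive
            failures[variant.name] = f"{type(e).__name__}: {e}"
            (run_dir / "FAILED.txt").parent.mkdir(parents=True, exist_ok=True)
            (run_dir / "FAILED.txt").write_text(traceback.format_exc())
    report = pd.DataFrame(rows)
    report.to_csv(root / "suite_report.csv", index=False)
    if failures:
        (root / "failures.json").write_text(json.dumps(failures, indent=2))
    return report


def _run_variant(variant: ExperimentVariant, suite: ExperimentSuite,
                 splits: DatasetSplit, run_dir: Path) -> list[dict]:
    run_dir.mkdir(parents=True, exist_ok=True)
    arch = _arch_for(variant, suite)
    metrics_path = run_dir / "metrics.json"
    if suite.resume and metrics_path.exists() and (run_dir / "best.npz").exists():
        stored = json.loads(metrics_path.read_text())
        return _rows_from_stored(variant.name, stored)

    cfg = suite.train_cfg
    model = HybridUNet(arch, np.random.default_rng(cfg.seed))
    with open(run_dir / "config.yaml", "w") as f:
        yaml.safe_dump(
            {"variant": variant.name, "architecture": arch.to_dict(),
             "train": vars(cfg).copy()}, f)
    best, log = train(model, splits, cfg, variant, out_dir=run_dir)
    model.load_state_dict(best["state"])

    stored = {}
    for split_name, recs in (("val", splits.val), ("test", splits.test)):
        report = evaluate_split(
            model, recs, input_size=cfg.input_size,
            resamples=suite.bootstrap_resamples, seed=suite.seed)
        stored[split_name] = _report_to_json(report)
        if split_name == "test":
            _plot_confusion(report, run_dir / "confusion.png")
            _plot_roc(model, recs, cfg.input_size, run_dir / "roc.png",
                      seed=suite.seed)
    metrics_path.write_text(json.dumps(stored, indent=2))
    _stored_to_csv(stored).to_csv(run_dir / "metrics.csv", index=False)
    return _rows_from_stored(variant.name, stored)


def _rows_from_stored(variant_name: str, stored: dict) -> list[dict]:
    rows = []
    for split_name, rep in stored.items():
        for metric, value in rep["point"].items():
            rows.append(
                {
                    "variant": variant_name,
                    "split": split_name,
                    "metric": metric,
                    "point": value,
                    "ci_lower": rep["ci_lower"][metric],
                    "ci_upper": rep["ci_upper"][metric],
                }
            )
        if rep.get("auc") is not None:
            rows.append({"variant": variant_name, "split": split_name,
                         "metric": "auc", "point": rep["auc"],
                         "ci_lower": np.nan, "ci_upper": np.nan})
    return rows


def _stored_to_csv(stored: dict) -> pd.DataFrame:
    return pd.DataFrame(_rows_from_stored("", stored)).drop(columns=["variant"])


def regenerate_report(output_root: str | Path) -> pd.DataFrame:
    """Rebuild the consolidated table from per-variant artifacts alone."""
    root = Path(output_root)
    rows = []
    for metrics_path in sorted(root.glob("*/metrics.json")):
        stored = json.loads(metrics_path.read_text())
        rows.extend(_rows_from_stored(metrics_path.parent.name, stored))
    report = pd.DataFrame(rows)
    report.to_csv(root / "suite_report.csv", index=False)
    return report
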