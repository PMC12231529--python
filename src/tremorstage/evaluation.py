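"""Classification metrics, confusion matrices, and feature-set ablation.

Per class m in a one-vs-rest reduction of the confusion matrix:

    precision_m = TP / (TP + FP)      recall_m = TP / (TP + FN)
    F1_m = 2 * P * R / (P + R)

with overall accuracy = trace / total and macro averages the unweighted
means across classes.  Cells with a zero denominator yield 0 and are
flagged in the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import classifier as clf
from . import dataset as ds

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion",
    "per_class_metrics",
    "macro_average",
    "evaluate_model",
    "ablation_report",
]


@dataclass
class ConfusionMatrix:
    """Counts[i][j] = windows of true class i predicted as class j (1-based)."""

    counts: np.ndarray
    class_names: list[str]

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        pd.DataFrame(self.counts, index=self.class_names,
                     columns=self.class_names).to_csv(path)


@dataclass
class EvalReport:
    """Per-class and macro-averaged performance for one feature set."""

    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    feature_set: int
    n_samples: int
    undefined_metrics: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        return cls(**json.loads(text))


def confusion(true_labels, predicted_labels, n_classes: int = 5,
              class_names: list[str] | None = None) -> ConfusionMatrix:
    """Build the confusion matrix from 1-based label vectors."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    if t.size and (t.min() < 1 or t.max() > n_classes
                   or p.min() < 1 or p.max() > n_classes):
        raise ValueError(f"labels must lie in 1..{n_classes}")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (t - 1, p - 1), 1)
    names = class_names or [f"level{m}" for m in range(1, n_classes + 1)]
    return ConfusionMatrix(counts=counts, class_names=names)


def per_class_metrics(cm: ConfusionMatrix):
    """One-vs-rest precision/recall/F1 per class plus overall accuracy.

    Returns ``(per_class, accuracy, undefined)`` where ``undefined`` lists
    "class:metric" strings for zero-denominator cases (reported as 0).
    """
    counts = cm.counts
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp

    per_class: dict[str, dict[str, float]] = {}
    undefined: list[str] = []
    for m, name in enumerate(cm.class_names):
        if tp[m] + fp[m] > 0:
            precision = tp[m] / (tp[m] + fp[m])
        else:
            precision = 0.0
            undefined.append(f"{name}:precision")
        if tp[m] + fn[m] > 0:
            recall = tp[m] / (tp[m] + fn[m])
        else:
            recall = 0.0
            undefined.append(f"{name}:recall")
        if precision + recall > 0:
            f1 = 2 * precision * recall / (precision + recall)
        else:
            f1 = 0.0
            undefined.append(f"{name}:f1")
        per_class[name] = {"precision": float(precision),
                           "recall": float(recall), "f1": float(f1)}
    accuracy = float(tp.sum() / total)
    return per_class, accuracy, undefined


def macro_average(per_class: dict[str, dict[str, float]]) -> dict[str, float]:
    """Unweighted mean of each metric across classes."""
    metrics = ("precision", "recall", "f1")
    return {m: float(np.mean([v[m] for v in per_class.values()]))
            for m in metrics}


def evaluate_model(model, windows: list, feature_set: int = 0) -> EvalReport:
    """Predict on held-out windows and compile the report."""
    X, y, _ = ds.stack_windows(windows)
    pred, _ = clf.predict(model, X)
    cm = confusion(y, pred, n_classes=model.config.n_classes)
    per_class, accuracy, undefined = per_class_metrics(cm)
    macro = macro_average(per_class)
    macro["accuracy"] = accuracy
    return EvalReport(per_class=per_class, macro=macro,
                      feature_set=feature_set, n_samples=len(windows),
                      undefined_metrics=undefined)


def ablation_report(windows: list, channel_names: list[str],
                    feature_set_ids=(1, 2, 3, 4),
                    config: "clf.NetworkConfig | None" = None,
                    seed: int = 0, test_fraction: float = 0.1,
                    grouped: bool = False):
    """Train one model per feature set on the identical split and seed.

    ``windows`` must carry the full 19-channel canonical set; each feature
    set selects its channel subset from the same underlying windows, so the
    comparison isolates the sensing modalities.  Returns
    ``(reports, loss_curves)`` with one entry per feature set.
    """
    index = {n: i for i, n in enumerate(channel_names)}
    train_w, test_w = ds.split_train_test(windows, test_fraction=test_fraction,
                                          seed=seed, grouped=grouped)
    X_tr, y_tr, _ = ds.stack_windows(train_w)
    X_te, y_te, _ = ds.stack_windows(test_w)

    reports: list[EvalReport] = []
    loss_curves: dict[int, list[float]] = {}
    for set_id in feature_set_ids:
        spec = ds.FeatureSetSpec.from_id(set_id)
        missing = [n for n in spec.channel_names if n not in index]
        if missing:
            raise KeyError(f"feature set {set_id} needs absent channels: "
                           f"{missing}")
        rows = [index[n] for n in spec.channel_names]
        base = config or clf.NetworkConfig(n_features=spec.n_channels,
                                           seed=seed)
        cfg = clf.NetworkConfig(**{**asdict(base),
                                   "n_features": spec.n_channels,
                                   "seed": seed})
        model = clf.build_network(cfg, channel_names=spec.channel_names)
        clf.train(model, X_tr[:, rows, :], y_tr, cfg)
        pred, _ = clf.predict(model, X_te[:, rows, :])
        cm = confusion(y_te, pred, n_classes=cfg.n_classes)
        per_class, accuracy, undefined = per_class_metrics(cm)
        macro = macro_average(per_class)
        macro["accuracy"] = accuracy
        reports.append(EvalReport(per_class=per_class, macro=macro,
                                  feature_set=set_id, n_samples=len(test_w),
                                  undefined_metrics=undefined))
        loss_curves[set_id] = list(model.history)
    return reports, loss_curves
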