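"""Confusion-matrix metrics and a small model-comparison harness.

Metrics are reported on the percentage scale: precision = TP/(TP+FP)*100,
recall = TP/(TP+FN)*100, F1 = 2*P*R/(P+R) (harmonic mean of the percentage
P and R, identical to fraction-scale F1*100), accuracy = (TP+TN)/n*100, and
false rate = (FP+FN)/n*100.  A metric whose denominator is zero is reported
as *undefined* (None) and listed, never silently coerced to 0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError
from .io import FeatureTable, SplitSpec, split_dataset

logger = logging.getLogger("pdpipe")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ContractError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(predicted, true) -> ConfusionMatrix:
    """Tally TP/FP/FN/TN for binary label vectors (1 = PD positive)."""
    predicted = np.asarray(predicted, dtype=int)
    true = np.asarray(true, dtype=int)
    if predicted.shape != true.shape or predicted.ndim != 1:
        raise ContractError("predicted and true must be equal-length vectors")
    for v in (predicted, true):
        if not np.isin(v, (0, 1)).all():
            raise ContractError("labels must be binary 0/1")
    return ConfusionMatrix(
        tp=int(((predicted == 1) & (true == 1)).sum()),
        fp=int(((predicted == 1) & (true == 0)).sum()),
        fn=int(((predicted == 0) & (true == 1)).sum()),
        tn=int(((predicted == 0) & (true == 0)).sum()),
    )


@dataclass
class EvaluationReport:
    """Percentage-scale metrics with explicit undefined markers."""

    confusion_matrix: ConfusionMatrix
    precision: float | None
    recall: float | None
    f1: float | None
    accuracy: float | None
    false_rate: float | None
    undefined: list[str] = field(default_factory=list)
    risk_counts: dict[str, int] = field(default_factory=dict)
    seed: int | None = None
    split: str | None = None

    def to_dict(self) -> dict:
        cm = self.confusion_matrix
        return {
            "confusion_matrix": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "false_rate": self.false_rate,
            "undefined": self.undefined,
            "risk_counts": self.risk_counts,
            "seed": self.seed,
            "split": self.split,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        d = json.loads(text)
        return cls(
            confusion_matrix=ConfusionMatrix(**d["confusion_matrix"]),
            precision=d["precision"],
            recall=d["recall"],
            f1=d["f1"],
            accuracy=d["accuracy"],
            false_rate=d["false_rate"],
            undefined=d["undefined"],
            risk_counts=d["risk_counts"],
            seed=d["seed"],
            split=d["split"],
        )


def metrics(cm: ConfusionMatrix, **extra) -> EvaluationReport:
    """Percentage-scale precision/recall/F1/accuracy/false rate from counts."""
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return 100.0 * num / den

    precision = ratio(cm.tp, cm.tp + cm.fp, "precision")
    recall = ratio(cm.tp, cm.tp + cm.fn, "recall")
    if precision is None or recall is None or precision + recall == 0.0:
        undefined.append("f1")
        f1 = None
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    accuracy = ratio(cm.tp + cm.tn, cm.n, "accuracy")
    false_rate = ratio(cm.fp + cm.fn, cm.n, "false_rate")
    return EvaluationReport(
        confusion_matrix=cm,
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy,
        false_rate=false_rate,
        undefined=undefined,
        **extra,
    )


def evaluate_predictions(predicted, true, risks=None, **extra) -> EvaluationReport:
    """Confusion + metrics + per-risk-class counts in one call."""
    report = metrics(confusion(predicted, true), **extra)
    if risks is not None:
        counts = {"low": 0, "medium": 0, "high": 0}
        for r in risks:
            counts[r.risk_class] += 1
        report.risk_counts = counts
    return report


class MajorityClassifier:
    """Baseline predicting the most frequent training label."""

    def fit(self, values, labels):
        labels = np.asarray(labels, dtype=int)
        self.label_ = int(np.bincount(labels, minlength=2).argmax())
        return self

    def predict(self, values):
        n = len(values)
        return np.full(n, self.label_, dtype=int)


def compare_models(
    table: FeatureTable,
    model_specs: dict,
    seeds: list[int],
    split: SplitSpec | None = None,
    preprocess_kwargs: dict | None = None,
):
    """Evaluate several classifiers on identical splits across seeds.

    ``model_specs`` maps a name to a zero-argument factory returning an
    object with sklearn-style ``fit(X, y)`` / ``predict(X)``; externally
    provided classifiers plug in the same way.  Preprocessing is fit on the
    training partition and applied to test.  A model that fails to train is
    recorded as failed and the run continues.  Returns a pandas DataFrame of
    per-(model, seed) rows plus a mean +/- SD summary.
    """
    import pandas as pd

    from .preprocessing import preprocess

    rows = []
    for seed in seeds:
        spec = SplitSpec(seed=seed) if split is None else SplitSpec(
            train_frac=split.train_frac, val_frac=split.val_frac,
            test_frac=split.test_frac, seed=seed, stratified=split.stratified,
        )
        tr, va, te = split_dataset(table, spec)
        norm_tr, prep = preprocess(tr, **(preprocess_kwargs or {}))
        norm_te = prep.transform(te)
        for name, factory in model_specs.items():
            try:
                clf = factory()
                clf.fit(norm_tr.values, norm_tr.labels)
                pred = np.asarray(clf.predict(norm_te.values), dtype=int)
                report = evaluate_predictions(pred, norm_te.labels, seed=seed)
                rows.append(
                    {"model": name, "seed": seed, "failed": False}
                    | {k: report.to_dict()[k]
                       for k in ("accuracy", "precision", "recall", "f1", "false_rate")}
                )
            except Exception as exc:  # noqa: BLE001 — a failed model must not kill the run
                logger.warning("model %s failed on seed %d: %s", name, seed, exc)
                rows.append({"model": name, "seed": seed, "failed": True})
    detail = pd.DataFrame(rows)
    summary = (
        detail[~detail["failed"]]
        .groupby("model")[["accuracy", "precision", "recall", "f1", "false_rate"]]
        .agg(["mean", "std"])
    )
    return detail, summary


def paired_binomial_test(correct_a, correct_b) -> float:
    """Exact binomial test on the discordant pairs of two models.

    Two-sided p-value that, among rows the models disagree on, each is
    equally likely to be the correct one (an exact McNemar-style test).
    Returns 1.0 when there are no discordant pairs.
    """
    from math import comb

    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape:
        raise ContractError("correctness vectors must be equal length")
    n01 = int((~a & b).sum())
    n10 = int((a & ~b).sum())
    n = n01 + n10
    if n == 0:
        return 1.0
    k = min(n01, n10)
    tail = sum(comb(n, i) for i in range(k + 1)) / 2.0**n
    return float(min(1.0, 2.0 * tail))
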