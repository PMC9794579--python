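"""Repeated-resampling evaluation of the TdP-risk classifier.

The test pool holds every variability series of each test drug (posterior
samples x Cmax multipliers).  One evaluation round draws exactly one series
per drug, predicts all drugs, and scores the resulting 16-point test set;
repeating this (10,000 rounds in the standard configuration) yields a
distribution per metric, summarised as median (min-max).

Metrics per round: one-vs-rest ROC AUC per risk class from the predicted
class probabilities (Mann-Whitney form, ties at 0.5), and from the argmax
labels the per-class diagnostic likelihood ratios LR+ = sens/(1-spec) and
LR- = (1-sens)/spec, overall accuracy, and macro-averaged F1.  Division by
zero yields +inf (reported as "Inf"); 0/0 yields a missing sentinel that is
skipped in summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tdprisk.classifier import LABELS, LABEL_TO_INDEX, TrainedModel
from tdprisk.biomarkers import VariabilityPool


def roc_auc_ovr(labels, scores, positive) -> float:
    """One-vs-rest AUC: P(random positive outranks random negative), ties 0.5.

    Returns NaN (missing sentinel) when only one class is present.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must align")
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    # Mann-Whitney U from midranks
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores))
    sorted_scores = scores[order]
    i = 0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class ClassMetrics:
    sensitivity: float
    specificity: float
    lr_pos: float
    lr_neg: float
    f1: float


def _safe_div(num: float, den: float) -> float:
    if den == 0:
        return float("inf") if num > 0 else float("nan")
    return num / den


def confusion_metrics(labels, predictions) -> dict:
    """Per-class LR+/LR-, overall accuracy and macro F1 from hard labels.

    LR+ = sensitivity / (1 - specificity); LR- = (1 - sensitivity) /
    specificity.  Division by zero gives +inf, 0/0 gives NaN (missing).
    """
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must align")
    if labels.size == 0:
        raise ValueError("empty inputs")
    out: dict = {"per_class": {}}
    f1s = []
    for cls in LABELS:
        tp = int(np.sum((labels == cls) & (predictions == cls)))
        fn = int(np.sum((labels == cls) & (predictions != cls)))
        fp = int(np.sum((labels != cls) & (predictions == cls)))
        tn = int(np.sum((labels != cls) & (predictions != cls)))
        sens = _safe_div(tp, tp + fn)
        spec = _safe_div(tn, tn + fp)
        lr_pos = _safe_div(sens, 1.0 - spec)
        lr_neg = _safe_div(1.0 - sens, spec)
        prec = tp / (tp + fp) if (tp + fp) else float("nan")
        f1 = (
            2 * prec * sens / (prec + sens)
            if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
            else 0.0
        )
        f1s.append(f1)
        out["per_class"][cls] = ClassMetrics(sens, spec, lr_pos, lr_neg, f1)
    out["accuracy"] = float(np.mean(labels == predictions))
    out["f1_macro"] = float(np.mean(f1s))
    return out


def _summary(values: np.ndarray) -> tuple[float, float, float]:
    """(median, min, max) over the extended real line, skipping NaN."""
    v = values[~np.isnan(values)]
    if v.size == 0:
        return (float("nan"),) * 3
    # median over the extended reals: +inf sorts to the top, so an "Inf"
    # median is possible and is reported as such
    sv = np.sort(v)
    mid = (len(sv) - 1) / 2
    lo_m, hi_m = sv[int(np.floor(mid))], sv[int(np.ceil(mid))]
    med = float(lo_m) if lo_m == hi_m else float(0.5 * (lo_m + hi_m))
    return med, float(sv[0]), float(sv[-1])


@dataclass
class TestSummary:
    """Median (min-max) metric summaries over the repeated test draws."""

    auc: dict[str, tuple[float, float, float]]
    lr_pos: dict[str, tuple[float, float, float]]
    lr_neg: dict[str, tuple[float, float, float]]
    accuracy: tuple[float, float, float]
    f1: tuple[float, float, float]
    n_iterations: int
    per_iteration: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, per_cls in (("AUC", self.auc), ("LR+", self.lr_pos), ("LR-", self.lr_neg)):
            for cls in LABELS:
                med, lo, hi = per_cls[cls]
                rows.append({"metric": name, "class": cls, "median": med, "min": lo, "max": hi})
        for name, tup in (("Accuracy", self.accuracy), ("F1 score", self.f1)):
            med, lo, hi = tup
            rows.append({"metric": name, "class": "overall", "median": med, "min": lo, "max": hi})
        return pd.DataFrame(rows)


def run_repeated_test(
    model: TrainedModel, pool: VariabilityPool, n_iter: int, seed: int
) -> TestSummary:
    """The repeated one-sample-per-drug test algorithm.

    Each iteration draws one series per drug uniformly from that drug's
    full pool, predicts every drug, and records per-class AUC (from class
    probabilities) plus LR/accuracy/F1 (from argmax labels).  Since
    inference is deterministic, predictions are computed once per unique
    series and iterations only resample rows.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    drugs = pool.drugs
    if not drugs:
        raise ValueError("empty test pool")
    rng = np.random.default_rng(seed)

    probs_by_drug = {}
    risk_by_drug = {}
    for drug in drugs:
        entry = pool.get(drug)
        if entry.values.shape[0] < 1:
            raise ValueError(f"drug {drug!r} has no series")
        if entry.values.shape[1] != model.config.input_length:
            raise ValueError(
                f"pool series length {entry.values.shape[1]} != model input "
                f"length {model.config.input_length}"
            )
        # chunked batch prediction over the drug's whole pool
        chunks = []
        for start in range(0, entry.values.shape[0], 2048):
            chunks.append(model.net.forward(entry.values[start : start + 2048]))
        probs_by_drug[drug] = np.concatenate(chunks, axis=0)
        risk_by_drug[drug] = entry.risk

    labels = np.array([risk_by_drug[d] for d in drugs])
    records = []
    for it in range(n_iter):
        probs = np.stack(
            [
                probs_by_drug[d][rng.integers(probs_by_drug[d].shape[0])]
                for d in drugs
            ]
        )
        preds = np.array([LABELS[i] for i in probs.argmax(axis=1)])
        rec = {"iteration": it}
        for cls in LABELS:
            rec[f"auc_{cls}"] = roc_auc_ovr(labels, probs[:, LABEL_TO_INDEX[cls]], cls)
        cm = confusion_metrics(labels, preds)
        for cls in LABELS:
            rec[f"lr_pos_{cls}"] = cm["per_class"][cls].lr_pos
            rec[f"lr_neg_{cls}"] = cm["per_class"][cls].lr_neg
        rec["accuracy"] = cm["accuracy"]
        rec["f1"] = cm["f1_macro"]
        records.append(rec)

    df = pd.DataFrame(records)
    return TestSummary(
        auc={cls: _summary(df[f"auc_{cls}"].to_numpy()) for cls in LABELS},
        lr_pos={cls: _summary(df[f"lr_pos_{cls}"].to_numpy()) for cls in LABELS},
        lr_neg={cls: _summary(df[f"lr_neg_{cls}"].to_numpy()) for cls in LABELS},
        accuracy=_summary(df["accuracy"].to_numpy()),
        f1=_summary(df["f1"].to_numpy()),
        n_iterations=n_iter,
        per_iteration=df,
    )
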