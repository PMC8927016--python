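"""Threshold metrics, ROC/PRC areas and curves, and the two-channel ensembles.

A prediction set is a DataFrame with columns ``subject_id``, ``p_ad`` (the
probability assigned to AD) and ``label`` (1 = AD). Hard classification uses
p_ad >= threshold (default 0.5, the argmax rule of a two-class softmax).
AUC-ROC is the rank formulation (ties count 1/2); AUC-PRC is average
precision, the area of the step-shaped precision-recall curve traversed in
decreasing-score order (no optimistic interpolation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn import metrics as skm


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int
    auc_roc: float | None = None
    auc_prc: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _validate(preds: pd.DataFrame) -> pd.DataFrame:
    if len(preds) == 0:
        raise ValueError("empty prediction set")
    missing = {"subject_id", "p_ad", "label"} - set(preds.columns)
    if missing:
        raise ValueError(f"prediction set lacks columns {sorted(missing)}")
    if ((preds["p_ad"] < 0) | (preds["p_ad"] > 1)).any():
        raise ValueError("p_ad outside [0, 1]")
    if not preds["label"].isin([0, 1]).all():
        raise ValueError("labels must be binary")
    return preds


def confusion_metrics(preds: pd.DataFrame, threshold: float = 0.5) -> MetricsReport:
    """Accuracy, precision, recall and F1 at the given decision threshold.

    Precision and F1 are reported as 0 (with a warning) when their
    denominators vanish.
    """
    preds = _validate(preds)
    y = preds["label"].to_numpy().astype(int)
    yhat = (preds["p_ad"].to_numpy() >= threshold).astype(int)
    tp = int(((yhat == 1) & (y == 1)).sum())
    fp = int(((yhat == 1) & (y == 0)).sum())
    fn = int(((yhat == 0) & (y == 1)).sum())
    tn = int(((yhat == 0) & (y == 0)).sum())
    accuracy = (tp + tn) / len(y)
    if tp + fp == 0:
        warnings.warn("no subject predicted AD; precision reported as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    if precision + recall == 0:
        warnings.warn("degenerate precision/recall; F1 reported as 0")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall,
                         f1=f1, threshold=threshold, tp=tp, fp=fp, fn=fn, tn=tn)


def auc_roc(preds: pd.DataFrame) -> float:
    """Probability a random AD subject outscores a random control (ties 1/2)."""
    preds = _validate(preds)
    y = preds["label"].to_numpy()
    if y.min() == y.max():
        raise ValueError("AUC-ROC requires both classes")
    return float(skm.roc_auc_score(y, preds["p_ad"].to_numpy()))


def roc_points(preds: pd.DataFrame) -> pd.DataFrame:
    preds = _validate(preds)
    fpr, tpr, _ = skm.roc_curve(preds["label"], preds["p_ad"])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def auc_prc(preds: pd.DataFrame) -> float:
    """Average precision: sum of precision x recall-increment down the ranking."""
    preds = _validate(preds)
    y = preds["label"].to_numpy()
    if y.sum() == 0:
        raise ValueError("AUC-PRC requires at least one AD subject")
    return float(skm.average_precision_score(y, preds["p_ad"].to_numpy()))


def prc_points(preds: pd.DataFrame) -> pd.DataFrame:
    preds = _validate(preds)
    precision, recall, _ = skm.precision_recall_curve(preds["label"], preds["p_ad"])
    return pd.DataFrame({"recall": recall, "precision": precision})


def evaluate(preds: pd.DataFrame, threshold: float = 0.5) -> MetricsReport:
    """All six metrics; AUCs are omitted when a class is absent."""
    report = confusion_metrics(preds, threshold)
    y = preds["label"].to_numpy()
    if 0 < y.sum() < len(y):
        report.auc_roc = auc_roc(preds)
        report.auc_prc = auc_prc(preds)
    return report


def _align(preds_g: pd.DataFrame, preds_i: pd.DataFrame):
    g = _validate(preds_g).set_index("subject_id")
    i = _validate(preds_i).set_index("subject_id")
    if set(g.index) != set(i.index) or len(g) != len(i):
        raise ValueError("ensembles require identical subject sets")
    i = i.loc[g.index]
    if not (g["label"].to_numpy() == i["label"].to_numpy()).all():
        raise ValueError("labels disagree between prediction sets")
    return g, i


def ensemble_avg(preds_g: pd.DataFrame, preds_i: pd.DataFrame) -> pd.DataFrame:
    """Average the two channels' AD probabilities per subject."""
    g, i = _align(preds_g, preds_i)
    return pd.DataFrame({"subject_id": g.index,
                         "p_ad": (g["p_ad"].to_numpy() + i["p_ad"].to_numpy()) / 2.0,
                         "label": g["label"].to_numpy()})


def ensemble_vote(preds_g: pd.DataFrame, preds_i: pd.DataFrame,
                  threshold: float = 0.5) -> pd.DataFrame:
    """Conjunctive vote: AD only if both channels classify AD.

    Output probabilities are hard 0/1 votes; ROC/PRC areas are not
    meaningful for this ensemble.
    """
    g, i = _align(preds_g, preds_i)
    vote = ((g["p_ad"].to_numpy() >= threshold)
            & (i["p_ad"].to_numpy() >= threshold)).astype(float)
    return pd.DataFrame({"subject_id": g.index, "p_ad": vote,
                         "label": g["label"].to_numpy()})
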