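"""Binary-classification evaluation: confusion counts, SES/SPC/ACC/MCC,
ROC/AUC, single-feature AUC ranking, and balanced dataset partitioning.

PCT is the positive class throughout.  The metrics are

    SES = TP / (TP + FN)                      (sensitivity / recall)
    SPC = TN / (TN + FP)                      (specificity)
    ACC = (TP + TN) / (P + N)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with any 0/0 ratio reported as 0 (warning logged).  AUC is computed by the
trapezoid rule over the tie-grouped ROC curve, which equals the Mann-Whitney
concordance probability with ties counted 1/2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "PCT"
NEGATIVE_LABEL = "LNCT"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.p + self.n < 1:
            raise ValueError("at least one sample required")

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class Metrics:
    ses: float
    spc: float
    acc: float
    mcc: float


def confusion(truth: list[str], predicted: list[str]) -> ConfusionCounts:
    """Confusion counts with PCT as the positive class."""
    if len(truth) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(truth)} truth vs {len(predicted)} predicted"
        )
    valid = {POSITIVE_LABEL, NEGATIVE_LABEL}
    unknown = (set(truth) | set(predicted)) - valid
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}")
    tp = fp = tn = fn = 0
    for t, p in zip(truth, predicted):
        if t == POSITIVE_LABEL:
            if p == POSITIVE_LABEL:
                tp += 1
            else:
                fn += 1
        else:
            if p == POSITIVE_LABEL:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (0/0); reporting 0", name)
        return 0.0
    return num / den


def metrics(counts: ConfusionCounts) -> Metrics:
    """SES, SPC, ACC and MCC from confusion counts (AUC needs scores)."""
    ses = _ratio(counts.tp, counts.p, "SES")
    spc = _ratio(counts.tn, counts.n, "SPC")
    acc = (counts.tp + counts.tn) / (counts.p + counts.n)
    mcc_den = math.sqrt(
        float(counts.tp + counts.fp)
        * float(counts.tp + counts.fn)
        * float(counts.tn + counts.fp)
        * float(counts.tn + counts.fn)
    )
    mcc = _ratio(
        float(counts.tp) * counts.tn - float(counts.fp) * counts.fn, mcc_den, "MCC"
    )
    return Metrics(ses=ses, spc=spc, acc=acc, mcc=mcc)


def roc_auc(
    scores: list[float], truth: list[str]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) by threshold sweep and trapezoid AUC."""
    if len(scores) != len(truth):
        raise ValueError("scores and truth must have equal length")
    labels = set(truth)
    if labels != {POSITIVE_LABEL, NEGATIVE_LABEL}:
        raise ValueError(
            "ROC requires both PCT and LNCT in the truth labels; "
            f"got {sorted(labels)}"
        )
    y = np.array([1 if t == POSITIVE_LABEL else 0 for t in truth])
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def rank_features_by_auc(
    features: pd.DataFrame, truth: list[str]
) -> list[tuple[str, float]]:
    """Single-feature AUCs, orientation-corrected as max(AUC, 1-AUC).

    Each raw feature value is used directly as a classification score; the
    orientation correction reports discriminative power regardless of the
    direction of the class contrast.  Sorted descending, ties broken
    alphabetically.  Constant features get AUC 0.5.
    """
    ranked = []
    for name in features.columns:
        col = features[name].astype(float)
        if col.nunique() <= 1:
            auc = 0.5
        else:
            _, auc = roc_auc(col.tolist(), truth)
            auc = max(auc, 1.0 - auc)
        ranked.append((name, auc))
    ranked.sort(key=lambda item: (-item[1], item[0]))
    return ranked


def auc_correlation(aucs_a: list[float], aucs_b: list[float]) -> float:
    """Pearson correlation between two matched AUC vectors (length >= 3)."""
    if len(aucs_a) != len(aucs_b):
        raise ValueError("AUC vectors must have equal length")
    if len(aucs_a) < 3:
        raise ValueError("Pearson correlation requires at least 3 features")
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    return float(stats.pearsonr(a, b).statistic)


def balanced_split(
    pos: list[str],
    neg: list[str],
    n_train_per_class: int,
    n_test_per_class: int,
    seed: int,
) -> tuple[list[str], list[str], list[str]]:
    """Disjoint balanced train/test id sets, deterministic for a seed.

    Returns (train_ids, test_ids, remaining_ids); train and test each hold
    exactly ``n_train_per_class`` / ``n_test_per_class`` ids from both the
    positive and the negative list.
    """
    need = n_train_per_class + n_test_per_class
    for name, ids in (("positive", pos), ("negative", neg)):
        if len(ids) < need:
            raise ValueError(
                f"{name} class has {len(ids)} ids; {need} required "
                f"({n_train_per_class} train + {n_test_per_class} test)"
            )
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    remaining: list[str] = []
    for ids in (pos, neg):
        perm = [ids[i] for i in rng.permutation(len(ids))]
        train.extend(perm[:n_train_per_class])
        test.extend(perm[n_train_per_class:need])
        remaining.extend(perm[need:])
    return train, test, remaining


def write_metrics_tsv(results: dict[str, Metrics], path) -> None:
    """Write a named-row metrics table as TSV."""
    with open(path, "w") as fh:
        fh.write("name\tSES\tSPC\tACC\tMCC\n")
        for name, m in results.items():
            fh.write(f"{name}\t{m.ses:.6f}\t{m.spc:.6f}\t{m.acc:.6f}\t{m.mcc:.6f}\n")


def write_roc_tsv(points: list[tuple[float, float]], path) -> None:
    """Write ROC points as two-column (FPR, TPR) TSV."""
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in points:
            fh.write(f"{fpr:.6f}\t{tpr:.6f}\n")
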