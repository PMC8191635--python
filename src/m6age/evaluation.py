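"""Binary-classification metrics for site predictors.

ACC, SEN and SPE are reported as percentages (matching the field's
benchmark tables); MCC, F1 and AUC on their natural scales. AUC uses the
rank (Mann-Whitney) formulation with half credit for score ties, which the
trapezoidal area under the ROC curve reproduces exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """ACC/SEN/SPE in percent; MCC in [-1,1]; F1, AUC in [0,1]."""

    ACC: float
    MCC: float
    SEN: float
    SPE: float
    F1: float
    AUC: float
    confusion: ConfusionCounts
    roc: tuple[np.ndarray, np.ndarray] | None = None

    def to_dict(self) -> dict:
        return {
            "ACC": round(self.ACC, 2), "MCC": self.MCC,
            "SEN": round(self.SEN, 2), "SPE": round(self.SPE, 2),
            "F1": self.F1, "AUC": self.AUC,
            "TP": self.confusion.TP, "TN": self.confusion.TN,
            "FP": self.confusion.FP, "FN": self.confusion.FN,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def __str__(self) -> str:
        return (f"ACC={self.ACC:.2f}%  MCC={self.MCC:.4f}  "
                f"SEN={self.SEN:.2f}%  SPE={self.SPE:.2f}%  "
                f"F1={self.F1:.4f}  AUC={self.AUC:.4f}")


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def mcc_from_counts(c: ConfusionCounts) -> float:
    """Matthews correlation; 0 by convention when a denominator factor is 0."""
    denom = ((c.TP + c.FN) * (c.TN + c.FP) * (c.TP + c.FP) * (c.TN + c.FN))
    if denom == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / np.sqrt(float(denom))


def rank_auc(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    y_true = np.asarray(y_true).astype(int)
    y_score = np.asarray(y_score, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: y_true contains a single class")
    ranks = rankdata(y_score)  # average ranks handle ties with 0.5 credit
    return (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def roc_curve(y_true: np.ndarray, y_score: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """(FPR, TPR) at every distinct score threshold, from (0,0) to (1,1).

    The trapezoidal area under this curve equals the rank AUC.
    """
    y_true = np.asarray(y_true).astype(int)
    y_score = np.asarray(y_score, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: y_true contains a single class")
    order = np.argsort(-y_score, kind="stable")
    sorted_true = y_true[order]
    sorted_score = y_score[order]
    tps = np.cumsum(sorted_true)
    fps = np.cumsum(1 - sorted_true)
    # keep only the last index of each tied-score run
    distinct = np.r_[np.diff(sorted_score) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return fpr, tpr


def trapezoid_auc(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def compute_metrics(y_true, y_pred, y_score=None,
                    with_roc: bool = True) -> MetricsReport:
    """All six metrics from hard predictions and (optionally) scores.

    Without scores, AUC is computed from the hard predictions (a two-point
    ROC). A single-class y_true raises: MCC and AUC are undefined there.
    """
    y_true = np.asarray(y_true).astype(int)
    if y_true.min() == y_true.max():
        raise ValueError(
            "y_true contains a single class; MCC and AUC are undefined "
            "(confusion counts can still be obtained via confusion_counts)"
        )
    c = confusion_counts(y_true, y_pred)
    acc = 100.0 * (c.TP + c.TN) / c.total
    sen = 100.0 * c.TP / (c.TP + c.FN)
    spe = 100.0 * c.TN / (c.TN + c.FP)
    f1 = 2 * c.TP / (2 * c.TP + c.FP + c.FN) if (2 * c.TP + c.FP + c.FN) else 0.0
    mcc = mcc_from_counts(c)
    scores = np.asarray(y_pred, dtype=float) if y_score is None else y_score
    auc = rank_auc(y_true, scores)
    roc = roc_curve(y_true, scores) if with_roc else None
    return MetricsReport(ACC=acc, MCC=mcc, SEN=sen, SPE=spe, F1=f1, AUC=auc,
                         confusion=c, roc=roc)


def plot_roc(reports: dict[str, MetricsReport], path) -> None:
    """Save an ROC overlay plot (one curve per named report)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, rep in reports.items():
        if rep.roc is None:
            continue
        fpr, tpr = rep.roc
        ax.plot(fpr, tpr, label=f"{name} (AUC={rep.AUC:.4f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
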