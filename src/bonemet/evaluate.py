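"""Evaluation of predicted risk groups: survival curves and classification metrics.

Predicted high/low-risk groups are compared by Kaplan--Meier curves and the
two-group log-rank test on bone-metastasis-free time (all scored patients,
including those the 5-year rule could not label).  Threshold-free ranking
quality is measured by the Mann--Whitney AUC of the continuous gamma score;
thresholded predictions are summarised by accuracy and the Matthews
correlation coefficient, which stays informative on unbalanced cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.metrics import roc_auc_score

__all__ = [
    "SurvivalComparison",
    "MetricsReport",
    "km_logrank",
    "plot_km",
    "auc",
    "mcc",
    "confusion_counts",
    "metrics_report",
]


@dataclass
class SurvivalComparison:
    groups: pd.Series  # patient -> group label
    curves: dict  # group -> DataFrame(time, survival, at_risk)
    logrank_chi2: float
    logrank_p: float


@dataclass
class MetricsReport:
    auc: float
    accuracy: float
    mcc: float
    tp: int
    fp: int
    tn: int
    fn: int


def plot_km(comparison: "SurvivalComparison", path) -> None:
    """Optional Kaplan--Meier step plot of the group curves (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for group, curve in comparison.curves.items():
        ax.step(curve["time"], curve["survival"], where="post",
                label=f"group {group}")
    ax.set_xlabel("metastasis-free time (years)")
    ax.set_ylabel("metastasis-free survival")
    ax.set_ylim(0, 1.02)
    ax.legend(title=f"log-rank p = {comparison.logrank_p:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def km_logrank(times, events, groups) -> SurvivalComparison:
    """Kaplan--Meier curves per group plus the two-group log-rank test."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = pd.Series(groups)
    if (times < 0).any():
        raise ValueError("negative times")
    uniq = sorted(groups.unique())
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    masks = {g: (groups == g).to_numpy() for g in uniq}
    if any(m.sum() == 0 for m in masks.values()):
        raise ValueError("empty group")
    curves = {}
    for g, m in masks.items():
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], events[m])
        tl = kmf.survival_function_.index.to_numpy(dtype=float)
        curves[g] = pd.DataFrame(
            {
                "time": tl,
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": [int(kmf.event_table.loc[t, "at_risk"]) for t in tl],
            }
        )
    if events.sum() == 0:
        chi2, p = 0.0, 1.0  # no events anywhere: groups indistinguishable
    else:
        m0 = masks[uniq[0]]
        res = logrank_test(times[m0], times[~m0], events[m0], events[~m0])
        chi2, p = float(res.test_statistic), float(res.p_value)
    p = float(min(max(p, np.finfo(float).tiny), 1.0))  # keep p in (0, 1]
    return SurvivalComparison(
        groups=groups, curves=curves, logrank_chi2=chi2, logrank_p=p
    )


def auc(scores, labels) -> float:
    """Rank-based (Mann--Whitney) AUC of continuous scores, ties averaged."""
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; any zero denominator factor -> 0."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be non-negative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / float(np.sqrt(denom))


def confusion_counts(predicted, actual) -> tuple[int, int, int, int]:
    predicted = np.asarray(predicted, dtype=int)
    actual = np.asarray(actual, dtype=int)
    tp = int(np.sum((predicted == 1) & (actual == 1)))
    fp = int(np.sum((predicted == 1) & (actual == 0)))
    tn = int(np.sum((predicted == 0) & (actual == 0)))
    fn = int(np.sum((predicted == 0) & (actual == 1)))
    return tp, fp, tn, fn


def metrics_report(scores, predicted, actual) -> MetricsReport:
    """AUC from continuous scores plus confusion-matrix summaries."""
    tp, fp, tn, fn = confusion_counts(predicted, actual)
    n = tp + fp + tn + fn
    return MetricsReport(
        auc=auc(scores, actual),
        accuracy=(tp + tn) / n if n else float("nan"),
        mcc=mcc(tp, fp, tn, fn),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )
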