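"""Differential-expression refinement of driver candidates.

Driver candidates are reduced to the prognostic signature by a two-sample
t-test on *continuous* expression between high- and low-risk training
patients; genes below the p-value threshold (default 0.002) are retained,
sorted by ascending p.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import HIGH, LOW

__all__ = ["Signature", "t_test_select"]


@dataclass
class Signature:
    """Selected signature genes with their differential-expression p-values."""

    genes: list[str]
    p_values: list[float]
    threshold: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "p_value": self.p_values})


def t_test_select(
    expr: pd.DataFrame,
    labels: pd.DataFrame,
    candidates: Sequence[str],
    threshold: float = 0.002,
    equal_var: bool = False,
) -> Signature:
    """Select differentially expressed candidates by two-sided t-test.

    Welch's unequal-variance test by default (``equal_var=True`` for
    Student's).  Excluded patients are ignored.  A gene with zero variance
    in both classes gets p = 1 by convention.
    """
    lab = labels.set_index("patient_id")["label"]
    hi = [p for p in lab.index if lab[p] == HIGH and p in expr.columns]
    lo = [p for p in lab.index if lab[p] == LOW and p in expr.columns]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError("need >=2 training patients in each risk class")
    missing = [g for g in candidates if g not in expr.index]
    if missing:
        raise KeyError(f"candidate genes absent from expression: {missing[:5]}")
    cand = list(candidates)
    if not cand:
        return Signature(genes=[], p_values=[], threshold=threshold)
    a = expr.loc[cand, hi].to_numpy(dtype=float)
    b = expr.loc[cand, lo].to_numpy(dtype=float)
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant genes
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p[degenerate] = 1.0
    p[np.isnan(p)] = 1.0
    keep = [(pv, g) for g, pv in zip(cand, p) if pv < threshold]
    keep.sort()
    return Signature(
        genes=[g for _, g in keep],
        p_values=[pv for pv, _ in keep],
        threshold=threshold,
    )
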