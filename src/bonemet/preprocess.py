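"""Median binarisation, 5-year risk labelling and PPI candidate filtering.

These are the preparation steps shared by network inference and feature
selection: continuous expression is reduced to per-gene above/below-median
indicators, patients are labelled high-risk / low-risk / excluded by the
5-year metastasis rule, and the candidate (modulator, dependent) gene pairs
are restricted to edges of a protein--protein interaction scaffold.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HIGH",
    "LOW",
    "EXCLUDED",
    "binarize",
    "label_risk",
    "candidate_pairs",
    "read_expression",
    "read_clinical",
    "read_scaffold",
]

HIGH = 1
LOW = 0
EXCLUDED = -1


def binarize(expr: pd.DataFrame) -> pd.DataFrame:
    """Binarise expression by the per-gene median.

    A value strictly above the gene's median (over all retained patients)
    maps to 1; values at or below the median map to 0.  A constant gene
    therefore becomes an all-zero row.
    """
    if expr.shape[0] == 0 or expr.shape[1] < 2:
        raise ValueError("expression matrix must have >=1 gene and >=2 patients")
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    med = np.median(values, axis=1, keepdims=True)
    return pd.DataFrame(
        (values > med).astype(np.int8), index=expr.index, columns=expr.columns
    )


def label_risk(
    clinical: pd.DataFrame,
    threshold_years: float = 5.0,
    time_unit: str = "years",
) -> pd.DataFrame:
    """Apply the 5-year rule to metastasis-free time and event status.

    A patient with the event within ``threshold_years`` is high-risk (1); a
    patient event-free beyond the threshold is low-risk (0); a patient
    censored at or before the threshold is excluded (-1) — kept in the table
    with an explicit marker, never dropped.
    """
    if time_unit == "years":
        time = clinical["time"].to_numpy(dtype=float)
    elif time_unit == "months":
        time = clinical["time"].to_numpy(dtype=float) / 12.0
    else:
        raise ValueError(f"unknown time_unit {time_unit!r}")
    if (time < 0).any():
        raise ValueError("negative metastasis-free time")
    event = clinical["event"].to_numpy(dtype=int)
    label = np.full(len(time), EXCLUDED, dtype=np.int8)
    label[(event == 1) & (time <= threshold_years)] = HIGH
    label[time > threshold_years] = LOW
    out = clinical.copy()
    out["time"] = time
    out["label"] = label
    return out


def candidate_pairs(
    genes: Iterable[str], scaffold: Sequence[tuple[str, str]]
) -> list[tuple[str, str]]:
    """Ordered candidate dependency pairs from an undirected scaffold.

    Every scaffold edge {A, B} whose two genes are both measured yields the
    two ordered candidates (A modulates B) and (B modulates A); edges touching
    unmeasured genes and self-loops are dropped.  Order is deterministic.
    """
    measured = set(genes)
    if not measured.intersection({g for e in scaffold for g in e}):
        raise ValueError("no scaffold gene is present in the expression matrix")
    seen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    for a, b in scaffold:
        if a == b or a not in measured or b not in measured:
            continue
        for pair in ((a, b), (b, a)):
            if pair not in seen:
                seen.add(pair)
                out.append(pair)
    out.sort()
    return out


def read_expression(path) -> pd.DataFrame:
    expr = pd.read_csv(path, sep="\t", index_col=0)
    if expr.index.duplicated().any() or expr.columns.duplicated().any():
        raise ValueError("duplicate gene or patient identifiers")
    return expr


def read_clinical(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"patient_id": str})


def read_scaffold(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [tuple(r) for r in df.iloc[:, :2].itertuples(index=False)]
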