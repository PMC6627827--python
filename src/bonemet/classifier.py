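"""Nearest-centroid risk classifier over the signature genes.

With n+ high-risk and n- low-risk training patients, the model consists of
the class mean expression vectors c+ and c- over the signature genes, their
midpoint c = (c+ + c-)/2 and the weight vector w = c+ - c-.  A sample s is
scored by the linear discriminant

    gamma = <s - c, w>

and predicted high-risk iff gamma > 0 (gamma = 0 falls to the low-risk
class).  Algebraically gamma = (||s - c-||^2 - ||s - c+||^2) / 2, i.e. the
sign of gamma reproduces nearest-centroid assignment by Euclidean distance;
gamma itself serves as the continuous risk score for ROC analysis.

Expression is not standardised by default; an optional z-score flag (using
training-set statistics) is provided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import HIGH, LOW

__all__ = ["CentroidModel", "PredictionScore", "fit", "score", "predict"]


@dataclass
class CentroidModel:
    genes: list[str]
    c_plus: np.ndarray
    c_minus: np.ndarray
    c_mid: np.ndarray
    w: np.ndarray
    n_plus: int
    n_minus: int
    standardize: bool = False
    mu: np.ndarray | None = None
    sd: np.ndarray | None = None

    def to_json(self, path) -> None:
        obj = {
            "genes": self.genes,
            "c_plus": self.c_plus.tolist(),
            "c_minus": self.c_minus.tolist(),
            "n_plus": self.n_plus,
            "n_minus": self.n_minus,
            "standardize": self.standardize,
            "mu": None if self.mu is None else self.mu.tolist(),
            "sd": None if self.sd is None else self.sd.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CentroidModel":
        with open(path) as fh:
            obj = json.load(fh)
        c_plus = np.asarray(obj["c_plus"], dtype=float)
        c_minus = np.asarray(obj["c_minus"], dtype=float)
        return cls(
            genes=list(obj["genes"]),
            c_plus=c_plus,
            c_minus=c_minus,
            c_mid=(c_plus + c_minus) / 2.0,
            w=c_plus - c_minus,
            n_plus=int(obj["n_plus"]),
            n_minus=int(obj["n_minus"]),
            standardize=bool(obj.get("standardize", False)),
            mu=None if obj.get("mu") is None else np.asarray(obj["mu"], float),
            sd=None if obj.get("sd") is None else np.asarray(obj["sd"], float),
        )


@dataclass
class PredictionScore:
    patient_id: str
    gamma: float
    predicted_label: int


def _signature_matrix(expr: pd.DataFrame, genes: Sequence[str]) -> np.ndarray:
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"signature gene(s) absent from expression: {missing[:5]}")
    return expr.loc[list(genes)].to_numpy(dtype=float)


def fit(
    expr: pd.DataFrame,
    labels: pd.DataFrame,
    signature: Sequence[str],
    standardize: bool = False,
) -> CentroidModel:
    """Fit per-class mean centroids over the signature genes."""
    genes = list(signature)
    if not genes:
        raise ValueError("empty signature")
    lab = labels.set_index("patient_id")["label"]
    hi = [p for p in lab.index if lab[p] == HIGH and p in expr.columns]
    lo = [p for p in lab.index if lab[p] == LOW and p in expr.columns]
    if not hi or not lo:
        raise ValueError("each risk class needs at least one training patient")
    x = _signature_matrix(expr, genes)
    cols = {p: j for j, p in enumerate(expr.columns)}
    mu = sd = None
    if standardize:
        train = x[:, [cols[p] for p in hi + lo]]
        mu = train.mean(axis=1)
        sd = train.std(axis=1, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        x = (x - mu[:, None]) / sd[:, None]
    c_plus = x[:, [cols[p] for p in hi]].mean(axis=1)
    c_minus = x[:, [cols[p] for p in lo]].mean(axis=1)
    return CentroidModel(
        genes=genes,
        c_plus=c_plus,
        c_minus=c_minus,
        c_mid=(c_plus + c_minus) / 2.0,
        w=c_plus - c_minus,
        n_plus=len(hi),
        n_minus=len(lo),
        standardize=standardize,
        mu=mu,
        sd=sd,
    )


def score(model: CentroidModel, sample: np.ndarray, patient_id: str = "") -> PredictionScore:
    """Score one sample vector (ordered as model.genes)."""
    s = np.asarray(sample, dtype=float)
    if s.shape != model.c_mid.shape:
        raise ValueError("sample does not cover the signature genes")
    if model.standardize:
        s = (s - model.mu) / model.sd
    gamma = float(np.dot(s - model.c_mid, model.w))
    return PredictionScore(
        patient_id=patient_id, gamma=gamma, predicted_label=int(gamma > 0)
    )


def predict(model: CentroidModel, expr: pd.DataFrame) -> pd.DataFrame:
    """Score every patient column; returns patient_id, gamma, predicted_label."""
    x = _signature_matrix(expr, model.genes)
    if model.standardize:
        x = (x - model.mu[:, None]) / model.sd[:, None]
    gam = (x - model.c_mid[:, None]).T @ model.w
    return pd.DataFrame(
        {
            "patient_id": list(expr.columns),
            "gamma": gam,
            "predicted_label": (gam > 0).astype(int),
        }
    )
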