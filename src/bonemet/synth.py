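"""Synthetic cohorts with planted conditional gene--risk dependencies.

The generator emulates the data model of a breast-cancer bone-metastasis
cohort: a gene expression matrix (genes x patients), a clinical table with
metastasis-free time and event status, and an undirected protein--protein
interaction (PPI) scaffold.  A configurable number of scaffold edges carry a
planted *gene dependency*: the association between a dependent gene's
expression and the binary 5-year metastasis-risk label exists only within one
expression stratum (high or low) of a modulator gene.  Everything is seeded
and byte-reproducible.

Generative model
----------------
Each patient first receives a latent risk label ``R ~ Bernoulli(baseline_risk)``.
Expression of every gene is a balanced two-component Gaussian mixture
(components at -1 and +1), so the per-gene median split recovers the latent
component with high probability.  For a planted pair (modulator B, dependent
A) expression is drawn conditional on ``R``:

* within the *active* stratum of B (the high or low mixture component, which
  the median split recovers), the dependent's component is drawn so that
  P(R | A high) - P(R | A low) equals ``effect_size`` exactly, centred on the
  baseline (levels baseline +- effect_size/2); in the inactive stratum A is
  independent of risk;
* the modulator's *continuous* value is shifted by ``modulator_shift`` for
  high-risk patients.  Because expression is bimodal, this mean shift is
  nearly invisible to the median binarisation (so it contributes almost no
  dependency signal of its own) but makes the modulator differentially
  expressed on the continuous scale, as a driver biomarker must be.

Drawing genes conditional on the shared risk label (rather than risk
conditional on genes) keeps cohort risk prevalence at ``baseline_risk``
regardless of how many pairs are planted, while preserving each pair's full
conditional contrast.  Centring the dependent's contrast keeps the planted
dependency *directed*: the collider association that the reverse orientation
(A as modulator) could pick up cancels to the curvature of the binary
entropy, an order of magnitude below the forward signal.

Survival times are sampled conditional on the latent label so that the
5-year labelling rule recovers it exactly: high-risk patients experience the
event within 5 years (truncated exponential); low-risk patients are
event-free past 5 years, with a ``censor_rate`` fraction censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "PlantedTruth",
    "ConfigError",
    "generate_scaffold",
    "generate_cohort",
    "split_cohort",
    "write_cohort",
]

#: years after which an event-free patient is called low-risk
RISK_HORIZON_YEARS = 5.0

#: Gaussian-mixture component means / sd shared by all genes
_MIX_MEANS = (-1.0, 1.0)
_MIX_SD = 0.3


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic study.

    Defaults describe the cohorts used throughout the test-suite: a few
    hundred patients on a preferential-attachment PPI scaffold with a
    moderate planted effect and ~30% five-year bone-metastasis prevalence.
    """

    n_genes: int = 200
    n_patients: int = 600
    scaffold_model: str = "barabasi_albert"  # or "erdos_renyi"
    scaffold_param: float = 2
    n_planted_pairs: int = 10
    effect_size: float = 0.5
    modulator_shift: float | None = None  # continuous shift; default 0.8*effect
    diffexpr_frac: float = 0.3  # fraction of genes differentially expressed
    diffexpr_shift: float = 0.4  # their continuous shift magnitude (random sign)
    active_stratum: str = "high"  # stratum of the modulator carrying the signal
    baseline_risk: float = 0.35
    followup_scale: float = 5.0  # mean extra follow-up (years) past the horizon
    censor_rate: float = 0.3
    split_fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 4:
            raise ConfigError("n_genes must be >= 4")
        if self.n_patients < 2:
            raise ConfigError("n_patients must be >= 2")
        if self.scaffold_model not in ("barabasi_albert", "erdos_renyi"):
            raise ConfigError(f"unknown scaffold_model {self.scaffold_model!r}")
        if self.active_stratum not in ("high", "low"):
            raise ConfigError("active_stratum must be 'high' or 'low'")
        for name in ("effect_size", "baseline_risk", "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.baseline_risk + self.effect_size > 1.0:
            raise ConfigError("baseline_risk + effect_size must not exceed 1")
        if self.n_planted_pairs > 0 and self.effect_size > 0 and (
            self.effect_size > 2.0 * self.baseline_risk
        ):
            raise ConfigError(
                "effect_size must not exceed 2*baseline_risk for a planted "
                "contrast to be realisable"
            )
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ConfigError("split_fractions must sum to 1")
        if any(f < 0 for f in self.split_fractions):
            raise ConfigError("split_fractions must be non-negative")
        if self.followup_scale <= 0:
            raise ConfigError("followup_scale must be positive")
        if self.modulator_shift is not None and self.modulator_shift < 0:
            raise ConfigError("modulator_shift must be non-negative")
        if not 0.0 <= self.diffexpr_frac <= 1.0:
            raise ConfigError("diffexpr_frac must lie in [0, 1]")
        if self.diffexpr_shift < 0:
            raise ConfigError("diffexpr_shift must be non-negative")

    @property
    def resolved_modulator_shift(self) -> float:
        if self.modulator_shift is not None:
            return self.modulator_shift
        return 0.8 * self.effect_size


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth planted dependencies: directed (modulator, dependent) pairs."""

    pairs: tuple[tuple[str, str], ...]
    effect_sizes: tuple[float, ...] = field(default=())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "modulator": [m for m, _ in self.pairs],
                "dependent": [d for _, d in self.pairs],
                "effect_size": list(self.effect_sizes),
            }
        )


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def generate_scaffold(cfg: SynthConfig) -> list[tuple[str, str]]:
    """Generate the undirected PPI scaffold as a sorted edge list.

    ``barabasi_albert`` (preferential attachment, integer attachment count)
    yields the heavy-tailed degree structure typical of PPI references;
    ``erdos_renyi`` (edge probability) gives a homogeneous control.
    """
    names = _gene_names(cfg.n_genes)
    if cfg.scaffold_model == "barabasi_albert":
        m = int(cfg.scaffold_param)
        if m != cfg.scaffold_param or not 1 <= m < cfg.n_genes:
            raise ConfigError(
                f"barabasi_albert attachment count must be an integer in "
                f"[1, n_genes), got {cfg.scaffold_param}"
            )
        g = nx.barabasi_albert_graph(cfg.n_genes, m, seed=cfg.seed)
    else:
        p = float(cfg.scaffold_param)
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"erdos_renyi edge probability must be in [0,1], got {p}")
        g = nx.gnp_random_graph(cfg.n_genes, p, seed=cfg.seed)
    edges = sorted(
        (names[min(u, v)], names[max(u, v)]) for u, v in g.edges() if u != v
    )
    return edges


def _binary_mi(p: float, q: float) -> float:
    """MI (bits) of a balanced binary split with class-1 rates p and q."""

    def h(x: float) -> float:
        if x <= 0.0 or x >= 1.0:
            return 0.0
        return -(x * np.log2(x) + (1 - x) * np.log2(1 - x))

    return h((p + q) / 2.0) - 0.5 * (h(p) + h(q))


def _balanced_risk_levels(b: float, e: float) -> tuple[float, float]:
    """Risk levels (q1, q0) with q1 - q0 = e and MI(q1, b) = MI(q0, b).

    Centred on the baseline in the mutual-information sense rather than
    arithmetically, so that conditioning on the dependent gene leaves no
    first-order association between the modulator's component and risk.
    """
    if e == 0.0 or b <= 0.0 or b >= 1.0:
        return b + e / 2.0, b - e / 2.0
    from scipy.optimize import brentq

    def f(q0: float) -> float:
        return _binary_mi(q0 + e, b) - _binary_mi(q0, b)

    lo, hi = 1e-9, 1.0 - e - 1e-9
    if hi <= lo or f(lo) * f(hi) > 0:
        raise ConfigError("effect_size/baseline_risk combination is infeasible")
    q0 = float(brentq(f, lo, hi, xtol=1e-12))
    return q0 + e, q0


def _conditional_component(
    rng: np.random.Generator,
    risk: np.ndarray,
    mask: np.ndarray,
    p_active_given_r1: float,
    p_active_given_r0: float,
) -> np.ndarray:
    """Draw a binary component for patients in ``mask`` conditional on risk."""
    n = risk.size
    comp = np.zeros(n, dtype=np.int8)
    u = rng.random(n)  # one uniform per patient keeps draws order-stable
    p = np.where(risk == 1, p_active_given_r1, p_active_given_r0)
    comp[mask] = (u[mask] < p[mask]).astype(np.int8)
    return comp


def generate_cohort(
    cfg: SynthConfig, scaffold: Sequence[tuple[str, str]]
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Generate expression, clinical table and planted truth for one cohort.

    Returns
    -------
    expr : DataFrame, genes x patients, continuous values.
    clinical : DataFrame with columns patient_id, time (years), event {0,1}.
    truth : PlantedTruth with the planted (modulator, dependent) pairs.
    """
    if cfg.n_planted_pairs > len(scaffold):
        raise ConfigError(
            f"n_planted_pairs={cfg.n_planted_pairs} exceeds scaffold size "
            f"{len(scaffold)}"
        )
    rng = np.random.default_rng([cfg.seed, 1])
    genes = _gene_names(cfg.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    n = cfg.n_patients
    patients = [f"P{i + 1:05d}" for i in range(n)]

    # latent 5-year risk label, shared by all planted pairs
    b = cfg.baseline_risk
    risk = (rng.random(n) < b).astype(np.int8)

    # choose planted edges with pairwise-disjoint endpoints, random orientation
    order = rng.permutation(len(scaffold))
    used: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for idx in order:
        u, v = scaffold[idx]
        if u in used or v in used:
            continue
        if rng.random() < 0.5:
            u, v = v, u
        pairs.append((u, v))  # (modulator, dependent)
        used.update((u, v))
        if len(pairs) == cfg.n_planted_pairs:
            break
    if len(pairs) < cfg.n_planted_pairs:
        raise ConfigError(
            "scaffold does not contain enough vertex-disjoint edges for "
            f"n_planted_pairs={cfg.n_planted_pairs}"
        )

    e = cfg.effect_size
    # Dependent component | risk within the active stratum.  The two risk
    # levels q1 = P(R | A high), q0 = P(R | A low) have contrast exactly e and
    # are balanced so that MI(q1, b) = MI(q0, b): the collider association the
    # reverse orientation could exploit cancels identically, keeping the
    # planted dependency directed.
    q1, q0 = _balanced_risk_levels(b, e)
    m_act = (q1 + q0) / 2.0  # P(risk | active stratum); P(A high) = 1/2
    if 0.0 < m_act < 1.0:
        pA1 = 0.5 * q1 / m_act  # P(A high | R=1)
        pA0 = 0.5 * (1.0 - q1) / (1.0 - m_act)  # P(A high | R=0)
    else:
        pA1 = pA0 = 0.5
    if not (0.0 <= pA0 <= 1.0 and 0.0 <= pA1 <= 1.0):
        raise ConfigError("effect_size/baseline_risk combination is infeasible")

    # mixture components: independent Bernoulli(1/2) for every gene by default
    comp = rng.integers(0, 2, size=(cfg.n_genes, n), dtype=np.int8)
    modulators = []
    for mod, dep in pairs:
        comp_b = comp[gene_index[mod]]  # independent of risk by construction
        active = comp_b == (1 if cfg.active_stratum == "high" else 0)
        comp_a = np.where(
            active,
            _conditional_component(rng, risk, active, pA1, pA0),
            rng.integers(0, 2, size=n, dtype=np.int8),
        ).astype(np.int8)
        comp[gene_index[dep]] = comp_a
        modulators.append(mod)

    means = np.asarray(_MIX_MEANS)[comp]
    values = rng.normal(means, _MIX_SD)
    shift = cfg.resolved_modulator_shift
    for mod in modulators:
        values[gene_index[mod]] += shift * risk
    # widespread differential expression downstream of the phenotype: a random
    # fraction of non-pair genes gets a continuous risk-associated mean shift
    # (random sign), emulating the broad transcriptional differences between
    # metastatic and non-metastatic tumours.  The shift is nearly invisible to
    # median binarisation (bimodal expression), so it leaves the dependency
    # network unchanged while making realistic candidates for the t-test stage.
    pair_genes = used
    free = [i for i, g in enumerate(genes) if g not in pair_genes]
    n_de = int(round(cfg.diffexpr_frac * len(free)))
    de_idx = rng.choice(len(free), size=n_de, replace=False) if n_de else []
    signs = rng.choice([-1.0, 1.0], size=n_de)
    for j, s in zip(de_idx, signs):
        values[free[j]] += s * cfg.diffexpr_shift * risk
    expr = pd.DataFrame(values, index=genes, columns=patients)

    # survival consistent with the latent label under the 5-year rule
    horizon = RISK_HORIZON_YEARS
    scale_hi = cfg.followup_scale / 3.0
    u = rng.random(n)
    t_hi = -scale_hi * np.log1p(-u * (1.0 - np.exp(-horizon / scale_hi)))
    t_lo = horizon + rng.exponential(cfg.followup_scale, size=n)
    censored_lo = rng.random(n) < cfg.censor_rate
    time = np.where(risk == 1, t_hi, t_lo)
    event = np.where(risk == 1, 1, np.where(censored_lo, 0, 1)).astype(np.int8)
    clinical = pd.DataFrame(
        {"patient_id": patients, "time": time, "event": event}
    )

    truth = PlantedTruth(
        pairs=tuple(pairs), effect_sizes=tuple([e] * len(pairs))
    )
    return expr, clinical, truth


def split_cohort(
    clinical: pd.DataFrame,
    fractions: tuple[float, float, float],
    seed: int,
) -> tuple[list[str], list[str], list[str]]:
    """Partition patient ids into train / test / independent sets.

    The partition is disjoint and exhaustive; cut points are the rounded
    cumulative fractions, so e.g. 855 patients at fractions
    (380/855, 189/855, 286/855) split exactly 380/189/286.
    """
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f < 0 for f in fractions):
        raise ConfigError("fractions must be non-negative and sum to 1")
    ids = list(clinical["patient_id"])
    n = len(ids)
    if n == 0:
        raise ConfigError("empty cohort")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    c1 = int(round(fractions[0] * n))
    c2 = int(round((fractions[0] + fractions[1]) * n))
    train = [ids[i] for i in perm[:c1]]
    test = [ids[i] for i in perm[c1:c2]]
    indep = [ids[i] for i in perm[c2:]]
    for frac, part in zip(fractions, (train, test, indep)):
        if frac > 0 and not part:
            raise ConfigError("a requested split is empty")
    return train, test, indep


def write_cohort(
    outdir,
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    scaffold: Sequence[tuple[str, str]],
    truth: PlantedTruth,
) -> None:
    """Write the cohort as TSV files in the layout downstream stages read."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    expr.to_csv(out / "expression.tsv", sep="\t", index_label="gene")
    clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    pd.DataFrame(scaffold, columns=["gene_a", "gene_b"]).to_csv(
        out / "scaffold.tsv", sep="\t", index=False
    )
    truth.as_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
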