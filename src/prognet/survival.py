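"""Survival evaluation of selected modules.

Patients are scored by the signed sum of module statistics (positive-
coefficient modules add, negative-coefficient modules subtract), split into
equal-sized high- and low-risk groups at the median rank, and compared by
the two-sample log-rank test and the high-vs-low hazard ratio.  The
discrimination score (Dscore) aggregates log-rank p-values across data
sets as −Σ log10(p_i), so larger is better and values add over cohorts.
A random-gene-set permutation test asks whether the selected modules beat
equally sized random gene sets on the same cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test

from .io import ClinicalTable, ExpressionMatrix
from .mcode import Module
from .prognostic import PrognosticProfile, fit_cox_univariate, module_statistic

logger = logging.getLogger(__name__)

__all__ = [
    "RiskAssessment",
    "risk_scores",
    "split_and_test",
    "dscore",
    "RandomSetTest",
    "random_geneset_test",
    "plot_km",
]


def risk_scores(
    expr: ExpressionMatrix,
    selected_modules: Sequence[Module],
    profiles: Sequence[PrognosticProfile],
) -> pd.Series:
    """Per-sample risk score: Σ s_i (positive-coefficient modules) − Σ s_j
    (negative-coefficient modules).

    A module whose mean Cox coefficient is exactly 0 is treated as positive
    (logged); the sign comes from the training-set resampling profile, so
    scores for new cohorts need no refitting.
    """
    if not selected_modules:
        raise ValueError("selected module set is empty")
    coef = {p.module_id: p.mean_coefficient for p in profiles}
    total = pd.Series(0.0, index=expr.sample_ids)
    for module in selected_modules:
        if module.module_id not in coef:
            raise ValueError(f"no profile for module {module.module_id}")
        c = coef[module.module_id]
        if not np.isfinite(c):
            raise ValueError(f"module {module.module_id} has no valid coefficient")
        if c == 0:
            logger.info("module %d coefficient is 0; treated as positive",
                        module.module_id)
        sign = 1.0 if c >= 0 else -1.0
        total = total + sign * module_statistic(expr, module).values
    total.name = "risk_score"
    return total


@dataclass
class RiskAssessment:
    """Two-group risk stratification and its survival test results."""

    risk_score: pd.Series
    group: pd.Series  # "high" | "low" per sample
    logrank_p: float
    hazard_ratio: float
    n_high: int
    n_low: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"risk_score": self.risk_score, "group": self.group})


def split_and_test(scores: pd.Series, clinical: ClinicalTable) -> RiskAssessment:
    """Median split of risk scores plus log-rank test and hazard ratio.

    Samples are sorted by score descending (ties by sample ID); the top
    half is the high-risk group, with the extra sample on odd n going to
    the low-risk group.  The hazard ratio is from a univariate Cox fit on
    the high-vs-low indicator.
    """
    shared = [s for s in scores.index if s in set(clinical.sample_ids)]
    if len(shared) < 4:
        raise ValueError("need at least 4 samples with clinical data")
    s = scores.loc[shared]
    if s.nunique() == 1:
        raise ValueError("all risk scores identical; cannot stratify")
    order = sorted(shared, key=lambda sid: (-s.loc[sid], sid))
    n_high = len(order) // 2
    high = order[:n_high]
    low = order[n_high:]
    group = pd.Series("low", index=shared, name="group")
    group.loc[high] = "high"
    time = clinical.time.loc[shared]
    event = clinical.event.loc[shared]
    res = logrank_test(
        time.loc[high], time.loc[low],
        event_observed_A=event.loc[high], event_observed_B=event.loc[low],
    )
    indicator = (group == "high").astype(float).to_numpy()
    fit = fit_cox_univariate(indicator, time.to_numpy(), event.to_numpy())
    hr = float(np.exp(fit.coefficient)) if fit.converged else float("nan")
    if not fit.converged:
        logger.warning("hazard-ratio Cox fit did not converge")
    return RiskAssessment(
        risk_score=s,
        group=group,
        logrank_p=float(res.p_value),
        hazard_ratio=hr,
        n_high=len(high),
        n_low=len(low),
    )


def dscore(p_values: Sequence[float]) -> float:
    """Discrimination score: −Σ log10(p_i) over per-dataset log-rank p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return float(-np.sum(np.log10(p)))


@dataclass
class RandomSetTest:
    """Random-gene-set permutation test of an observed Dscore."""

    p_value: float
    observed_dscore: float
    null_dscores: np.ndarray = field(repr=False)
    gene_count: int = 0


def random_geneset_test(
    datasets: Sequence[tuple[ExpressionMatrix, ClinicalTable]],
    observed_dscore: float,
    gene_count: int,
    n_sets: int = 1000,
    seed: int | None = None,
) -> RandomSetTest:
    """Does the selected-module Dscore beat random gene sets of equal size?

    Each of ``n_sets`` random gene sets (drawn from the genes shared by all
    data sets) is scored as a single positive module — its per-sample mean
    expression is the risk score — then split and log-rank tested per data
    set, and its Dscore computed.  p = (1 + #{null ≥ observed}) /
    (n_sets + 1).
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    pool = set(datasets[0][0].gene_ids)
    for expr, _ in datasets[1:]:
        pool &= set(expr.gene_ids)
    pool = sorted(pool)
    if gene_count > len(pool):
        raise ValueError("gene_count exceeds the shared gene pool")
    rng = np.random.default_rng(seed)
    null = np.empty(n_sets)
    for i in range(n_sets):
        genes = list(rng.choice(pool, size=gene_count, replace=False))
        pvals = []
        for expr, clinical in datasets:
            score = expr.data.loc[genes].mean(axis=0)
            pvals.append(split_and_test(score, clinical).logrank_p)
        null[i] = dscore(pvals)
    p = (1.0 + int((null >= observed_dscore).sum())) / (n_sets + 1.0)
    return RandomSetTest(
        p_value=p,
        observed_dscore=observed_dscore,
        null_dscores=null,
        gene_count=gene_count,
    )


def plot_km(assessment: RiskAssessment, clinical: ClinicalTable, ax=None):
    """Kaplan–Meier curves of the two risk groups, log-rank p annotated.

    Requires matplotlib (optional dependency)."""
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter

    if ax is None:
        _, ax = plt.subplots()
    for name in ("high", "low"):
        ids = assessment.group.index[assessment.group == name]
        kmf = KaplanMeierFitter()
        kmf.fit(clinical.time.loc[ids], clinical.event.loc[ids],
                label=f"{name} risk (n={len(ids)})")
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_title(f"log-rank p = {assessment.logrank_p:.3g}, "
                 f"HR = {assessment.hazard_ratio:.2f}")
    return ax
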