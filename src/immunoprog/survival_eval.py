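"""Survival evaluation: Kaplan-Meier, log-rank, C-index, Cox reporting, FDR.

Conventions follow the risk-score orientation of the prognostic model: a
higher score means higher modeled relapse risk, so Harrell's concordance
counts a pair as concordant when the patient with the earlier event carried
the higher score. Kaplan-Meier confidence intervals use the log-log
(exponential Greenwood) transform by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .prognostic_model import CoxFitResult, cox_fit

logger = logging.getLogger("immunoprog")

__all__ = [
    "KMCurve",
    "kaplan_meier",
    "survival_at",
    "log_rank",
    "ConcordanceResult",
    "harrell_c",
    "CoxReport",
    "cox_report",
    "bh_adjust",
]


@dataclass
class KMCurve:
    """Product-limit estimate with Greenwood-based confidence band."""

    times: np.ndarray  # observed event times
    survival: np.ndarray  # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray
    ci_lower: np.ndarray | None
    ci_upper: np.ndarray | None
    kmf: KaplanMeierFitter


def kaplan_meier(time, event, alpha: float = 0.05, ci: str = "log-log") -> KMCurve:
    """Kaplan-Meier estimate of the survival function.

    ``ci`` selects the confidence-interval flavor: "log-log" (exponential
    Greenwood, the default) or "plain" (linear Greenwood). With no events
    the curve is constant 1 and the CI undefined (warned).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if np.any(t <= 0):
        raise ValueError("times must be > 0")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(t, e)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    times = event_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy()
    n_at_risk = event_rows["at_risk"].to_numpy(dtype=int)
    n_events = event_rows["observed"].to_numpy(dtype=int)
    if e.sum() == 0:
        warnings.warn("no events: survival constant 1, confidence interval undefined")
        return KMCurve(times, surv, n_at_risk, n_events, None, None, kmf)
    if ci == "log-log":
        band = kmf.confidence_interval_survival_function_
        lower = band.iloc[:, 0]
        upper = band.iloc[:, 1]
        lo = np.array([lower[lower.index <= x].iloc[-1] for x in times])
        hi = np.array([upper[upper.index <= x].iloc[-1] for x in times])
    elif ci == "plain":
        # linear Greenwood: S +/- z * SE(S)
        z = stats.norm.ppf(1 - alpha / 2)
        var_terms = event_rows["observed"] / (
            event_rows["at_risk"] * (event_rows["at_risk"] - event_rows["observed"])
        )
        cum = np.cumsum(var_terms.to_numpy())
        se = surv * np.sqrt(cum)
        lo = np.clip(surv - z * se, 0, 1)
        hi = np.clip(surv + z * se, 0, 1)
    else:
        raise ValueError(f"unknown ci flavor {ci!r}")
    return KMCurve(times, surv, n_at_risk, n_events, lo, hi, kmf)


def survival_at(curve: KMCurve, t: float = 5.0) -> tuple[float, tuple[float, float] | None]:
    """Survival rate and 95% CI at horizon ``t`` (step value at the last
    event time <= t)."""
    rate = float(curve.kmf.survival_function_at_times(t).iloc[0])
    if curve.ci_lower is None:
        return rate, None
    mask = curve.times <= t
    if not mask.any():
        return rate, None  # before the first event the band is degenerate
    idx = np.nonzero(mask)[0][-1]
    return rate, (float(curve.ci_lower[idx]), float(curve.ci_upper[idx]))


def log_rank(groups, time, event) -> tuple[float, float]:
    """Log-rank chi-square test across 2 or more groups."""
    g = pd.Series(groups).reset_index(drop=True)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    labels = g.unique()
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    counts = g.value_counts()
    if (counts < 1).any():
        raise ValueError("every group needs at least 1 subject")
    if len(labels) == 2:
        a = g == labels[0]
        res = logrank_test(t[a], t[~a], e[a], e[~a])
    else:
        res = multivariate_logrank_test(t, g.to_numpy(), e)
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class ConcordanceResult:
    c_index: float
    concordant: float
    discordant: float
    tied_pairs: float
    comparable_pairs: float


def harrell_c(score, time, event) -> ConcordanceResult:
    """Harrell's concordance index, higher score = higher risk.

    A pair is comparable when the earlier time is an event (or, at a tied
    time, one patient has the event and the other is censored). Concordant:
    the earlier-event patient has the higher score; score ties count 0.5.
    """
    s = np.asarray(score, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    n = s.size
    # comparable[i, j]: i is the reference event preceding j
    ti, tj = t[:, None], t[None, :]
    ei, ej = e[:, None], e[None, :]
    comparable = ((ti < tj) & (ei == 1)) | ((ti == tj) & (ei == 1) & (ej == 0))
    np.fill_diagonal(comparable, False)
    si, sj = s[:, None], s[None, :]
    conc = float(np.sum(comparable & (si > sj)))
    disc = float(np.sum(comparable & (si < sj)))
    tied = float(np.sum(comparable & (si == sj)))
    total = conc + disc + tied
    if total == 0:
        warnings.warn("no comparable pairs: concordance undefined")
        return ConcordanceResult(float("nan"), 0.0, 0.0, 0.0, 0.0)
    return ConcordanceResult((conc + 0.5 * tied) / total, conc, disc, tied, total)


@dataclass(frozen=True)
class CoxReport:
    variable: str
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n: int
    adjusters: tuple[str, ...] = ()


def cox_report(
    features: pd.DataFrame,
    variable: str,
    time,
    event,
    adjusters: Sequence[str] = (),
    standardize: bool | None = None,
) -> CoxReport:
    """HR with 95% CI and a likelihood-ratio p-value for one variable.

    Univariable (no adjusters): LRT against the null Cox model.
    Multivariable: LRT between the adjusted models with and without the
    variable. Continuous variables (more than two distinct values, or
    ``standardize=True``) are centered and scaled before the HR is
    computed. Complete cases over variable + adjusters only.
    """
    cols = [variable, *adjusters]
    if variable in adjusters:
        raise ValueError(f"{variable} appears among its own adjusters")
    keep = features[cols].notna().all(axis=1)
    X = features.loc[keep, cols].astype(float).copy()
    t = np.asarray(time, dtype=float)[np.asarray(keep)]
    e = np.asarray(event, dtype=int)[np.asarray(keep)]
    if standardize is None:
        standardize = X[variable].nunique() > 2
    if standardize:
        X[variable] = (X[variable] - X[variable].mean()) / X[variable].std(ddof=1)
    full = cox_fit(X, t, e)
    if not full.converged:
        raise RuntimeError(f"Cox fit for {cols} did not converge")
    reduced = cox_fit(X[list(adjusters)], t, e)
    lrt = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    p = float(stats.chi2.sf(lrt, df=1))
    coef = float(full.coefficients[variable])
    se = float(full.standard_errors[variable])
    z = stats.norm.ppf(0.975)
    return CoxReport(
        variable=variable,
        hazard_ratio=float(np.exp(coef)),
        ci_lower=float(np.exp(coef - z * se)),
        ci_upper=float(np.exp(coef + z * se)),
        p_value=p,
        n=int(keep.sum()),
        adjusters=tuple(adjusters),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up false discovery rates."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
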