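"""Cox model development and the HER2-EveNT prognostic score.

The published HER2-EveNT model is a five-term linear score on standardized
BCR evenness, TILs (%), breast pCR, hormone-receptor status and clinical
nodal status; its coefficients are log hazard ratios from a Cox model for
event-free survival, so a lower score means a lower modeled relapse risk.
This module exposes that model as a frozen object, reproduces the
development procedure (forward stepwise selection by AIC starting from a
null Cox model), derives tertile cutoffs, and assigns prognostic groups.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("immunoprog")

__all__ = [
    "ScoreTerm",
    "ScoreModel",
    "published_her2event",
    "standardize_evenness",
    "compute_score",
    "score_frame",
    "derive_tertile_cutoffs",
    "assign_groups",
    "CoxFitResult",
    "cox_fit",
    "null_cox_log_likelihood",
    "StepwiseTrace",
    "forward_stepwise_aic",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ScoreTerm:
    variable: str
    coefficient: float
    note: str = ""


@dataclass(frozen=True)
class ScoreModel:
    """A linear prognostic score with tertile cutoffs and group rule.

    ``evenness_center``/``evenness_scale`` standardize raw BCR evenness
    before it enters the score (the published constants are the development
    cohort's mean and SD). Patients with score <= ``cutoff_good`` fall in
    the good-prognosis group (first tertile); the second and third tertiles
    are merged into the poor-prognosis group.
    """

    terms: tuple[ScoreTerm, ...]
    cutoff_good: float
    cutoff_mid: float
    evenness_center: float | None = None
    evenness_scale: float | None = None
    provenance: str = "fitted"

    def __post_init__(self) -> None:
        if self.cutoff_good > self.cutoff_mid:
            raise ValueError("cutoff_good must be <= cutoff_mid")
        if not all(np.isfinite(t.coefficient) for t in self.terms):
            raise ValueError("coefficients must be finite")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(t.variable for t in self.terms)

    def to_dict(self) -> dict:
        return {
            "terms": [
                {"variable": t.variable, "coefficient": t.coefficient, "note": t.note}
                for t in self.terms
            ],
            "cutoff_good": self.cutoff_good,
            "cutoff_mid": self.cutoff_mid,
            "evenness_center": self.evenness_center,
            "evenness_scale": self.evenness_scale,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoreModel":
        return cls(
            terms=tuple(ScoreTerm(**t) for t in d["terms"]),
            cutoff_good=d["cutoff_good"],
            cutoff_mid=d["cutoff_mid"],
            evenness_center=d.get("evenness_center"),
            evenness_scale=d.get("evenness_scale"),
            provenance=d.get("provenance", "fitted"),
        )


_PUBLISHED_TERMS = (
    ScoreTerm("bcr_evenness_std", 0.300436587, "BCR evenness, standardized"),
    ScoreTerm("tils", -0.024107504, "stromal TILs, %"),
    ScoreTerm("pcr_breast", -0.568111234, "breast pCR (ypT0/is): 1=pCR, 0=RD"),
    ScoreTerm("hr", -0.525011259, "hormone receptor status: 1=positive"),
    ScoreTerm("cn0", -0.504914127, "clinical nodal status: 1=cN0, 0=cN+/x"),
)


def published_her2event() -> ScoreModel:
    """The published HER2-EveNT model, frozen.

    Five coefficients, the development cohort's evenness standardization
    constants (mean 0.7917893, SD 0.1004482) and tertile cutoffs
    (-1.3763, -0.8143).
    """
    return ScoreModel(
        terms=_PUBLISHED_TERMS,
        cutoff_good=-1.3763,
        cutoff_mid=-0.8143,
        evenness_center=0.7917893,
        evenness_scale=0.1004482,
        provenance="published",
    )


def standardize_evenness(raw_evenness, model: ScoreModel):
    """Center/scale raw BCR evenness with the model's stored constants."""
    if model.evenness_center is None or model.evenness_scale is None:
        raise ValueError("model carries no evenness standardization constants")
    return (np.asarray(raw_evenness, dtype=float) - model.evenness_center) / model.evenness_scale


def compute_score(features: Mapping[str, float], model: ScoreModel) -> float:
    """Linear score for one patient: sum of coefficient x covariate value.

    Raises KeyError when a model variable is absent and returns NaN (with a
    logged reason) when any required value is missing.
    """
    total = 0.0
    for term in model.terms:
        value = features[term.variable]
        if value is None or (isinstance(value, float) and np.isnan(value)):
            logger.info("score undefined: missing %s", term.variable)
            return float("nan")
        total += term.coefficient * float(value)
    return total


def score_frame(features: pd.DataFrame, model: ScoreModel) -> pd.Series:
    """Per-patient scores over a feature table; NaN where any term is missing.

    If the table has a raw ``bcr_evenness`` column but no
    ``bcr_evenness_std``, standardization with the model's constants is
    applied first.
    """
    df = features
    if "bcr_evenness_std" in model.variables and "bcr_evenness_std" not in df.columns:
        if "bcr_evenness" not in df.columns:
            raise KeyError("need bcr_evenness or bcr_evenness_std column")
        df = df.copy()
        df["bcr_evenness_std"] = standardize_evenness(df["bcr_evenness"], model)
    missing_cols = [v for v in model.variables if v not in df.columns]
    if missing_cols:
        raise KeyError(f"feature table lacks model variables: {missing_cols}")
    scores = pd.Series(0.0, index=df.index, name="score")
    for term in model.terms:
        scores = scores + term.coefficient * df[term.variable].astype(float)
    n_missing = int(scores.isna().sum())
    if n_missing:
        logger.info("score undefined for %d/%d patients (missing model variables)",
                    n_missing, len(scores))
    return scores


def derive_tertile_cutoffs(scores: Sequence[float]) -> tuple[float, float]:
    """Empirical 1/3 and 2/3 quantiles (type-7, linear interpolation)."""
    s = np.asarray(scores, dtype=float)
    s = s[np.isfinite(s)]
    if s.size < 3:
        raise ValueError("need at least 3 scores to derive tertiles")
    lo, hi = np.quantile(s, [1.0 / 3.0, 2.0 / 3.0])
    return float(lo), float(hi)


def assign_groups(scores: pd.Series, model: ScoreModel) -> pd.DataFrame:
    """Tertile and good/poor group per patient.

    Good prognosis iff score <= cutoff_good (first tertile); tertiles 2-3
    are the merged poor-prognosis group. NaN scores get no assignment.
    """
    s = pd.Series(scores, dtype=float)
    tertile = pd.Series(pd.NA, index=s.index, dtype="Int64")
    tertile[s <= model.cutoff_good] = 1
    tertile[(s > model.cutoff_good) & (s <= model.cutoff_mid)] = 2
    tertile[s > model.cutoff_mid] = 3
    group = tertile.map({1: "good", 2: "poor", 3: "poor"})
    return pd.DataFrame({"score": s, "tertile": tertile, "group": group})


# ---------------------------------------------------------------------------
# Cox fitting and forward stepwise AIC


@dataclass
class CoxFitResult:
    variables: tuple[str, ...]
    coefficients: pd.Series
    standard_errors: pd.Series
    log_likelihood: float
    aic: float
    converged: bool

    def confidence_intervals(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "lower": self.coefficients - z * self.standard_errors,
                "upper": self.coefficients + z * self.standard_errors,
            }
        )


def null_cox_log_likelihood(time, event) -> float:
    """Log partial likelihood of the covariate-free Cox model.

    With no covariates every relative risk is 1, so each distinct event
    time with d events in a risk set of size n contributes
    -sum_{l=0}^{d-1} log(n - l) (Efron and Breslow coincide).
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    order = np.argsort(t)
    t, e = t[order], e[order]
    ll = 0.0
    n = t.size
    for ut in np.unique(t[e == 1]):
        at_risk = int(np.sum(t >= ut))
        d = int(np.sum((t == ut) & (e == 1)))
        ll -= np.sum(np.log(at_risk - np.arange(d)))
    return float(ll)


def _efron_loglik_derivs(beta, X, w_groups):
    """Efron log partial likelihood with gradient and observed information.

    ``w_groups`` carries the precomputed tie structure: see
    :func:`_prepare_cox_arrays`.
    """
    (first_idx, d, ev_mask, red_bounds, jidx, r, sum_x_events) = w_groups
    eta = X @ beta
    eta = eta - eta.max()  # risk ratios are shift-invariant; guards exp overflow
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    # reverse cumulative sums give risk-set aggregates at each position
    cw = np.cumsum(w[::-1])[::-1]
    cwx = np.cumsum(wx[::-1], axis=0)[::-1]
    cwxx = np.cumsum(wxx[::-1], axis=0)[::-1]
    S_R, Z_R, M_R = cw[first_idx], cwx[first_idx], cwxx[first_idx]
    # per-group sums over the tied events themselves
    S_D = np.add.reduceat(w[ev_mask], red_bounds)
    Z_D = np.add.reduceat(wx[ev_mask], red_bounds, axis=0)
    M_D = np.add.reduceat(wxx[ev_mask], red_bounds, axis=0)

    phi = S_R[jidx] - r * S_D[jidx]
    num_z = Z_R[jidx] - r[:, None] * Z_D[jidx]
    num_m = M_R[jidx] - r[:, None, None] * M_D[jidx]
    mu = num_z / phi[:, None]

    ll = float(eta[ev_mask].sum() - np.log(phi).sum())
    grad = sum_x_events - mu.sum(axis=0)
    info = (num_m / phi[:, None, None]).sum(axis=0) - mu.T @ mu
    return ll, grad, info


def _prepare_cox_arrays(X, t, e):
    order = np.argsort(t, kind="stable")
    X, t, e = X[order], t[order], e[order]
    ev_mask = e == 1
    ut, d = np.unique(t[ev_mask], return_counts=True)
    first_idx = np.searchsorted(t, ut, side="left")
    red_bounds = np.concatenate([[0], np.cumsum(d)[:-1]])
    jidx = np.repeat(np.arange(ut.size), d)
    l = np.concatenate([np.arange(k) for k in d]).astype(float)
    r = l / np.repeat(d.astype(float), d)
    sum_x_events = X[ev_mask].sum(axis=0)
    groups = (first_idx, d, ev_mask, red_bounds, jidx, r, sum_x_events)
    return X, t, e, groups


def cox_fit(features: pd.DataFrame, time, event) -> CoxFitResult:
    """Cox proportional-hazards fit (Efron ties) with AIC.

    Maximum partial likelihood by Newton's method with step-halving,
    vectorized over tied-event groups. AIC = -2 logPL + 2k. An empty
    feature set returns the closed-form null model. Non-convergence or
    separation yields a flagged (converged=False) result so that stepwise
    selection can skip the candidate.
    """
    variables = tuple(features.columns)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if np.sum(e) < 2:
        raise ValueError("need at least 2 events")
    if not variables:
        ll0 = null_cox_log_likelihood(t, e)
        empty = pd.Series(dtype=float)
        return CoxFitResult((), empty, empty, ll0, -2.0 * ll0, True)
    if any(features[v].nunique(dropna=True) < 2 for v in variables):
        bad = [v for v in variables if features[v].nunique(dropna=True) < 2]
        raise ValueError(f"constant covariates: {bad}")
    X_raw = features.to_numpy(dtype=float)
    center = X_raw.mean(axis=0)
    X, t_s, e_s, groups = _prepare_cox_arrays(X_raw - center, t, e)

    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _efron_loglik_derivs(beta, X, groups)
    converged = False
    for _ in range(100):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving keeps the likelihood non-decreasing
        factor = 1.0
        for _ in range(30):
            candidate = beta + factor * step
            ll_new, grad_new, info_new = _efron_loglik_derivs(candidate, X, groups)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        else:
            break
        improvement = ll_new - ll
        beta, ll, grad, info = candidate, ll_new, grad_new, info_new
        if abs(improvement) < 1e-10 and np.max(np.abs(grad)) < 1e-6:
            converged = True
            break
        if np.max(np.abs(beta)) > 20:  # separation: coefficients diverge
            converged = False
            break
    if converged and np.max(np.abs(beta)) > 20:
        converged = False  # likelihood plateau under separation
    if not converged or not np.all(np.isfinite(beta)):
        logger.warning("Cox fit did not converge for %s", variables)
        nan = pd.Series(np.nan, index=list(variables))
        return CoxFitResult(variables, nan, nan, np.nan, np.inf, False)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    aic = -2.0 * ll + 2.0 * p
    return CoxFitResult(
        variables,
        pd.Series(beta, index=list(variables)),
        pd.Series(se, index=list(variables)),
        float(ll),
        float(aic),
        True,
    )


@dataclass
class StepwiseTrace:
    """Record of a forward stepwise AIC run; AIC strictly decreases."""

    steps: list[tuple[str, float]]
    final_variables: tuple[str, ...]
    final_aic: float
    null_aic: float
    final_fit: CoxFitResult | None = None


def forward_stepwise_aic(
    pool: Sequence[str],
    features: pd.DataFrame,
    time,
    event,
    max_steps: int | None = None,
) -> StepwiseTrace:
    """Greedy forward selection of Cox covariates by AIC.

    Starting from the null model, each step adds the pool variable giving
    the lowest AIC, stopping when no addition lowers it. Ties break by pool
    order. Rows with a missing value in any pool variable are dropped first
    (complete-case development set). Candidates whose fit fails to converge
    are skipped.
    """
    pool = list(pool)
    keep = features[pool].notna().all(axis=1)
    X = features.loc[keep, pool]
    t = np.asarray(time, dtype=float)[np.asarray(keep)]
    e = np.asarray(event, dtype=int)[np.asarray(keep)]
    if keep.sum() < len(features):
        logger.info("stepwise: %d/%d complete cases", int(keep.sum()), len(features))

    current: list[str] = []
    current_aic = cox_fit(X[[]], t, e).aic
    null_aic = current_aic
    steps: list[tuple[str, float]] = []
    best_fit: CoxFitResult | None = None
    while max_steps is None or len(steps) < max_steps:
        best_var, best_aic, best_candidate_fit = None, current_aic, None
        for candidate in pool:
            if candidate in current:
                continue
            try:
                fit = cox_fit(X[current + [candidate]], t, e)
            except ValueError:
                continue
            if fit.converged and fit.aic < best_aic:  # strict < keeps pool-order ties
                best_var, best_aic, best_candidate_fit = candidate, fit.aic, fit
        if best_var is None:
            break
        current.append(best_var)
        current_aic = best_aic
        best_fit = best_candidate_fit
        steps.append((best_var, best_aic))
        logger.info("stepwise: + %s (AIC %.4f)", best_var, best_aic)
    return StepwiseTrace(steps, tuple(current), current_aic, null_aic, best_fit)


# ---------------------------------------------------------------------------
# Serialization


def save_model(model: ScoreModel, path) -> None:
    text = str(path)
    payload = model.to_dict()
    if text.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    else:
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def load_model(path) -> ScoreModel:
    text = str(path)
    with open(path) as fh:
        payload = json.load(fh) if text.endswith(".json") else yaml.safe_load(fh)
    return ScoreModel.from_dict(payload)
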