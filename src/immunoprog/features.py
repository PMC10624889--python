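"""Feature transformation and standardization for model development.

Candidate model variables (repertoire metrics, TILs, gene-signature scores,
clinical encodings) are prepared the same way the prognostic model expects
them: a Shapiro-Francia-driven decision on log10 transformation (with a
small constant equal to one tenth of the 10% quantile when zeros are
present), then centering and scaling on the fitting cohort. A spec fitted
on one cohort can be serialized and applied unchanged to another.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("immunoprog")

__all__ = [
    "shapiro_francia",
    "TransformSpec",
    "fit_transform_spec",
    "apply_transform",
    "SignatureDef",
    "read_signature_tsv",
    "signature_score",
    "normalize_counts",
    "ClinicalRecord",
    "encode_clinical",
    "encode_clinical_frame",
    "DegenerateInputError",
]


class DegenerateInputError(ValueError):
    """Raised for inputs on which a statistic is undefined (e.g. constant)."""


# ---------------------------------------------------------------------------
# Shapiro-Francia normality test


def shapiro_francia(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Francia normality test.

    W' is the squared Pearson correlation between the sample order
    statistics and the expected standard-normal order statistics (Blom
    plotting positions, offset 3/8). The p-value uses Royston's 1993 normal
    approximation of log(1 - W'), valid for 5 <= n <= 5000.

    Returns (W', p).
    """
    x = np.sort(np.asarray(values, dtype=float))
    x = x[np.isfinite(x)]
    n = x.size
    if n < 5:
        raise ValueError(f"Shapiro-Francia requires n >= 5, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant input: normality test undefined")
    a = 3.0 / 8.0  # Blom plotting positions
    m = stats.norm.ppf((np.arange(1, n + 1) - a) / (n + 1 - 2 * a))
    w_prime = float(np.corrcoef(x, m)[0, 1] ** 2)
    # Royston (1993) coefficients for the distribution of log(1 - W')
    nu = math.log(n)
    u1 = math.log(nu) - nu
    u2 = math.log(nu) + 2.0 / nu
    mu = -1.2725 + 1.0521 * u1
    sigma = 1.0308 - 0.26758 * u2
    z = (math.log(1.0 - w_prime) - mu) / sigma
    p = float(stats.norm.sf(z))
    return w_prime, p


# ---------------------------------------------------------------------------
# Per-variable transformation specs


@dataclass(frozen=True)
class TransformSpec:
    """Fitted transformation + standardization for one variable."""

    variable: str
    use_log10: bool
    small_constant: float
    center: float
    scale: float
    fitted_on: str = ""
    sf_p_original: float | None = None
    sf_p_transformed: float | None = None

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "use_log10": self.use_log10,
            "small_constant": self.small_constant,
            "center": self.center,
            "scale": self.scale,
            "fitted_on": self.fitted_on,
            "sf_p_original": self.sf_p_original,
            "sf_p_transformed": self.sf_p_transformed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TransformSpec":
        return cls(**dict(d))


def _candidate_transform(v: np.ndarray) -> tuple[np.ndarray, float]:
    """log10 candidate: plain log when strictly positive, else shifted."""
    if v.min() > 0:
        return np.log10(v), 0.0
    # type-7 (linear interpolation) quantile: the small constant depends on it
    small = float(np.quantile(v, 0.10)) / 10.0
    return np.log10(v + small), small


def fit_transform_spec(
    values: Sequence[float],
    variable: str,
    fitted_on: str = "",
    rule: str = "original_first",
) -> TransformSpec:
    """Decide the log10 transform for one variable and fit center/scale.

    The candidate is log10(x) when the variable has no zeros in the cohort,
    else log10(x + c) with c = (10% quantile)/10. Under the default rule the
    original values are tested first: if they already look normal
    (Shapiro-Francia p > 0.05) no transform is applied; otherwise the
    candidate is kept only when its Shapiro-Francia p exceeds the
    original's. ``rule="improvement"`` skips the first gate and always keeps
    the transform iff it improves the p-value. Center and scale are the mean
    and sample SD (n-1 denominator) of the chosen representation.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 5:
        raise ValueError(f"{variable}: need >= 5 non-missing values, got {v.size}")
    if v.min() < 0:
        raise ValueError(f"{variable}: negative values, log transform undefined")
    if rule not in ("original_first", "improvement"):
        raise ValueError(f"unknown rule {rule!r}")

    p_orig = shapiro_francia(v)[1]
    transformed, small = _candidate_transform(v)
    p_trans: float | None = None
    use_log = False
    if np.all(np.isfinite(transformed)):
        if rule == "original_first" and p_orig > 0.05:
            use_log = False
        else:
            p_trans = shapiro_francia(transformed)[1]
            use_log = p_trans > p_orig
    chosen = transformed if use_log else v
    spec = TransformSpec(
        variable=variable,
        use_log10=use_log,
        small_constant=small if use_log else 0.0,
        center=float(np.mean(chosen)),
        scale=float(np.std(chosen, ddof=1)),
        fitted_on=fitted_on,
        sf_p_original=p_orig,
        sf_p_transformed=p_trans,
    )
    logger.info(
        "%s: log10=%s (SF p original=%.3g, transformed=%s)",
        variable,
        use_log,
        p_orig,
        "n/a" if p_trans is None else f"{p_trans:.3g}",
    )
    return spec


def apply_transform(values: Sequence[float], spec: TransformSpec) -> np.ndarray:
    """Apply a fitted spec: y = (t(x) - center) / scale; missing propagates."""
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    ok = np.isfinite(v)
    t = v[ok]
    if spec.use_log10:
        shifted = t + spec.small_constant
        if np.any(shifted <= 0):
            bad = t[shifted <= 0]
            raise ValueError(
                f"{spec.variable}: values {bad.tolist()} not positive after adding "
                f"small constant {spec.small_constant}"
            )
        t = np.log10(shifted)
    out[ok] = (t - spec.center) / spec.scale
    return out


# ---------------------------------------------------------------------------
# Gene-signature scoring


@dataclass(frozen=True)
class SignatureDef:
    name: str
    genes: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.weights):
            raise ValueError("genes and weights must have equal length")
        if any(w == 0 for w in self.weights):
            raise ValueError("signature weights must be nonzero")


def read_signature_tsv(path, name: str | None = None) -> SignatureDef:
    """Read a two-column (gene, weight) TSV into a SignatureDef."""
    df = pd.read_csv(path, sep="\t")
    gene_col, weight_col = df.columns[:2]
    return SignatureDef(
        name=name or str(getattr(path, "stem", path)),
        genes=tuple(df[gene_col].astype(str)),
        weights=tuple(df[weight_col].astype(float)),
    )


def normalize_counts(expr_counts: pd.DataFrame, min_total: int = 20) -> pd.DataFrame:
    """Filter and normalize a gene-by-sample count matrix for scoring.

    Genes with a total count across samples below ``min_total`` are dropped;
    each sample's counts are divided by that sample's mean gene count
    (computed on the filtered matrix), then log10 after adding 0.001.
    """
    kept = expr_counts.loc[expr_counts.sum(axis=1) >= min_total]
    if kept.empty:
        raise ValueError("no gene passed the minimum-total-count filter")
    scaled = kept / kept.mean(axis=0)
    return np.log10(scaled + 0.001)


def signature_score(
    expr_counts: pd.DataFrame,
    sig: SignatureDef,
    normalized: pd.DataFrame | None = None,
) -> pd.Series:
    """Weighted-mean signature score per sample.

    The score is sum(w_g * log-expression_g) / sum(|w_g|) over the
    signature's genes surviving the count filter. Pass ``normalized`` to
    reuse a precomputed :func:`normalize_counts` matrix. Returns all-NaN
    with a warning when no signature gene survives filtering; missing genes
    are reported at INFO level.
    """
    log_expr = normalize_counts(expr_counts) if normalized is None else normalized
    present = [g for g in sig.genes if g in log_expr.index]
    missing = [g for g in sig.genes if g not in log_expr.index]
    if missing:
        logger.info("signature %s: %d/%d genes absent after filtering: %s",
                    sig.name, len(missing), len(sig.genes), missing)
    if not present:
        warnings.warn(f"signature {sig.name}: no gene survives filtering; score undefined")
        return pd.Series(np.nan, index=log_expr.columns, name=sig.name)
    w = pd.Series(dict(zip(sig.genes, sig.weights)))[present]
    score = log_expr.loc[present].mul(w, axis=0).sum(axis=0) / w.abs().sum()
    score.name = sig.name
    return score


# ---------------------------------------------------------------------------
# Clinical encodings


@dataclass
class ClinicalRecord:
    """Per-patient clinical covariates and survival endpoints."""

    patient_id: str
    hr_status: str  # pos | neg
    er_status: str  # pos | neg
    tumor_size: str  # cT1 | cT2 | cT3plus
    nodal: str  # cN0 | cNplus_or_x
    tils_pct: float | None
    pcr_breast: str  # yes | no
    pcr_breast_axilla: str | None  # yes | no | None
    arm: str  # L | T | T+L
    age: float
    pam50: str  # HER2E | Basal | LumA | LumB | Normal
    efs_time: float
    efs_event: int
    os_time: float | None = None
    os_event: int | None = None

    def __post_init__(self) -> None:
        if self.efs_time <= 0:
            raise ValueError("efs_time must be > 0")
        if self.efs_event not in (0, 1):
            raise ValueError("efs_event must be 0 or 1")
        if self.tils_pct is not None and not (0 <= self.tils_pct <= 100):
            raise ValueError("tils_pct must be in [0, 100]")


def encode_clinical(rec: ClinicalRecord) -> dict[str, float | None]:
    """Dichotomize clinical covariates for modeling.

    Conventions: pCR = 1 / RD = 0; HR+ = 1; cN0 = 1 vs cN+/x = 0;
    tumor size >= cT3 = 1; combination arm (T+L) = 1 vs single agent 0;
    PAM50 HER2-enriched = 1 vs others. TILs (%) and age (years) stay on
    their raw scales. Missing fields encode as None, never as silent 0.
    """
    return {
        "pcr_breast": 1.0 if rec.pcr_breast == "yes" else 0.0,
        "pcr_breast_axilla": (
            None if rec.pcr_breast_axilla is None
            else 1.0 if rec.pcr_breast_axilla == "yes" else 0.0
        ),
        "hr": 1.0 if rec.hr_status == "pos" else 0.0,
        "er": 1.0 if rec.er_status == "pos" else 0.0,
        "cn0": 1.0 if rec.nodal == "cN0" else 0.0,
        "ct3_plus": 1.0 if rec.tumor_size == "cT3plus" else 0.0,
        "arm_combo": 1.0 if rec.arm == "T+L" else 0.0,
        "pam50_her2e": 1.0 if rec.pam50 == "HER2E" else 0.0,
        "tils": rec.tils_pct,
        "age": rec.age,
    }


_ENCODED_COLUMNS = [
    "pcr_breast", "pcr_breast_axilla", "hr", "er", "cn0",
    "ct3_plus", "arm_combo", "pam50_her2e", "tils", "age",
]


def encode_clinical_frame(clinical: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`encode_clinical` over a clinical table.

    Expects the ClinicalRecord column names; returns a numeric frame indexed
    by patient_id with NaN for missing values. Survival columns and any raw
    repertoire columns (e.g. bcr_evenness) are carried through unchanged.
    """
    out = pd.DataFrame(index=clinical["patient_id"])
    out["pcr_breast"] = (clinical["pcr_breast"] == "yes").astype(float).values
    if "pcr_breast_axilla" in clinical:
        ax = clinical["pcr_breast_axilla"]
        out["pcr_breast_axilla"] = np.where(
            ax.isna(), np.nan, (ax == "yes").astype(float)
        )
    out["hr"] = (clinical["hr_status"] == "pos").astype(float).values
    out["er"] = (clinical["er_status"] == "pos").astype(float).values
    out["cn0"] = (clinical["nodal"] == "cN0").astype(float).values
    out["ct3_plus"] = (clinical["tumor_size"] == "cT3plus").astype(float).values
    out["arm_combo"] = (clinical["arm"] == "T+L").astype(float).values
    out["pam50_her2e"] = (clinical["pam50"] == "HER2E").astype(float).values
    out["tils"] = pd.to_numeric(clinical["tils_pct"], errors="coerce").values
    out["age"] = pd.to_numeric(clinical["age"], errors="coerce").values
    for col in ("bcr_evenness", "efs_time", "efs_event", "os_time", "os_event"):
        if col in clinical:
            out[col] = pd.to_numeric(clinical[col], errors="coerce").values
    return out
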