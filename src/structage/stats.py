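"""Cross-sectional and longitudinal structure-age analyses.

Two models quantify how cognitive status relates to predicted structure age
PA_S:

* cross-sectional, baseline scans only (OLS per structure):
      PA_S,i = b0 + b1 * Age_i + b3 * Diagnosis_i + e_S,i
  with healthy subjects as the reference diagnosis level, so the MCI and
  ADD coefficients are the extra predicted years attributable to diagnosis
  at equal chronological age;

* longitudinal, subjects healthy at baseline with repeated scans (linear
  mixed model per structure, random intercept and random slope on time):
      PA_S,i,j = b0 + b1 * Age_i,0 + b2_g * (Delta_scan_i,j x Group_i)
                 + u0_i + u1_i * Delta_scan_i,j + e_S,i,j
  coded as one time slope per conversion group (no reference level), so the
  "aging pace" of a converter group is its slope relative to the
  non-converter slope, reported as a signed percentage.

All p-values are corrected with the Benjamini-Hochberg false discovery
rate across the structures x contrasts of one analysis table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import norm
from statsmodels.regression.mixed_linear_model import MixedLMParams
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DIAGNOSES",
    "CONVERSION_GROUPS",
    "ScanRecord",
    "ModelFit",
    "records_to_frame",
    "select_longitudinal_cohort",
    "fit_cross_sectional",
    "fit_longitudinal",
    "aging_slope_percent",
    "fdr_correct",
]

DIAGNOSES = ("healthy", "MCI", "ADD")
CONVERSION_GROUPS = ("non_converter", "MCI_converter", "ADD_converter")
_DIAG_TO_GROUP = {
    "healthy": "non_converter",
    "MCI": "MCI_converter",
    "ADD": "ADD_converter",
}


@dataclass
class ScanRecord:
    """One scan: identity, timing, diagnosis and per-structure ages."""

    subject_id: str
    scan_id: str
    age_at_scan: float
    diagnosis: str
    delta_scan: float  # years since the subject's baseline scan
    structure_ages: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")
        if self.delta_scan < 0:
            raise ValueError("delta_scan must be >= 0")


def records_to_frame(records: Sequence[ScanRecord]) -> pd.DataFrame:
    """Tidy frame: one row per scan, one column per structure age."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "scan_id": r.scan_id,
            "age_at_scan": r.age_at_scan,
            "diagnosis": r.diagnosis,
            "delta_scan": r.delta_scan,
        }
        row.update(r.structure_ages)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ModelFit:
    """Per-structure fit summary (either analysis)."""

    structure: str
    kind: str  # "cross_sectional" | "longitudinal"
    coefficients: pd.DataFrame  # term, estimate, se, ci_low, ci_high, p, p_fdr
    group_slopes: dict[str, float] = field(default_factory=dict)
    random_effect_variances: dict[str, float] = field(default_factory=dict)
    residual_variance: float | None = None
    converged: bool = True

    def coef(self, term: str) -> float:
        row = self.coefficients.loc[self.coefficients["term"] == term]
        if row.empty:
            raise KeyError(f"no term {term!r} in fit for {self.structure}")
        return float(row["estimate"].iloc[0])


def _safe_p(estimate: float, se: float, p: float) -> float:
    """Wald p-value, defined also in the degenerate zero-variance limit
    (noiseless data), where statsmodels emits NaN."""
    if np.isfinite(p):
        return float(p)
    if se == 0:
        return 0.0 if abs(estimate) > 0 else 1.0
    return 1.0


def fdr_correct(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_longitudinal_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Longitudinal inclusion filter and conversion grouping.

    Keeps subjects with >= 2 scans whose baseline diagnosis is healthy and
    whose age at last scan is at least 70; groups each by last diagnosis
    (healthy -> non_converter, MCI -> MCI_converter, ADD -> ADD_converter).
    Returns a frame with columns subject_id, group.
    """
    out = []
    for sid, grp in records.groupby("subject_id", sort=True):
        grp = grp.sort_values("delta_scan")
        if len(grp) < 2:
            continue
        if grp["diagnosis"].iloc[0] != "healthy":
            continue
        if grp["age_at_scan"].iloc[-1] < 70:
            continue
        out.append((sid, _DIAG_TO_GROUP[grp["diagnosis"].iloc[-1]]))
    return pd.DataFrame(out, columns=["subject_id", "group"])


def fit_cross_sectional(
    baseline: pd.DataFrame,
    structure_cols: Sequence[str],
) -> dict[str, ModelFit]:
    """OLS of predicted structure age on true age and diagnosis, healthy as
    reference; one fit per structure, FDR across structures x contrasts."""
    present = set(baseline["diagnosis"].unique())
    missing = [d for d in DIAGNOSES if d not in present]
    if missing:
        raise ValueError(
            f"diagnosis level(s) absent from baseline data: {missing}; "
            "the diagnosis contrast would be rank-deficient"
        )
    if baseline["subject_id"].duplicated().any():
        raise ValueError("baseline frame must contain one scan per subject")
    fits: dict[str, ModelFit] = {}
    pvals: list[float] = []
    index: list[tuple[str, int]] = []
    for col in structure_cols:
        model = smf.ols(
            f"Q('{col}') ~ age_at_scan + C(diagnosis, Treatment('healthy'))",
            data=baseline,
        )
        res = model.fit()
        ci = res.conf_int()
        rows = []
        rename = {
            "Intercept": "intercept",
            "age_at_scan": "age",
            "C(diagnosis, Treatment('healthy'))[T.MCI]": "MCI",
            "C(diagnosis, Treatment('healthy'))[T.ADD]": "ADD",
        }
        for name in res.params.index:
            term = rename.get(name, name)
            rows.append(
                {
                    "term": term,
                    "estimate": float(res.params[name]),
                    "se": float(res.bse[name]),
                    "ci_low": float(ci.loc[name, 0]),
                    "ci_high": float(ci.loc[name, 1]),
                    "p": _safe_p(
                        float(res.params[name]),
                        float(res.bse[name]),
                        float(res.pvalues[name]),
                    ),
                    "p_fdr": np.nan,
                }
            )
            if term in ("MCI", "ADD"):
                pvals.append(rows[-1]["p"])
                index.append((col, len(rows) - 1))
        fits[col] = ModelFit(
            structure=col,
            kind="cross_sectional",
            coefficients=pd.DataFrame(rows),
            residual_variance=float(res.mse_resid),
        )
    adj = fdr_correct(pvals)
    for (col, row_i), q in zip(index, adj):
        fits[col].coefficients.loc[row_i, "p_fdr"] = q
    return fits


def _fit_mixed(formula: str, data: pd.DataFrame):
    """REML mixed model with correlated random intercept + slope; falls back
    to uncorrelated random effects when the covariance is singular or the
    optimizer fails to converge."""
    model = smf.mixedlm(
        formula, data, groups=data["subject_id"], re_formula="~delta_scan"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
        if not res.converged:
            # statsmodels' default gradient optimizers often stall on the
            # profiled REML surface; Powell is slower but dependable
            res = model.fit(reml=True, method="powell", maxiter=2000)
    cov_re = np.asarray(res.cov_re)
    singular = not np.all(np.linalg.eigvalsh(cov_re) > 1e-10)
    if singular or not res.converged:
        warnings.warn(
            "random-effect covariance singular; refitting with uncorrelated "
            "random effects",
            stacklevel=3,
        )
        free = MixedLMParams.from_components(
            fe_params=np.ones(model.k_fe), cov_re=np.eye(2)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=True, free=free)
            if not res.converged:
                res = model.fit(reml=True, free=free, method="powell", maxiter=2000)
    return res


def fit_longitudinal(
    records: pd.DataFrame,
    groups: pd.DataFrame,
    structure_cols: Sequence[str],
) -> dict[str, ModelFit]:
    """Linear mixed model of structure age on baseline age and one
    time-since-baseline slope per conversion group, with per-subject random
    intercept and slope.

    ``records`` holds all scans of the included subjects; ``groups`` is the
    output of :func:`select_longitudinal_cohort`.  Converter-vs-non-converter
    slope contrasts carry FDR-corrected p-values across structures.
    """
    data = records.drop(columns=["group"], errors="ignore").merge(
        groups, on="subject_id", how="inner"
    )
    if data.empty:
        raise ValueError("no records match the longitudinal cohort")
    counts = data.groupby("subject_id")["scan_id"].count()
    if (counts < 2).any():
        raise ValueError("every included subject needs >= 2 scans")
    base = (
        data.sort_values("delta_scan")
        .groupby("subject_id")["age_at_scan"]
        .first()
        .rename("age_baseline")
    )
    data = data.merge(base, on="subject_id")
    data["group"] = pd.Categorical(data["group"], categories=CONVERSION_GROUPS)

    fits: dict[str, ModelFit] = {}
    pvals: list[float] = []
    index: list[tuple[str, int]] = []
    slope_terms = {g: f"delta_scan:group[{g}]" for g in CONVERSION_GROUPS}
    # group main effects (converter intercept offsets, non-converter as
    # reference) plus one time slope per group; without the mains, converter
    # level differences leak into the slope coefficients
    for col in structure_cols:
        res = _fit_mixed(f"Q('{col}') ~ group + age_baseline + delta_scan:group", data)
        ci = res.conf_int()
        rename = {
            "Intercept": "intercept",
            "age_baseline": "baseline_age",
            "group[T.MCI_converter]": "offset_MCI_converter",
            "group[T.ADD_converter]": "offset_ADD_converter",
            slope_terms["non_converter"]: "slope_non_converter",
            slope_terms["MCI_converter"]: "slope_MCI_converter",
            slope_terms["ADD_converter"]: "slope_ADD_converter",
        }
        rows = []
        fe_names = list(res.fe_params.index)
        for name in fe_names:
            term = rename.get(name, name)
            rows.append(
                {
                    "term": term,
                    "estimate": float(res.fe_params[name]),
                    "se": float(res.bse[name]),
                    "ci_low": float(ci.loc[name, 0]),
                    "ci_high": float(ci.loc[name, 1]),
                    "p": _safe_p(
                        float(res.fe_params[name]),
                        float(res.bse[name]),
                        float(res.pvalues[name]),
                    ),
                    "p_fdr": np.nan,
                }
            )
            if term.startswith("offset_"):  # converter fixed effects
                pvals.append(rows[-1]["p"])
                index.append((col, len(rows) - 1))
        # converter minus non-converter slope contrasts
        k = len(fe_names)
        cov = np.asarray(res.cov_params())[:k, :k]
        i_hc = fe_names.index(slope_terms["non_converter"])
        for conv in ("MCI_converter", "ADD_converter"):
            i_c = fe_names.index(slope_terms[conv])
            c = np.zeros(k)
            c[i_c], c[i_hc] = 1.0, -1.0
            est = float(c @ np.asarray(res.fe_params))
            se = float(np.sqrt(c @ cov @ c))
            p = _safe_p(est, se, float(2 * norm.sf(abs(est / se))) if se > 0 else np.nan)
            rows.append(
                {
                    "term": f"contrast_{conv}_minus_non",
                    "estimate": est,
                    "se": se,
                    "ci_low": est - 1.959963984540054 * se,
                    "ci_high": est + 1.959963984540054 * se,
                    "p": p,
                    "p_fdr": np.nan,
                }
            )
            pvals.append(p)
            index.append((col, len(rows) - 1))
        cov_re = np.asarray(res.cov_re)
        fits[col] = ModelFit(
            structure=col,
            kind="longitudinal",
            coefficients=pd.DataFrame(rows),
            group_slopes={
                g: float(res.fe_params[slope_terms[g]]) for g in CONVERSION_GROUPS
            },
            random_effect_variances={
                "intercept": float(cov_re[0, 0]),
                "slope": float(cov_re[1, 1]),
                "covariance": float(cov_re[0, 1]),
            },
            residual_variance=float(res.scale),
            converged=bool(res.converged),
        )
    adj = fdr_correct(pvals)
    for (col, row_i), q in zip(index, adj):
        fits[col].coefficients.loc[row_i, "p_fdr"] = q
    return fits


def aging_slope_percent(fit: ModelFit) -> dict[str, float]:
    """Converter aging pace relative to non-converters, as signed percent:
    (slope_converter / slope_non_converter - 1) x 100."""
    if not fit.group_slopes:
        raise ValueError("fit has no group slopes (not a longitudinal fit)")
    b_hc = fit.group_slopes["non_converter"]
    if abs(b_hc) < 1e-8:
        raise ZeroDivisionError(
            "non-converter slope is ~0; the slope ratio is undefined"
        )
    return {
        g: (fit.group_slopes[g] / b_hc - 1.0) * 100.0
        for g in ("MCI_converter", "ADD_converter")
    }
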