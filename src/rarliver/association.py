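"""The survey-weighted model battery linking rhythm quintiles to biomarkers.

For each rest-activity parameter the exposure is its quintile label entered
as indicator contrasts against the presumed lowest-risk quintile (Q5 for
pseudo-F, amplitude, mesor, amplitude:mesor and IS; Q1 for acrophase and
IV).  Outcomes are the six abnormality flags (logistic), the log levels
(linear), and the 0/1/2/3+ abnormal composite (proportional odds).
Adjustment sets:

* model1: age + gender
* model2 (main): model1 + race/ethnicity, education, income, marital
  status, smoking, alcohol, hepatitis B/C/E
* model3: model2 + diabetes;  model4: model2 + BMI category
* sensitivity_behavior: model2 + total physical activity + sleep duration

Trend tests refit with the quintile index as a single continuous covariate
(robust Wald p); interaction tests are Rao-Scott-corrected working LRTs of
the cross-product terms; stratified and shift-worker-exclusion runs refit
the same specification on subsets.  Complete-case handling per model; every
fit's n is recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import BIOMARKERS, RAR_PARAMETERS, REFERENCE_QUINTILE
from .survey import SurveyLogit, SurveyLogLinear, SurveyOrdinal, working_lrt

__all__ = ["ModelSpec", "AssociationResult", "ADJUSTMENT_SETS",
           "build_design", "fit_weighted_logistic", "fit_weighted_linear_log",
           "fit_ordinal_logistic", "trend_test", "interaction_test",
           "stratified_run", "sensitivity_exclude_shift", "run_full_analysis"]

CATEGORICAL = ["gender", "race", "education", "income", "marital", "smoking",
               "alcohol", "bmi_cat", "diabetes", "hep_b", "hep_c", "hep_e",
               "session"]

ADJUSTMENT_SETS = {
    "model1": ["age", "gender"],
    "model2": ["age", "gender", "race", "education", "income", "marital",
               "smoking", "alcohol", "hep_b", "hep_c", "hep_e"],
    "model3": ["age", "gender", "race", "education", "income", "marital",
               "smoking", "alcohol", "hep_b", "hep_c", "hep_e", "diabetes"],
    "model4": ["age", "gender", "race", "education", "income", "marital",
               "smoking", "alcohol", "hep_b", "hep_c", "hep_e", "bmi_cat"],
    "sensitivity_behavior": ["age", "gender", "race", "education", "income",
                             "marital", "smoking", "alcohol", "hep_b", "hep_c",
                             "hep_e", "total_activity", "sleep_duration"],
    "none": [],
}


@dataclass
class ModelSpec:
    """One cell of the battery: outcome x exposure x adjustment set."""

    outcome: str                       # biomarker name or 'abnormal_composite'
    outcome_type: str = "binary"       # binary | loglinear | ordinal
    exposure: str = "pseudo_f"         # RAR parameter or 'impaired_score'
    exposure_type: str = "quintile"    # quintile | score | continuous
    adjustment: str = "model2"
    weights: str = "weight"
    reference: int | None = None       # default: REFERENCE_QUINTILE[exposure]

    def __post_init__(self):
        if self.adjustment not in ADJUSTMENT_SETS:
            raise ValueError(f"unknown adjustment set {self.adjustment!r}")
        if self.reference is None and self.exposure_type == "quintile":
            self.reference = REFERENCE_QUINTILE.get(self.exposure, 5)
        if self.reference is None and self.exposure_type == "score":
            self.reference = 0

    @property
    def covariates(self) -> list:
        return ADJUSTMENT_SETS[self.adjustment]


@dataclass
class AssociationResult:
    """Per-contrast estimates plus trend p for one fitted battery cell."""

    spec: ModelSpec
    estimates: pd.DataFrame      # contrast, n, weighted_pct, OR/beta, CI, p
    trend_p: float = np.nan
    n: int = 0
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def summary(self) -> str:
        head = (f"{self.spec.exposure} -> {self.spec.outcome} "
                f"[{self.spec.outcome_type}, {self.spec.adjustment}], "
                f"n={self.n}, p_trend={self.trend_p:.4g}\n")
        return head + self.estimates.to_string(index=False,
                                               float_format=lambda v: f"{v:.3f}")


def _exposure_column(spec: ModelSpec) -> str:
    if spec.exposure_type == "quintile":
        return f"{spec.exposure}_q"
    if spec.exposure_type == "score":
        return spec.exposure
    return spec.exposure


def _outcome_column(spec: ModelSpec) -> str:
    if spec.outcome_type == "binary":
        return f"{spec.outcome}_abnormal"
    if spec.outcome_type == "ordinal":
        return spec.outcome
    return spec.outcome  # loglinear uses the raw level


def build_design(data: pd.DataFrame, spec: ModelSpec, trend: bool = False,
                 interaction_with: str | None = None, constant: bool = True):
    """Complete-case design matrix, outcome, weights for one model cell.

    Returns ``(y, X, w, exposure_cols, interaction_cols)``.  Exposure enters
    as indicators against the reference level unless ``trend``, in which
    case it is the raw (numeric) level as a single covariate.
    """
    exp_col = _exposure_column(spec)
    out_col = _outcome_column(spec)
    cols = [out_col, exp_col, spec.weights] + list(spec.covariates)
    if interaction_with:
        cols.append(interaction_with)
    missing = [c for c in dict.fromkeys(cols) if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    sub = data[list(dict.fromkeys(cols))].dropna()

    y = sub[out_col].to_numpy(dtype=float)
    w = sub[spec.weights].to_numpy(dtype=float)

    parts = []
    if constant:
        parts.append(pd.DataFrame({"const": np.ones(len(sub))}, index=sub.index))

    exposure_cols: list = []
    if trend:
        vals = sub[exp_col].to_numpy(dtype=float)
        if np.unique(vals).size < 2:
            raise ValueError(f"exposure {exp_col} is constant; trend undefined")
        parts.append(pd.DataFrame({f"{exp_col}_trend": vals}, index=sub.index))
        exposure_cols = [f"{exp_col}_trend"]
    else:
        levels = sorted(pd.unique(sub[exp_col].dropna()))
        ref = spec.reference if spec.reference in levels else levels[0]
        for lev in levels:
            if lev == ref:
                continue
            name = f"{exp_col}[{_fmt_level(lev)}]"
            parts.append(pd.DataFrame(
                {name: (sub[exp_col] == lev).astype(float)}, index=sub.index))
            exposure_cols.append(name)

    for cov in spec.covariates:
        if cov in CATEGORICAL:
            d = pd.get_dummies(sub[cov], prefix=cov, drop_first=True,
                               dtype=float)
            parts.append(d)
        else:
            parts.append(sub[[cov]].astype(float))

    interaction_cols: list = []
    if interaction_with:
        mod = pd.get_dummies(sub[interaction_with], prefix=interaction_with,
                             drop_first=True, dtype=float)
        if mod.shape[1] == 0:
            raise ValueError(f"modifier {interaction_with!r} is constant")
        if interaction_with not in spec.covariates:
            parts.append(mod)
        for ec in exposure_cols:
            base = next(p[ec] for p in parts if ec in getattr(p, "columns", []))
            for mc in mod.columns:
                name = f"{ec}:{mc}"
                parts.append(pd.DataFrame({name: base * mod[mc]},
                                          index=sub.index))
                interaction_cols.append(name)

    X = pd.concat(parts, axis=1)
    return y, X, w, exposure_cols, interaction_cols, sub


def _fmt_level(lev) -> str:
    try:
        return f"Q{int(lev)}"
    except (TypeError, ValueError):
        return str(lev)


def _engine(spec: ModelSpec):
    return {"binary": SurveyLogit, "loglinear": SurveyLogLinear,
            "ordinal": SurveyOrdinal}[spec.outcome_type]


def _fit(spec: ModelSpec, data: pd.DataFrame, trend=False,
         interaction_with=None):
    constant = spec.outcome_type != "ordinal"
    y, X, w, exp_cols, int_cols, sub = build_design(
        data, spec, trend=trend, interaction_with=interaction_with,
        constant=constant)
    model = _engine(spec)(y, X, weights=w)
    return model.fit(), exp_cols, int_cols, sub


def _per_quintile_counts(sub: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    exp_col, out_col = _exposure_column(spec), _outcome_column(spec)
    g = sub.groupby(exp_col)
    n = g.size()
    if spec.outcome_type == "binary":
        wpct = g.apply(lambda d: 100.0 * np.average(d[out_col],
                                                    weights=d[spec.weights]),
                       include_groups=False)
    else:
        wpct = pd.Series(np.nan, index=n.index)
    return pd.DataFrame({"level": n.index, "n": n.to_numpy(),
                         "weighted_pct": wpct.to_numpy()})


def fit_weighted_logistic(spec: ModelSpec, data: pd.DataFrame) -> AssociationResult:
    """Survey-weighted logistic fit; ORs with 95% CI per non-reference level."""
    res, exp_cols, _, sub = _fit(spec, data)
    ors = res.odds_ratios().loc[exp_cols]
    est = ors.reset_index(names="contrast")
    counts = _per_quintile_counts(sub, spec)
    try:
        trend_p = trend_test(spec, data)
    except ValueError:
        trend_p = np.nan
    return AssociationResult(
        spec=spec, estimates=est, trend_p=trend_p, n=res.nobs,
        converged=res.converged,
        diagnostics={**res.diagnostics, "per_level": counts})


def fit_weighted_linear_log(spec: ModelSpec, data: pd.DataFrame) -> AssociationResult:
    """Weighted least squares on natural-log biomarker levels; betas + CIs."""
    spec = ModelSpec(**{**spec.__dict__, "outcome_type": "loglinear"})
    res, exp_cols, _, sub = _fit(spec, data)
    ci = res.conf_int().loc[exp_cols]
    est = pd.DataFrame({"contrast": exp_cols,
                        "beta": res.params[exp_cols].to_numpy(),
                        "lower": ci["lower"].to_numpy(),
                        "upper": ci["upper"].to_numpy(),
                        "p": res.pvalues[exp_cols].to_numpy()})
    try:
        trend_p = trend_test(spec, data)
    except ValueError:
        trend_p = np.nan
    return AssociationResult(spec=spec, estimates=est, trend_p=trend_p,
                             n=res.nobs, converged=res.converged)


def fit_ordinal_logistic(spec: ModelSpec, data: pd.DataFrame) -> AssociationResult:
    """Weighted proportional-odds fit of the abnormal composite; ORs + CIs."""
    spec = ModelSpec(**{**spec.__dict__, "outcome_type": "ordinal"})
    res, exp_cols, _, sub = _fit(spec, data)
    ors = res.odds_ratios().loc[exp_cols]
    est = ors.reset_index(names="contrast")
    try:
        trend_p = trend_test(spec, data)
    except ValueError:
        trend_p = np.nan
    return AssociationResult(spec=spec, estimates=est, trend_p=trend_p,
                             n=res.nobs, converged=res.converged,
                             diagnostics=res.diagnostics)


def trend_test(spec: ModelSpec, data: pd.DataFrame) -> float:
    """Robust Wald p for the exposure entered as a continuous index."""
    res, exp_cols, _, _ = _fit(spec, data, trend=True)
    _, p = res.wald_test(exp_cols[0])
    return p


def interaction_test(spec: ModelSpec, modifier: str, data: pd.DataFrame):
    """Working LRT (Rao-Scott corrected) for exposure x modifier cross terms.

    Returns (statistic, df, p).  A constant modifier is an error; a modifier
    level with zero outcome events is flagged in a warning but the test is
    still computed.
    """
    full, exp_cols, int_cols, sub = _fit(spec, data, interaction_with=modifier)
    if not int_cols:
        raise ValueError(f"modifier {modifier!r} produced no cross terms")
    if spec.outcome_type == "binary":
        out_col = _outcome_column(spec)
        events = sub.groupby(modifier)[out_col].sum()
        if (events == 0).any():
            warnings.warn(f"modifier level(s) with zero events: "
                          f"{events[events == 0].index.tolist()}", stacklevel=2)
    y, X, w, _, _, _ = build_design(
        data, spec, interaction_with=modifier,
        constant=spec.outcome_type != "ordinal")
    reduced = _engine(spec)(y, X.drop(columns=int_cols), weights=w).fit()
    return working_lrt(full, reduced, int_cols)


def stratified_run(spec: ModelSpec, strata: str, data: pd.DataFrame,
                   min_cell_events: int = 5) -> dict:
    """Fit the spec within each stratum; small strata flagged, empty skipped."""
    out = {}
    for level, sub in data.groupby(strata):
        if len(sub) == 0:
            warnings.warn(f"empty stratum {level!r} skipped", stacklevel=2)
            continue
        try:
            res = fit_weighted_logistic(spec, sub) if spec.outcome_type == "binary" \
                else fit_weighted_linear_log(spec, sub)
        except ValueError as exc:
            warnings.warn(f"stratum {level!r} skipped: {exc}", stacklevel=2)
            continue
        if spec.outcome_type == "binary":
            counts = res.diagnostics.get("per_level")
            events = (counts["n"] * counts["weighted_pct"].fillna(0) / 100.0
                      if counts is not None else None)
            res.diagnostics["small_stratum"] = bool(
                events is not None and (events < min_cell_events).any())
        out[level] = res
    return out


def sensitivity_exclude_shift(spec: ModelSpec, data: pd.DataFrame,
                              shift_flags) -> AssociationResult:
    """Refit after removing flagged night-shift/unconventional-timing rows."""
    flags = np.asarray(shift_flags, dtype=bool)
    if flags.all():
        raise ValueError("all participants flagged; empty analysis set")
    kept = data.loc[~flags]
    res = fit_weighted_logistic(spec, kept)
    res.diagnostics["n_removed"] = int(flags.sum())
    return res


def run_full_analysis(data: pd.DataFrame, adjustments=("model1", "model2",
                                                       "model3", "model4"),
                      outcomes=BIOMARKERS, exposures=RAR_PARAMETERS,
                      include_composite: bool = True,
                      include_impaired_score: bool = True) -> pd.DataFrame:
    """Run the whole battery on a scored participant table; tidy results.

    Emits one row per (exposure, outcome, model, contrast) with n, weighted
    percent abnormal, OR, CI and trend p; failed cells are recorded with a
    reason and the run continues.
    """
    rows = []
    for exposure in exposures:
        for outcome in outcomes:
            for adj in adjustments:
                spec = ModelSpec(outcome=outcome, exposure=exposure,
                                 adjustment=adj)
                try:
                    res = fit_weighted_logistic(spec, data)
                except Exception as exc:
                    rows.append({"exposure": exposure, "outcome": outcome,
                                 "model": adj, "contrast": None,
                                 "error": str(exc)})
                    continue
                per_level = res.diagnostics.get("per_level")
                for _, r in res.estimates.iterrows():
                    rows.append({"exposure": exposure, "outcome": outcome,
                                 "model": adj, "contrast": r["contrast"],
                                 "OR": r["OR"], "lower": r["lower"],
                                 "upper": r["upper"], "p": r["p"],
                                 "p_trend": res.trend_p, "n": res.n,
                                 "converged": res.converged, "error": None})
    if include_impaired_score:
        for outcome in outcomes:
            spec = ModelSpec(outcome=outcome, exposure="impaired_score",
                             exposure_type="score", adjustment="model2")
            try:
                res = fit_weighted_logistic(spec, data)
                for _, r in res.estimates.iterrows():
                    rows.append({"exposure": "impaired_score",
                                 "outcome": outcome, "model": "model2",
                                 "contrast": r["contrast"], "OR": r["OR"],
                                 "lower": r["lower"], "upper": r["upper"],
                                 "p": r["p"], "p_trend": res.trend_p,
                                 "n": res.n, "converged": res.converged,
                                 "error": None})
            except Exception as exc:
                rows.append({"exposure": "impaired_score", "outcome": outcome,
                             "model": "model2", "contrast": None,
                             "error": str(exc)})
    if include_composite:
        for exposure in exposures:
            spec = ModelSpec(outcome="abnormal_composite",
                             outcome_type="ordinal", exposure=exposure,
                             adjustment="model2")
            try:
                res = fit_ordinal_logistic(spec, data)
                for _, r in res.estimates.iterrows():
                    rows.append({"exposure": exposure,
                                 "outcome": "abnormal_composite",
                                 "model": "model2", "contrast": r["contrast"],
                                 "OR": r["OR"], "lower": r["lower"],
                                 "upper": r["upper"], "p": r["p"],
                                 "p_trend": res.trend_p, "n": res.n,
                                 "converged": res.converged, "error": None})
            except Exception as exc:
                rows.append({"exposure": exposure,
                             "outcome": "abnormal_composite",
                             "model": "model2", "contrast": None,
                             "error": str(exc)})
    return pd.DataFrame(rows)
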