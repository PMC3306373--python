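"""Ancestry-diabetes epidemiological models.

Implements the phenotype-classification rules, HOMA-IR, ancestry tertiles,
the nested logistic / linear model ladder (base -> +BMI -> +SES ->
+BMI+SES), restricted-cubic-spline risk curves, and the attenuation
decompositions:

* excess odds explained = 100 * (theta1 - theta2) / (theta1 - 1), the
  fraction of the base-model excess odds ratio removed by adjustment; and
* effect explained = 100 * (beta1 - beta2) / beta1, the analogue for a
  linear regression coefficient.

Both are attenuation measures, not counterfactual mediation quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import DecompositionError

MODEL_LADDER = {
    1: [],  # base: age + sex + study
    2: ["bmi"],
    3: ["C(education)", "C(income)", "C(occupation, Treatment('homemaker'))"],
    4: ["bmi", "C(education)", "C(income)", "C(occupation, Treatment('homemaker'))"],
}
MODEL_NAMES = {1: "base", 2: "BMI", 3: "SES", 4: "BMI+SES"}

GLUCOSE_MGDL_PER_MMOL = 18.0
FASTING_GLUCOSE_CUT_MGDL = 126.0
RANDOM_GLUCOSE_CUT_MGDL = 200.0
HBA1C_CUT = 6.5
EARLY_ONSET_AGE = 30.0


# ---------------------------------------------------------------------------
# Phenotype classification and HOMA-IR


def classify_diabetes(record) -> tuple[str, bool]:
    """Classify one phenotype record as ('case'|'control'|'excluded', flagged).

    Case if ANY of: fasting glucose >= 126 mg/dL; non-fasting glucose >=
    200 mg/dL; HbA1c >= 6.5%; on diabetes medication; self-reported
    diagnosis. A case with age at diagnosis < 30 is excluded (type 1
    suspicion; applied outside MEC, whose case definition is
    questionnaire-based). Glucose present without a fasting flag is judged
    against the non-fasting threshold and the record is flagged.
    """

    def get(key):
        v = record.get(key) if hasattr(record, "get") else getattr(record, key, None)
        if v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NA:
            return None
        return v

    flagged = False
    case = False
    glucose = get("glucose")
    fasting = get("fasting")
    if glucose is not None:
        if fasting is None:
            flagged = True
            case = case or glucose >= RANDOM_GLUCOSE_CUT_MGDL
        elif bool(fasting):
            case = case or glucose >= FASTING_GLUCOSE_CUT_MGDL
        else:
            case = case or glucose >= RANDOM_GLUCOSE_CUT_MGDL
    hba1c = get("hba1c")
    if hba1c is not None:
        case = case or hba1c >= HBA1C_CUT
    if get("on_treatment"):
        case = True
    if get("self_report") or get("diabetes"):
        case = True

    if not case:
        return "control", flagged
    aad = get("age_at_diagnosis")
    study = get("study")
    if aad is not None and aad < EARLY_ONSET_AGE and study != "MEC":
        return "excluded", flagged
    return "case", flagged


def classify_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised classify_diabetes; adds 'dm_status' and 'dm_flagged' columns."""
    out = df.copy()
    res = [classify_diabetes(row) for row in df.to_dict("records")]
    out["dm_status"] = [r[0] for r in res]
    out["dm_flagged"] = [r[1] for r in res]
    return out


def homa_ir(glucose, insulin, glucose_unit: str = "mmol/L"):
    """HOMA-IR = fasting glucose [mmol/L] x fasting insulin [mU/L] / 22.5."""
    glucose = np.asarray(glucose, dtype=float)
    insulin = np.asarray(insulin, dtype=float)
    if np.any(glucose <= 0) or np.any(insulin <= 0):
        raise ValueError("glucose and insulin must be positive")
    if glucose_unit == "mg/dL":
        glucose = glucose / GLUCOSE_MGDL_PER_MMOL
    elif glucose_unit != "mmol/L":
        raise ValueError(f"unknown glucose unit {glucose_unit!r}")
    out = glucose * insulin / 22.5
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Tertiles


@dataclass
class Tertiles:
    cuts: tuple[float, float]
    labels: np.ndarray  # 1/2/3 per individual
    cuts_percent: tuple[float, float]  # cut points on the 0-100 scale, 1 decimal


def ancestry_tertiles(values) -> Tertiles:
    """Empirical tertiles of an ancestry distribution; ties go to the lower tertile."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(np.unique(x)) < 3:
        raise DecompositionError("need at least 3 distinct ancestry values for tertiles")
    c1, c2 = np.quantile(x, [1 / 3, 2 / 3])
    if c1 == c2:
        raise DecompositionError("degenerate ancestry distribution: tertile cuts coincide")
    vals = np.asarray(values, dtype=float)
    labels = 1 + (vals > c1).astype(int) + (vals > c2).astype(int)
    # Report cut points on the 0-100 percent scale whichever scale came in.
    scale = 1.0 if np.nanmax(x) > 1.5 else 100.0
    return Tertiles(
        cuts=(float(c1), float(c2)),
        labels=labels,
        cuts_percent=(round(scale * c1, 1), round(scale * c2, 1)),
    )


# ---------------------------------------------------------------------------
# Decomposition formulas


def excess_odds_explained(theta1: float, theta2: float) -> float:
    """Percent of the base-model excess odds removed by adjustment."""
    if theta1 <= 1:
        raise DecompositionError(
            "excess odds explained is undefined when the base odds ratio <= 1"
        )
    return 100.0 * (theta1 - theta2) / (theta1 - 1.0)


def effect_explained(beta1: float, beta2: float) -> float:
    """Percent of the base-model regression coefficient removed by adjustment."""
    if beta1 == 0:
        raise DecompositionError("effect explained is undefined when the base coefficient is 0")
    return 100.0 * (beta1 - beta2) / beta1


# ---------------------------------------------------------------------------
# Model ladder fits


def _ladder_formula(outcome: str, model_id: int, df: pd.DataFrame, tertile_term: str) -> str:
    base = ["age", "C(sex)"]
    if df["study"].nunique() > 1:
        base.append("C(study)")
    terms = [tertile_term] + base + MODEL_LADDER[model_id]
    return f"{outcome} ~ " + " + ".join(terms)


def _fit_one(df, outcome, model_id, family):
    formula = _ladder_formula(outcome, model_id, df, "C(tertile, Treatment(1))")
    if family == "logistic":
        fit = smf.glm(formula, data=df, family=sm.families.Binomial()).fit()
    else:
        fit = smf.ols(formula, data=df).fit()
    trend_formula = _ladder_formula(outcome, model_id, df, "tertile")
    if family == "logistic":
        trend_fit = smf.glm(trend_formula, data=df, family=sm.families.Binomial()).fit()
    else:
        trend_fit = smf.ols(trend_formula, data=df).fit()
    return fit, float(trend_fit.pvalues["tertile"])


def _tertile_rows(fit, trend_p, model_id, family):
    rows = []
    separated = bool(np.any(np.abs(fit.params) > 15)) if family == "logistic" else False
    for tert in (2, 3):
        name = f"C(tertile, Treatment(1))[T.{tert}]"
        beta = float(fit.params[name])
        se = float(fit.bse[name])
        p = float(fit.pvalues[name])
        lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
        if family == "logistic":
            est, lo, hi = np.exp(beta), np.exp(lo), np.exp(hi)
            if separated:
                lo, hi = 0.0, np.inf
        else:
            est = beta
        rows.append(
            {
                "model_id": model_id,
                "model": MODEL_NAMES[model_id],
                "tertile": tert,
                "estimate": float(est),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "p_value": p,
                "trend_p": trend_p,
                "beta": beta,
                "separated": separated,
            }
        )
    return rows


def _add_percent_explained(result: pd.DataFrame, family: str) -> pd.DataFrame:
    base = result[result["model_id"] == 1].set_index("tertile")
    pct = []
    for row in result.itertuples():
        if row.model_id == 1:
            pct.append(np.nan)
            continue
        if family == "logistic":
            theta1 = float(base.loc[row.tertile, "estimate"])
            try:
                pct.append(excess_odds_explained(theta1, row.estimate))
            except DecompositionError:
                pct.append(np.nan)
        else:
            b1 = float(base.loc[row.tertile, "beta"])
            try:
                pct.append(effect_explained(b1, row.beta))
            except DecompositionError:
                pct.append(np.nan)
    result = result.copy()
    result["percent_explained"] = pct
    return result


def fit_logistic_tertiles(
    df: pd.DataFrame,
    outcome: str = "diabetes",
    ancestry_col: str = "african_ancestry",
    models=(1, 2, 3, 4),
) -> pd.DataFrame:
    """Tertile odds-ratio ladder for a binary outcome.

    Fits the nested covariate models (1: age+sex+study; 2: +BMI; 3: +SES;
    4: +BMI+SES) with ancestry tertile 1 as reference; returns one row per
    (model, tertile in {2, 3}) with OR, Wald 95% CI, comparison and trend
    p-values, and percent excess odds explained relative to model 1.
    """
    work = df.copy()
    tert = ancestry_tertiles(work[ancestry_col].to_numpy())
    work["tertile"] = tert.labels
    rows = []
    for mid in models:
        sub = _complete_cases(work, outcome, mid)
        fit, trend_p = _fit_one(sub, outcome, mid, "logistic")
        rows.extend(_tertile_rows(fit, trend_p, mid, "logistic"))
    result = pd.DataFrame(rows)
    result.attrs["tertile_cuts_percent"] = tert.cuts_percent
    return _add_percent_explained(result, "logistic")


def _complete_cases(df: pd.DataFrame, outcome: str, model_id: int) -> pd.DataFrame:
    cols = [outcome, "tertile", "age", "sex"]
    if df["study"].nunique() > 1:
        cols.append("study")
    if model_id in (2, 4):
        cols.append("bmi")
    if model_id in (3, 4):
        cols += ["education", "income", "occupation"]
    return df.dropna(subset=[c for c in cols if c in df.columns])


def fit_trait_models(
    df: pd.DataFrame,
    trait: str,
    ancestry_col: str = "african_ancestry",
    models=(1, 2, 3, 4),
    exclude_treated: bool = True,
) -> pd.DataFrame:
    """Tertile mean-difference ladder for a quantitative trait.

    Mirrors fit_logistic_tertiles with linear models; ``exclude_treated``
    drops individuals on diabetes treatment first (treatment shifts trait
    levels directly). Tertile cuts are recomputed on the analysis sample.
    """
    work = df.copy()
    if exclude_treated and "on_treatment" in work:
        work = work[work["on_treatment"].fillna(0).astype(float) == 0]
    work = work.dropna(subset=[trait])
    if len(work) == 0:
        raise DecompositionError(f"no individuals left for trait {trait!r} after exclusions")
    tert = ancestry_tertiles(work[ancestry_col].to_numpy())
    work["tertile"] = tert.labels
    rows = []
    for mid in models:
        sub = _complete_cases(work, trait, mid)
        if len(sub) == 0:
            raise DecompositionError(f"empty stratum for trait {trait!r}, model {mid}")
        fit, trend_p = _fit_one(sub, trait, mid, "linear")
        rows.extend(_tertile_rows(fit, trend_p, mid, "linear"))
    result = pd.DataFrame(rows)
    result.attrs["tertile_cuts_percent"] = tert.cuts_percent
    result.attrs["n"] = len(work)
    return _add_percent_explained(result, "linear")


def variance_explained(
    df: pd.DataFrame, trait: str, term: str, base_terms=("age", "C(sex)", "C(study)")
) -> float:
    """Incremental coefficient of determination of ``term`` over the base model.

    Returns R2(base + term) - R2(base) in percent, the conventional measure
    of how much trait variance a covariate accounts for beyond age, sex and
    study.
    """
    work = df.dropna(subset=[trait])
    base_terms = [t for t in base_terms if not (t == "C(study)" and work["study"].nunique() < 2)]
    base = smf.ols(f"{trait} ~ " + " + ".join(base_terms), data=work).fit()
    full = smf.ols(f"{trait} ~ " + " + ".join(list(base_terms) + [term]), data=work).fit()
    return 100.0 * float(full.rsquared - base.rsquared)


# ---------------------------------------------------------------------------
# Restricted cubic splines


def rcs_knots(x, percentiles=(5, 35, 65, 95)) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.percentile(x[~np.isnan(x)], percentiles)


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted (natural) cubic spline design columns.

    Truncated-power construction: with K knots t_1 < ... < t_K the basis is
    [x, s_1(x), ..., s_{K-2}(x)] where

        s_j(x) = (x - t_j)+^3
                 - (x - t_{K-1})+^3 (t_K - t_j)/(t_K - t_{K-1})
                 + (x - t_K)+^3 (t_{K-1} - t_j)/(t_K - t_{K-1}),

    which is linear beyond the boundary knots. K knots give K-1 columns
    (4 knots -> 3 columns).
    """
    x = np.asarray(x, dtype=float)
    knots = np.sort(np.asarray(knots, dtype=float))
    if len(knots) < 4:
        raise ValueError("restricted cubic splines need at least 4 knots")
    if len(np.unique(knots)) != len(knots):
        raise ValueError("duplicate knots")
    t = knots
    K = len(t)

    def plus3(v):
        return np.clip(v, 0, None) ** 3

    cols = [x]
    denom = t[K - 1] - t[K - 2]
    for j in range(K - 2):
        s = (
            plus3(x - t[j])
            - plus3(x - t[K - 2]) * (t[K - 1] - t[j]) / denom
            + plus3(x - t[K - 1]) * (t[K - 2] - t[j]) / denom
        )
        cols.append(s)
    return np.column_stack(cols)


def rcs_logistic_curve(
    df: pd.DataFrame,
    outcome: str = "diabetes",
    ancestry_col: str = "african_ancestry",
    extra_terms=("age", "C(sex)", "C(study)"),
    knot_percentiles=(5, 35, 65, 95),
    ref_percentile: float = 5.0,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Odds-ratio risk curve over ancestry from a restricted-cubic-spline fit.

    The curve is exp(f(x) - f(x_ref)) with x_ref at ``ref_percentile`` of
    the ancestry distribution; the 95% CI comes from the delta method on
    the spline-coefficient contrast.
    """
    work = df.dropna(subset=[outcome, ancestry_col]).copy()
    x = work[ancestry_col].to_numpy(dtype=float)
    knots = rcs_knots(x, knot_percentiles)
    basis = rcs_basis(x, knots)
    for j in range(basis.shape[1]):
        work[f"rcs{j}"] = basis[:, j]
    spline_terms = [f"rcs{j}" for j in range(basis.shape[1])]
    extra = [t for t in extra_terms if not (t == "C(study)" and work["study"].nunique() < 2)]
    formula = f"{outcome} ~ " + " + ".join(spline_terms + extra)
    fit = smf.glm(formula, data=work, family=sm.families.Binomial()).fit()

    if grid is None:
        grid = np.linspace(np.percentile(x, 1), np.percentile(x, 99), 101)
    ref = float(np.percentile(x, ref_percentile))
    bg = rcs_basis(grid, knots)
    br = rcs_basis(np.array([ref]), knots)
    contrast = bg - br  # (G, ncols)
    coefs = np.array([fit.params[t] for t in spline_terms])
    cov = fit.cov_params().loc[spline_terms, spline_terms].to_numpy()
    eta = contrast @ coefs
    se = np.sqrt(np.einsum("gi,ij,gj->g", contrast, cov, contrast))
    zq = stats.norm.ppf(0.975)
    return pd.DataFrame(
        {
            "ancestry": grid,
            "odds_ratio": np.exp(eta),
            "ci_low": np.exp(eta - zq * se),
            "ci_high": np.exp(eta + zq * se),
        }
    )
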