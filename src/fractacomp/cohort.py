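"""Cohort assembly and diagnostic-model building.

Implements the study workflow on a subject-level table: apply the IDF
metabolic-syndrome label, split into training/test sets, screen
candidate predictors with univariate logistic regression (p < 0.1),
prune multicollinearity with VIF and Spearman correlation, and fit
multivariable logistic models (clinical, radiological, combined).

Continuous predictors are z-scored on training-set statistics before any
fit, so reported odds ratios are per-SD; binary predictors are left on
their 0/1 scale.  Maximum-likelihood fits go through statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RADIOLOGICAL_PREDICTORS",
    "DEFAULT_CLINICAL_CANDIDATES",
    "WAIST_CUTOFFS_CM",
    "ModelFit",
    "label_mets",
    "split_cohort",
    "univariate_screen",
    "vif_scores",
    "prune_collinearity",
    "fit_logistic",
    "build_three_models",
    "predict_prob",
]

#: the three imaging features of the radiological model
RADIOLOGICAL_PREDICTORS = ["imr", "imat_fd", "imat_multifractal_range"]

#: clinical variables offered to the univariate screen by default
DEFAULT_CLINICAL_CANDIDATES = [
    "age", "height_m", "weight_kg", "waist_cm", "hdl_c", "triglyceride",
    "total_cholesterol", "diabetes", "hypertension", "smoking", "alcohol",
]

#: ethnicity-specific central-obesity waist cutoffs, cm
WAIST_CUTOFFS_CM = {"male": 90.0, "female": 80.0}


# ---------------------------------------------------------------------------
# Outcome label
# ---------------------------------------------------------------------------

def label_mets(record: pd.Series | dict, waist_cutoffs: Dict[str, float] = WAIST_CUTOFFS_CM) -> int:
    """IDF metabolic-syndrome label for one subject.

    Obesity gate: waist >= sex-specific cutoff OR BMI > 30 kg/m^2.
    Additional criteria (>= 2 required): fasting glucose >= 5.6 mmol/L or
    diabetes history; SBP/DBP >= 130/80 mmHg or antihypertensive
    treatment; triglyceride >= 1.7 mmol/L or treatment; HDL-C < 1.03 (men)
    / < 1.29 (women) mmol/L or treatment.  Missing optional measurements
    (glucose, BP) fall back on the corresponding history flag.
    """
    rec = dict(record)

    def has(key):
        v = rec.get(key)
        return v is not None and not (isinstance(v, float) and np.isnan(v))

    if not (has("waist_cm") or has("bmi")):
        raise ValueError("obesity gate needs waist_cm or bmi")
    sex = rec.get("sex", "male")
    gate = False
    if has("waist_cm"):
        gate |= rec["waist_cm"] >= waist_cutoffs[sex]
    if has("bmi"):
        gate |= rec["bmi"] > 30.0
    if not gate:
        return 0

    criteria = 0
    criteria += int((has("fasting_glucose") and rec["fasting_glucose"] >= 5.6) or rec.get("diabetes", 0) == 1)
    bp = (has("sbp") and rec["sbp"] >= 130) or (has("dbp") and rec["dbp"] >= 80)
    criteria += int(bp or rec.get("hypertension", 0) == 1)
    criteria += int((has("triglyceride") and rec["triglyceride"] >= 1.7) or rec.get("tg_treatment", 0) == 1)
    hdl_cut = 1.03 if sex == "male" else 1.29
    criteria += int((has("hdl_c") and rec["hdl_c"] < hdl_cut) or rec.get("hdl_treatment", 0) == 1)
    return int(criteria >= 2)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_cohort(
    table: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratify_by_outcome: bool = True,
    outcome: str = "mets_label",
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Random train/test partition with per-stratum round-to-nearest sizes.

    With outcome strata of 93 and 91 subjects at fraction 0.7 this yields
    round(65.1) + round(63.7) = 129 training and 55 test subjects.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    strata = table.groupby(outcome).groups if stratify_by_outcome else {None: table.index}
    train_idx: List = []
    for _, idx in sorted(strata.items(), key=lambda kv: str(kv[0])):
        idx = np.asarray(idx)
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))  # round half up
        if n_train == 0 or n_train == len(idx):
            raise ValueError(f"stratum of size {len(idx)} too small for a nonempty split")
        perm = rng.permutation(len(idx))
        train_idx.extend(idx[perm[:n_train]])
    train_mask = table.index.isin(train_idx)
    return table.loc[train_mask].copy(), table.loc[~train_mask].copy()


# ---------------------------------------------------------------------------
# Screening and collinearity pruning
# ---------------------------------------------------------------------------

def _is_binary(x: np.ndarray) -> bool:
    return np.isin(np.unique(x[~np.isnan(x)]), (0, 1)).all()


def univariate_screen(
    train: pd.DataFrame,
    outcome: str = "mets_label",
    predictors: Optional[Sequence[str]] = None,
    alpha: float = 0.1,
) -> pd.DataFrame:
    """One single-predictor logistic fit per variable; retain Wald p < alpha.

    Continuous predictors are z-scored on the training mean/SD so the ORs
    are per-SD.  Constant predictors are flagged, not fit.  Returns a
    DataFrame indexed by variable with columns or, ci_low, ci_high, p,
    retained, flagged.
    """
    y = train[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) != 2:
        raise ValueError("outcome must have both classes present")
    predictors = list(predictors) if predictors is not None else [
        c for c in train.columns
        if c != outcome and pd.api.types.is_numeric_dtype(train[c])
    ]
    rows = []
    for var in predictors:
        x = train[var].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            rows.append((var, np.nan, np.nan, np.nan, np.nan, False, True))
            continue
        if not _is_binary(x):
            x = (x - np.nanmean(x)) / np.nanstd(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        coef, se, p = res.params[1], res.bse[1], res.pvalues[1]
        rows.append((var, np.exp(coef), np.exp(coef - 1.96 * se),
                     np.exp(coef + 1.96 * se), p, bool(p < alpha), False))
    out = pd.DataFrame(rows, columns=["variable", "or", "ci_low", "ci_high",
                                      "p", "retained", "flagged"]).set_index("variable")
    out.attrs["alpha"] = alpha
    return out


def vif_scores(train: pd.DataFrame, predictors: Sequence[str], cap: float = 1e12) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j).

    R^2_j comes from the OLS regression of predictor j on the others (with
    intercept).  Exactly collinear predictors are reported at ``cap``.
    """
    predictors = list(predictors)
    if len(predictors) < 2:
        raise ValueError("VIF needs at least 2 predictors")
    X = train[predictors].to_numpy(dtype=float)
    if (X.std(axis=0) == 0).any():
        raise ValueError("constant predictor in VIF computation")
    vals = {}
    for j, var in enumerate(predictors):
        yj = X[:, j]
        Xo = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(yj, Xo).fit().rsquared
        vals[var] = cap if r2 >= 1 - 1 / cap else 1.0 / (1.0 - r2)
    return pd.Series(vals, name="vif")


def prune_collinearity(
    candidates: pd.DataFrame,
    train: pd.DataFrame,
    vif_max: float = 10.0,
    r_max: float = 0.8,
    rule: str = "or",
) -> List[str]:
    """Sequentially remove collinear predictors until VIF and |rho| are clean.

    ``candidates`` is the univariate_screen output; only retained
    variables enter.  Each iteration recomputes VIF and pairwise Spearman
    |rho|; while any variable violates (VIF > vif_max) OR/AND (|rho| >
    r_max, per ``rule``), one is removed — the highest-VIF violator first,
    and within an offending correlation pair the member with the larger
    univariate p.  Terminates in at most len(candidates) iterations.
    """
    if rule not in ("or", "and"):
        raise ValueError("rule must be 'or' or 'and'")
    keep = [v for v in candidates.index if candidates.loc[v, "retained"]]
    pvals = candidates["p"]
    for _ in range(len(keep)):
        if len(keep) < 2:
            break
        vif = vif_scores(train, keep)
        rho = train[keep].corr(method="spearman").abs()
        np.fill_diagonal(rho.values, 0.0)
        vif_bad = set(vif[vif > vif_max].index)
        corr_bad = set()
        worst_pair: Optional[Tuple[str, str]] = None
        if (rho.values > r_max).any():
            i, j = np.unravel_index(np.argmax(rho.values), rho.shape)
            worst_pair = (rho.index[i], rho.columns[j])
            for a in keep:
                if (rho.loc[a] > r_max).any():
                    corr_bad.add(a)
        offenders = (vif_bad | corr_bad) if rule == "or" else (vif_bad & corr_bad)
        if not offenders:
            break
        if vif_bad & offenders:
            drop = max(vif_bad & offenders, key=lambda v: vif.loc[v])
        else:
            a, b = worst_pair
            drop = a if pvals.get(a, 0) >= pvals.get(b, 0) else b
        keep.remove(drop)
    if not keep:
        raise ValueError("collinearity pruning removed every candidate")
    return keep


# ---------------------------------------------------------------------------
# Multivariable fitting and prediction
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """A fitted multivariable logistic model with per-SD standardization."""

    predictors: List[str]
    coefficients: Dict[str, float]
    standard_errors: Dict[str, float]
    odds_ratios: Dict[str, float]
    ci: Dict[str, Tuple[float, float]]
    p_values: Dict[str, float]
    intercept: float
    converged: bool
    standardization: Dict[str, Tuple[float, float]]  # var -> (mean, sd); identity for binary
    training_set: str = ""

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            (v, self.coefficients[v], self.standard_errors[v], self.odds_ratios[v],
             self.ci[v][0], self.ci[v][1], self.p_values[v])
            for v in self.predictors
        ]
        return pd.DataFrame(rows, columns=["variable", "coef", "se", "or",
                                           "ci_low", "ci_high", "p"]).set_index("variable")


def _design(df: pd.DataFrame, predictors: Sequence[str],
            standardization: Dict[str, Tuple[float, float]]) -> np.ndarray:
    X = np.empty((len(df), len(predictors)))
    for j, v in enumerate(predictors):
        m, s = standardization[v]
        X[:, j] = (df[v].to_numpy(dtype=float) - m) / s
    return X


def fit_logistic(train: pd.DataFrame, predictors: Sequence[str],
                 outcome: str = "mets_label", training_set: str = "train") -> ModelFit:
    """Maximum-likelihood multivariable logistic fit (Newton/IRLS).

    Raises on non-convergence or perfect separation rather than returning
    a silently unusable fit.
    """
    predictors = list(predictors)
    y = train[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) != 2:
        raise ValueError("outcome must have both classes present")
    if len(train) <= len(predictors) + 1:
        raise ValueError("too few subjects for the number of predictors")
    standardization = {}
    for v in predictors:
        x = train[v].to_numpy(dtype=float)
        if _is_binary(x):
            standardization[v] = (0.0, 1.0)
        else:
            sd = float(np.std(x))
            if sd == 0:
                raise ValueError(f"constant predictor {v!r}")
            standardization[v] = (float(np.mean(x)), sd)
    X = sm.add_constant(_design(train, predictors, standardization))
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
            raise RuntimeError(f"perfect separation in logistic fit: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError("logistic fit did not converge")
    coefs = dict(zip(predictors, res.params[1:]))
    ses = dict(zip(predictors, res.bse[1:]))
    return ModelFit(
        predictors=predictors,
        coefficients={v: float(c) for v, c in coefs.items()},
        standard_errors={v: float(s) for v, s in ses.items()},
        odds_ratios={v: float(np.exp(c)) for v, c in coefs.items()},
        ci={v: (float(np.exp(coefs[v] - 1.96 * ses[v])),
                float(np.exp(coefs[v] + 1.96 * ses[v]))) for v in predictors},
        p_values={v: float(p) for v, p in zip(predictors, res.pvalues[1:])},
        intercept=float(res.params[0]),
        converged=True,
        standardization=standardization,
        training_set=training_set,
    )


def predict_prob(fit: ModelFit, records: pd.DataFrame | pd.Series | dict) -> np.ndarray | float:
    """Predicted MetS probability under a fitted model.

    Applies the training standardization to each predictor before the
    linear predictor; scalar input gives a scalar probability.
    """
    if not fit.converged:
        raise RuntimeError("cannot predict from a non-converged fit")
    scalar = not isinstance(records, pd.DataFrame)
    df = pd.DataFrame([dict(records)]) if scalar else records
    missing = [v for v in fit.predictors if v not in df.columns or df[v].isna().any()]
    if missing:
        raise ValueError(f"missing predictor values: {missing}")
    eta = fit.intercept + _design(df, fit.predictors, fit.standardization) @ np.array(
        [fit.coefficients[v] for v in fit.predictors]
    )
    prob = 1.0 / (1.0 + np.exp(-eta))
    return float(prob[0]) if scalar else prob


def build_three_models(
    train: pd.DataFrame,
    outcome: str = "mets_label",
    clinical_candidates: Optional[Sequence[str]] = None,
    alpha: float = 0.1,
    vif_max: float = 10.0,
    r_max: float = 0.8,
) -> Dict[str, ModelFit]:
    """Fit the clinical, radiological and combined models on one training set.

    * radiological: exactly {IMR, IMAT FD, IMAT multifractal range};
    * clinical: screened (p < alpha) and collinearity-pruned clinical
      candidates;
    * combined: the union of the two predictor sets.
    """
    clinical_candidates = list(clinical_candidates) if clinical_candidates is not None \
        else [c for c in DEFAULT_CLINICAL_CANDIDATES if c in train.columns]
    screen = univariate_screen(train, outcome, clinical_candidates, alpha)
    clinical = prune_collinearity(screen, train, vif_max=vif_max, r_max=r_max)
    models = {
        "clinical": fit_logistic(train, clinical, outcome),
        "radiological": fit_logistic(train, RADIOLOGICAL_PREDICTORS, outcome),
        "combined": fit_logistic(train, clinical + RADIOLOGICAL_PREDICTORS, outcome),
    }
    for m in models.values():
        m.training_set = "train"
    return models
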