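"""MetS labeling, cohort splitting, screening, pruning and logistic fits."""

import numpy as np
import pandas as pd
import pytest

from fractacomp.cohort import (
    RADIOLOGICAL_PREDICTORS,
    build_three_models,
    fit_logistic,
    label_mets,
    predict_prob,
    prune_collinearity,
    split_cohort,
    univariate_screen,
    vif_scores,
)
from fractacomp.simulate import CohortGenSpec, synth_cohort


# ---------------------------------------------------------------------------
# IDF label
# ---------------------------------------------------------------------------

def test_label_positive_with_two_criteria():
    rec = {"sex": "male", "bmi": 31.0, "diabetes": 1, "triglyceride": 1.8,
           "hdl_c": 1.5, "hypertension": 0}
    assert label_mets(rec) == 1


def test_label_negative_with_single_criterion():
    rec = {"sex": "male", "bmi": 31.0, "diabetes": 1, "triglyceride": 1.0,
           "hdl_c": 1.5, "hypertension": 0}
    assert label_mets(rec) == 0


def test_label_negative_when_obesity_gate_fails():
    rec = {"sex": "male", "waist_cm": 85.0, "bmi": 24.0, "diabetes": 0,
           "triglyceride": 1.0, "hdl_c": 1.5, "hypertension": 0}
    assert label_mets(rec) == 0


def test_label_sex_specific_cutoffs():
    base = {"bmi": 25.0, "diabetes": 1, "triglyceride": 2.0, "hdl_c": 1.5, "hypertension": 0}
    assert label_mets({**base, "sex": "female", "waist_cm": 81.0}) == 1
    assert label_mets({**base, "sex": "male", "waist_cm": 81.0}) == 0
    with pytest.raises(ValueError):
        label_mets({"sex": "male", "diabetes": 1})


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def test_split_reproduces_129_55():
    df = pd.DataFrame({"mets_label": [1] * 93 + [0] * 91})
    train, test = split_cohort(df, 0.7, seed=42)
    assert len(train) == 129 and len(test) == 55
    assert train["mets_label"].sum() == 65 and test["mets_label"].sum() == 28


def test_split_small_exact_arithmetic_and_determinism():
    df = pd.DataFrame({"mets_label": [0] * 10, "x": range(10)})
    tr, te = split_cohort(df, 0.7, seed=1)
    assert len(tr) == 7 and len(te) == 3
    tr2, te2 = split_cohort(df, 0.7, seed=1)
    assert tr.index.tolist() == tr2.index.tolist()
    # partition
    assert sorted(tr.index.tolist() + te.index.tolist()) == list(range(10))
    with pytest.raises(ValueError):
        split_cohort(pd.DataFrame({"mets_label": [0, 1]}), 0.7, seed=0)


# ---------------------------------------------------------------------------
# Univariate screen
# ---------------------------------------------------------------------------

def _two_by_two(a, b, c, d):
    """outcome=1 rows: a exposed, b unexposed; outcome=0: c exposed, d unexposed."""
    return pd.DataFrame({
        "x": [1] * a + [0] * b + [1] * c + [0] * d,
        "mets_label": [1] * (a + b) + [0] * (c + d),
    })


def test_screen_binary_or_equals_cross_product_ratio():
    df = _two_by_two(30, 15, 15, 30)
    res = univariate_screen(df, predictors=["x"])
    assert res.loc["x", "or"] == pytest.approx(4.0, rel=1e-4)
    assert bool(res.loc["x", "retained"])


def test_screen_no_association_not_retained():
    df = _two_by_two(20, 20, 20, 20)
    res = univariate_screen(df, predictors=["x"])
    assert res.loc["x", "or"] == pytest.approx(1.0, abs=1e-8)
    assert not bool(res.loc["x", "retained"])


def test_screen_constant_predictor_flagged(rng):
    df = pd.DataFrame({"c": np.ones(40), "mets_label": rng.integers(0, 2, 40)})
    df.loc[0, "mets_label"] = 0
    df.loc[1, "mets_label"] = 1
    res = univariate_screen(df, predictors=["c"])
    assert bool(res.loc["c", "flagged"]) and not bool(res.loc["c", "retained"])


# ---------------------------------------------------------------------------
# VIF and pruning
# ---------------------------------------------------------------------------

def test_vif_orthogonal_predictors(rng):
    n = 64
    x1 = np.tile([1.0, -1.0], n // 2)
    x2 = np.repeat([1.0, -1.0], n // 2)
    df = pd.DataFrame({"x1": x1, "x2": x2, "x3": x1 * x2})
    v = vif_scores(df, ["x1", "x2", "x3"])
    assert np.allclose(v, 1.0)


def test_vif_correlated_pair_closed_form(rng):
    n = 400
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    # orthonormalize empirically so the sample correlation is exactly 0.8
    z1 = (z1 - z1.mean()) / z1.std()
    z2 = z2 - z2.mean() - np.dot(z2 - z2.mean(), z1) / np.dot(z1, z1) * z1
    z2 = z2 / z2.std()
    x2 = 0.8 * z1 + 0.6 * z2
    df = pd.DataFrame({"x1": z1, "x2": x2})
    v = vif_scores(df, ["x1", "x2"])
    assert v["x1"] == pytest.approx(1 / (1 - 0.64), abs=1e-3)
    assert v["x2"] == pytest.approx(2.778, abs=1e-3)


def test_vif_exact_collinearity_capped(rng):
    n = 50
    x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
    df = pd.DataFrame({"x1": x1, "x2": x2, "x3": x1 + x2})
    v = vif_scores(df, ["x1", "x2", "x3"])
    assert v["x3"] > 1e6


def _screen_frame(names, ps):
    return pd.DataFrame({
        "p": ps, "retained": [True] * len(names),
        "or": 2.0, "ci_low": 1.0, "ci_high": 4.0, "flagged": False,
    }, index=pd.Index(names, name="variable"))


def test_prune_clean_set_unchanged(rng):
    n = 200
    df = pd.DataFrame(rng.standard_normal((n, 3)), columns=["a", "b", "c"])
    out = prune_collinearity(_screen_frame(["a", "b", "c"], [0.01, 0.02, 0.03]), df)
    assert out == ["a", "b", "c"]


def test_prune_removes_duplicated_column(rng):
    n = 200
    a = rng.standard_normal(n)
    df = pd.DataFrame({"a": a, "dup": a.copy(), "b": rng.standard_normal(n)})
    out = prune_collinearity(_screen_frame(["a", "dup", "b"], [0.01, 0.05, 0.02]), df)
    assert sorted(out) in (["a", "b"], ["b", "dup"])
    assert len(out) == 2


def test_prune_postcondition_on_seeded_input(rng):
    n = 300
    base = rng.standard_normal((n, 3))
    df = pd.DataFrame({
        "a": base[:, 0],
        "b": 0.95 * base[:, 0] + 0.3 * rng.standard_normal(n),
        "c": base[:, 1],
        "d": base[:, 1] + base[:, 2],
        "e": base[:, 2],
    })
    names = list(df.columns)
    out = prune_collinearity(_screen_frame(names, [0.01, 0.06, 0.02, 0.08, 0.03]), df)
    if len(out) >= 2:
        v = vif_scores(df, out)
        assert (v <= 10).all()
        rho = df[out].corr(method="spearman").abs().values
        np.fill_diagonal(rho, 0)
        assert rho.max() <= 0.8


# ---------------------------------------------------------------------------
# Multivariable fit and prediction
# ---------------------------------------------------------------------------

def test_fit_logistic_matches_cross_product_ratio():
    df = _two_by_two(30, 15, 15, 30)
    fit = fit_logistic(df, ["x"])
    assert fit.coefficients["x"] == pytest.approx(np.log(4.0), abs=1e-6)
    # OR/CI algebra invariants
    assert fit.odds_ratios["x"] == pytest.approx(np.exp(fit.coefficients["x"]))
    lo, hi = fit.ci["x"]
    assert lo == pytest.approx(np.exp(fit.coefficients["x"] - 1.96 * fit.standard_errors["x"]))
    assert hi == pytest.approx(np.exp(fit.coefficients["x"] + 1.96 * fit.standard_errors["x"]))


def test_fit_logistic_null_model_small_coefficients(rng):
    n = 2000
    df = pd.DataFrame({
        "a": rng.standard_normal(n),
        "b": rng.integers(0, 2, n).astype(float),
        "mets_label": rng.integers(0, 2, n),
    })
    fit = fit_logistic(df, ["a", "b"])
    assert abs(fit.coefficients["a"]) < 0.15
    assert abs(fit.coefficients["b"]) < 0.3


def test_fit_logistic_perfect_separation_raises():
    df = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)],
                       "mets_label": np.r_[np.zeros(20), np.ones(20)].astype(int)})
    with pytest.raises(RuntimeError, match="separation"):
        fit_logistic(df, ["x"])


def test_predict_prob_closed_forms(rng):
    n = 120
    df = pd.DataFrame({
        "a": rng.standard_normal(n),
        "mets_label": rng.integers(0, 2, n),
    })
    fit = fit_logistic(df, ["a"])
    # round-trip: predict_prob on training rows equals in-sample fitted probs
    import statsmodels.api as sm

    x = (df["a"] - df["a"].mean()) / df["a"].std()
    ref = sm.Logit(df["mets_label"], sm.add_constant(np.asarray(x))).fit(disp=0)
    assert np.allclose(predict_prob(fit, df), ref.predict(), atol=1e-6)
    # hand closed forms
    fit.intercept = 0.0
    fit.coefficients["a"] = 0.0
    assert predict_prob(fit, {"a": 1.23}) == pytest.approx(0.5)
    fit.intercept = 0.7
    assert predict_prob(fit, {"a": 0.0}) == pytest.approx(1 / (1 + np.exp(-0.7)))
    fit.coefficients["a"] = 1.0
    p1 = predict_prob(fit, {"a": 0.5})
    p2 = predict_prob(fit, {"a": 1.5})
    assert p2 > p1
    with pytest.raises(ValueError, match="missing"):
        predict_prob(fit, {"b": 1.0})


def test_build_three_models_structure():
    df = synth_cohort(seed=7)
    train, _ = split_cohort(df, 0.7, seed=7)
    models = build_three_models(train)
    assert models["radiological"].predictors == RADIOLOGICAL_PREDICTORS
    assert not set(models["clinical"].predictors) & set(RADIOLOGICAL_PREDICTORS)
    assert set(models["combined"].predictors) == set(models["clinical"].predictors) | set(RADIOLOGICAL_PREDICTORS)
    # screen consistency: every clinical predictor passed the univariate screen
    from fractacomp.cohort import DEFAULT_CLINICAL_CANDIDATES, univariate_screen

    screen = univariate_screen(train, predictors=[c for c in DEFAULT_CLINICAL_CANDIDATES if c in train.columns])
    for v in models["clinical"].predictors:
        assert bool(screen.loc[v, "retained"])


def test_combined_beats_clinical_when_only_imat_signal():
    """With signal only on IMAT features, adding them must help held-out AUC."""
    from fractacomp.evaluation import auc

    spec = CohortGenSpec(
        groups=(("center1", 400),),
        continuous=(
            ("triglyceride", (("center1", 1.6, 0.9),)),
            ("imat_fd", (("center1", 1.15, 0.06),)),
            ("imr", (("center1", 0.19, 0.07),)),
            ("imat_multifractal_range", (("center1", 0.2, 0.05),)),
        ),
        binary=(("diabetes", (("center1", 0.5),)),),
        coefficients=(("imat_fd", 1.2), ("imat_multifractal_range", 1.0)),
        intercept=0.0,
    )
    wins = 0
    for rep in range(20):
        df = synth_cohort(spec, seed=1000 + rep)
        train, test = split_cohort(df, 0.7, seed=rep)
        clin = fit_logistic(train, ["triglyceride", "diabetes"])
        comb = fit_logistic(train, ["triglyceride", "diabetes", "imat_fd",
                                    "imr", "imat_multifractal_range"])
        a_clin = auc(predict_prob(clin, test), test["mets_label"])
        a_comb = auc(predict_prob(comb, test), test["mets_label"])
        wins += a_comb >= a_clin
    assert wins >= 16  # combined wins in the overwhelming majority of reps
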