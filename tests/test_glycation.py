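"""Observational pipeline: filters, classification, TGI, gap, regressions,
diagnostics and 0.632-bootstrap validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrgap import glycation as gl
from mrgap import simulate as sim
from mrgap.exceptions import EstimationError

from conftest import spawn_seeds


def _row(age=50.0, sex="female", fg=5.1, tg=1.16, hdl=1.3, hba1c=5.4, hb=140.0, **kw):
    return dict(age=age, sex=sex, fg=fg, tg=tg, hdl=hdl, hba1c=hba1c, hb=hb, **kw)


# ---------------------------------------------------------------------------
# filters


def test_filters_keep_typical_healthy_record():
    kept, tally = gl.apply_cohort_filters(pd.DataFrame([_row()]))
    assert len(kept) == 1
    assert tally["kept"] == 1


@pytest.mark.parametrize(
    "row, reason",
    [
        (_row(fg=7.0), "fasting_glucose"),  # threshold is >=
        (_row(hba1c=6.5), "hba1c"),
        (_row(age=66), "age"),
        (_row(age=17.9), "age"),
        (_row(sex="female", hb=119.9), "hemoglobin"),
        (_row(sex="male", hb=171.0), "hemoglobin"),
        (_row(sex="unknown"), "unclassifiable_sex"),
        (_row(diabetes_clinic_2y=True), "diabetes_clinic_2y"),
    ],
)
def test_filters_exclusion_reasons(row, reason):
    kept, tally = gl.apply_cohort_filters(pd.DataFrame([row]))
    assert len(kept) == 0
    assert tally[reason] == 1


def test_filters_boundaries_inclusive_for_age_and_hb():
    df = pd.DataFrame(
        [_row(age=18.0), _row(age=65.0), _row(sex="male", hb=130.0), _row(sex="male", hb=170.0)]
    )
    kept, _ = gl.apply_cohort_filters(df)
    assert len(kept) == 4


def test_filters_first_matching_reason_and_accounting():
    # violates both fg and age: counted once, under fasting_glucose
    df = pd.DataFrame([_row(fg=7.5, age=80), _row()])
    kept, tally = gl.apply_cohort_filters(df)
    assert tally["fasting_glucose"] == 1
    assert tally["age"] == 0
    assert sum(v for k, v in tally.items()) == len(df)


# ---------------------------------------------------------------------------
# classification


def test_classification_examples():
    df = pd.DataFrame([_row(hba1c=6.1, fg=5.7), _row(hba1c=5.4, fg=5.1)])
    labels = gl.classify_glycemic_status(df)
    assert list(labels) == ["preT2D", "normoglycemia"]


def test_classification_rule_both_leaves_indeterminate():
    df = pd.DataFrame([_row(hba1c=5.9, fg=6.5)])
    assert gl.classify_glycemic_status(df, rule="either")[0] == "preT2D"
    assert gl.classify_glycemic_status(df, rule="both")[0] == "indeterminate"


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.floats(min_value=4.0, max_value=6.49),
            st.floats(min_value=3.0, max_value=6.99),
        ),
        min_size=1,
        max_size=30,
    )
)
def test_classification_partitions_under_either(pairs):
    df = pd.DataFrame([_row(hba1c=a, fg=g) for a, g in pairs])
    labels = gl.classify_glycemic_status(df, rule="either")
    assert set(labels) <= {"normoglycemia", "preT2D"}
    assert (labels == "normoglycemia").sum() + (labels == "preT2D").sum() == len(df)


# ---------------------------------------------------------------------------
# TGI / predicted HbA1c / gap


def test_tgi_reference_values():
    assert round(gl.tgi(1.16, 5.10), 2) == 8.46
    assert round(gl.tgi(1.33, 5.70), 2) == 8.71
    assert gl.tgi(1.0, 1.0) == pytest.approx(np.log(88.57 * 18 / 2))


def test_tgi_rejects_nonpositive():
    with pytest.raises(ValueError):
        gl.tgi(0.0, 5.0)
    with pytest.raises(ValueError):
        gl.tgi(1.0, -2.0)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    st.floats(min_value=0.1, max_value=10.0),
    st.floats(min_value=0.1, max_value=10.0),
    st.floats(min_value=0.5, max_value=2.0),
)
def test_tgi_monotone_and_product_dependent(tg, fg, k):
    assert gl.tgi(tg * 1.01, fg) > gl.tgi(tg, fg)
    assert gl.tgi(tg, fg * 1.01) > gl.tgi(tg, fg)
    # depends on the inputs only through their product
    assert gl.tgi(tg * k, fg / k) == pytest.approx(gl.tgi(tg, fg), rel=1e-12)


def test_predicted_hba1c_equation():
    assert gl.predicted_hba1c(0.0) == pytest.approx(4.163)
    assert round(float(gl.predicted_hba1c(5.10)), 2) == 5.04


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    st.floats(min_value=3.0, max_value=8.0, allow_nan=False),
    st.floats(min_value=3.0, max_value=8.0, allow_nan=False),
)
def test_gap_plus_predicted_recovers_measured(m, p):
    assert gl.glycation_gap(m, p) + p == pytest.approx(m, rel=0, abs=1e-12)


def test_gap_reference_value():
    assert round(gl.glycation_gap(5.40, float(gl.predicted_hba1c(5.10))), 2) == 0.36


# ---------------------------------------------------------------------------
# prediction-model fit


def test_fit_predicted_hba1c_recovers_planted_equation():
    rng = np.random.default_rng(31)
    n = 2000
    fg = rng.uniform(4.0, 6.5, n)
    df = pd.DataFrame(
        {
            "fg": fg,
            "age": rng.uniform(20, 64, n),
            "sex": np.where(rng.random(n) < 0.5, "female", "male"),
            "hba1c": 4.163 + 0.172 * fg + rng.normal(0, 0.1, n),
        }
    )
    model = gl.fit_predicted_hba1c(df)
    slope = model.fg_only[1]
    se = float(model.full.bse[1])
    assert abs(slope - 0.172) < 3 * se
    assert model.predict(0.0) == pytest.approx(model.fg_only[0])


def test_fit_predicted_hba1c_preconditions():
    df = pd.DataFrame([_row()] * 5)
    with pytest.raises(EstimationError):
        gl.fit_predicted_hba1c(df)
    df = pd.DataFrame([_row(sex="male")] * 20)
    with pytest.raises(EstimationError, match="both sexes"):
        gl.fit_predicted_hba1c(df)


# ---------------------------------------------------------------------------
# regressions


def test_stratified_gap_regression_recovers_generator_truth(cohort):
    results = {r.stratum: r for r in gl.regress_gap_on_tgi(cohort)}
    pre, normo = results["preT2D"], results["normoglycemia"]
    assert abs(pre.beta - (-0.087)) < 3 * pre.se
    assert abs(normo.beta - 0.023) < 3 * normo.se
    assert pre.beta < 0 < normo.beta
    assert pre.intercept == pytest.approx(1.77, abs=0.35)


def test_hb_regression_recovers_generator_truth(cohort):
    r = gl.regress_hb_on_tgi(cohort)
    assert abs(r.beta - 1.88) < 3 * r.se


def test_hb_regression_runs_on_single_sex(cohort):
    single = cohort[cohort["sex"] == "female"]
    r = gl.regress_hb_on_tgi(single)
    assert r.n == len(single)


def test_small_stratum_skipped(cohort):
    strata = [("tiny", cohort.index < cohort.index[5]), ("all", cohort.index >= 0)]
    results = gl.regress_gap_on_tgi(cohort, strata=strata)
    assert [r.stratum for r in results] == ["all"]


def test_null_stratum_rarely_significant():
    """With gap replaced by pure noise, the TGI slope should be null:
    p > 0.05 in at least ~90% of seeded replicates."""
    nonsig = 0
    R = 200
    for s in spawn_seeds(909, R):
        rng = np.random.default_rng(s)
        n = 300
        df = pd.DataFrame({"tgi": rng.normal(8.5, 0.5, n), "gap": rng.normal(0, 0.3, n)})
        res = gl.regress_gap_on_tgi(df, strata=[("null", pd.Series(True, index=df.index))])
        nonsig += res[0].pval > 0.05
    assert nonsig >= 0.9 * R


# ---------------------------------------------------------------------------
# diagnostics


def test_diagnostics_normal_residuals_straight_qq(cohort):
    res = gl.regress_gap_on_tgi(cohort)[1]  # normoglycemia stratum
    d = gl.diagnostics(res)
    assert d["qq_correlation"] > 0.99
    assert set(d["residuals_vs_fitted"].columns) == {"fitted", "residual"}


def test_diagnostics_detect_curvature():
    rng = np.random.default_rng(8)
    x = np.linspace(-2, 2, 400)
    df = pd.DataFrame({"tgi": x, "gap": x**3 + rng.normal(0, 0.05, x.size)})
    res = gl.regress_gap_on_tgi(df, strata=[("cubic", pd.Series(True, index=df.index))])[0]
    d = gl.diagnostics(res, df)
    assert d["runs_test_p"] < 0.05
    assert "residuals_vs_tgi" in d


def test_diagnostics_perfect_fit_zero_residuals():
    x = np.linspace(0, 1, 60)
    df = pd.DataFrame({"tgi": x, "gap": 2.0 + 0.5 * x})
    res = gl.regress_gap_on_tgi(df, strata=[("exact", pd.Series(True, index=df.index))])[0]
    d = gl.diagnostics(res)
    np.testing.assert_allclose(d["residuals_vs_fitted"]["residual"], 0.0, atol=1e-10)


# ---------------------------------------------------------------------------
# 0.632 bootstrap


def test_bootstrap_noiseless_model_has_zero_optimism():
    x = np.linspace(0.0, 1.0, 100)
    df = pd.DataFrame({"x": x, "y": 1.0 + 2.0 * x})
    v = gl.bootstrap_validate_632(gl.ModelSpec("y", ("x",)), df, n_boot=50, seed=1)
    assert v.r2_apparent == pytest.approx(1.0)
    assert v.r2_corrected == pytest.approx(1.0)
    assert v.optimism == pytest.approx(0.0, abs=1e-9)
    assert not v.overfit


def test_bootstrap_well_specified_large_n_small_optimism(cohort):
    sub = cohort[cohort["glycemic_status"] == "normoglycemia"]
    v = gl.bootstrap_validate_632(gl.ModelSpec("gap", ("tgi",)), sub, n_boot=100, seed=2)
    assert v.optimism < 0.02
    assert not v.overfit


def test_bootstrap_flags_engineered_overfit():
    rng = np.random.default_rng(42)
    cols = {f"x{i}": rng.normal(size=60) for i in range(20)}
    cols["y"] = rng.normal(size=60)
    df = pd.DataFrame(cols)
    v = gl.bootstrap_validate_632(
        gl.ModelSpec("y", tuple(f"x{i}" for i in range(20))), df, n_boot=100, seed=3
    )
    assert v.optimism > 0.1
    assert v.overfit
    assert v.mse_change_pct > 0
    assert v.slope_shrinkage > 0.1
    assert v.g_index_change_pct < 0  # shrunken model spreads less


def test_bootstrap_requires_minimum_cohort():
    df = pd.DataFrame({"x": np.arange(10.0), "y": np.arange(10.0)})
    with pytest.raises(EstimationError):
        gl.bootstrap_validate_632(gl.ModelSpec("y", ("x",)), df)


# ---------------------------------------------------------------------------
# summaries


def test_summary_and_hexbin_tables(cohort):
    summary = gl.summarize_cohort(cohort)
    assert {"characteristic", "normoglycemia", "preT2D", "pval"} <= set(summary.columns)
    assert (summary["pval"].dropna() <= 1).all()
    dumps = gl.hexbin_tables(cohort)
    assert set(dumps) == {"all", "preT2D", "normoglycemia"}
    assert len(dumps["all"]) == len(cohort)
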