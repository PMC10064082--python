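"""Univariable MR estimators against hand-computed and simulation oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from mrgap import mr
from mrgap import simulate as sim
from mrgap.exceptions import EstimationError
from mrgap.summary_stats import HarmonizedSet

from conftest import spawn_seeds


def _set(bx, by, se_out, se_exp=None, **meta):
    bx = np.asarray(bx, dtype=float)
    se_exp = np.full_like(bx, 0.05) if se_exp is None else se_exp
    return HarmonizedSet.from_arrays(bx, se_exp, by, se_out, **meta)


# ---------------------------------------------------------------------------
# Wald ratio


@pytest.mark.parametrize(
    "bx, sx, by, sy, beta, se",
    [
        (0.5, 0.05, 0.25, 0.05, 0.5, 0.1),
        (1.0, 0.03, 0.42, 0.07, 0.42, 0.07),
        (-0.5, 0.05, 0.25, 0.05, -0.5, 0.1),
    ],
)
def test_wald_ratio_arithmetic(bx, sx, by, sy, beta, se):
    est = mr.wald_ratio(bx, sx, by, sy)
    assert est.beta == pytest.approx(beta)
    assert est.se == pytest.approx(se)


def test_wald_ratio_zero_exposure_fatal():
    with pytest.raises(EstimationError):
        mr.wald_ratio(0.0, 0.05, 0.1, 0.05)


# ---------------------------------------------------------------------------
# IVW


def test_ivw_hand_example(hand_set):
    fixed = mr.ivw(hand_set, effects_model="fixed")
    assert fixed.beta == pytest.approx(0.6)
    assert fixed.se == pytest.approx(np.sqrt(1 / 300))
    # Q = 2 on 2 df: the multiplicative inflation does not kick in
    random = mr.ivw(hand_set)
    assert random.se == pytest.approx(fixed.se)
    assert mr.cochran_q(hand_set, 0.6).Q == pytest.approx(2.0)


def test_ivw_single_snp_equals_wald_ratio():
    h = _set([0.5], [0.25], [0.05])
    est = mr.ivw(h)
    ref = mr.wald_ratio(0.5, 0.05, 0.25, 0.05)
    assert est.beta == ref.beta and est.se == ref.se and est.pval == ref.pval


def test_ivw_matches_wls_through_origin(strong_set):
    """Independent oracle: statsmodels WLS without intercept."""
    w = 1.0 / strong_set.se_out**2
    wls = sm.WLS(strong_set.beta_out, strong_set.beta_exp, weights=w).fit()
    assert mr.ivw(strong_set, effects_model="fixed").beta == pytest.approx(
        float(wls.params[0]), rel=1e-12
    )


def test_ivw_recovers_truth_in_strong_regime(strong_set):
    est = mr.ivw(strong_set)
    assert abs(est.beta - 0.5) < 3 * est.se


# ---------------------------------------------------------------------------
# MR-Egger


def test_egger_two_point_exact_fit():
    h = _set([1.0, 2.0], [0.6, 1.0], [0.1, 0.1])
    est = mr.egger(h)
    assert est.beta == pytest.approx(0.4)
    assert est.intercept == pytest.approx(0.2)


def test_egger_matches_wls_with_intercept(strong_set):
    """Independent oracle on positively-oriented data: statsmodels WLS."""
    w = 1.0 / strong_set.se_out**2
    X = sm.add_constant(strong_set.beta_exp)
    wls = sm.WLS(strong_set.beta_out, X, weights=w).fit()
    est = mr.egger(strong_set)
    assert est.intercept == pytest.approx(float(wls.params[0]), rel=1e-10)
    assert est.beta == pytest.approx(float(wls.params[1]), rel=1e-10)


def test_egger_intercept_null_when_no_pleiotropy(strong_set):
    est = mr.egger(strong_set)
    assert abs(est.intercept) < 3 * est.intercept_se


def test_egger_constant_pleiotropy_shifts_intercept_only(strong_set):
    alpha = 0.05
    shifted = HarmonizedSet.from_arrays(
        strong_set.beta_exp,
        strong_set.se_exp,
        strong_set.beta_out + alpha,
        strong_set.se_out,
    )
    base, est = mr.egger(strong_set), mr.egger(shifted)
    assert est.intercept - base.intercept == pytest.approx(alpha, abs=1e-10)
    assert est.beta == pytest.approx(base.beta, abs=1e-10)


def test_egger_zero_intercept_refit_equals_ivw(strong_set):
    """Constraining the Egger intercept to zero recovers the IVW slope."""
    w = 1.0 / strong_set.se_out**2
    origin = sm.WLS(strong_set.beta_out, strong_set.beta_exp, weights=w).fit()
    assert float(origin.params[0]) == pytest.approx(
        mr.ivw(strong_set, effects_model="fixed").beta, rel=1e-12
    )


# ---------------------------------------------------------------------------
# weighted median


def test_weighted_median_equal_weights_is_sample_median():
    h = _set([1.0, 1.0, 1.0], [0.4, 0.9, 0.5], [0.1, 0.1, 0.1])
    est = mr.weighted_median(h, n_boot=100, seed=1)
    assert est.beta == pytest.approx(0.5)


def test_weighted_median_hand_interpolation():
    # sorted ratios (0.4, 0.5, 0.9), normalized weights (0.6, 0.2, 0.2):
    # cumulative-minus-half-weight grid (0.3, 0.7, 0.9) -> interp at 0.5 = 0.45
    r = np.array([0.4, 0.5, 0.9])
    w = np.array([0.6, 0.2, 0.2])
    assert mr.weighted_median_point(r, w) == pytest.approx(0.45)


def test_weighted_median_robust_to_minority_outliers():
    rng = np.random.default_rng(5)
    J = 30
    bx = np.ones(J)
    ratios = np.where(np.arange(J) < 18, 0.5, 4.0) + rng.normal(0, 0.01, J)
    h = _set(bx, ratios, np.full(J, 0.05))
    wm = mr.weighted_median(h, n_boot=200, seed=2)
    iv = mr.ivw(h)
    assert abs(wm.beta - 0.5) < 0.1
    assert abs(iv.beta - 0.5) > 1.0


# ---------------------------------------------------------------------------
# mode


def test_mode_degenerate_identical_ratios():
    h = _set([1.0, 2.0, 4.0], [0.7, 1.4, 2.8], [0.1, 0.1, 0.1])
    est = mr.mode_based(h, weighted=False, n_boot=50, seed=3)
    assert est.beta == pytest.approx(0.7)


def test_mode_cluster_argmax_matches_grid_oracle():
    ratios = np.array([0.5, 0.5, 0.5, 2.0])
    h = _set(np.ones(4), ratios, np.full(4, 0.05))
    est = mr.mode_based(h, weighted=False, phi=0.25, n_boot=50, seed=4)

    # independent oracle: brute-force normal-kernel density on a fine grid
    sd = ratios.std(ddof=1)
    iqr = np.subtract(*np.percentile(ratios, [75, 25]))
    bw = 0.25 * 0.9 * min(sd, iqr / 1.349) * 4 ** (-0.2)
    grid = np.linspace(-1, 3, 20001)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios) / bw) ** 2).sum(axis=1)
    assert est.beta == pytest.approx(grid[np.argmax(dens)], abs=0.02)
    assert est.beta == pytest.approx(0.5, abs=0.02)


def test_weighted_mode_prefers_heavier_cluster():
    ratios = np.concatenate([np.full(5, 0.4), np.full(4, 1.2)])
    se_out = np.concatenate([np.full(5, 0.02), np.full(4, 0.2)])
    h = _set(np.ones(9), ratios, se_out)
    est = mr.mode_based(h, weighted=True, phi=0.5, n_boot=50, seed=5)
    assert est.beta == pytest.approx(0.4, abs=0.05)


# ---------------------------------------------------------------------------
# heterogeneity & instrument strength


def test_cochran_q_identical_ratios_is_zero():
    h = _set([1.0, 2.0], [0.5, 1.0], [0.1, 0.1])
    het = mr.cochran_q(h, 0.5)
    assert het.Q == pytest.approx(0.0)
    assert het.I2 == 0.0


def test_i_squared_reference_value():
    # heterogeneity far above its df: I2 = (Q - df)/Q * 100
    assert mr.i_squared(857.625, 47) == pytest.approx(94.520, abs=5e-4)
    assert mr.i_squared(1.0, 5) == 0.0


@pytest.mark.parametrize(
    "z, expected", [([4.0], 16.0), ([3.0, 5.0], 17.0)]
)
def test_f_statistic_mean_squared_z(z, expected):
    z = np.array(z)
    h = _set(z * 0.05, z * 0.0, np.full(len(z), 0.1))
    assert mr.f_statistic(h) == pytest.approx(expected)


def test_weak_instrument_warning(caplog):
    h = _set([0.05, 0.06], [0.01, 0.01], [0.1, 0.1])  # z = 1.0, 1.2
    with caplog.at_level("WARNING"):
        F = mr.f_statistic(h)
    assert F < 10
    assert "weak instrument" in caplog.text


# ---------------------------------------------------------------------------
# leave-one-out


def test_leave_one_out_identical_ratios_all_equal():
    h = _set([1.0, 2.0, 3.0], [0.5, 1.0, 1.5], [0.1, 0.1, 0.1])
    full = mr.ivw(h).beta
    for _, est in mr.leave_one_out(h):
        assert est.beta == pytest.approx(full)


def test_leave_one_out_hand_example(hand_set):
    results = dict(mr.leave_one_out(hand_set))
    assert results["snp3"].beta == pytest.approx(0.6)  # mean of 0.5, 0.7


def test_leave_one_out_flags_single_outlier():
    J = 10
    bx = np.ones(J)
    by = np.full(J, 0.5)
    by[3] = 5.0  # gross outlier
    h = _set(bx, by, np.full(J, 0.05))
    loo = mr.leave_one_out(h)
    betas = {snp: est.beta for snp, est in loo}
    others = [b for snp, b in betas.items() if snp != "snp4"]
    spread = max(others) - min(others)
    assert abs(betas["snp4"] - np.mean(others)) > 10 * spread
    assert betas["snp4"] == pytest.approx(0.5, abs=1e-9)


# ---------------------------------------------------------------------------
# suite


def test_suite_schema_and_reproducibility(strong_set):
    t1 = mr.run_univariable_suite(strong_set, n_boot=50, seed=9)
    t2 = mr.run_univariable_suite(strong_set, n_boot=50, seed=9)
    assert list(t1["method"]) == list(mr.METHOD_ORDER)
    assert t1.equals(t2)
    # Q/I2 populated exactly for Egger and IVW rows
    assert t1["Q"].notna().sum() == 2
    assert (t1["F"] > 0).all()


def test_suite_identical_ratio_set_agrees_across_methods():
    h = _set([1.0, 2.0, 3.0, 4.0], [0.5, 1.0, 1.5, 2.0], [0.1] * 4)
    t = mr.run_univariable_suite(h, n_boot=50, seed=1)
    np.testing.assert_allclose(t["beta"], 0.5, atol=1e-9)


def test_pvalues_floored_not_zero():
    h = _set([1.0, 1.0, 1.0], [0.5, 0.5, 0.5], [1e-6] * 3)
    est = mr.ivw(h)
    assert est.pval > 0.0
    assert np.isfinite(mr.log10_pvalue(est.beta / est.se))


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_random_effects_se_never_below_fixed(seed):
    """Multiplicative random-effects SE >= fixed SE, equal iff Q <= df."""
    rng = np.random.default_rng(seed)
    J = int(rng.integers(2, 20))
    bx = rng.normal(0.5, 0.2, J)
    bx[np.abs(bx) < 0.05] = 0.05
    h = _set(bx, rng.normal(0.3 * bx, 0.1), rng.uniform(0.05, 0.2, J))
    fixed = mr.ivw(h, effects_model="fixed")
    random = mr.ivw(h)
    het = mr.cochran_q(h, fixed.beta)
    assert random.se >= fixed.se - 1e-15
    if het.Q <= het.df:
        assert random.se == pytest.approx(fixed.se)
    else:
        assert random.se > fixed.se


def test_type_i_error_calibrated_under_null():
    """Fixed-effect IVW rejects ~5% of null datasets (quick 150-rep check;
    the full 500-rep version runs in the acceptance suite)."""
    rej = 0
    R = 150
    for s in spawn_seeds(424_242, R):
        h = sim.simulate_harmonized(sim.scenario_presets("null", seed=s))
        rej += mr.ivw(h, effects_model="fixed").pval < 0.05
    assert abs(rej / R - 0.05) < 0.05
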