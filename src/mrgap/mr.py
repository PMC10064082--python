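"""Univariable two-sample Mendelian randomization estimators.

Given a :class:`~mrgap.summary_stats.HarmonizedSet` of per-SNP exposure
effects :math:`\\hat\\beta_{Xj} \\pm \\sigma_{Xj}` and outcome effects
:math:`\\hat\\beta_{Yj} \\pm \\sigma_{Yj}`, this module provides the five
standard summary-data estimators of the causal effect :math:`\\theta`:

* inverse-variance weighted (IVW): zero-intercept weighted regression of
  outcome on exposure effects, equivalent to an inverse-variance
  meta-analysis of per-SNP Wald ratios;
* MR-Egger: the same regression with a free intercept, whose intercept
  estimates average directional pleiotropy (unbiased under InSIDE);
* weighted median: robust when up to half the weight sits on invalid SNPs;
* simple and weighted mode: the kernel-density mode of the Wald ratios,
  consistent when the largest homogeneous cluster of SNPs is valid;

plus Cochran's Q heterogeneity statistics with :math:`I^2`, the mean
instrument F-statistic, leave-one-out IVW, and a table runner mirroring
the usual five-row sensitivity layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EstimationError
from .summary_stats import HarmonizedSet, Instrument

logger = logging.getLogger(__name__)

#: Conventional weak-instrument threshold on the mean F-statistic.
WEAK_INSTRUMENT_F = 10.0

_P_FLOOR = np.finfo(float).tiny  # two-sided p-values are floored, never 0

METHOD_ORDER = (
    "MR Egger",
    "Weighted median",
    "Inverse variance weighted",
    "Simple mode",
    "Weighted mode",
)


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate from summary data.

    ``beta`` is in outcome units per SD (or unit) of the exposure.  The
    intercept fields are populated only for MR-Egger.
    """

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValueError(f"{self.method}: se must be positive, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.method}: pval must lie in (0, 1], got {self.pval}")


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q with derived I² and (optionally) the instrument F."""

    Q: float
    df: int
    p_Q: float
    I2: float
    F: float | None = None

    def __post_init__(self) -> None:
        if self.Q < 0 or self.df < 1:
            raise ValueError("Q must be >= 0 and df >= 1")


def _two_sided_p(z: float) -> float:
    return float(max(2.0 * stats.norm.sf(abs(z)), _P_FLOOR))


def _two_sided_p_t(t: float, df: int) -> float:
    if df < 1:
        return 1.0
    return float(max(2.0 * stats.t.sf(abs(t), df), _P_FLOOR))


def log10_pvalue(z: float) -> float:
    """Exact base-10 log of the two-sided normal p, safe far beyond underflow."""
    return float((stats.norm.logsf(abs(z)) + np.log(2.0)) / np.log(10.0))


def i_squared(Q: float, df: int) -> float:
    """Higgins' I² (percent): share of Q exceeding its expectation under
    homogeneity, floored at zero."""
    if Q <= 0:
        return 0.0
    return max(0.0, (Q - df) / Q) * 100.0


# ---------------------------------------------------------------------------
# ratio helpers


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> MREstimate:
    """Single-SNP causal estimate ``beta_out / beta_exp``.

    The standard error uses the first-order delta method,
    ``se_out / |beta_exp|`` (the exposure's sampling error is ignored, as
    is conventional for genome-wide significant instruments).
    """
    if beta_exp == 0:
        raise EstimationError("wald_ratio undefined for beta_exp = 0")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return MREstimate(
        method="wald", beta=float(beta), se=float(se), pval=_two_sided_p(beta / se), n_snp=1
    )


def _ratios(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and their delta-method standard errors."""
    bx, by = hset.beta_exp, hset.beta_out
    if np.any(bx == 0):
        raise EstimationError("harmonized set contains beta_exp = 0; exclude upstream")
    return by / bx, hset.se_out / np.abs(bx)


# ---------------------------------------------------------------------------
# IVW and Egger


def cochran_q(
    hset: HarmonizedSet,
    beta_ref: float,
    intercept: float = 0.0,
    df_drop: int = 1,
    with_f: bool = True,
) -> HeterogeneityStats:
    """Cochran's Q around a reference slope (and optional intercept).

    ``Q = sum_j w_j (beta_out_j - intercept - beta_ref * beta_exp_j)^2``
    with inverse-variance weights ``w_j = 1/se_out_j^2``; ``df = J -
    df_drop`` (1 for IVW, 2 for Egger).  I² is reported in percent.
    """
    if hset.n_snp < 2:
        raise EstimationError("heterogeneity needs at least 2 SNPs")
    w = 1.0 / hset.se_out**2
    resid = hset.beta_out - intercept - beta_ref * hset.beta_exp
    Q = float(np.sum(w * resid**2))
    df = hset.n_snp - df_drop
    p_Q = float(max(stats.chi2.sf(Q, df), _P_FLOOR)) if df >= 1 else 1.0
    F = f_statistic(hset, warn=False) if with_f else None
    return HeterogeneityStats(Q=Q, df=max(df, 1), p_Q=p_Q, I2=i_squared(Q, df), F=F)


def ivw(hset: HarmonizedSet, effects_model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance weighted estimate.

    A zero-intercept weighted regression of outcome on exposure effects
    with weights ``1/se_out^2``.  Under ``multiplicative_random`` (the
    default) the fixed-effect SE is inflated by ``sqrt(max(1, Q/df))`` so
    that heterogeneity widens, and can never narrow, the interval.
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects model {effects_model!r}")
    J = hset.n_snp
    if J == 0:
        raise EstimationError("empty harmonized set")
    if J == 1:
        est = wald_ratio(
            hset.beta_exp[0], hset.se_exp[0], hset.beta_out[0], hset.se_out[0]
        )
        return MREstimate(
            method="ivw", beta=est.beta, se=est.se, pval=est.pval, n_snp=1
        )
    bx, by = hset.beta_exp, hset.beta_out
    w = 1.0 / hset.se_out**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se = denom**-0.5
    if effects_model == "multiplicative_random":
        het = cochran_q(hset, beta, with_f=False)
        se *= np.sqrt(max(1.0, het.Q / het.df))
    return MREstimate(
        method="ivw", beta=beta, se=float(se), pval=_two_sided_p(beta / se), n_snp=J
    )


def egger(hset: HarmonizedSet) -> MREstimate:
    """MR-Egger regression.

    Weighted regression of outcome on exposure effects with a free
    intercept (weights ``1/se_out^2``), after orienting each SNP so that
    the exposure effect is positive — MR-Egger is not invariant to allele
    recoding, and the positive-exposure orientation is the convention.
    The intercept estimates average directional pleiotropy.  SEs carry a
    multiplicative ``sqrt(max(1, Q/(J-2)))`` inflation; p-values use a t
    distribution with ``J-2`` df.
    """
    J = hset.n_snp
    if J < 2:
        raise EstimationError("MR-Egger needs at least 2 SNPs")
    if J < 3:
        logger.warning("MR-Egger with J=2 fits exactly; inference is vacuous")
    sign = np.sign(hset.beta_exp)
    if np.any(sign == 0):
        raise EstimationError("harmonized set contains beta_exp = 0; exclude upstream")
    bx = hset.beta_exp * sign
    by = hset.beta_out * sign
    w = 1.0 / hset.se_out**2

    X = np.column_stack([np.ones(J), bx])
    XtW = X.T * w
    try:
        cov_unscaled = np.linalg.inv(XtW @ X)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(
            "MR-Egger needs variation in |beta_exp| across SNPs"
        ) from exc
    coef = cov_unscaled @ (XtW @ by)
    intercept, slope = float(coef[0]), float(coef[1])

    resid = by - X @ coef
    Q = float(np.sum(w * resid**2))
    df = J - 2
    scale = np.sqrt(max(1.0, Q / df)) if df > 0 else 1.0
    se = np.sqrt(np.diag(cov_unscaled)) * scale
    se_i, se_b = float(se[0]), float(se[1])

    if df > 0:
        pval = _two_sided_p_t(slope / se_b, df)
        p_i = _two_sided_p_t(intercept / se_i, df)
    else:  # exact two-point fit: no residual df
        pval, p_i = 1.0, 1.0
    return MREstimate(
        method="egger",
        beta=slope,
        se=se_b,
        pval=pval,
        n_snp=J,
        intercept=intercept,
        intercept_se=se_i,
        intercept_p=p_i,
    )


def egger_q(hset: HarmonizedSet) -> HeterogeneityStats:
    """Cochran's Q about the Egger fit (df = J - 2).

    Computed in the positive-exposure orientation the Egger regression is
    fitted in (the intercept is not orientation-invariant).
    """
    est = egger(hset)
    sign = np.sign(hset.beta_exp)
    w = 1.0 / hset.se_out**2
    resid = hset.beta_out * sign - (est.intercept or 0.0) - est.beta * hset.beta_exp * sign
    Q = float(np.sum(w * resid**2))
    df = max(hset.n_snp - 2, 1)
    return HeterogeneityStats(
        Q=Q,
        df=df,
        p_Q=float(max(stats.chi2.sf(Q, df), _P_FLOOR)),
        I2=i_squared(Q, df),
        F=f_statistic(hset, warn=False),
    )


# ---------------------------------------------------------------------------
# median and mode


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of the cumulative weight.

    With normalized weights ``w`` over ratios sorted ascending, the
    standardized cumulative weight is ``p_j = S_j - w_j/2``; the estimate
    interpolates the sorted ratios at ``p = 1/2``.
    """
    order = np.argsort(ratios)
    r = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    w = w / w.sum()
    p = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, p, r))


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap standard error.

    Weights are the inverse variances of the per-SNP Wald ratios
    (delta-method SEs).  The estimator is consistent provided valid SNPs
    carry more than half the total weight.  The SE resamples
    ``beta_exp``/``beta_out`` from their sampling normals ``n_boot`` times
    and takes the standard deviation of the recomputed medians.
    """
    J = hset.n_snp
    if J < 3:
        raise EstimationError("weighted median needs at least 3 SNPs")
    r, se_r = _ratios(hset)
    beta = weighted_median_point(r, 1.0 / se_r**2)
    se = _bootstrap_se(hset, "median", n_boot, seed, weighted=True)
    return MREstimate(
        method="weighted_median",
        beta=beta,
        se=se,
        pval=_two_sided_p(beta / se),
        n_snp=J,
    )


def _silverman_bandwidth(r: np.ndarray, phi: float) -> float:
    """Modified Silverman rule: ``phi * 0.9 * min(sd, IQR/1.349) * J^(-1/5)``."""
    sd = float(np.std(r, ddof=1))
    iqr = float(np.subtract(*np.percentile(r, [75, 25])))
    spread = [s for s in (sd, iqr / 1.349) if s > 0]
    if not spread:
        return 0.0
    return phi * 0.9 * min(spread) * len(r) ** (-0.2)


def mode_point(
    ratios: np.ndarray,
    weights: np.ndarray | None = None,
    phi: float = 1.0,
    grid_points: int = 512,
) -> float:
    """Argmax of a normal-kernel density of the Wald ratios.

    ``weights=None`` gives the simple mode; inverse-variance weights give
    the weighted mode.  The grid spans the ratios ± 3 bandwidths.  With
    zero bandwidth (all ratios identical) the common ratio is returned.
    """
    r = np.asarray(ratios, dtype=float)
    h = _silverman_bandwidth(r, phi)
    if h == 0.0:
        return float(r[0])
    if weights is None:
        w = np.full(r.shape, 1.0 / len(r))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, grid_points)
    dens = np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2) @ w
    return float(grid[np.argmax(dens)])


def mode_based(
    hset: HarmonizedSet,
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
    grid_points: int = 512,
) -> MREstimate:
    """Mode-based estimate (simple or weighted) with bootstrap SE.

    SNPs sharing a causal mechanism cluster at the same Wald ratio; the
    kernel-density mode picks the largest cluster, so the estimator is
    consistent when that plurality of SNPs is valid (ZEMPA).  ``phi``
    scales the modified-Silverman bandwidth.
    """
    J = hset.n_snp
    if J < 3:
        raise EstimationError("mode-based estimation needs at least 3 SNPs")
    r, se_r = _ratios(hset)
    w = 1.0 / se_r**2 if weighted else None
    beta = mode_point(r, w, phi=phi, grid_points=grid_points)
    se = _bootstrap_se(
        hset, "mode", n_boot, seed, weighted=weighted, phi=phi, grid_points=grid_points
    )
    method = "weighted_mode" if weighted else "simple_mode"
    return MREstimate(
        method=method, beta=beta, se=se, pval=_two_sided_p(beta / se), n_snp=J
    )


def _bootstrap_se(
    hset: HarmonizedSet,
    estimator: str,
    n_boot: int,
    seed: int | None,
    weighted: bool = True,
    phi: float = 1.0,
    grid_points: int = 512,
) -> float:
    """Parametric bootstrap over the sampling distributions of the betas."""
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    bx, sx = hset.beta_exp, hset.se_exp
    by, sy = hset.beta_out, hset.se_out
    J = hset.n_snp
    reps = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs[bxs == 0] = np.finfo(float).eps
        r = bys / bxs
        se_r = sy / np.abs(bxs)
        if estimator == "median":
            reps[b] = weighted_median_point(r, 1.0 / se_r**2)
        else:
            w = 1.0 / se_r**2 if weighted else None
            reps[b] = mode_point(r, w, phi=phi, grid_points=grid_points)
    se = float(np.std(reps, ddof=1))
    if se == 0.0:  # degenerate resamples (e.g. tiny SEs); avoid a zero SE
        se = np.finfo(float).eps
    return se


# ---------------------------------------------------------------------------
# instrument strength, leave-one-out, suite


def f_statistic(obj: Instrument | HarmonizedSet, warn: bool = True) -> float:
    """Mean instrument F: the average squared z of the SNP-exposure effects.

    Values below 10 conventionally flag a weak instrument; a warning is
    logged in that case.
    """
    if isinstance(obj, Instrument):
        z = np.array([r.z for r in obj.records])
    else:
        z = obj.beta_exp / obj.se_exp
    if z.size == 0:
        raise EstimationError("empty instrument")
    F = float(np.mean(z**2))
    if warn and F < WEAK_INSTRUMENT_F:
        logger.warning("weak instrument: mean F = %.3f < %.0f", F, WEAK_INSTRUMENT_F)
    return F


def leave_one_out(
    hset: HarmonizedSet, effects_model: str = "multiplicative_random"
) -> list[tuple[str, MREstimate]]:
    """IVW re-estimated with each SNP removed in turn.

    A single SNP whose omission moves the estimate far from the rest flags
    an influential, possibly pleiotropic variant.
    """
    if hset.n_snp < 3:
        raise EstimationError("leave-one-out needs at least 3 SNPs")
    out = []
    for snp in hset.snp_ids:
        out.append((snp, ivw(hset.without(snp), effects_model=effects_model)))
    return out


def run_univariable_suite(
    hset: HarmonizedSet,
    n_boot: int = 1000,
    seed: int | None = None,
    effects_model: str = "multiplicative_random",
    phi: float = 1.0,
) -> pd.DataFrame:
    """All five estimators plus heterogeneity and instrument strength.

    Returns one row per method in the fixed order Egger, weighted median,
    IVW, simple mode, weighted mode, with Q/df/p_Q/I² populated for Egger
    and IVW and the mean instrument F repeated on every row.  ``seed``
    drives the bootstrap SEs, making the table reproducible.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] >> 1) for s in ss]

    est_egger = egger(hset)
    est_wm = weighted_median(hset, n_boot=n_boot, seed=seeds[0])
    est_ivw = ivw(hset, effects_model=effects_model)
    est_sm = mode_based(hset, weighted=False, phi=phi, n_boot=n_boot, seed=seeds[1])
    est_wmode = mode_based(hset, weighted=True, phi=phi, n_boot=n_boot, seed=seeds[2])

    F = f_statistic(hset)
    het_ivw = cochran_q(hset, est_ivw.beta, with_f=False)
    het_egger = egger_q(hset)

    rows = []
    for name, est, het in (
        ("MR Egger", est_egger, het_egger),
        ("Weighted median", est_wm, None),
        ("Inverse variance weighted", est_ivw, het_ivw),
        ("Simple mode", est_sm, None),
        ("Weighted mode", est_wmode, None),
    ):
        rows.append(
            {
                "method": name,
                "n_snp": est.n_snp,
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "log10_p": log10_pvalue(est.beta / est.se),
                "egger_intercept": est.intercept,
                "egger_intercept_se": est.intercept_se,
                "egger_intercept_p": est.intercept_p,
                "Q": het.Q if het else np.nan,
                "Q_df": het.df if het else np.nan,
                "p_Q": het.p_Q if het else np.nan,
                "I2": het.I2 if het else np.nan,
                "F": F,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plot-ready exports (no rendering here)


def scatter_table(hset: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP effects with SEs, ready for an effect-vs-effect scatter."""
    return hset.table[["snp_id", "beta_exp", "se_exp", "beta_out", "se_out"]].copy()


def funnel_table(hset: HarmonizedSet) -> pd.DataFrame:
    """Wald ratios against precision (1/se), ready for a funnel plot."""
    r, se_r = _ratios(hset)
    return pd.DataFrame(
        {"snp_id": hset.snp_ids, "ratio": r, "precision": 1.0 / se_r}
    )
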