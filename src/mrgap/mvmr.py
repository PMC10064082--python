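"""Inverse-variance-weighted multivariable Mendelian randomization.

Multivariable MR regresses each SNP's outcome effect jointly on its
effects on K exposures, estimating the *direct* effect of each exposure
conditional on the others — e.g. the effect of fasting insulin on HbA1c
net of fasting glucose, type-2 diabetes liability, or hemoglobin.  The
instrument is the union of the single-exposure instruments, harmonized to
a common effect allele per SNP; SNPs lacking an effect estimate for any
exposure are dropped.

Conditional instrument strength uses the Sanderson–Windmeijer form: for
each exposure, the weighted Q of regressing its SNP effects on the other
exposures' SNP effects, divided by ``J - K + 1``.  A conditional F below
10 flags an instrument too collinear/weak to separate that exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import CollinearityError, EstimationError, HarmonizationError
from .mr import MREstimate, HeterogeneityStats, WEAK_INSTRUMENT_F, _two_sided_p, i_squared, _P_FLOOR
from .summary_stats import Instrument, SummaryStatRecord, _align_to_reference

logger = logging.getLogger(__name__)

#: Condition-number threshold beyond which the weighted design is treated
#: as collinear.
COLLINEARITY_CONDITION_LIMIT = 1e8


@dataclass(frozen=True)
class MVMRSet:
    """Per-SNP outcome effects with effects on K exposures.

    ``beta_exp`` is J×K, column k holding SNP effects on exposure k, all
    aligned to a common effect allele per SNP.  K=1 is permitted so the
    single-exposure estimator can be checked against univariable IVW;
    :func:`build_mvmr_set` itself requires at least two exposures.
    """

    snp_ids: tuple[str, ...]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    exposure_names: tuple[str, ...]

    def __post_init__(self) -> None:
        J, K = self.beta_exp.shape
        if len(self.exposure_names) != K:
            raise ValueError("exposure_names length must match beta_exp columns")
        if len(set(self.snp_ids)) != J:
            raise ValueError("duplicated snp_ids")
        if np.isnan(self.beta_exp).any():
            raise ValueError("missing exposure betas are not allowed")
        if not ((self.se_exp > 0).all() and (self.se_out > 0).all()):
            raise ValueError("all standard errors must be positive")

    @property
    def n_snp(self) -> int:
        return self.beta_exp.shape[0]

    @property
    def n_exposure(self) -> int:
        return self.beta_exp.shape[1]


def build_mvmr_set(
    instruments: Sequence[Instrument],
    outcome_records: Sequence[SummaryStatRecord],
    full_records: Mapping[str, Sequence[SummaryStatRecord]] | None = None,
    palindrome_policy: str = "infer_by_eaf",
    eaf_ambiguity_band: tuple[float, float] = (0.42, 0.58),
) -> MVMRSet:
    """Assemble the union-of-instruments multivariable set.

    The SNP list is the union of the exposures' instruments in first-seen
    order.  Each exposure's effect at each SNP is looked up in
    ``full_records[exposure_name]`` when provided (the realistic case:
    union SNPs need not be genome-wide significant for every exposure),
    falling back to the instrument's own records.  The first exposure
    carrying a SNP fixes its reference allele; every other exposure and
    the outcome are aligned to it with the same strand/palindrome logic as
    univariable harmonization.  SNPs missing any exposure's beta, missing
    from the outcome, or unalignable are dropped and logged.  Fewer than
    two surviving SNPs is fatal.
    """
    if len(instruments) < 2:
        raise EstimationError("multivariable MR needs at least 2 exposures")
    names = tuple(ins.exposure_name for ins in instruments)
    if len(set(names)) != len(names):
        raise ValueError("exposure names must be unique")

    lookup: list[dict[str, SummaryStatRecord]] = []
    for ins in instruments:
        recs = (full_records or {}).get(ins.exposure_name, ins.records)
        lookup.append({r.snp_id: r for r in recs})
    outcome_by_id = {r.snp_id: r for r in outcome_records}

    union: list[str] = []
    seen: set[str] = set()
    for ins in instruments:
        for snp in ins.snp_ids:
            if snp not in seen:
                seen.add(snp)
                union.append(snp)

    rows = []
    for snp in union:
        sources = [lk.get(snp) for lk in lookup]
        if any(src is None for src in sources):
            logger.info("%s: missing from at least one exposure; dropped", snp)
            continue
        if snp not in outcome_by_id:
            logger.info("%s: missing from outcome; dropped", snp)
            continue
        ref = next(src for src in sources if src is not None)
        betas, ses = [], []
        ok = True
        for src in sources:
            aligned = _align_to_reference(ref, src, palindrome_policy, eaf_ambiguity_band)
            if isinstance(aligned, str):
                logger.info("%s: dropped (%s vs %s)", snp, aligned, ref.snp_id)
                ok = False
                break
            betas.append(aligned[0])
            ses.append(src.se)
        if not ok:
            continue
        aligned_out = _align_to_reference(
            ref, outcome_by_id[snp], palindrome_policy, eaf_ambiguity_band
        )
        if isinstance(aligned_out, str):
            logger.info("%s: outcome dropped (%s)", snp, aligned_out)
            continue
        rows.append((snp, betas, ses, aligned_out[0], outcome_by_id[snp].se))

    if len(rows) < 2:
        raise HarmonizationError(
            f"multivariable set construction left {len(rows)} SNP(s); need >= 2"
        )
    snp_ids, bxs, sxs, bys, sys_ = zip(*rows)
    return MVMRSet(
        snp_ids=tuple(snp_ids),
        beta_exp=np.array(bxs, dtype=float),
        se_exp=np.array(sxs, dtype=float),
        beta_out=np.array(bys, dtype=float),
        se_out=np.array(sys_, dtype=float),
        exposure_names=names,
    )


def _check_rank(Xw: np.ndarray, names: Sequence[str]) -> None:
    cond = np.linalg.cond(Xw)
    if not np.isfinite(cond) or cond > COLLINEARITY_CONDITION_LIMIT:
        pairs = []
        with np.errstate(invalid="ignore"):
            C = np.corrcoef(Xw, rowvar=False)
        for i, j in combinations(range(len(names)), 2):
            if abs(C[i, j]) > 0.99 or not np.isfinite(C[i, j]):
                pairs.append(f"{names[i]}~{names[j]}")
        detail = f" (near-collinear: {', '.join(pairs)})" if pairs else ""
        raise CollinearityError(
            f"exposure design is rank-deficient or ill-conditioned "
            f"(condition number {cond:.3g}){detail}"
        )


def mvmr_ivw(mvset: MVMRSet, allow_collinear: bool = False) -> list[MREstimate]:
    """IVW multivariable MR: one direct-effect estimate per exposure.

    Zero-intercept weighted regression of outcome effects on the K columns
    of exposure effects with weights ``1/se_out^2``.  SEs carry the
    multiplicative ``sqrt(max(1, Q/(J-K)))`` heterogeneity inflation;
    p-values are normal.  A rank-deficient design raises
    :class:`CollinearityError` naming the collinear exposures unless
    ``allow_collinear`` (which merely skips the guard — a singular design
    still fails).
    """
    J, K = mvset.beta_exp.shape
    if J <= K:
        raise EstimationError(f"need more SNPs than exposures (J={J}, K={K})")
    w = 1.0 / mvset.se_out**2
    sw = np.sqrt(w)
    Xw = mvset.beta_exp * sw[:, None]
    yw = mvset.beta_out * sw
    if not allow_collinear:
        _check_rank(Xw, mvset.exposure_names)
    XtX = Xw.T @ Xw
    cov_unscaled = np.linalg.inv(XtX)
    theta = cov_unscaled @ (Xw.T @ yw)

    resid = mvset.beta_out - mvset.beta_exp @ theta
    Q = float(np.sum(w * resid**2))
    scale = np.sqrt(max(1.0, Q / (J - K)))
    se = np.sqrt(np.diag(cov_unscaled)) * scale

    out = []
    for k, name in enumerate(mvset.exposure_names):
        b, s = float(theta[k]), float(se[k])
        out.append(
            MREstimate(
                method=f"mvmr_ivw[{name}]",
                beta=b,
                se=s,
                pval=_two_sided_p(b / s),
                n_snp=J,
            )
        )
    return out


def mvmr_q(mvset: MVMRSet, estimates: Sequence[MREstimate]) -> HeterogeneityStats:
    """Cochran's Q about the fitted multivariable model (df = J - K)."""
    J, K = mvset.beta_exp.shape
    if len(estimates) != K:
        raise ValueError("one estimate per exposure required")
    theta = np.array([e.beta for e in estimates])
    w = 1.0 / mvset.se_out**2
    resid = mvset.beta_out - mvset.beta_exp @ theta
    Q = float(np.sum(w * resid**2))
    df = max(J - K, 1)
    return HeterogeneityStats(
        Q=Q,
        df=df,
        p_Q=float(max(stats.chi2.sf(Q, df), _P_FLOOR)),
        I2=i_squared(Q, df),
    )


def conditional_f(mvset: MVMRSet, warn: bool = True) -> dict[str, float]:
    """Sanderson–Windmeijer conditional instrument strength per exposure.

    For exposure k, regress its SNP effects on the other exposures' SNP
    effects with weights ``1/se_exp_k^2`` and form the weighted residual
    sum of squares ``Q_k``; then ``F_k = Q_k / (J - K + 1)``.  Large
    values mean the instrument moves exposure k independently of the
    others; values below 10 are logged as weak.
    """
    J, K = mvset.beta_exp.shape
    if K < 2:
        raise EstimationError(
            "conditional F requires >= 2 exposures; use mr.f_statistic for one"
        )
    if J <= K:
        raise EstimationError(f"need more SNPs than exposures (J={J}, K={K})")
    out: dict[str, float] = {}
    for k, name in enumerate(mvset.exposure_names):
        others = np.delete(mvset.beta_exp, k, axis=1)
        target = mvset.beta_exp[:, k]
        delta = 1.0 / mvset.se_exp[:, k] ** 2
        sw = np.sqrt(delta)
        coef, *_ = np.linalg.lstsq(others * sw[:, None], target * sw, rcond=None)
        resid = target - others @ coef
        Q_k = float(np.sum(delta * resid**2))
        F_k = Q_k / (J - K + 1)
        if warn and F_k < WEAK_INSTRUMENT_F:
            logger.warning(
                "weak conditional instrument for %s: F = %.3f < %.0f",
                name,
                F_k,
                WEAK_INSTRUMENT_F,
            )
        out[name] = F_k
    return out
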