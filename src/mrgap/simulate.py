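"""Seeded generators for two-sample GWAS summary statistics and cohorts.

These generators stand in for the consortium GWAS tables and the hospital
cohort the analyses were designed for, reproducing the statistical
structure the methods assume rather than any individual's data:

* :func:`simulate_two_sample_gwas` draws per-SNP exposure effects for an
  instrument of J independent variants, adds a configurable horizontal-
  pleiotropy model, and produces noisy exposure and outcome association
  records (with realistic allele bookkeeping, so the harmonization code
  paths are exercised by default);
* :func:`simulate_cohort` draws patient-level records whose stratum
  marginals (fasting glucose, triglycerides, HDL, age, sex mix) are
  calibrated to the published cohort's medians and IQRs, and whose
  glycation-gap and hemoglobin structure follows the published regression
  slopes as generator truth;
* :func:`scenario_presets` names the handful of study-condition presets
  the test-suite and acceptance checks run on.

Everything is reproducible: the same config (which carries the seed)
yields identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats

from .glycation import DEFAULT_HBA1C_COEFS, predicted_hba1c, tgi
from .summary_stats import COMPLEMENT, HarmonizedSet, SummaryStatRecord, harmonize

_P_FLOOR = np.finfo(float).tiny
_GWS = 5e-8

_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class Pleiotropy:
    """Horizontal-pleiotropy model for the direct SNP→outcome effects α_j.

    ``none``: α_j = 0.  ``balanced``: α_j ~ N(0, sd) — violates exclusion
    but not InSIDE, leaving IVW consistent.  ``directional``: α_j ~
    N(mean, sd) — biases IVW by ``mean`` while MR-Egger's intercept
    absorbs it.  ``inside_violating``: corr(α_j, γ_j) = ``corr`` — breaks
    the InSIDE assumption MR-Egger relies on.
    """

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0
    corr: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "balanced", "directional", "inside_violating"):
            raise ValueError(f"unknown pleiotropy kind {self.kind!r}")
        if self.kind == "inside_violating" and not (-1 < self.corr < 1):
            raise ValueError("corr must lie in (-1, 1)")

    @classmethod
    def none(cls) -> "Pleiotropy":
        return cls("none")

    @classmethod
    def balanced(cls, sd: float) -> "Pleiotropy":
        return cls("balanced", sd=sd)

    @classmethod
    def directional(cls, mean: float, sd: float) -> "Pleiotropy":
        return cls("directional", mean=mean, sd=sd)

    @classmethod
    def inside_violating(cls, corr: float, sd: float) -> "Pleiotropy":
        return cls("inside_violating", corr=corr, sd=sd)


@dataclass(frozen=True)
class GwasSimConfig:
    """Study conditions for a simulated two-sample MR instrument.

    ``J`` SNPs with true causal effect ``theta``; exposure/outcome GWAS
    sample sizes set the per-SNP standard errors through the standardized-
    trait approximation ``se ≈ 1/sqrt(2·maf·(1-maf)·n)``.  True
    instrument strengths |z| are drawn as ``z_min + |N(0, z_spread)|``
    (sign random), so ``z_min`` controls whether the panel sits in the
    genome-wide-significant regime.  ``invalid_fraction`` of SNPs get
    their Wald ratio shifted by ``invalid_ratio_offset`` (gross pleiotropy
    for robustness scenarios).  ``ensure_significant`` redraws observed
    exposure effects until genome-wide significant, emulating
    post-selection instruments.
    """

    J: int = 49
    theta: float = 0.5
    n_exp: int = 150_000
    n_out: int = 400_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy.none)
    invalid_fraction: float = 0.0
    invalid_ratio_offset: float = 1.0
    z_min: float = 8.0
    z_spread: float = 2.0
    palindromic_fraction: float = 0.2
    missing_outcome_fraction: float = 0.0
    ensure_significant: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.J < 3:
            raise ValueError("J must be at least 3")
        if self.n_exp <= 0 or self.n_out <= 0:
            raise ValueError("sample sizes must be positive")
        if not (0.0 <= self.invalid_fraction < 0.5):
            raise ValueError("invalid_fraction must lie in [0, 0.5)")


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.maximum(2.0 * stats.norm.sf(np.abs(beta / se)), _P_FLOOR)


def _draw_alleles(rng: np.random.Generator, J: int, palindromic_fraction: float):
    ea = np.empty(J, dtype=object)
    oa = np.empty(J, dtype=object)
    pal = rng.random(J) < palindromic_fraction
    for j in range(J):
        if pal[j]:
            ea[j], oa[j] = _PALINDROMIC_PAIRS[rng.integers(4)]
        else:
            a = _BASES[rng.integers(4)]
            choices = [b for b in _BASES if b != a and b != COMPLEMENT[a]]
            ea[j], oa[j] = a, choices[rng.integers(2)]
    return ea, oa


def simulate_two_sample_gwas(
    config: GwasSimConfig,
) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord]]:
    """Generate matched exposure and outcome summary-statistic records.

    Truth model per SNP j: exposure effect γ_j (scaled by ``z_min`` /
    ``z_spread``), pleiotropic direct effect α_j per the configured model,
    outcome mean ``θ·γ_j + α_j`` (plus ``invalid_ratio_offset·γ_j`` for
    invalid SNPs).  Observed betas add sampling noise at the GWAS standard
    errors; p-values are exactly ``2·Φ̄(|beta/se|)``.  The outcome file
    randomly swaps allele labels (sign-flipping its beta) and/or reports
    the opposite strand, so downstream harmonization is non-trivial.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    J = cfg.J

    maf = rng.uniform(*cfg.maf_range, J)
    se_x = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * cfg.n_exp)
    se_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * cfg.n_out)

    # Truth is expressed per exposure-increasing allele (the convention for
    # published instrument panels), so gamma > 0; directional pleiotropy is
    # directional *relative to that orientation*.  Outcome-file label swaps
    # below still scramble the observed signs.
    z_true = cfg.z_min + np.abs(rng.normal(0.0, cfg.z_spread, J))
    gamma = z_true * se_x

    pl = cfg.pleiotropy
    if pl.kind == "none":
        alpha = np.zeros(J)
    elif pl.kind == "balanced":
        alpha = rng.normal(0.0, pl.sd, J)
    elif pl.kind == "directional":
        alpha = rng.normal(pl.mean, pl.sd, J)
    else:  # inside_violating: corr(alpha, gamma) = corr
        g_std = (gamma - gamma.mean()) / gamma.std()
        alpha = pl.sd * (pl.corr * g_std + np.sqrt(1 - pl.corr**2) * rng.normal(0.0, 1.0, J))

    n_invalid = int(round(cfg.invalid_fraction * J))
    invalid = np.zeros(J, dtype=bool)
    if n_invalid:
        invalid[rng.choice(J, n_invalid, replace=False)] = True
        alpha = alpha + invalid * cfg.invalid_ratio_offset * gamma

    mu_y = cfg.theta * gamma + alpha

    beta_x = rng.normal(gamma, se_x)
    if cfg.ensure_significant:
        for _ in range(1000):
            weak = _pvals(beta_x, se_x) >= _GWS
            if not weak.any():
                break
            beta_x[weak] = rng.normal(gamma[weak], se_x[weak])
    beta_y = rng.normal(mu_y, se_y)

    ea, oa = _draw_alleles(rng, J, cfg.palindromic_fraction)
    side = rng.random(J) < 0.5
    eaf_exp = np.where(side, maf, 1.0 - maf)
    eaf_out = np.clip(eaf_exp + rng.normal(0.0, 0.005, J), 1e-3, 1 - 1e-3)

    p_x = _pvals(beta_x, se_x)
    p_y = _pvals(beta_y, se_y)

    exposure, outcome = [], []
    swap = rng.random(J) < 0.3
    flip_strand = rng.random(J) < 0.3
    drop_out = rng.random(J) < cfg.missing_outcome_fraction
    for j in range(J):
        snp = f"rs{j + 1:05d}"
        exposure.append(
            SummaryStatRecord(
                snp_id=snp,
                effect_allele=ea[j],
                other_allele=oa[j],
                beta=float(beta_x[j]),
                se=float(se_x[j]),
                pval=float(p_x[j]),
                eaf=float(eaf_exp[j]),
                n=float(cfg.n_exp),
            )
        )
        if drop_out[j]:
            continue
        o_ea, o_oa = ea[j], oa[j]
        o_beta, o_eaf = float(beta_y[j]), float(eaf_out[j])
        if swap[j]:
            o_ea, o_oa = o_oa, o_ea
            o_beta, o_eaf = -o_beta, 1.0 - o_eaf
        if flip_strand[j]:
            o_ea, o_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
        outcome.append(
            SummaryStatRecord(
                snp_id=snp,
                effect_allele=o_ea,
                other_allele=o_oa,
                beta=o_beta,
                se=float(se_y[j]),
                pval=float(p_y[j]),
                eaf=o_eaf,
                n=float(cfg.n_out),
            )
        )
    return exposure, outcome


def simulate_harmonized(config: GwasSimConfig, **harmonize_kwargs) -> HarmonizedSet:
    """Generate a study and harmonize it in one step (testing convenience)."""
    exposure, outcome = simulate_two_sample_gwas(config)
    return harmonize(exposure, outcome, **harmonize_kwargs)


# ---------------------------------------------------------------------------
# cohort generator


#: Per-stratum marginal targets (medians and IQRs of the published cohort).
COHORT_MARGINALS: dict[str, dict] = {
    "normoglycemia": {
        "fg": (5.10, (4.70, 5.50)),
        "tg": (1.16, (0.85, 1.68)),
        "hdl": (1.29, (1.07, 1.57)),
        "age": (50.0, (41.0, 58.0)),
        "female_frac": 0.48,
    },
    "preT2D": {
        "fg": (5.70, (5.20, 6.20)),
        "tg": (1.33, (0.99, 1.92)),
        "hdl": (1.19, (1.01, 1.43)),
        "age": (56.0, (49.0, 61.0)),
        "female_frac": 0.51,
    },
}


@dataclass(frozen=True)
class CohortSimConfig:
    """Study conditions for the synthetic observational cohort.

    Gap slopes/intercepts and the hemoglobin slope are the published
    regression coefficients used as generator truth; noise SDs are
    calibrated so the gap IQRs match the published stratum IQRs.
    ``hb_intercept`` places median hemoglobin at 145 g/L at the
    normoglycemic median TGI.
    """

    n: int = 7600
    frac_pre: float = 0.144
    gap_slope_pre: float = -0.087
    gap_slope_normo: float = 0.023
    gap_intercept_pre: float = 1.77
    gap_intercept_normo: float = 0.14
    hb_slope: float = 1.88
    hb_intercept: float = 129.1
    gap_noise_sd_pre: float = 0.18
    gap_noise_sd_normo: float = 0.33
    hb_noise_sd: float = 13.0
    hba1c_coefs: tuple[float, float] = DEFAULT_HBA1C_COEFS
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.frac_pre < 1.0):
            raise ValueError("frac_pre must lie in (0, 1)")
        if self.n < 100:
            raise ValueError("n must be at least 100")


def _lognormal(rng, median: float, iqr: tuple[float, float], size: int) -> np.ndarray:
    sigma = np.log(iqr[1] / iqr[0]) / (2.0 * stats.norm.ppf(0.75))
    return np.exp(rng.normal(np.log(median), sigma, size))


def _trunc_normal(rng, median, iqr, lo, hi, size) -> np.ndarray:
    sd = (iqr[1] - iqr[0]) / (2.0 * stats.norm.ppf(0.75))
    out = np.empty(0)
    while out.size < size:
        x = rng.normal(median, sd, 2 * size)
        out = np.concatenate([out, x[(x >= lo) & (x <= hi)]])
    return out[:size]


def _draw_stratum(rng: np.random.Generator, m: int, name: str, cfg: CohortSimConfig) -> pd.DataFrame:
    """Draw ``m`` records for one glycemic stratum.

    Records are drawn from the stratum's marginal model and accepted only
    if they satisfy the stratum's defining thresholds and the study's
    inclusion bounds — the same truncation that defines the strata in real
    data, where membership is itself a function of the measured values.
    """
    marg = COHORT_MARGINALS[name]
    pre = name == "preT2D"
    slope = cfg.gap_slope_pre if pre else cfg.gap_slope_normo
    intercept = cfg.gap_intercept_pre if pre else cfg.gap_intercept_normo
    noise_sd = cfg.gap_noise_sd_pre if pre else cfg.gap_noise_sd_normo

    chunks: list[pd.DataFrame] = []
    got = 0
    while got < m:
        k = max(2 * (m - got), 200)
        fg = _lognormal(rng, *marg["fg"], k)
        tg = _lognormal(rng, *marg["tg"], k)
        t = tgi(tg, fg)
        gap = intercept + slope * t + rng.normal(0.0, noise_sd, k)
        hba1c = predicted_hba1c(fg, cfg.hba1c_coefs) + gap
        if pre:
            ok = (fg < 7.0) & (hba1c < 6.5) & ((fg >= 6.0) | (hba1c >= 6.0)) & (fg > 3.5)
        else:
            ok = (fg < 6.0) & (hba1c < 6.0) & (fg > 3.0) & (hba1c > 3.5)
        idx = np.flatnonzero(ok)[: m - got]
        if idx.size == 0:
            continue
        hb = cfg.hb_intercept + cfg.hb_slope * t[idx] + rng.normal(0.0, cfg.hb_noise_sd, idx.size)
        hb = np.clip(hb, 80.0, 210.0)  # physiologic bounds; essentially never binds
        chunk = pd.DataFrame(
            {
                "age": _trunc_normal(rng, *marg["age"], 18.0, 65.0, idx.size),
                "sex": np.where(rng.random(idx.size) < marg["female_frac"], "female", "male"),
                "fg": fg[idx],
                "tg": tg[idx],
                "hdl": _lognormal(rng, *marg["hdl"], idx.size),
                "hba1c": hba1c[idx],
                "hb": hb,
                "stratum": name,
            }
        )
        chunks.append(chunk)
        got += idx.size
    return pd.concat(chunks, ignore_index=True)


def simulate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Generate a patient-level cohort table.

    Stratum membership is binomial with probability ``frac_pre``; each
    stratum is drawn from its calibrated marginal model with HbA1c built
    as predicted(FG) + glycation gap, the gap linear in TGI with the
    configured slope, and hemoglobin linear in TGI.  Rows are shuffled.
    Columns: age, sex, fg, tg, hdl, hba1c, hb, stratum (the generator's
    true label; the analysis pipeline re-derives labels by
    classification, which agrees by construction).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_pre = int(rng.binomial(cfg.n, cfg.frac_pre))
    parts = [
        _draw_stratum(rng, cfg.n - n_pre, "normoglycemia", cfg),
        _draw_stratum(rng, n_pre, "preT2D", cfg),
    ]
    df = pd.concat(parts, ignore_index=True)
    return df.iloc[rng.permutation(len(df))].reset_index(drop=True)


# ---------------------------------------------------------------------------
# presets


_PRESETS = {
    "fi_hb_like": "49-SNP genome-wide-significant instrument, theta=0.5",
    "strong_instrument": "49 SNPs with |z| large enough that NOME holds",
    "weak_instrument": "mean F below 10",
    "median_robust": "40% of SNPs invalid with gross ratio offsets",
    "null": "no causal effect (theta=0)",
}


def scenario_presets(name: str, seed: int | None = None) -> GwasSimConfig:
    """Named study-condition presets for the GWAS generator.

    ``fi_hb_like`` mirrors a realistic 49-SNP post-selection instrument.
    ``strong_instrument`` pushes |z| high enough that the no-measurement-
    error (NOME) assumption holds to Monte-Carlo resolution — the regime
    in which all five estimators are unbiased and consistency checks are
    meaningful (at realistic strengths every ratio-based estimator,
    MR-Egger most of all, shows the known weak-instrument dilution).
    ``weak_instrument`` sits below the F=10 convention; ``median_robust``
    makes 40% of SNPs grossly pleiotropic; ``null`` sets theta to zero.
    """
    if name == "fi_hb_like":
        cfg = GwasSimConfig(J=49, theta=0.5, ensure_significant=True)
    elif name == "strong_instrument":
        cfg = GwasSimConfig(
            J=49, theta=0.5, z_min=80.0, z_spread=40.0, ensure_significant=True
        )
    elif name == "weak_instrument":
        cfg = GwasSimConfig(J=49, theta=0.5, z_min=1.0, z_spread=1.0)
    elif name == "median_robust":
        cfg = GwasSimConfig(
            J=49, theta=0.5, invalid_fraction=0.4, invalid_ratio_offset=1.0,
            z_min=80.0, z_spread=40.0, ensure_significant=True,
        )
    elif name == "null":
        cfg = GwasSimConfig(J=49, theta=0.0, ensure_significant=True)
    else:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(sorted(_PRESETS))}"
        )
    return dataclasses.replace(cfg, seed=seed)
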