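"""Reading, selecting and harmonizing GWAS summary statistics.

The two-sample MR workflow starts from per-SNP association tables: one row
per variant carrying the effect allele, the other allele, the effect-allele
frequency (EAF), the estimated effect ``beta`` with standard error ``se``,
the two-sided p-value and the sample size.  This module turns such tables
into analysis-ready instrument sets:

* :func:`read_summary_stats` — parse a delimited text file into records;
* :func:`select_instrument` — keep genome-wide significant SNPs;
* :func:`proxy_substitute` — replace SNPs missing from the outcome study by
  LD proxies from a user-supplied lookup table;
* :func:`harmonize` — align exposure and outcome effects to a common effect
  allele, resolving strand flips and palindromic variants.

Harmonized data are held in :class:`HarmonizedSet`, a thin wrapper around a
:class:`pandas.DataFrame` that the estimators in :mod:`mrgap.mr` consume.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import HarmonizationError, InstrumentError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default header names for summary-statistic files.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp_id": "SNP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

_REQUIRED_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-effect-allele effect in trait-SD units (or log-odds
    for binary traits); ``se`` is its standard error on the same scale.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(
                f"{self.snp_id}: alleles must be single bases A/C/G/T, "
                f"got {self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not (self.se > 0):
            raise ValueError(f"{self.snp_id}: se must be positive, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.snp_id}: pval must lie in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"{self.snp_id}: eaf must lie in (0, 1), got {self.eaf}")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T or C/G variants, whose strand is label-ambiguous."""
        return COMPLEMENT[self.effect_allele] == self.other_allele

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass(frozen=True)
class Instrument:
    """A set of SNPs robustly associated with an exposure.

    ``proxied`` records which snp_ids entered via LD-proxy substitution.
    """

    exposure_name: str
    records: tuple[SummaryStatRecord, ...]
    p_threshold: float
    proxied: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        ids = [r.snp_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError(f"instrument for {self.exposure_name} has duplicated snp_ids")
        bad = [r.snp_id for r in self.records if not r.pval < self.p_threshold]
        if bad:
            raise ValueError(
                f"instrument for {self.exposure_name}: records above the "
                f"p threshold {self.p_threshold:g}: {bad[:5]}"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(r.snp_id for r in self.records)


@dataclass(frozen=True)
class HarmonizedSet:
    """Per-SNP exposure/outcome effects aligned to a common effect allele.

    ``table`` columns: ``snp_id, beta_exp, se_exp, beta_out, se_out,
    eaf_exp, eaf_out, proxy_used, flipped``.  Every ``beta_out`` is
    expressed per copy of the exposure's effect allele.
    """

    table: pd.DataFrame
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    palindrome_policy: str = "infer_by_eaf"
    dropped: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        t = self.table
        if t["snp_id"].duplicated().any():
            raise ValueError("harmonized set has duplicated snp_ids")
        if not ((t["se_exp"] > 0).all() and (t["se_out"] > 0).all()):
            raise ValueError("harmonized set contains non-positive standard errors")

    # -- array accessors used by the estimators ---------------------------
    @property
    def n_snp(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def beta_exp(self) -> np.ndarray:
        return self.table["beta_exp"].to_numpy(dtype=float)

    @property
    def se_exp(self) -> np.ndarray:
        return self.table["se_exp"].to_numpy(dtype=float)

    @property
    def beta_out(self) -> np.ndarray:
        return self.table["beta_out"].to_numpy(dtype=float)

    @property
    def se_out(self) -> np.ndarray:
        return self.table["se_out"].to_numpy(dtype=float)

    @classmethod
    def from_arrays(
        cls,
        beta_exp: Sequence[float],
        se_exp: Sequence[float],
        beta_out: Sequence[float],
        se_out: Sequence[float],
        snp_ids: Sequence[str] | None = None,
        **meta,
    ) -> "HarmonizedSet":
        """Build a set directly from aligned effect arrays (tests, simulation)."""
        beta_exp = np.asarray(beta_exp, dtype=float)
        if snp_ids is None:
            snp_ids = [f"snp{i+1}" for i in range(len(beta_exp))]
        table = pd.DataFrame(
            {
                "snp_id": list(snp_ids),
                "beta_exp": beta_exp,
                "se_exp": np.asarray(se_exp, dtype=float),
                "beta_out": np.asarray(beta_out, dtype=float),
                "se_out": np.asarray(se_out, dtype=float),
                "eaf_exp": np.nan,
                "eaf_out": np.nan,
                "proxy_used": False,
                "flipped": False,
            }
        )
        return cls(table=table, **meta)

    def without(self, snp_id: str) -> "HarmonizedSet":
        """Return a copy with one SNP removed (leave-one-out support)."""
        table = self.table[self.table["snp_id"] != snp_id].reset_index(drop=True)
        return replace(self, table=table, dropped=())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, **meta) -> "HarmonizedSet":
        table = pd.read_csv(path, sep="\t")
        return cls(table=table, **meta)


# ---------------------------------------------------------------------------
# reading


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[SummaryStatRecord]:
    """Read a delimited summary-statistic file into records.

    ``column_map`` maps field names (keys of :data:`DEFAULT_COLUMN_MAP`) to
    the file's header names; omitted keys fall back to the defaults.  Rows
    with missing or non-numeric beta/se are dropped and counted in the log;
    duplicated snp_ids keep the row with the lowest p-value.  Alleles are
    upper-cased.  A required column that cannot be mapped is fatal.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [cmap[f] for f in _REQUIRED_FIELDS if cmap[f] not in df.columns]
    if missing:
        raise InstrumentError(f"{path}: required columns not found: {missing}")

    has_eaf = cmap["eaf"] in df.columns
    has_n = cmap["n"] in df.columns

    records: list[SummaryStatRecord] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        try:
            beta = float(row[cmap["beta"]])
            se = float(row[cmap["se"]])
            if not (math.isfinite(beta) and math.isfinite(se)):
                raise ValueError("non-finite beta/se")
            eaf = float(row[cmap["eaf"]]) if has_eaf else None
            if eaf is not None and not math.isfinite(eaf):
                eaf = None
            n = float(row[cmap["n"]]) if has_n else None
            if n is not None and not math.isfinite(n):
                n = None
            rec = SummaryStatRecord(
                snp_id=str(row[cmap["snp_id"]]),
                effect_allele=str(row[cmap["effect_allele"]]).upper(),
                other_allele=str(row[cmap["other_allele"]]).upper(),
                beta=beta,
                se=se,
                pval=float(row[cmap["pval"]]),
                eaf=eaf,
                n=n,
            )
        except (TypeError, ValueError) as exc:
            n_rejected += 1
            logger.info("%s: rejected row (%s)", path, exc)
            continue
        records.append(rec)
    if n_rejected:
        logger.warning("%s: rejected %d rows with unusable values", path, n_rejected)

    return deduplicate(records)


def deduplicate(records: Iterable[SummaryStatRecord]) -> list[SummaryStatRecord]:
    """Keep the lowest-p record per snp_id, preserving first-seen order."""
    best: dict[str, SummaryStatRecord] = {}
    order: list[str] = []
    n_dropped = 0
    for rec in records:
        if rec.snp_id not in best:
            best[rec.snp_id] = rec
            order.append(rec.snp_id)
        else:
            n_dropped += 1
            if rec.pval < best[rec.snp_id].pval:
                best[rec.snp_id] = rec
    if n_dropped:
        logger.warning("dropped %d duplicated snp_ids (kept lowest p)", n_dropped)
    return [best[s] for s in order]


def records_to_frame(records: Sequence[SummaryStatRecord]) -> pd.DataFrame:
    """Tabulate records using the default column names (for export)."""
    return pd.DataFrame(
        {
            "SNP": [r.snp_id for r in records],
            "EA": [r.effect_allele for r in records],
            "OA": [r.other_allele for r in records],
            "EAF": [r.eaf for r in records],
            "BETA": [r.beta for r in records],
            "SE": [r.se for r in records],
            "P": [r.pval for r in records],
            "N": [r.n for r in records],
        }
    )


def write_summary_stats(records: Sequence[SummaryStatRecord], path, sep: str = "\t") -> None:
    records_to_frame(records).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# instrument selection


def select_instrument(
    records: Sequence[SummaryStatRecord],
    p_threshold: float = 5e-8,
    exposure_name: str = "exposure",
) -> Instrument:
    """Retain SNPs genome-wide significantly associated with the exposure.

    Selection is a strict inequality ``pval < p_threshold``; original order
    is preserved.  Zero survivors is fatal.
    """
    if not records:
        raise InstrumentError("no summary-statistic records supplied")
    kept = tuple(r for r in records if r.pval < p_threshold)
    if not kept:
        raise InstrumentError(
            f"no SNP reached the significance threshold p < {p_threshold:g} "
            f"for exposure {exposure_name!r}"
        )
    return Instrument(exposure_name=exposure_name, records=kept, p_threshold=p_threshold)


def proxy_substitute(
    instrument: Instrument,
    outcome_records: Sequence[SummaryStatRecord],
    ld_table: pd.DataFrame | Sequence[tuple[str, str, float]],
    r2_min: float = 0.8,
) -> Instrument:
    """Replace instrument SNPs absent from the outcome study by LD proxies.

    ``ld_table`` rows are ``(snp, proxy, r2)``.  A missing SNP is replaced
    by its highest-r² proxy with ``r2 > r2_min`` that is present in
    ``outcome_records``; with no such proxy the SNP is dropped.  The
    substituted record keeps the original SNP's exposure statistics but
    adopts the proxy's identifier and the outcome file's alleles/EAF (the
    proxy's own allele orientation is not knowable from an r² table alone —
    at r² > 0.8 the orientation of the frequency-matched allele is assumed
    to carry the effect).
    """
    if not isinstance(ld_table, pd.DataFrame):
        ld_table = pd.DataFrame(ld_table, columns=["snp", "proxy", "r2"])
    else:
        ld_table = ld_table.rename(
            columns=dict(zip(ld_table.columns[:3], ["snp", "proxy", "r2"]))
        )
    outcome_by_id = {r.snp_id: r for r in outcome_records}

    new_records: list[SummaryStatRecord] = []
    proxied: set[str] = set()
    for rec in instrument.records:
        if rec.snp_id in outcome_by_id:
            new_records.append(rec)
            continue
        cands = ld_table[(ld_table["snp"] == rec.snp_id) & (ld_table["r2"] > r2_min)]
        cands = cands[cands["proxy"].isin(outcome_by_id)]
        cands = cands[~cands["proxy"].isin({r.snp_id for r in new_records})]
        if cands.empty:
            logger.info(
                "%s: no outcome match and no proxy with r2 > %.2f; dropped",
                rec.snp_id,
                r2_min,
            )
            continue
        best = cands.loc[cands["r2"].idxmax()]
        out = outcome_by_id[str(best["proxy"])]
        new_records.append(
            replace(
                rec,
                snp_id=out.snp_id,
                effect_allele=out.effect_allele,
                other_allele=out.other_allele,
                eaf=out.eaf,
            )
        )
        proxied.add(out.snp_id)
        logger.info(
            "%s: substituted proxy %s (r2=%.3f)", rec.snp_id, out.snp_id, best["r2"]
        )
    if not new_records:
        raise InstrumentError("proxy substitution left an empty instrument")
    return Instrument(
        exposure_name=instrument.exposure_name,
        records=tuple(new_records),
        p_threshold=instrument.p_threshold,
        proxied=frozenset(proxied),
    )


# ---------------------------------------------------------------------------
# harmonization


def _align_to_reference(
    ref: SummaryStatRecord,
    other: SummaryStatRecord,
    palindrome_policy: str,
    eaf_ambiguity_band: tuple[float, float],
) -> tuple[float, float | None, bool] | str:
    """Align ``other``'s effect to ``ref``'s effect allele.

    Returns ``(beta, eaf, flipped)`` on success or a drop-reason string.
    The comparison tries direct label match, label swap, strand complement
    and complement-plus-swap; palindromic variants, for which labels cannot
    resolve the strand, are handled per ``palindrome_policy``.
    """
    e = (ref.effect_allele, ref.other_allele)
    o = (other.effect_allele, other.other_allele)
    oc = (COMPLEMENT[other.effect_allele], COMPLEMENT[other.other_allele])

    if ref.is_palindromic:
        if set(o) != set(e):
            return "incompatible_alleles"
        if palindrome_policy == "drop_all":
            return "palindromic"
        if palindrome_policy != "infer_by_eaf":
            raise ValueError(f"unknown palindrome policy {palindrome_policy!r}")
        lo, hi = eaf_ambiguity_band
        if ref.eaf is None or other.eaf is None:
            return "palindromic_no_eaf"
        if lo < ref.eaf < hi or lo < other.eaf < hi:
            return "palindromic_ambiguous_eaf"
        # Frequency of other's allele matching ref's EA label:
        f = other.eaf if o == e else 1.0 - other.eaf
        beta = other.beta if o == e else -other.beta
        if (ref.eaf < 0.5) == (f < 0.5):
            return beta, f, beta != other.beta
        # opposite frequency sides: the label match is a strand artefact
        return -beta, 1.0 - f, -beta != other.beta

    if o == e or oc == e:
        return other.beta, other.eaf, False
    if o == (e[1], e[0]) or oc == (e[1], e[0]):
        eaf = None if other.eaf is None else 1.0 - other.eaf
        return -other.beta, eaf, True
    return "incompatible_alleles"


def harmonize(
    exposure_records: Sequence[SummaryStatRecord] | Instrument,
    outcome_records: Sequence[SummaryStatRecord],
    palindrome_policy: str = "infer_by_eaf",
    eaf_ambiguity_band: tuple[float, float] = (0.42, 0.58),
    exposure_name: str | None = None,
    outcome_name: str = "outcome",
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    For each SNP shared by both studies the outcome beta is re-expressed
    per copy of the exposure's effect allele, flipping sign (and
    complementing EAF) when the outcome file lists the alleles in the
    opposite orientation.  Palindromic (A/T, C/G) variants are dropped
    outright under ``palindrome_policy='drop_all'``; under
    ``'infer_by_eaf'`` the strand is inferred from allele frequency unless
    either study's EAF lies inside ``eaf_ambiguity_band``.  SNPs with
    irreconcilable alleles are dropped and logged.  An empty intersection
    is fatal.
    """
    proxied: frozenset[str] = frozenset()
    if isinstance(exposure_records, Instrument):
        if exposure_name is None:
            exposure_name = exposure_records.exposure_name
        proxied = exposure_records.proxied
        exposure_records = exposure_records.records
    if exposure_name is None:
        exposure_name = "exposure"

    outcome_by_id = {r.snp_id: r for r in outcome_records}
    shared = [r for r in exposure_records if r.snp_id in outcome_by_id]
    if not shared:
        raise HarmonizationError(
            f"no SNPs shared between {exposure_name} and {outcome_name}"
        )

    rows = []
    dropped: list[tuple[str, str]] = []
    for exp in shared:
        out = outcome_by_id[exp.snp_id]
        aligned = _align_to_reference(exp, out, palindrome_policy, eaf_ambiguity_band)
        if isinstance(aligned, str):
            dropped.append((exp.snp_id, aligned))
            logger.info("%s: dropped during harmonization (%s)", exp.snp_id, aligned)
            continue
        beta_out, eaf_out, flipped = aligned
        rows.append(
            {
                "snp_id": exp.snp_id,
                "beta_exp": exp.beta,
                "se_exp": exp.se,
                "beta_out": beta_out,
                "se_out": out.se,
                "eaf_exp": np.nan if exp.eaf is None else exp.eaf,
                "eaf_out": np.nan if eaf_out is None else eaf_out,
                "proxy_used": exp.snp_id in proxied,
                "flipped": flipped,
            }
        )
    if not rows:
        raise HarmonizationError(
            f"harmonization of {exposure_name} on {outcome_name} left no SNPs "
            f"(all {len(shared)} shared SNPs dropped)"
        )
    table = pd.DataFrame(rows)
    return HarmonizedSet(
        table=table,
        exposure_name=exposure_name,
        outcome_name=outcome_name,
        palindrome_policy=palindrome_policy,
        dropped=tuple(dropped),
    )
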