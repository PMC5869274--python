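"""Per-locus diversity indices and the Hardy-Weinberg chi-square test.

For a biallelic locus with allele frequencies p (insertion) and q = 1 - p:

* expected homozygosity  Ho  = p^2 + q^2          (Nei gene identity)
* expected heterozygosity He = 1 - Ho = 2pq       (Nei gene diversity)
* polymorphism information content
  PIC = 1 - p^2 - q^2 - 2 p^2 q^2                 (Botstein)

PIC is classed low (<= 0.25), medium (0.25-0.5] and high (> 0.5); the
boundary values fall in the lower class.

The HWE test is the Pearson chi-square over the three genotype classes
against expectations n*(p^2, 2pq, q^2) at the estimated allele frequencies,
with no continuity correction.  Two degree-of-freedom conventions are
offered: ``match_shesis`` (df = 2, genotype classes minus one — the
convention used by the SHEsis platform, whose tail is exp(-chi2/2)) and
``theoretical`` (df = 1, subtracting the estimated allele frequency).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .io import GenotypeCounts


class EmptyLocusError(ValueError):
    """No non-missing genotypes at the locus."""


class MonomorphicLocusError(ValueError):
    """Only one allele observed; the statistic is undefined."""


def round_half_away(x: float, digits: int = 3) -> float:
    """Round half away from zero, as printed tables conventionally do."""
    return float(Decimal(repr(x)).quantize(Decimal(1).scaleb(-digits),
                                           rounding=ROUND_HALF_UP))


def allele_frequencies(counts: GenotypeCounts) -> tuple[float, float]:
    """Allele frequencies (p_ins, q_del) by gene counting."""
    n = counts.n_total
    if n == 0:
        raise EmptyLocusError("no genotyped animals at locus")
    p = (2 * counts.n_II + counts.n_ID) / (2 * n)
    return p, 1.0 - p


def _check_freqs(freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9 or (freqs < 0).any():
        raise ValueError("allele frequencies must be non-negative and sum to 1")
    return freqs


def heterozygosity(freqs) -> tuple[float, float]:
    """Expected homozygosity Ho = sum p_i^2 and heterozygosity He = 1 - Ho."""
    freqs = _check_freqs(freqs)
    ho = float(np.sum(freqs ** 2))
    return ho, 1.0 - ho


def pic(freqs) -> float:
    """Polymorphism information content, 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2."""
    freqs = _check_freqs(freqs)
    sq = freqs ** 2
    cross = np.outer(sq, sq)
    return float(1.0 - sq.sum() - np.triu(cross, k=1).sum() * 2.0)


def pic_class(value: float) -> str:
    """Diversity class: low (<=0.25), medium (0.25, 0.5], high (>0.5)."""
    if not 0.0 <= value <= 1.0:
        raise ValueError("PIC must lie in [0, 1]")
    if value <= 0.25:
        return "low"
    if value <= 0.5:
        return "medium"
    return "high"


@dataclass(frozen=True)
class HweResult:
    chi2: float
    df: int
    p: float
    expected: tuple[float, float, float]


def hwe_test(counts: GenotypeCounts, df_mode: str = "match_shesis") -> HweResult:
    """Pearson chi-square test of Hardy-Weinberg proportions.

    Expected counts are n*(p^2, 2pq, q^2) from the estimated allele
    frequencies.  Expected counts below 5 warn but do not refuse.
    """
    if df_mode not in ("match_shesis", "theoretical"):
        raise ValueError(f"unknown df_mode {df_mode!r}")
    p, q = allele_frequencies(counts)
    if p == 0.0 or q == 0.0:
        raise MonomorphicLocusError("HWE test undefined at a monomorphic locus")
    n = counts.n_total
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    if (expected < 5).any():
        warnings.warn("expected genotype count below 5; chi-square approximation "
                      "may be poor", stacklevel=2)
    chi2 = float(np.sum((counts.as_array() - expected) ** 2 / expected))
    df = 2 if df_mode == "match_shesis" else 1
    pval = float(stats.chi2.sf(chi2, df))
    return HweResult(chi2=chi2, df=df, p=pval, expected=tuple(expected))


def inbreeding_coefficient(counts: GenotypeCounts) -> float:
    """Wright's F = 1 - H_obs / He, the relative heterozygote deficit."""
    p, q = allele_frequencies(counts)
    _, he = heterozygosity([p, q])
    if he == 0.0:
        raise MonomorphicLocusError("F undefined at a monomorphic locus")
    h_obs = counts.n_ID / counts.n_total
    return 1.0 - h_obs / he


@dataclass(frozen=True)
class DiversitySummary:
    """Everything a per-locus diversity table row carries."""

    locus_id: str
    counts: GenotypeCounts
    genotype_freqs: tuple[float, float, float]
    p_ins: float
    q_del: float
    ho: float
    he: float
    pic: float
    pic_class: str
    hwe_chi2: float
    hwe_df: int
    hwe_p: float
    inbreeding_f: float


def summarize_locus(
    counts: GenotypeCounts, locus_id: str = "", df_mode: str = "match_shesis"
) -> DiversitySummary:
    """Assemble the full diversity summary for one locus."""
    n = counts.n_total
    if n == 0:
        raise EmptyLocusError("no genotyped animals at locus")
    p, q = allele_frequencies(counts)
    ho, he = heterozygosity([p, q])
    pic_val = pic([p, q])
    hwe = hwe_test(counts, df_mode=df_mode)
    return DiversitySummary(
        locus_id=locus_id,
        counts=counts,
        genotype_freqs=(counts.n_II / n, counts.n_ID / n, counts.n_DD / n),
        p_ins=p,
        q_del=q,
        ho=ho,
        he=he,
        pic=pic_val,
        pic_class=pic_class(pic_val),
        hwe_chi2=hwe.chi2,
        hwe_df=hwe.df,
        hwe_p=hwe.p,
        inbreeding_f=inbreeding_coefficient(counts),
    )
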