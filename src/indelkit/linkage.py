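"""Two-locus linkage disequilibrium from unphased genotype counts.

Haplotype frequencies are estimated by the standard two-locus EM algorithm.
With biallelic loci only the double-heterozygote cell (ID, ID) is phase
ambiguous: it mixes cis (I-I / D-D) and trans (I-D / D-I) pairs.  The
E-step splits that cell between the two phases in proportion to the current
haplotype-frequency products; the M-step re-estimates the four haplotype
frequencies by gene counting.  Marginal allele frequencies are preserved
exactly at every iteration, and the observed-data log-likelihood is
non-decreasing.

From the haplotype frequencies f = (f_II, f_ID, f_DI, f_DD), where the
first index is the allele at locus A and the second at locus B:

* D       = f_II - p_A * p_B
* D'      = |D| / D_max, with D_max = min(p_A q_B, q_A p_B) for D > 0 and
            min(p_A p_B, q_A q_B) for D < 0
* r^2     = D^2 / (p_A q_A p_B q_B)

r^2 > 0.33 is conventionally called strong LD and r^2 = 1 complete LD.
(Some sources describe r^2 = 0 as "perfect LD"; that contradicts standard
usage — r^2 = 0 is linkage equilibrium — and is not followed here.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CohortTable, GENOTYPES, IndelLocus


class UndefinedLDError(ValueError):
    """A locus is monomorphic in the table, so LD is undefined."""


# haplotype order: (I,I), (I,D), (D,I), (D,D); index = alleles at (A, B)
HAPLOTYPES = ("II", "ID", "DI", "DD")


@dataclass
class TwoLocusCounts:
    """3x3 joint genotype counts; rows locus A (II/ID/DD), cols locus B."""

    table: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != (3, 3):
            raise ValueError("joint genotype table must be 3x3")
        if (self.table < 0).any() or self.table.sum() <= 0:
            raise ValueError("counts must be non-negative with positive total")

    @classmethod
    def from_cohort(
        cls, cohort: CohortTable, locus_a: IndelLocus | str, locus_b: IndelLocus | str
    ) -> "TwoLocusCounts":
        """Cross-tabulate complete cases at both loci."""
        a = locus_a.locus_id if isinstance(locus_a, IndelLocus) else locus_a
        b = locus_b.locus_id if isinstance(locus_b, IndelLocus) else locus_b
        sub = cohort.data[[a, b]].dropna()
        table = np.zeros((3, 3))
        for i, ga in enumerate(GENOTYPES):
            for j, gb in enumerate(GENOTYPES):
                table[i, j] = ((sub[a] == ga) & (sub[b] == gb)).sum()
        return cls(table)

    @property
    def n(self) -> float:
        return float(self.table.sum())


@dataclass
class HaplotypeEstimate:
    freqs: np.ndarray          # order HAPLOTYPES
    D: float
    D_prime: float
    r2: float
    loglik: float
    iterations: int
    converged: bool

    @property
    def freqs_dict(self) -> dict[str, float]:
        return dict(zip(HAPLOTYPES, self.freqs))


def cell_probabilities(freqs: np.ndarray) -> np.ndarray:
    """3x3 genotype-cell probabilities under random union of haplotypes."""
    f11, f12, f21, f22 = freqs
    return np.array([
        [f11 ** 2,        2 * f11 * f12,                  f12 ** 2],
        [2 * f11 * f21,   2 * f11 * f22 + 2 * f12 * f21,  2 * f12 * f22],
        [f21 ** 2,        2 * f21 * f22,                  f22 ** 2],
    ])


def genotype_loglik(freqs: np.ndarray, counts: TwoLocusCounts) -> float:
    """Observed-data multinomial log-likelihood of a haplotype 4-vector."""
    probs = cell_probabilities(np.asarray(freqs, dtype=float))
    mask = counts.table > 0
    if (probs[mask] <= 0).any():
        return -np.inf
    return float(np.sum(counts.table[mask] * np.log(probs[mask])))


def _allele_margins(counts: TwoLocusCounts) -> tuple[float, float]:
    """Frequencies of allele I at locus A and locus B from genotype margins."""
    n2 = 2.0 * counts.n
    row = counts.table.sum(axis=1)
    col = counts.table.sum(axis=0)
    p_a = (2 * row[0] + row[1]) / n2
    p_b = (2 * col[0] + col[1]) / n2
    return p_a, p_b


def em_haplotypes(
    counts: TwoLocusCounts,
    tol: float = 1e-8,
    max_iter: int = 1000,
    start: np.ndarray | None = None,
) -> HaplotypeEstimate:
    """EM estimate of two-locus haplotype frequencies and LD measures.

    The profile likelihood in the one free phase parameter can carry two
    local maxima separated by a saddle at linkage equilibrium, so by default
    the (deterministic) iteration is run from three starts — the
    linkage-equilibrium product of the marginal allele frequencies and the
    two near-boundary phase configurations — and the highest-likelihood
    solution is kept.  An explicit ``start`` runs a single EM from there.
    """
    p_a, p_b = _allele_margins(counts)
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise UndefinedLDError("a locus is monomorphic in the joint table")

    if start is None:
        lo = max(0.0, p_a + p_b - 1.0)
        hi = min(p_a, p_b)
        starts = []
        for f11 in (p_a * p_b, lo + 0.98 * (hi - lo), lo + 0.02 * (hi - lo)):
            starts.append(np.array([f11, p_a - f11, p_b - f11,
                                    1.0 - p_a - p_b + f11]))
        fits = [em_haplotypes(counts, tol=tol, max_iter=max_iter, start=s)
                for s in starts]
        return max(fits, key=lambda e: e.loglik)

    freqs = np.asarray(start, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9 or (freqs < -1e-12).any():
        raise ValueError("start frequencies must be a probability 4-vector")
    freqs = np.clip(freqs, 0.0, None)
    t = counts.table
    n2 = 2.0 * counts.n
    # phase-unambiguous haplotype contributions from the eight fixed cells
    base = np.array([
        2 * t[0, 0] + t[0, 1] + t[1, 0],
        2 * t[0, 2] + t[0, 1] + t[1, 2],
        2 * t[2, 0] + t[1, 0] + t[2, 1],
        2 * t[2, 2] + t[1, 2] + t[2, 1],
    ])
    n_dh = t[1, 1]

    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        cis = freqs[0] * freqs[3]
        trans = freqs[1] * freqs[2]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        new = (base + n_dh * np.array([w, 1 - w, 1 - w, w])) / n2
        step = float(np.max(np.abs(new - freqs)))
        freqs = new
        if step < tol:
            converged = True
            break

    d, d_prime, r2 = ld_measures(freqs)
    return HaplotypeEstimate(
        freqs=freqs, D=d, D_prime=d_prime, r2=r2,
        loglik=genotype_loglik(freqs, counts),
        iterations=iterations, converged=converged,
    )


def ld_measures(freqs) -> tuple[float, float, float]:
    """D, D' and r^2 from a haplotype frequency 4-vector (order HAPLOTYPES)."""
    freqs = np.asarray(freqs, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9 or (freqs < 0).any():
        raise ValueError("haplotype frequencies must be non-negative and sum to 1")
    p_a = freqs[0] + freqs[1]
    p_b = freqs[0] + freqs[2]
    q_a, q_b = 1 - p_a, 1 - p_b
    if min(p_a, q_a, p_b, q_b) <= 0:
        raise UndefinedLDError("marginal allele frequency of 0 or 1")
    d = freqs[0] - p_a * p_b
    if d >= 0:
        d_max = min(p_a * q_b, q_a * p_b)
    else:
        d_max = min(p_a * p_b, q_a * q_b)
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    r2 = d * d / (p_a * q_a * p_b * q_b)
    return float(d), float(d_prime), float(r2)


def ld_class(r2: float, strong_threshold: float = 0.33) -> str:
    """Label r^2: complete (=1), strong (> threshold), else weak."""
    if not 0.0 <= r2 <= 1.0 + 1e-12:
        raise ValueError("r^2 must lie in [0, 1]")
    if r2 >= 1.0 - 1e-12:
        return "complete"
    if r2 > strong_threshold:
        return "strong"
    return "weak"
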