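"""Independent oracles used by the test suite.

These deliberately avoid the library's own code paths: the LD oracle
profiles the multinomial likelihood over the single free phase parameter by
dense grid search, and the ANOVA oracle is scipy's f_oneway.
"""

from __future__ import annotations

import numpy as np


def grid_profile_loglik(table: np.ndarray, n_grid: int = 20001) -> float:
    """Maximum log-likelihood over haplotype freqs with margins fixed at the
    observed allele frequencies, by dense grid over f(I,I).

    The 3x3 genotype table determines the allele frequencies at both loci
    exactly; the only free parameter is the frequency of the cis I-I
    haplotype, bounded by the Frechet limits.
    """
    t = np.asarray(table, dtype=float)
    n2 = 2.0 * t.sum()
    row, col = t.sum(axis=1), t.sum(axis=0)
    p_a = (2 * row[0] + row[1]) / n2
    p_b = (2 * col[0] + col[1]) / n2
    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    f11 = np.linspace(lo, hi, n_grid)
    f12 = p_a - f11
    f21 = p_b - f11
    f22 = 1.0 - p_a - p_b + f11
    # genotype-cell probabilities under random union of haplotypes
    probs = np.stack([
        f11 ** 2, 2 * f11 * f12, f12 ** 2,
        2 * f11 * f21, 2 * f11 * f22 + 2 * f12 * f21, 2 * f12 * f22,
        f21 ** 2, 2 * f21 * f22, f22 ** 2,
    ])  # 9 x n_grid
    counts = t.reshape(9, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * np.log(probs), 0.0)
        ll = np.where((counts > 0) & (probs <= 0), -np.inf, ll)
    return float(np.nanmax(ll.sum(axis=0)))


def random_small_table(rng: np.random.Generator, max_total: int = 30) -> np.ndarray:
    """A random polymorphic 3x3 genotype table with total <= max_total."""
    while True:
        total = int(rng.integers(4, max_total + 1))
        probs = rng.dirichlet(np.ones(9))
        t = rng.multinomial(total, probs).reshape(3, 3)
        n2 = 2.0 * total
        row, col = t.sum(axis=1), t.sum(axis=0)
        p_a = (2 * row[0] + row[1]) / n2
        p_b = (2 * col[0] + col[1]) / n2
        if 0.0 < p_a < 1.0 and 0.0 < p_b < 1.0:
            return t
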