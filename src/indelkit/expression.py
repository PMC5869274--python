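"""qPCR relative expression: geNorm reference selection and 2^-ddCt.

geNorm stability: each gene's Ct is transformed to a relative quantity
a = 2^(minCt - Ct); for every ordered gene pair (j, k) the pairwise
variation V_jk is the standard deviation over samples of log2(a_j / a_k),
and the stability measure M_j is the mean of V_jk over k != j.  The gene
with the lowest M is the most stable candidate reference.  M is invariant
to per-sample loading offsets because they cancel in the ratios.

Relative expression uses the ddCt method with amplification efficiency
fixed at 2: dCt = Ct_target - Ct_reference per sample, ddCt = dCt minus the
calibrator group's mean dCt, fold = 2^-ddCt.  The calibrator group's mean
ddCt is exactly zero by construction, so its geometric-mean fold is 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import compact_letters
from .io import CtMatrix


@dataclass
class GeNormResult:
    m_values: pd.Series            # per-gene M, ascending = more stable
    ranking: list[str]             # most stable first
    selected: str


@dataclass
class DdctResult:
    target: str
    reference: str
    calibrator: str
    per_sample: pd.DataFrame       # columns: group, dct, ddct, fold
    per_group: pd.DataFrame        # columns: n, mean_fold, se_fold


def genorm_m(ct: CtMatrix, candidates: list[str]) -> GeNormResult:
    """geNorm average pairwise-variation M for candidate reference genes."""
    missing = [g for g in candidates if g not in ct.genes]
    if missing:
        raise KeyError(f"candidate genes not in Ct matrix: {missing}")
    if len(candidates) < 2:
        raise ValueError("geNorm needs >= 2 candidate genes")
    sub = ct.ct[candidates].astype(float)
    if len(sub) < 2:
        raise ValueError("geNorm needs >= 2 samples")
    if sub.isna().any().any():
        n_before = len(sub)
        sub = sub.dropna()
        warnings.warn(f"dropped {n_before - len(sub)} samples with missing Ct",
                      stacklevel=2)
    # log2 a_j - log2 a_k = (minCt_j - Ct_j) - (minCt_k - Ct_k)
    logq = sub.min(axis=0) - sub
    m = {}
    for j in candidates:
        vs = [float(np.std(logq[j] - logq[k], ddof=1))
              for k in candidates if k != j]
        m[j] = float(np.mean(vs))
    m_series = pd.Series(m).sort_values()
    return GeNormResult(m_values=m_series,
                        ranking=list(m_series.index),
                        selected=str(m_series.index[0]))


def ddct(
    ct: CtMatrix, target: str, reference: str, calibrator: str
) -> DdctResult:
    """Livak 2^-ddCt relative expression against a calibrator group."""
    for gene in (target, reference):
        if gene not in ct.genes:
            raise KeyError(f"gene {gene!r} not in Ct matrix")
    groups = ct.groups.astype(str)
    if not (groups == calibrator).any():
        raise ValueError(f"calibrator group {calibrator!r} empty")
    dct = ct.ct[target].astype(float) - ct.ct[reference].astype(float)
    cal_mean = float(dct[groups == calibrator].mean())
    ddct_vals = dct - cal_mean
    fold = np.power(2.0, -ddct_vals)
    per_sample = pd.DataFrame({
        "group": groups, "dct": dct, "ddct": ddct_vals, "fold": fold,
    })
    grp = per_sample.groupby("group")["fold"]
    per_group = pd.DataFrame({
        "n": grp.size(),
        "mean_fold": grp.mean(),
        "se_fold": grp.apply(lambda v: v.std(ddof=1) / np.sqrt(len(v))
                             if len(v) > 1 else 0.0),
    })
    return DdctResult(target=target, reference=reference, calibrator=calibrator,
                      per_sample=per_sample, per_group=per_group)


@dataclass
class GroupComparison:
    design: str                    # "two-group" or "multi-group"
    p_overall: float
    letters: dict[str, str]
    pairwise_p: dict[tuple[str, str], float]
    excluded_groups: list[str]


def compare_groups(result: DdctResult, alpha: float = 0.05) -> GroupComparison:
    """Compare per-group fold changes: t-test (2 groups) or ANOVA + Tukey.

    Groups with fewer than 2 samples are excluded with a warning.  Letters
    follow the usual compact display: groups sharing a letter do not differ
    at the given alpha.
    """
    counts = result.per_sample.groupby("group").size()
    excluded = [g for g, n in counts.items() if n < 2]
    if excluded:
        warnings.warn(f"groups excluded (n < 2): {excluded}", stacklevel=2)
    kept = [g for g in counts.index if g not in excluded]
    if len(kept) < 2:
        raise ValueError("need >= 2 groups with >= 2 samples")
    values = {g: result.per_sample.loc[result.per_sample["group"] == g, "fold"]
              .to_numpy() for g in kept}
    means = {g: float(v.mean()) for g, v in values.items()}
    if len(kept) == 2:
        g1, g2 = kept
        _, p = stats.ttest_ind(values[g1], values[g2], equal_var=True)
        p = float(p)
        sig = {frozenset((g1, g2))} if p < alpha else set()
        letters = compact_letters(kept, means, sig)
        return GroupComparison(design="two-group", p_overall=p, letters=letters,
                               pairwise_p={(g1, g2): p}, excluded_groups=excluded)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    from itertools import combinations
    _, p_overall = stats.f_oneway(*values.values())
    flat = np.concatenate([values[g] for g in kept])
    labels = np.concatenate([[g] * len(values[g]) for g in kept])
    hsd = pairwise_tukeyhsd(flat, labels, alpha=alpha)
    uniq = [str(g) for g in hsd.groupsunique]
    pairwise, sig = {}, set()
    for (g1, g2), pv, rej in zip(combinations(uniq, 2), hsd.pvalues, hsd.reject):
        pairwise[(g1, g2)] = float(pv)
        if rej:
            sig.add(frozenset((g1, g2)))
    letters = compact_letters(kept, means, sig)
    return GroupComparison(design="multi-group", p_overall=float(p_overall),
                           letters=letters, pairwise_p=pairwise,
                           excluded_groups=excluded)
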