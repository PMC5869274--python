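"""Litter-size association with indel genotype.

The trait model is a two-factor fixed-effects linear model,

    Y_ij = mu + HYS_i + G_j + e_ij,

with herd-year-season (HYS) and genotype both fixed and no interaction.
The genotype F-test is sequential (HYS entered first): it compares the
residual sum of squares of ``mu + HYS`` against ``mu + HYS + G``.  With a
single HYS level this reduces exactly to one-way ANOVA.  Litter size is a
small count (mostly 1-2) fitted with a Gaussian linear model; that mirrors
common practice in livestock candidate-gene studies and is documented as a
limitation rather than replaced by an ordinal model.

Pairwise genotype contrasts use the Tukey-Kramer studentized-range test
with a greedy compact letter display.  Mothers are also dichotomised into
single-lamb (litter size 1, MSL) versus multi-lamb (>= 2, MML) classes and
genotype distributions compared by a 2x3 Pearson chi-square without
continuity correction; a genotype column is dropped only when its grand
total is zero (a zero cell within a non-empty column is retained).

The subset-robustness scan draws nested random subsets of increasing size
and demands significance at every size before declaring an association
robust.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import CohortTable, GENOTYPES, IndelLocus


def _locus_id(locus: IndelLocus | str) -> str:
    return locus.locus_id if isinstance(locus, IndelLocus) else locus


@dataclass
class AssociationResult:
    """Fixed-effects model fit plus per-genotype descriptive statistics."""

    locus_id: str
    groups: list[str]                      # genotype classes present, II/ID/DD order
    group_n: dict[str, int]
    group_mean: dict[str, float]
    group_se: dict[str, float]
    mu: float
    hys_effects: dict[str, float]
    genotype_effects: dict[str, float]     # contrasts relative to first group
    genotype_se: dict[str, float]          # SE of those contrasts
    F_genotype: float
    p_genotype: float
    df_num: int
    df_den: int
    F_oneway: float                        # plain one-way ANOVA ignoring HYS
    p_oneway: float
    n_used: int
    dropped_groups: list[str] = field(default_factory=list)
    _values: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


@dataclass
class ContingencyResult:
    observed: pd.DataFrame                 # rows MSL/MML, columns genotypes
    expected: pd.DataFrame
    chi2: float
    df: int
    p: float
    dropped_columns: list[str] = field(default_factory=list)


@dataclass
class SubsetScanResult:
    locus_id: str
    sizes: list[int]
    alpha: float
    seed: int
    nested: bool
    model_p: np.ndarray                    # replicates x sizes
    contingency_p: np.ndarray
    group_means: list[list[dict[str, float]]]
    decisions: np.ndarray                  # per-replicate conjunctive flag
    skipped_sizes: list[int] = field(default_factory=list)

    @property
    def decision_rate(self) -> float:
        return float(np.mean(self.decisions))


class ZeroVarianceError(ValueError):
    """All phenotype values identical; the F test is undefined."""


def _design(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded dummy columns for a categorical factor."""
    levels = [lv for lv in pd.unique(labels)]
    cols = [(labels == lv).to_numpy(dtype=float) for lv in levels[1:]]
    return (np.column_stack(cols) if cols else np.empty((len(labels), 0)),
            levels)


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid), int(rank)


def fit_litter_model(
    cohort: CohortTable, locus: IndelLocus | str, min_group_n: int = 2
) -> AssociationResult:
    """OLS fit of litter size on HYS + genotype with a sequential G test.

    Genotype classes with fewer than ``min_group_n`` phenotyped animals are
    omitted with a warning (small classes cannot support a within-group
    variance).  Requires at least two usable classes.
    """
    lid = _locus_id(locus)
    df = cohort.data[[lid, "hys", "litter_size"]].dropna()
    if df.empty:
        raise ValueError("no phenotyped, genotyped animals at locus")

    dropped = []
    sizes = df[lid].value_counts()
    for g in GENOTYPES:
        if 0 < sizes.get(g, 0) < min_group_n or sizes.get(g, 0) == 0:
            if sizes.get(g, 0) > 0:
                dropped.append(g)
    if dropped:
        warnings.warn(f"genotype class(es) {dropped} omitted (n < {min_group_n})",
                      stacklevel=2)
        df = df[~df[lid].isin(dropped)]
    groups = [g for g in GENOTYPES if g in set(df[lid])]
    if len(groups) < 2:
        raise ValueError("need >= 2 genotype classes with phenotypes")

    y = df["litter_size"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ZeroVarianceError("all litter sizes identical")

    ones = np.ones((len(df), 1))
    X_hys, hys_levels = _design(df["hys"])
    # genotype dummies in fixed II/ID/DD order, reference = first present class
    G_cols = np.column_stack([(df[lid] == g).to_numpy(dtype=float)
                              for g in groups[1:]])

    X_reduced = np.hstack([ones, X_hys])
    X_full = np.hstack([X_reduced, G_cols])
    beta_r, rss_r, rank_r = _rss(X_reduced, y)
    beta_f, rss_f, rank_f = _rss(X_full, y)

    df_num = rank_f - rank_r
    df_den = len(y) - rank_f
    if df_den <= 0 or rss_f <= 0 and df_num == 0:
        raise ZeroVarianceError("model saturated; F test undefined")
    ms_err = rss_f / df_den
    if ms_err == 0:
        F = np.inf if rss_r > rss_f else 0.0
        p = 0.0 if F == np.inf else 1.0
    else:
        F = ((rss_r - rss_f) / df_num) / ms_err
        p = float(stats.f.sf(F, df_num, df_den))

    # plain one-way ANOVA on genotype alone, reported alongside
    Xo_r = ones
    Xo_f = np.hstack([ones, G_cols])
    _, rsso_r, ranko_r = _rss(Xo_r, y)
    _, rsso_f, ranko_f = _rss(Xo_f, y)
    dfo_num, dfo_den = ranko_f - ranko_r, len(y) - ranko_f
    mso = rsso_f / dfo_den if dfo_den else np.nan
    Fo = ((rsso_r - rsso_f) / dfo_num) / mso if mso else np.inf
    po = float(stats.f.sf(Fo, dfo_num, dfo_den)) if np.isfinite(Fo) else 0.0

    # contrast SEs from the full-model covariance
    XtX_inv = np.linalg.pinv(X_full.T @ X_full)
    se_all = np.sqrt(np.clip(np.diag(XtX_inv), 0, None) * ms_err)
    k_hys = X_hys.shape[1]
    geno_eff = {groups[0]: 0.0}
    geno_se = {groups[0]: 0.0}
    for j, g in enumerate(groups[1:]):
        geno_eff[g] = float(beta_f[1 + k_hys + j])
        geno_se[g] = float(se_all[1 + k_hys + j])
    hys_eff = {hys_levels[0]: 0.0}
    for j, lv in enumerate(hys_levels[1:]):
        hys_eff[lv] = float(beta_f[1 + j])

    values = {g: df.loc[df[lid] == g, "litter_size"].to_numpy(dtype=float)
              for g in groups}
    return AssociationResult(
        locus_id=lid,
        groups=groups,
        group_n={g: int(len(v)) for g, v in values.items()},
        group_mean={g: float(v.mean()) for g, v in values.items()},
        group_se={g: float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
                  for g, v in values.items()},
        mu=float(beta_f[0]),
        hys_effects=hys_eff,
        genotype_effects=geno_eff,
        genotype_se=geno_se,
        F_genotype=float(F),
        p_genotype=float(p),
        df_num=df_num,
        df_den=df_den,
        F_oneway=float(Fo),
        p_oneway=po,
        n_used=int(len(y)),
        dropped_groups=dropped,
        _values=values,
    )


@dataclass
class TukeyResult:
    pairs: list[tuple[str, str]]
    p_adjusted: dict[tuple[str, str], float]
    letters: dict[str, str]
    alpha: float


def compact_letters(
    groups: list[str],
    means: dict[str, float],
    significant: set[frozenset[str]],
) -> dict[str, str]:
    """Insert-and-absorb compact letter display, from the largest mean down.

    Each letter names a clique of mutually non-different groups; a group
    joins every existing letter set it is compatible with, else founds a
    new one, which then absorbs every earlier group compatible with all of
    its members.
    """
    order = sorted(groups, key=lambda g: means[g], reverse=True)

    def compatible(g: str, s: set[str]) -> bool:
        return all(frozenset((g, other)) not in significant for other in s)

    letter_sets: list[set[str]] = []
    for i, g in enumerate(order):
        placed = False
        for s in letter_sets:
            if compatible(g, s):
                s.add(g)
                placed = True
        if not placed:
            new = {g}
            for h in order[:i]:
                if compatible(h, new):
                    new.add(h)
            letter_sets.append(new)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in s:
            out[g] += letter
    return {g: "".join(sorted(out[g])) for g in groups}


def tukey_pairwise(result: AssociationResult, alpha: float = 0.05) -> TukeyResult:
    """Tukey-Kramer pairwise comparisons on the fitted groups, with letters."""
    groups = result.groups
    if len(groups) < 2:
        return TukeyResult(pairs=[], p_adjusted={}, letters={g: "a" for g in groups},
                           alpha=alpha)
    values = np.concatenate([result._values[g] for g in groups])
    labels = np.concatenate([[g] * len(result._values[g]) for g in groups])
    hsd = pairwise_tukeyhsd(values, labels, alpha=alpha)
    uniq = [str(g) for g in hsd.groupsunique]
    p_adj: dict[tuple[str, str], float] = {}
    significant: set[frozenset[str]] = set()
    for (g1, g2), p, rej in zip(combinations(uniq, 2), hsd.pvalues, hsd.reject):
        p_adj[(g1, g2)] = float(p)
        if rej:
            significant.add(frozenset((g1, g2)))
    letters = compact_letters(groups, result.group_mean, significant)
    return TukeyResult(pairs=list(p_adj), p_adjusted=p_adj, letters=letters,
                       alpha=alpha)


def litter_class(litter_size: int) -> str:
    """Single-lamb (MSL) versus multi-lamb (MML) litter class."""
    if litter_size < 1:
        raise ValueError("litter size must be >= 1")
    return "MSL" if litter_size == 1 else "MML"


def contingency_from_counts(
    msl: tuple[int, int, int], mml: tuple[int, int, int],
    genotypes: tuple[str, ...] = GENOTYPES,
) -> ContingencyResult:
    """2xk Pearson chi-square on MSL/MML genotype counts.

    Columns whose grand total is zero are dropped (df adjusted); zero cells
    within non-empty columns are retained, without continuity correction.
    """
    obs = pd.DataFrame([msl, mml], index=["MSL", "MML"], columns=list(genotypes),
                       dtype=float)
    if (obs.sum(axis=1) == 0).any():
        raise ValueError("both litter classes must be non-empty")
    dropped = [c for c in obs.columns if obs[c].sum() == 0]
    kept = obs.drop(columns=dropped)
    if kept.shape[1] < 2:
        raise ValueError("need >= 2 genotype columns with observations")
    chi2, p, df, expected = stats.chi2_contingency(kept.to_numpy(),
                                                   correction=False)
    return ContingencyResult(
        observed=kept,
        expected=pd.DataFrame(expected, index=kept.index, columns=kept.columns),
        chi2=float(chi2), df=int(df), p=float(p), dropped_columns=dropped,
    )


def genotype_distribution_test(
    cohort: CohortTable, locus: IndelLocus | str
) -> ContingencyResult:
    """MSL-vs-MML genotype distribution chi-square at one locus."""
    lid = _locus_id(locus)
    df = cohort.data[[lid, "litter_size"]].dropna()
    classes = df["litter_size"].astype(int).map(litter_class)
    msl = tuple(int(((df[lid] == g) & (classes == "MSL")).sum()) for g in GENOTYPES)
    mml = tuple(int(((df[lid] == g) & (classes == "MML")).sum()) for g in GENOTYPES)
    return contingency_from_counts(msl, mml)


def subset_scan(
    cohort: CohortTable,
    locus: IndelLocus | str,
    sizes: list[int],
    alpha: float = 0.05,
    seed: int = 0,
    replicates: int = 1,
    nested: bool = True,
) -> SubsetScanResult:
    """Nested random-subset robustness scan.

    Per replicate, one permutation of the phenotyped animals defines a chain
    of nested subsets (each smaller subset contained in the next); the
    fixed-effects model and the MSL/MML contingency test run at every size,
    and the replicate's decision flag is True only when the model's genotype
    test is significant at every size (the conjunctive consistency rule).
    ``nested=False`` draws a fresh subset at each size instead.
    """
    lid = _locus_id(locus)
    df = cohort.data.dropna(subset=[lid, "litter_size"]).reset_index(drop=True)
    n_pheno = len(df)
    sizes = sorted(sizes)
    n_classes = df[lid].nunique()
    usable, skipped = [], []
    for s in sizes:
        if s < 2 * n_classes:
            skipped.append(s)
            warnings.warn(f"subset size {s} < 2 x {n_classes} classes; skipped",
                          stacklevel=2)
        elif s > n_pheno:
            raise ValueError(f"subset size {s} exceeds phenotyped cohort {n_pheno}")
        else:
            usable.append(s)
    rng = np.random.default_rng(seed)
    model_p = np.full((replicates, len(usable)), np.nan)
    cont_p = np.full((replicates, len(usable)), np.nan)
    means: list[list[dict[str, float]]] = []
    decisions = np.zeros(replicates, dtype=bool)
    sub_cohort = CohortTable(data=df, loci=cohort.loci)
    for r in range(replicates):
        perm = rng.permutation(n_pheno)
        rep_means: list[dict[str, float]] = []
        ok = True
        for j, s in enumerate(usable):
            idx = perm[:s] if nested else rng.choice(n_pheno, size=s, replace=False)
            sub = CohortTable(data=df.iloc[idx], loci=cohort.loci)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    fit = fit_litter_model(sub, lid)
                    model_p[r, j] = fit.p_genotype
                    rep_means.append(dict(fit.group_mean))
                except (ValueError, ZeroVarianceError):
                    rep_means.append({})
                try:
                    cont_p[r, j] = genotype_distribution_test(sub, lid).p
                except ValueError:
                    pass
            if not (np.isfinite(model_p[r, j]) and model_p[r, j] < alpha):
                ok = False
        decisions[r] = ok and len(usable) > 0
        means.append(rep_means)
    return SubsetScanResult(
        locus_id=lid, sizes=usable, alpha=alpha, seed=seed, nested=nested,
        model_p=model_p, contingency_p=cont_p, group_means=means,
        decisions=decisions, skipped_sizes=skipped,
    )
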