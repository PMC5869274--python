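import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from indelkit.association import (
    ZeroVarianceError,
    compact_letters,
    contingency_from_counts,
    fit_litter_model,
    genotype_distribution_test,
    litter_class,
    subset_scan,
    tukey_pairwise,
)
from indelkit.io import CohortTable
from indelkit.simulate import CohortScenario, LocusScenario, simulate_cohort


def _cohort(genotypes, litters, hys=None):
    n = len(genotypes)
    df = pd.DataFrame({
        "animal_id": [f"x{i}" for i in range(n)],
        "hys": hys if hys is not None else ["H1"] * n,
        "litter_size": pd.array(litters, dtype="Int64"),
        "loc": genotypes,
    })
    return CohortTable(data=df, loci=["loc"])


class TestLitterModel:
    def test_single_hys_equals_oneway_anova_oracle(self):
        rng = np.random.default_rng(5)
        genos = rng.choice(["II", "ID", "DD"], size=400, p=[0.5, 0.3, 0.2])
        litters = 1 + rng.binomial(1, 0.4 + 0.2 * (genos == "II"))
        fit = fit_litter_model(_cohort(genos, litters), "loc")
        groups = [litters[genos == g] for g in fit.groups]
        F, p = stats.f_oneway(*groups)
        assert fit.F_genotype == pytest.approx(F, abs=1e-10)
        assert fit.p_genotype == pytest.approx(p, abs=1e-10)
        assert fit.p_oneway == pytest.approx(p, abs=1e-10)

    def test_multi_hys_matches_statsmodels_sequential_anova(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(6)
        n = 500
        genos = rng.choice(["II", "ID", "DD"], size=n, p=[0.6, 0.3, 0.1])
        hys = rng.choice(["H1", "H2", "H3"], size=n)
        prob = 0.4 + 0.15 * (genos == "II") + 0.1 * (hys == "H2")
        litters = 1 + rng.binomial(1, prob)
        fit = fit_litter_model(_cohort(genos, litters, hys=hys), "loc")
        df = pd.DataFrame({"y": litters.astype(float), "g": genos, "h": hys})
        ols = smf.ols("y ~ C(h) + C(g)", data=df).fit()
        table = sm.stats.anova_lm(ols, typ=1)
        assert fit.F_genotype == pytest.approx(table.loc["C(g)", "F"], rel=1e-9)
        assert fit.p_genotype == pytest.approx(table.loc["C(g)", "PR(>F)"],
                                               rel=1e-9)

    def test_two_separated_groups_recovered_exactly(self):
        fit = fit_litter_model(
            _cohort(["II"] * 5 + ["DD"] * 5, [2] * 5 + [1] * 5), "loc")
        assert fit.group_mean == {"II": 2.0, "DD": 1.0}
        assert fit.p_genotype < 1e-12
        assert fit.genotype_effects["DD"] == pytest.approx(-1.0)

    def test_group_stats_equal_direct_arithmetic(self):
        rng = np.random.default_rng(9)
        genos = rng.choice(["II", "ID"], size=60)
        litters = 1 + rng.binomial(1, 0.5, size=60)
        fit = fit_litter_model(_cohort(genos, litters), "loc")
        for g in fit.groups:
            vals = litters[genos == g].astype(float)
            assert fit.group_mean[g] == pytest.approx(vals.mean())
            assert fit.group_se[g] == pytest.approx(
                vals.std(ddof=1) / np.sqrt(len(vals)))
            assert fit.group_n[g] == len(vals)
        assert sum(fit.group_n.values()) == fit.n_used

    def test_tiny_genotype_class_dropped_with_warning(self):
        genos = ["II"] * 20 + ["ID"] * 20 + ["DD"]
        litters = [1, 2] * 10 + [1, 2] * 10 + [1]
        with pytest.warns(UserWarning):
            fit = fit_litter_model(_cohort(genos, litters), "loc")
        assert fit.dropped_groups == ["DD"]
        assert fit.groups == ["II", "ID"]

    def test_constant_phenotype_rejected(self):
        with pytest.raises(ZeroVarianceError):
            fit_litter_model(_cohort(["II"] * 5 + ["DD"] * 5, [1] * 10), "loc")


class TestTukey:
    def test_far_separated_group_gets_distinct_letter(self):
        genos = ["II"] * 30 + ["ID"] * 30 + ["DD"] * 10
        litters = [1, 2] * 15 + [1, 2] * 15 + [1] * 10
        fit = fit_litter_model(_cohort(genos, litters), "loc")
        tk = tukey_pairwise(fit)
        assert tk.letters["II"] == tk.letters["ID"]
        assert tk.letters["DD"] not in (tk.letters["II"], tk.letters["ID"])

    def test_identical_groups_share_a_letter(self):
        genos = ["II"] * 20 + ["ID"] * 20 + ["DD"] * 20
        litters = [1, 2] * 30
        fit = fit_litter_model(_cohort(genos, litters), "loc")
        tk = tukey_pairwise(fit)
        assert set(tk.letters.values()) == {"a"}

    def test_compact_letters_greedy_from_largest_mean(self):
        letters = compact_letters(
            ["A", "B", "C"], {"A": 3.0, "B": 2.0, "C": 1.0},
            {frozenset(("A", "C"))})
        assert letters["A"] == "a"
        assert letters["C"] == "b"
        assert set(letters["B"]) == {"a", "b"}


class TestLitterClass:
    @pytest.mark.parametrize("size,label", [(1, "MSL"), (2, "MML"), (3, "MML")])
    def test_dichotomy(self, size, label):
        assert litter_class(size) == label

    def test_invalid(self):
        with pytest.raises(ValueError):
            litter_class(0)


class TestContingency:
    # published genotype-by-litter-class rows that reproduce from their counts
    ROWS = [
        ((42, 1, 7), (41, 9, 0), 0.001),
        ((81, 11, 8), (87, 13, 0), 0.015),
        ((119, 22, 9), (129, 21, 0), 0.009),
        ((156, 33, 11), (171, 29, 0), 0.003),
        ((200, 27, 13), (213, 37, 0), 0.001),
        ((836, 108, 17), (771, 78, 1), 0.001),
        ((9, 51, 90), (11, 65, 74), 0.178),
        ((15, 74, 111), (19, 78, 103), 0.646),
    ]

    @pytest.mark.parametrize("msl,mml,expected_p", ROWS)
    def test_published_rows_reproduce(self, msl, mml, expected_p):
        res = contingency_from_counts(msl, mml)
        assert round(res.p, 3) == pytest.approx(expected_p, abs=1e-9)
        assert res.df == 2

    def test_identical_rows_give_null_result(self):
        res = contingency_from_counts((30, 20, 10), (30, 20, 10))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_zero_total_column_dropped(self):
        res = contingency_from_counts((30, 20, 0), (25, 25, 0))
        assert res.dropped_columns == ["DD"]
        assert res.df == 1

    def test_invariance_under_row_swap_and_column_permutation(self):
        msl, mml = (81, 11, 8), (87, 13, 0)
        base = contingency_from_counts(msl, mml)
        swapped = contingency_from_counts(mml, msl)
        permuted = contingency_from_counts(msl[::-1], mml[::-1])
        assert swapped.chi2 == pytest.approx(base.chi2)
        assert permuted.chi2 == pytest.approx(base.chi2)

    def test_expected_margins_match_observed(self):
        res = contingency_from_counts((81, 11, 8), (87, 13, 0))
        assert np.allclose(res.expected.sum(axis=1), res.observed.sum(axis=1))
        assert np.allclose(res.expected.sum(axis=0), res.observed.sum(axis=0))

    def test_from_cohort_matches_from_counts(self, cohort):
        res = genotype_distribution_test(cohort, "indel16")
        direct = contingency_from_counts((836, 108, 17), (771, 78, 1))
        assert res.chi2 == pytest.approx(direct.chi2)


@pytest.fixture(scope="module")
def effect_cohort():
    sc = CohortScenario(
        n_animals=1811,
        loci=[LocusScenario("loc", p=0.941, f=0.109,
                            litter_effects={"II": 0.0, "ID": -0.06,
                                            "DD": -0.43})],
        baseline_extra_prob=0.49, seed=77)
    return simulate_cohort(sc)


class TestSubsetScan:
    def test_deterministic_under_seed(self, effect_cohort):
        kw = dict(sizes=[400, 800], alpha=0.05, seed=12, replicates=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = subset_scan(effect_cohort, "loc", **kw)
            b = subset_scan(effect_cohort, "loc", **kw)
        assert np.array_equal(a.model_p, b.model_p, equal_nan=True)
        assert np.array_equal(a.decisions, b.decisions)

    def test_nested_chains_monotone_in_information(self, effect_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = subset_scan(effect_cohort, "loc", sizes=[1811], alpha=0.05,
                              seed=1, replicates=1)
        # the full-cohort subset is the cohort itself
        full = fit_litter_model(effect_cohort, "loc")
        assert res.model_p[0, 0] == pytest.approx(full.p_genotype)

    def test_undersized_subset_skipped(self, effect_cohort):
        with pytest.warns(UserWarning):
            res = subset_scan(effect_cohort, "loc", sizes=[4, 400], seed=0)
        assert res.skipped_sizes == [4]
        assert res.sizes == [400]
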