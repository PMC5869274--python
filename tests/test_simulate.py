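import numpy as np
import pandas as pd
import pytest

from indelkit.io import count_genotypes
from indelkit.linkage import em_haplotypes
from indelkit.popgen import allele_frequencies, hwe_test
from indelkit.simulate import (
    CohortScenario,
    CtScenario,
    LocusScenario,
    ScenarioError,
    default_scenario,
    simulate_cohort,
    simulate_ct,
    simulate_two_locus,
)


class TestCohortSimulation:
    def test_seed_determinism(self):
        sc = default_scenario(seed=123)
        a, b = simulate_cohort(sc), simulate_cohort(sc)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_different_seeds_differ(self):
        a = simulate_cohort(default_scenario(seed=1))
        b = simulate_cohort(default_scenario(seed=2))
        assert not a.data["indel16"].equals(b.data["indel16"])

    def test_mean_genotype_counts_match_deficit_adjusted_expectation(self):
        """Mean counts over replicates stay within 2% of the expectation
        n*(p^2+Fpq, 2pq(1-F), q^2+Fpq) for the common-insertion locus."""
        p, f, n = 0.941, 0.109, 2326
        q = 1 - p
        expected = n * np.array([p * p + f * p * q, 2 * p * q * (1 - f),
                                 q * q + f * p * q])
        sums = np.zeros(3)
        reps = 300
        for k in range(reps):
            sc = CohortScenario(n_animals=n,
                                loci=[LocusScenario("L", p=p, f=f)],
                                seed=9000 + k)
            c = count_genotypes(simulate_cohort(sc), "L")
            sums += c.as_array()
        assert np.all(np.abs(sums / reps - expected) / expected < 0.02)

    def test_null_cohorts_pass_hwe_at_nominal_rate(self):
        rejections = 0
        reps = 200
        for k in range(reps):
            sc = CohortScenario(n_animals=1000,
                                loci=[LocusScenario("L", p=0.3, f=0.0)],
                                seed=4000 + k)
            counts = count_genotypes(simulate_cohort(sc), "L")
            rejections += hwe_test(counts, df_mode="theoretical").p < 0.05
        assert 0.01 <= rejections / reps <= 0.10

    def test_allele_frequency_converges_to_p(self):
        sc = CohortScenario(n_animals=20000, loci=[LocusScenario("L", p=0.7)],
                            seed=5)
        p_hat, _ = allele_frequencies(count_genotypes(simulate_cohort(sc), "L"))
        assert p_hat == pytest.approx(0.7, abs=3 * np.sqrt(0.21 / 40000))

    def test_infeasible_inbreeding_rejected(self):
        with pytest.raises(ScenarioError):
            LocusScenario("L", p=0.9, f=-0.9).genotype_probs()

    def test_litter_sizes_bounded_and_missing_rates_applied(self):
        sc = default_scenario(seed=10)
        cohort = simulate_cohort(sc)
        ls = cohort.data["litter_size"].dropna()
        assert ls.between(1, 2).all()
        pheno_rate = cohort.data["litter_size"].notna().mean()
        assert pheno_rate == pytest.approx(1811 / 2326, abs=0.03)
        typed5 = cohort.data["indel5"].notna().mean()
        assert typed5 == pytest.approx(615 / 2326, abs=0.03)

    def test_genotype_effects_shift_group_means(self):
        sc = CohortScenario(
            n_animals=5000,
            loci=[LocusScenario("L", p=0.5,
                                litter_effects={"II": 0.0, "ID": 0.0,
                                                "DD": -0.3})],
            baseline_extra_prob=0.5, seed=6)
        cohort = simulate_cohort(sc)
        df = cohort.data
        mean_II = df.loc[df["L"] == "II", "litter_size"].mean()
        mean_DD = df.loc[df["L"] == "DD", "litter_size"].mean()
        assert mean_II - mean_DD == pytest.approx(0.3, abs=0.06)

    def test_haplotype_mode_reproduces_target_ld(self):
        truth = np.array([0.5, 0.0, 0.2, 0.3])   # D' = 1 configuration
        sc = CohortScenario(n_animals=5000,
                            loci=[LocusScenario("A"), LocusScenario("B")],
                            hap_freqs=truth, seed=7)
        cohort = simulate_cohort(sc)
        from indelkit.linkage import TwoLocusCounts
        est = em_haplotypes(TwoLocusCounts.from_cohort(cohort, "A", "B"))
        assert est.D_prime > 0.95


class TestTwoLocusSimulation:
    def test_seed_determinism(self):
        a = simulate_two_locus(500, [0.4, 0.1, 0.2, 0.3], seed=11)
        b = simulate_two_locus(500, [0.4, 0.1, 0.2, 0.3], seed=11)
        assert np.array_equal(a.table, b.table)

    def test_total_preserved(self):
        t = simulate_two_locus(777, [0.25] * 4, seed=1)
        assert t.table.sum() == 777

    def test_complete_ld_recovered(self):
        counts = simulate_two_locus(1000, [0.5, 0.0, 0.0, 0.5], seed=2)
        assert em_haplotypes(counts).r2 > 0.95


class TestCtSimulation:
    def test_zero_noise_zero_shift_gives_unit_folds(self):
        from indelkit.expression import ddct
        sc = CtScenario(groups={"a": 3, "b": 3},
                        gene_baseline={"T": 24.0, "R": 18.0},
                        default_noise_sd=0.0, seed=1)
        ct = simulate_ct(sc)
        res = ddct(ct, "T", "R", "a")
        assert np.allclose(res.per_sample["fold"], 1.0)

    def test_one_log2_shift_doubles_mean_fold(self):
        from indelkit.expression import ddct
        sc = CtScenario(groups={"cal": 50, "up": 50},
                        gene_baseline={"T": 24.0, "R": 18.0},
                        target_shifts={"T": {"up": 1.0}},
                        default_noise_sd=0.1, seed=2)
        res = ddct(simulate_ct(sc), "T", "R", "cal")
        assert res.per_group.loc["up", "mean_fold"] == pytest.approx(2.0,
                                                                     rel=0.1)

    def test_loading_offsets_leave_genorm_m_unchanged(self):
        from indelkit.expression import genorm_m
        base = dict(groups={"a": 10}, gene_baseline={"G1": 20.0, "G2": 22.0,
                                                     "G3": 24.0},
                    default_noise_sd=0.3, seed=3)
        plain = simulate_ct(CtScenario(**base))
        loaded = simulate_ct(CtScenario(**base, loading_sd=1.5))
        m1 = genorm_m(plain, ["G1", "G2", "G3"]).m_values
        m2 = genorm_m(loaded, ["G1", "G2", "G3"]).m_values
        pd.testing.assert_series_equal(m1, m2)

    def test_seed_determinism(self):
        sc = CtScenario(groups={"a": 4}, gene_baseline={"G1": 20.0}, seed=9)
        a, b = simulate_ct(sc), simulate_ct(sc)
        pd.testing.assert_frame_equal(a.ct, b.ct)
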