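"""Synthetic cohorts and Ct matrices with the statistical structure the
analyses assume.

The cohort generator draws, per locus, genotypes from the inbreeding-
adjusted distribution (p^2 + Fpq, 2pq(1-F), q^2 + Fpq), which reproduces a
heterozygote deficit for F > 0.  First-born litter size is 1 plus a
Bernoulli "extra kid" draw whose probability is baseline + genotype effect
+ herd-year-season effect, so litters are mostly 1-2 (an optional Poisson
tail allows rarer triplets).  When two-locus haplotype frequencies are
given, genotypes at that locus pair arise by random union of haplotypes,
giving the requested LD.

The default scenario matches the cohort the association analyses target: a
~2,300-animal herd, one common-insertion locus (p ~= 0.94) with a
heterozygote deficit (F ~= 0.11) whose deletion homozygotes bear markedly
smaller litters, and one intermediate-frequency locus (p ~= 0.28, F ~= 0)
with no litter effect, typed on a ~615-animal subset.  All generators are
bit-reproducible under a fixed seed.

The Ct generator emulates a qPCR plate: per-gene baseline Ct, per-group
log2 shifts on target genes (1 shift unit = one doubling), Gaussian cycle
noise, and optional per-sample loading offsets applied to every gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CohortTable, CtMatrix
from .linkage import TwoLocusCounts

GENOTYPE_ORDER = ("II", "ID", "DD")


class ScenarioError(ValueError):
    """A scenario's parameters are internally inconsistent."""


@dataclass
class LocusScenario:
    """One locus: insertion-allele frequency p, inbreeding F, litter effects.

    ``litter_effects`` shift the extra-kid probability per genotype (additive
    on the probability scale); ``missing_rate`` is the chance a genotype is
    untyped.
    """

    locus_id: str
    p: float = 0.5
    f: float = 0.0
    litter_effects: dict[str, float] = field(
        default_factory=lambda: {"II": 0.0, "ID": 0.0, "DD": 0.0})
    missing_rate: float = 0.0

    def genotype_probs(self) -> np.ndarray:
        q = 1.0 - self.p
        probs = np.array([
            self.p ** 2 + self.f * self.p * q,
            2 * self.p * q * (1 - self.f),
            q ** 2 + self.f * self.p * q,
        ])
        if (probs < -1e-12).any():
            raise ScenarioError(
                f"infeasible inbreeding F={self.f} for p={self.p}")
        probs = np.clip(probs, 0.0, None)
        return probs / probs.sum()


@dataclass
class CohortScenario:
    n_animals: int = 2326
    loci: list[LocusScenario] = field(default_factory=list)
    baseline_extra_prob: float = 0.49
    hys_levels: list[str] = field(default_factory=lambda: ["HYS1"])
    hys_effects: list[float] = field(default_factory=lambda: [0.0])
    max_litter: int = 2
    poisson_tail_rate: float = 0.0         # extra-kid Poisson rate beyond twins
    phenotype_missing_rate: float = 0.0
    hap_freqs: np.ndarray | None = None    # LD between the first two loci
    seed: int = 0


def default_scenario(seed: int = 0) -> CohortScenario:
    """The study conditions: cohort size, allele frequencies, heterozygote
    deficit, genotype-dependent litter size and per-locus typing rates."""
    return CohortScenario(
        n_animals=2326,
        loci=[
            LocusScenario("indel16", p=0.941, f=0.109,
                          litter_effects={"II": 0.0, "ID": -0.06, "DD": -0.43}),
            LocusScenario("indel5", p=0.278, f=0.0,
                          missing_rate=1.0 - 615 / 2326),
        ],
        baseline_extra_prob=0.49,
        phenotype_missing_rate=1.0 - 1811 / 2326,
        seed=seed,
    )


def simulate_cohort(scenario: CohortScenario, seed: int | None = None) -> CohortTable:
    """Draw a cohort table under a scenario; reproducible under seed."""
    if not scenario.loci:
        raise ScenarioError("scenario declares no loci")
    if len(scenario.hys_levels) != len(scenario.hys_effects):
        raise ScenarioError("hys_levels and hys_effects differ in length")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n = scenario.n_animals

    genotypes: dict[str, np.ndarray] = {}
    if scenario.hap_freqs is not None:
        if len(scenario.loci) < 2:
            raise ScenarioError("hap_freqs needs at least two loci")
        hf = np.asarray(scenario.hap_freqs, dtype=float)
        if abs(hf.sum() - 1.0) > 1e-9 or (hf < 0).any():
            raise ScenarioError("hap_freqs must be a probability 4-vector")
        # two haplotypes per animal; allele index 0 = I, 1 = D
        haps = rng.choice(4, size=(n, 2), p=hf)
        a_alleles = haps // 2          # locus A: 0 for hap II/ID, 1 for DI/DD
        b_alleles = haps % 2
        for lid, alleles in ((scenario.loci[0].locus_id, a_alleles),
                             (scenario.loci[1].locus_id, b_alleles)):
            k = alleles.sum(axis=1)    # number of D alleles
            genotypes[lid] = np.array(GENOTYPE_ORDER, dtype=object)[k]
        rest = scenario.loci[2:]
    else:
        rest = scenario.loci
    for locus in rest:
        draws = rng.choice(3, size=n, p=locus.genotype_probs())
        genotypes[locus.locus_id] = np.array(GENOTYPE_ORDER, dtype=object)[draws]

    hys_idx = rng.integers(0, len(scenario.hys_levels), size=n)
    hys = np.array(scenario.hys_levels, dtype=object)[hys_idx]
    hys_eff = np.array(scenario.hys_effects)[hys_idx]

    prob = np.full(n, scenario.baseline_extra_prob) + hys_eff
    for locus in scenario.loci:
        if any(locus.litter_effects.values()):
            eff = np.array([locus.litter_effects.get(g, 0.0)
                            for g in genotypes[locus.locus_id]])
            prob = prob + eff
    prob = np.clip(prob, 0.0, 1.0)
    litter = 1 + rng.binomial(1, prob)
    if scenario.poisson_tail_rate > 0:
        litter = litter + rng.poisson(scenario.poisson_tail_rate, size=n)
    litter = np.minimum(litter, max(scenario.max_litter, 2))

    records = []
    for i in range(n):
        rec = {"animal_id": f"A{i + 1:05d}", "hys": hys[i],
               "litter_size": int(litter[i])}
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    for locus in scenario.loci:
        col = genotypes[locus.locus_id].copy()
        if locus.missing_rate > 0:
            col[rng.random(n) < locus.missing_rate] = None
        df[locus.locus_id] = col
    df["litter_size"] = df["litter_size"].astype("Int64")
    if scenario.phenotype_missing_rate > 0:
        mask = rng.random(n) < scenario.phenotype_missing_rate
        df.loc[mask, "litter_size"] = pd.NA
    return CohortTable(data=df, loci=[l.locus_id for l in scenario.loci])


def simulate_two_locus(n: int, hap_freqs, seed: int = 0) -> TwoLocusCounts:
    """Draw 2n haplotypes multinomially, pair them at random, cross-tabulate."""
    hf = np.asarray(hap_freqs, dtype=float)
    if abs(hf.sum() - 1.0) > 1e-9 or (hf < 0).any():
        raise ValueError("hap_freqs must be a probability 4-vector")
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(4), rng.multinomial(2 * n, hf))
    rng.shuffle(pool)
    pairs = pool.reshape(n, 2)
    row = (pairs // 2).sum(axis=1)     # number of D alleles at locus A
    col = (pairs % 2).sum(axis=1)
    table = np.zeros((3, 3))
    np.add.at(table, (row, col), 1)
    return TwoLocusCounts(table)


@dataclass
class CtScenario:
    """qPCR plate scenario: groups, gene baselines, target shifts, noise."""

    groups: dict[str, int]                         # group label -> n samples
    gene_baseline: dict[str, float]                # gene -> baseline Ct
    target_shifts: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    default_noise_sd: float = 0.2
    loading_sd: float = 0.0                        # per-sample global offset
    seed: int = 0


def simulate_ct(scenario: CtScenario, seed: int | None = None) -> CtMatrix:
    """Simulate a Ct matrix: Ct = baseline - group shift + loading + noise."""
    if not scenario.groups or not scenario.gene_baseline:
        raise ScenarioError("scenario needs groups and genes")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    sample_ids, labels = [], []
    for grp, size in scenario.groups.items():
        for i in range(size):
            sample_ids.append(f"{grp}_{i + 1}")
            labels.append(grp)
    n = len(sample_ids)
    # drawn even when sd = 0 so the noise stream is identical with and
    # without loading offsets (the geNorm invariance check relies on this)
    loading = rng.normal(0.0, scenario.loading_sd, size=n)
    data = {}
    for gene, base in scenario.gene_baseline.items():
        sd = scenario.noise_sd.get(gene, scenario.default_noise_sd)
        shift = np.array([scenario.target_shifts.get(gene, {}).get(g, 0.0)
                          for g in labels])
        ct = base - shift + loading + rng.normal(0.0, sd, size=n)
        data[gene] = np.clip(ct, 0.01, None)
    ct_df = pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id"))
    groups = pd.Series(labels, index=ct_df.index, name="group")
    roles = {g: ("target" if g in scenario.target_shifts else "candidate-reference")
             for g in scenario.gene_baseline}
    return CtMatrix(ct=ct_df, groups=groups, roles=roles)
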