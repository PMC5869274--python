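"""Published summary tables for the two goat KDM6A indel loci, and a
synthetic per-animal cohort reconstructed from them.

The study genotyped two intronic indels in Shaanbei white cashmere goats:
a 16 bp indel typed on 2,326 animals and a 5 bp indel typed on a 615-animal
subset; 1,811 animals carried first-born litter-size records.  Only summary
tables were published (genotype counts, and genotype-by-litter-class counts
at nested subset sizes), never per-animal data.  This module carries those
printed counts verbatim and can expand them into a SYNTHETIC per-animal
cohort: genotype and single-vs-multi litter-class membership follow the
published counts exactly, but individual litter sizes beyond the 1-vs->=2
split (multi-lamb litters are coded as 2) and the pairing of 5 bp genotypes
with particular animals are invented, so any statistic that depends on more
than the published margins is illustrative only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CohortTable, GenotypeCounts, IndelLocus

LOCUS_16BP = IndelLocus(
    "indel16", description="16 bp intron-17 indel, typed on 2,326 animals")
LOCUS_5BP = IndelLocus(
    "indel5", description="5 bp intron-17 indel, typed on 615 animals")

#: Published per-locus genotype counts (II, ID, DD).
GENOTYPE_COUNTS = {
    "indel16": GenotypeCounts(2074, 230, 22),
    "indel5": GenotypeCounts(52, 238, 325),
}

#: Published genotype-by-litter-class counts at nested subset sizes:
#: size -> (MSL (II, ID, DD), MML (II, ID, DD)).  MSL/MML = mothers of
#: single-/multi-lamb first-born litters.
SINGLE_VS_MULTI_16BP = {
    100: ((42, 1, 7), (41, 9, 0)),
    200: ((81, 11, 8), (87, 13, 0)),
    300: ((119, 22, 9), (129, 21, 0)),
    400: ((156, 33, 11), (171, 29, 0)),
    500: ((200, 27, 13), (213, 37, 0)),
    600: ((236, 50, 14), (262, 38, 0)),
    800: ((317, 69, 14), (347, 53, 0)),
    1000: ((402, 83, 15), (438, 62, 0)),
    1200: ((559, 97, 16), (463, 64, 1)),
    1811: ((836, 108, 17), (771, 78, 1)),
}

SINGLE_VS_MULTI_5BP = {
    100: ((2, 12, 36), (5, 12, 18)),
    200: ((5, 27, 68), (7, 46, 47)),
    300: ((9, 51, 90), (11, 65, 74)),
    400: ((15, 74, 111), (19, 78, 103)),
    500: ((22, 94, 134), (24, 99, 127)),
    600: ((26, 129, 175), (26, 106, 147)),
}

#: The 5 bp subset row at n=100 does not reproduce its published P-value
#: from its own counts under any standard chi-square reading (recomputation
#: gives ~0.09); it is retained here for completeness but excluded from
#: verification.
NON_REPRODUCING_ROWS = {("indel5", 100)}


def reconstructed_cohort(seed: int = 0) -> CohortTable:
    """SYNTHETIC per-animal cohort expanded from the published margins.

    2,326 animals with the published 16 bp genotype counts; the phenotyped
    1,811 carry the published genotype-by-litter-class membership (MSL ->
    litter 1, MML -> litter 2, an invented value since only the 1-vs->=2
    split was published); the first 615 carry 5 bp genotypes matching the
    published counts.  Row order is shuffled under ``seed`` so positional
    artefacts cannot masquerade as structure.
    """
    rng = np.random.default_rng(seed)
    geno16, litter = [], []
    msl, mml = SINGLE_VS_MULTI_16BP[1811]
    for g, n_s, n_m in zip(("II", "ID", "DD"), msl, mml):
        geno16 += [g] * (n_s + n_m)
        litter += [1] * n_s + [2] * n_m
    c16 = GENOTYPE_COUNTS["indel16"]
    for g, n_all, n_ph in zip(("II", "ID", "DD"),
                              (c16.n_II, c16.n_ID, c16.n_DD),
                              (sum(x) for x in zip(msl, mml))):
        geno16 += [g] * (n_all - n_ph)
        litter += [None] * (n_all - n_ph)

    c5 = GENOTYPE_COUNTS["indel5"]
    geno5 = (["II"] * c5.n_II + ["ID"] * c5.n_ID + ["DD"] * c5.n_DD
             + [None] * (c16.n_total - c5.n_total))

    # independent permutations: which animals carry 5 bp genotypes is not
    # published, so the two columns are paired at random
    order = rng.permutation(c16.n_total)
    order5 = rng.permutation(c16.n_total)
    df = pd.DataFrame({
        "animal_id": [f"G{i + 1:05d}" for i in range(c16.n_total)],
        "hys": "HYS1",
        "litter_size": pd.array([litter[i] for i in order], dtype="Int64"),
        "indel16": [geno16[i] for i in order],
        "indel5": [geno5[i] for i in order5],
    })
    return CohortTable(data=df, loci=["indel16", "indel5"])
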