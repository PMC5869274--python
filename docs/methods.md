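# Methods

## Scope and data model

The package analyses biallelic insertion/deletion (indel) markers typed as
unordered genotype pairs II/ID/DD on a per-animal cohort table (animal id,
herd-year-season label, one genotype column per locus, first-born litter
size), plus sample × gene qPCR Ct matrices. Genotypes come from gel
electrophoresis, so phase is never observed and "DI" is the same call as
"ID". Missing values are the empty string or "NA"; unknown genotype
strings are demoted to missing with a counted warning rather than
rejected, since hand-curated field tables routinely contain typos.

The bundled `datasets` module carries the published summary counts of the
motivating study (two goat *KDM6A* indels: a 16 bp locus typed on 2,326
animals, a 5 bp locus on a 615-animal subset, 1,811 animals phenotyped)
and can expand them into a per-animal table. That expansion is synthetic:
genotype margins and the single- vs multi-lamb split are exact, but
individual multi-lamb litter sizes (coded 2) and the animal-level pairing
of the two loci are invented, and the row order is shuffled under a seed.
Statistics that depend only on the published margins are therefore exact
on this table; anything else computed from it is illustrative.

## Diversity indices and Hardy–Weinberg testing

Allele frequencies are estimated by gene counting,
p = (2·n_II + n_ID)/(2n). Expected homozygosity and heterozygosity are
Nei's gene-identity forms Ho = Σpᵢ², He = 1 − Ho (note: He is the
*expected* heterozygosity 2pq, not the observed heterozygote proportion).
PIC follows Botstein, 1 − Σpᵢ² − Σ_{i<j} 2pᵢ²pⱼ², classed low (≤ 0.25),
medium (0.25–0.5] and high (> 0.5), boundaries assigned to the lower
class. The heterozygote deficit is summarised by Wright's
F = 1 − H_obs/He.

The HWE test is the Pearson χ² of the three genotype classes against
n·(p̂², 2p̂q̂, q̂²), no continuity correction. Two df conventions are
offered:

- `match_shesis` (default, df = 2 = genotype classes − 1): the convention
  used by widely deployed genotype-analysis platforms; its tail is
  analytically e^{−χ²/2}, which the test suite uses as an internal
  cross-check.
- `theoretical` (df = 1): subtracts the estimated allele frequency, the
  orthodox choice; on null cohorts simulated at HWE its type-I error sits
  at the nominal 5% (verified over 2,000 replicates).

Expected counts below 5 warn but do not refuse — the full published
tables pass (smallest expectation ≈ 8), while small subsets may not, and
a warning is the more useful behaviour there. Values destined for printed
tables are rounded half-away-from-zero to 3 decimals; JSON output keeps
full precision. One printed value in the motivating study's diversity
table (Ho = 0.598 for the 5 bp locus, where full precision gives 0.5985,
He printing as 0.401) is a truncation-vs-rounding artifact in that table;
He and PIC, which reproduce exactly, are the tested surface.

## EM haplotype estimation and LD

For two biallelic loci only the double-heterozygote cell (ID, ID) mixes
phases. The EM iteration splits that cell between cis and trans in
proportion to the current haplotype-frequency products, then re-estimates
the four frequencies by gene counting. Marginal allele frequencies are
preserved exactly at every step and the observed-data log-likelihood is
non-decreasing (both asserted in tests). Defaults: tolerance 1e-8 on the
max absolute frequency change, 1,000 iterations, with a `converged` flag
rather than an exception on hitting the cap.

The profile likelihood in the one free phase parameter can be bimodal,
with a saddle at linkage equilibrium; a single equilibrium start can
converge to the wrong mode. The estimator therefore runs the
deterministic EM from three starts — the equilibrium product and the two
near-boundary (Fréchet-corner) phase configurations — and keeps the
highest-likelihood fit. The test suite checks the result against a dense
grid search over the phase parameter (20,001 points) on 200 random small
tables; agreement is within 1e-6 log-likelihood units.

LD measures use the standard definitions: D = f_II − p_A p_B, D′ =
|D|/D_max with the sign-dependent D_max, r² = D²/(p_A q_A p_B q_B).
Labels: r² = 1 "complete", r² > 0.33 "strong", else "weak". (The
occasional description of r² = 0 as "perfect LD" in the applied
literature contradicts standard usage — r² = 0 is equilibrium — and is
not followed.) The motivating study printed D′ = 0.432, r² = 0.047 for
its locus pair but not the joint genotype table, so those numbers cannot
be recomputed from published data; the LD machinery is validated by the
grid-search oracle and by parameter recovery on simulated tables
(n = 10,000) instead, and the locus-pair estimate on the bundled
reconstructed cohort is illustrative only (the pairing of loci across
animals is synthetic).

## Litter-size association

The trait model is Y_ij = μ + HYS_i + G_j + e_ij with herd-year-season
and genotype as fixed effects, no interaction, fitted by OLS on explicit
design matrices. The genotype test is the sequential F with HYS entered
first (equivalently the comparison of residual sums of squares of
μ + HYS against μ + HYS + G); with a single HYS level it reduces exactly
to one-way ANOVA, verified against an independent oracle to 1e-10. The
full-vs-reduced fit is two `lstsq` calls, which keeps the thousands of
fits in the simulation-based checks cheap. A plain one-way P ignoring HYS
is reported alongside, since with one HYS level all sum-of-squares types
coincide and with several the attribution is otherwise ambiguous.

Litter size is a 1–2 (occasionally 3) count fitted with a Gaussian linear
model. That mirrors standard practice in livestock candidate-gene work
and keeps group means/SEs on the familiar scale; it is not an ordinal or
count model, and P-values for very small or very unbalanced groups
inherit the usual normal-approximation caveats. Genotype classes with
fewer than 2 phenotyped animals are omitted with a warning. Pairwise
contrasts use Tukey–Kramer (statsmodels' studentized-range
implementation) with an insert-and-absorb compact letter display assigned
from the largest mean down; α = 0.05 for letters, with P < 0.01
conventionally read as "strongly associated".

Mothers are dichotomised into single-lamb (litter 1, MSL) and multi-lamb
(≥ 2, MML) classes and the 2×3 genotype distribution compared by Pearson
χ² without continuity correction. A genotype column is dropped only when
its grand total is zero; a zero cell inside a non-empty column is kept.
This convention reproduces the published subset P-values exactly
(including rows with an empty rare-homozygote cell on one side) — with
one exception: the 5 bp locus' n = 100 subset row prints P = 0.001 while
its own printed counts give ≈ 0.091 under any standard χ² reading. That
row is flagged as non-reproducing in `datasets` and excluded from
verification, with no guess at the original intent.

### Subset-robustness scan

The scan formalises the "test in nested random subsets" strategy: per
replicate one permutation of the phenotyped animals defines a chain of
nested subsets (each contained in the next); the fixed-effects model and
the MSL/MML contingency test run at every size, and the replicate's
decision is positive only if the model's genotype test is significant at
*every* size. Subset sizes below twice the number of genotype classes are
skipped with a warning; a fresh-draw-per-size mode is available. The seed
is recorded for exact replay.

**Power caveat.** The decision's power is governed by the smallest subset
and the rarest genotype. With the rare homozygote near 1% (the
deficit-adjusted q² + Fpq of the strong locus), a uniformly drawn subset
of 300 contains ~3 such animals and the per-size tests have only ~10–25%
power at α = 0.05, so the conjunctive decision fires in a small minority
of replicates even for a real ~0.4-kid effect — the test suite measures
this honestly rather than asserting it away. Published analyses of this
design report rare-homozygote counts in small subsets several-fold above
uniform expectation, so printed subset P-values should be read with that
in mind. The scan is most informative when the smallest size is chosen to
guarantee a handful of rare homozygotes (roughly n ≥ 10/q_rare²).

## qPCR arm

geNorm stability: per-gene relative quantities a = 2^(minCt − Ct); for
each ordered pair the pairwise variation V_jk is the sample standard
deviation (ddof = 1) of log2(a_j/a_k) over samples; M_j is the mean V_jk
over partners; lowest M is selected. M is invariant to per-sample loading
offsets (they cancel in ratios) — asserted as a property. With exactly
two candidates both M values equal the single pairwise SD, so the ranking
is uninformative; three or more candidates are recommended.

Relative expression follows Livak's 2^−ΔΔCt with amplification efficiency
fixed at 2 (no Pfaffl efficiency correction): per-sample
ΔCt = Ct_target − Ct_reference, ΔΔCt = ΔCt − mean ΔCt of the calibrator
group, fold = 2^−ΔΔCt. Centering on the calibrator's *mean* ΔCt (rather
than per-sample pairing) matches the pooled-animals design of small
qPCR panels; the calibrator's mean ΔΔCt is exactly 0 by construction.
Group comparisons run on the fold values: two groups → two-sided pooled
t-test; more → one-way ANOVA with Tukey letters (shared machinery with
the association module). Groups with fewer than 2 samples are excluded
with a warning.

## Synthetic-data generators

`simulate_cohort` draws genotypes from (p² + Fpq, 2pq(1−F), q² + Fpq)
per locus (rejecting infeasible F), or by random union of haplotypes when
a two-locus haplotype 4-vector is supplied. Litter size is 1 + a
Bernoulli extra-kid draw with probability baseline + genotype effect +
HYS effect (clipped to [0, 1]), truncated at the maximum litter size; an
optional Poisson tail adds rarer triplets. The default scenario *is* the
cohort structure the analyses target: 2,326 animals; locus `indel16` at
p = 0.941 with F = 0.109 and extra-kid effects (0, −0.06, −0.43) for
II/ID/DD against a 0.49 baseline (group means ≈ 1.49/1.43/1.06); locus
`indel5` at p = 0.278, F = 0, typed on a 615/2326 fraction; litter
records on a 1811/2326 fraction; a single HYS level with zero effect (so
single-factor tests are exact; scenarios can switch multi-level HYS
effects on).

What the generator does *not* emulate: family/pedigree structure and
relatedness (animals are exchangeable), genotyping error, confounding
between HYS and genotype (HYS is assigned independently), overdispersed
or seasonal litter-size distributions, and qPCR efficiencies differing
from 2. Passing tests therefore demonstrate correctness of the statistics
under clean sampling assumptions, not robustness to those real-data
complications.

`simulate_two_locus` draws 2n haplotypes multinomially and pairs them at
random; `simulate_ct` builds Ct = baseline − group shift + loading +
noise, drawing the loading vector even at sd = 0 so that offset-free and
offset runs share the noise stream (this makes the geNorm invariance
check exact). All generators accept a seed and are bit-reproducible.

## Numerical conventions and problem sizes

Rounding for table display is half-away-from-zero to 3 decimals. EM:
tol 1e-8, ≤ 1,000 iterations, three deterministic starts. OLS uses
`numpy.linalg.lstsq` with rank-based degrees of freedom, so rank-deficient
designs (e.g. a genotype perfectly confounded with one HYS level)
degrade gracefully. Ties in compact letters are broken by descending
group mean. The simulation-based checks use 2,000 null replicates at
n = 600 for type-I calibration, 500 cohorts of 1,811 for effect-recovery
coverage, 500 replicates for reference-gene demotion, 200 random tables
for the EM grid oracle, and 60 replicates per arm for the subset-scan
decision rates — sizes chosen to keep Monte-Carlo error well inside the
asserted margins while the whole suite runs in well under a minute.

## Known limitations

- Gaussian model for a bounded count phenotype (see above).
- No multi-allelic loci, no VCF/PLINK ingestion, no pedigree models, no
  multiple-testing correction across loci (two loci; uncorrected by
  design), no qPCR efficiency estimation or melt-curve QC.
- The subset-scan decision has the power ceiling described above; a
  negative decision on small subsets is weak evidence against a real
  effect at a rare-homozygote locus.
- Statistics computed on the bundled reconstructed cohort beyond its
  published margins (notably cross-locus LD) reflect synthetic pairing
  choices, not data.
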