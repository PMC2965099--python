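# Methods

## The design and the data it produces

A *daughter design* genotypes a set of artificial-insemination sires and a
large number of their paternal half-sib daughters; phenotypes are recorded
on the daughters only.  Here the phenotype of daughter *j* of sire *i* is
her estimated breeding value (EBV) `y_ij` for one of five milk production
traits — milk yield (MY), fat yield (FY), protein yield (PY), fat
percentage (FP) and protein percentage (PP) — together with the EBV's
reliability `REL_ij` (squared accuracy, in (0, 1]).  Reliability drives
heteroscedastic residual weighting in both association models: a
low-reliability EBV is a noisier observation of the daughter's genetic
merit.

Maternal genotypes are unavailable throughout; dams are treated as unknown
and mutually unrelated.

## Quality control

Stage 1 (individuals; sires are exempt because removing one would orphan a
whole family):

1. daughters with more than `ind_missing_max = 10%` missing genotypes;
2. daughters whose Mendelian error rate against their sire exceeds
   `mendel_rate_max = 2%`.  The rate is estimated on a uniform random
   sample of up to 10,000 loci at which sire and daughter are both called
   homozygous; opposite homozygotes at such a locus are impossible under
   Mendelian inheritance whatever the dam carried.  If fewer than 10,000
   informative loci exist, all are used; with zero informative loci the
   rate is undefined and the daughter is flagged for review, not removed.

A daughter failing both criteria is attributed to missingness (the
Mendelian screen is never evaluated for her), so per-criterion removal
counts are order-dependent while the kept set is not.

Stage 2 (SNPs, computed on the individuals kept by stage 1, filters applied
in this order with first-failure attribution): call rate < 90%; minor
allele frequency < 3%; Hardy–Weinberg equilibrium P < 1e-6; minor genotype
class observed in fewer than 5 individuals.  HWE uses the Pearson 1-df
chi-square on observed vs expected genotype counts without continuity
correction — the classical default for 50K-era panels; a conditional exact
test (full enumeration of heterozygote counts given the allele counts) is
available via `hwe_test="exact"`.  X-linked SNPs pass through the same
filters as autosomal ones; no dosage special-casing is attempted.

## L1-TDT: single-parent transmission-disequilibrium regression

Each daughter-SNP pair receives a transmission score `TDS in {-1, 0, +1}`.
With only the sire genotyped the score is forced by Mendelian logic
exactly when the sire is heterozygous and the daughter homozygous (+1 when
the allele-b copy must have come from the sire, -1 for allele a); a
heterozygous daughter of a heterozygous sire is ambiguous without the dam
and is scored 0, as are all daughters of homozygous sires.  The
ambiguous-daughter rule is exposed as a plug-in (`build_tds_matrix(...,
rule=)`) for experimentation; scoring 0 is the conservative default.
SNPs at which no sire is heterozygous carry no transmission information at
all and are excluded from the scan up front, which is why the
transmission test's multiple-testing burden N is smaller than the
mixed-model scan's.

Per SNP, weighted least squares fits

    y_ij = mu + s_i + beta * TDS_ij + e_ij,

with the sire as a fixed factor, and tests `beta` by `F = (beta/se)^2` on
(1, n - rank) degrees of freedom.  Daughters with TDS = 0 stay in the
regression — they inform `mu` and `s_i`; only daughters with a missing
genotype at that SNP are dropped.  If every retained TDS is zero the test
is undefined and the SNP is reported with raw P = 1.

**Weights.** The default weight is `REL` itself (`weight_mode=
"reliability"`), because a residual variance proportional to `1/REL` —
the same residual model the mixed-model analysis assumes — implies WLS
weights proportional to `REL`.  The alternative `weight_mode="literal"`
(weights `1/REL`) is retained as a config option.  Internal consistency
between the two methods was preferred over the alternative reading.

## MMRA: pedigree mixed-model regression

Per SNP the model over all phenotyped daughters is

    y = 1*mu + x*b + Z*a + e,
    a ~ N(0, A*sigma_a2),    e ~ N(0, W*sigma_e2),  W = diag(1/REL),

with `x` the allele-b dosage (0/1/2) and `A` the pedigree numerator
relationship matrix.  The polygenic term absorbs the half-sib family
structure, which is what protects the scan from the stratification that a
plain regression on dosage would suffer (the package's positive-control
test demonstrates the inflation when the term is dropped).  `b` and its
sampling variance come from Henderson's mixed model equations with the
random-effect block absorbed:

    S = X' W^-1 X  -  X' W^-1 Z (Z' W^-1 Z + lambda*A^-1)^-1 Z' W^-1 X,
    var(b_hat) = sigma_e2 * (S^-1)_bb,        lambda = sigma_e2/sigma_a2,

and the test is the Wald chi-square `b^2/var(b)` on 1 df.  This is
algebraically identical to GLS with `V = Z A Z' sigma_a2 + W sigma_e2`
(the equivalence is the module's primary test oracle, checked to 1e-8 on
random instances).  The `(Z'W^-1 Z + lambda*A^-1)` block does not depend
on the SNP, so its sparse LU factorization is computed once per scan;
each SNP then costs two sparse triangular solves (~1 ms at 2,114 pedigree
members).  Daughters with a missing dosage are dropped for that SNP (the
block is re-factorized for such SNPs); dosages are never mean-imputed.
A dosage monomorphic among phenotyped daughters leaves the test undefined
(raw P = 1 recorded).

**Variance components.**  `sigma_a2` and `sigma_e2` are REML-estimated
once under the null (no-SNP) model `y = 1*mu + a + e` and reused for every
SNP; per-SNP re-estimation changes Wald statistics negligibly at this
design scale and is available behind `per_snp_reml=True`.  The restricted
likelihood is maximized by exact profiling on the spectral decomposition
of the reliability-scaled relationship matrix `W^-1/2 A_dd W^-1/2`: after
one eigendecomposition the restricted log-likelihood is O(n) to evaluate,
`sigma_e2` profiles out in closed form, and the problem reduces to a
one-dimensional search in `gamma = sigma_a2/sigma_e2` (coarse grid on
log-gamma, then Brent refinement to xatol 1e-10, plus an explicit check of
the `sigma_a2 = 0` boundary).  For a two-component model this is exact,
has no update-step failure modes, and replaces iterative AI-REML at lower
cost.  A dense-grid likelihood search is the test oracle.  The reported
log-likelihood includes the Jacobian of the scaling transform, i.e. it is
the restricted log-likelihood of the original observations.

## The numerator relationship matrix

`A` is built densely by the tabular method (parents processed before
offspring); `A^-1` sparsely by Henderson's rules with unknown-parent
weights 1 / (4/3) / 2 for 0/1/2 known parents.  Henderson's short rules
assume a non-inbred pedigree; inbreeding is detected (parents sharing a
known ancestor) and triggers a dense-inversion fallback with a warning.
A gene-dropping Monte Carlo estimator of `A` (10,000 replicates by
default) serves as an independent cross-check on small pedigrees.
Individual order is founders first (file order), then non-founders
topologically; all consumers match on ids, and the construction is
permutation-covariant.

## Inference

Genome-wise significance is Bonferroni: a SNP is significant when its raw
P value is below `alpha/N` with `alpha = 0.05` and N *method-specific* —
the number of SNPs that method actually tested.  Adjusted P values are
`min(1, raw * N)` with the N of the method that produced them.
Q-Q diagnostics use plotting positions `(i - 0.5)/n` and report the
median-based inflation factor (median observed chi-square / 0.4549);
values near 1 indicate no systematic stratification.  Cross-method
summaries count per-trait hits, overlaps and unions, plus the distinct
SNPs across traits split into both/solely-one-method groups.

## The synthetic generator

`simulate_daughter_design` emulates exactly the structure the models
assume.  Defaults are the design scale this package targets: 14 unrelated
sires, 150 daughters each, uniform MAF spectrum on (0.05, 0.5),
reliabilities uniform on (0.41, 0.71) per daughter-trait, and a 30/70
additive/residual variance split on the standardized trait scale
(`sigma_a2 = 0.3`, `sigma_e2 = 0.7`).  Sires are drawn in Hardy–Weinberg
proportions; each daughter receives one uniformly chosen sire allele and
one maternal allele at the population frequency; her polygenic value is
`0.5*u_sire + N(0, 0.75*sigma_a2)` per trait, so half-sib covariance is
`0.25*sigma_a2`, matching `A`.  EBV phenotypes are true genetic value
plus `N(0, sigma_e2/REL)` noise — the same residual model the MMRA
assumes; no attempt is made to simulate the multi-trait test-day
evaluation that produces real EBVs.  One global mean per trait; trait
correlations arise only through shared (pleiotropic) QTL entries.  QTL
effects are specified in phenotypic-SD units per allele-b copy.
`inject_artifacts` corrupts genotype cells for QC testing: uniform missing
calls, and guaranteed Mendelian inconsistencies (daughter flipped to the
homozygote opposite her sire's at sire-homozygous loci), with every
injected cell recorded in the truth tables.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: linkage disequilibrium between SNPs (each
SNP is independent, so clustered-hit patterns around a causal locus cannot
arise), genetic maps, X-dosage, selection/non-random mating, EBV
shrinkage correlations between relatives' phenotypes, and genotyping
batch effects.

## Calibration and recovery suites (problem sizes)

The package's own acceptance checks run at the full design scale: the
null calibration simulates 14 x 150 daughters with polygenic background
and no QTL and tests >10,000 SNPs with both methods (Kolmogorov–Smirnov
uniformity at alpha = 0.001, empirical type-I error at 5% within its 99%
binomial interval, MMRA inflation factor in [0.95, 1.05]).  REML recovery
uses 12 replicates in the test suite (24 in the acceptance script), with
agreement judged against 3 replicate standard errors; the planted-QTL
power check (0.5 phenotypic SD at MAF 0.3, genome-wise threshold for
N = 10,000 tests) uses 10 and 6 seeded replicates respectively.  These
replicate counts give stable replicate-SEs while keeping a full run of
suite plus script in the low minutes on one CPU.

## Numerical notes and edge cases

* Genotype codes are int8 with -1 as the missing sentinel; all-missing
  SNP columns get call rate 0 and NaN MAF/HWE and fall to the call-rate
  filter rather than raising.
* P values are floored at the smallest positive double so that results
  keep `raw_p in (0, 1]` even for astronomically significant SNPs.
* Rank-deficient L1-TDT designs (aliased sire levels) resolve via the
  minimum-norm least-squares solution with a warning; `df2` uses the
  realized rank.
* The allele coding convention (which allele is "2") is data-driven —
  lexicographically later observed allele unless overridden; every
  statistic is invariant under relabeling up to the sign of the effect
  estimate.
* PED/MAP round-trips are code-identical only when both alleles are
  observed at every SNP (the MAP dialect has no allele columns); the
  native genotype TSV carries allele metadata in its header and is fully
  lossless.
* Whether SNP metrics should be computed before or after the individual
  exclusions is a genuine ambiguity; this package computes them after
  (the stated precondition of the SNP stage).  Computing them before
  changes attribution counts only.

## Known limitations

Two-generation pedigrees only (deeper maternal pedigrees are out of
scope); no genomic relationship matrices; no dominance; single-trait
models only (multi-trait extensions would share information across the
correlated milk traits); Bonferroni only (no FDR or permutation
alternatives); no genomic-control correction; no imputation of failed
genotype calls.
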