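# Methods

This note documents the models, estimators and numerical conventions used
by `triorank`, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Transmission disequilibrium test

For a biallelic marker with alleles M1/M2, each parent with a complete
genotype in a Mendelian-consistent trio contributes one tally to the 2×2
table of (transmitted, non-transmitted) alleles, with cells a (M1/M1),
b (M1/M2), c (M2/M1), d (M2/M2); a + b + c + d = 2q over q contributing
trios. Only heterozygous parents are informative. Under the null the
transmitted allele of a heterozygous parent is a fair coin, so
b | (b + c) ~ Binomial(b + c, ½) and

    χ² = (b − c)² / (b + c)

is asymptotically chi-square with 1 df. SNPs with b + c = 0 are
*uninformative* and carry `NaN` statistics rather than raising; they are
excluded from rankings.

Transmission resolution subtracts the known parental contribution from the
child genotype. Exactly one configuration is phase-ambiguous — both parents
and the child heterozygous — and both of its resolutions tally one b and
one c, so counting is phase-invariant. Trios with a missing member genotype
or no Mendelian-consistent resolution at a SNP are excluded from that SNP's
table only (per-SNP exclusion keeps the maximum of data; genome-wide
exclusion would discard thousands of valid genotypes for one bad call).

**QC.** A SNP passes when its missing-call proportion over all individuals
(parents and offspring; the denominators are a package convention) is below
`max_missing` (default 0.15) and the Hardy–Weinberg goodness-of-fit p-value
exceeds `hwe_min_p` (default 10⁻⁶). HWE is computed on parents only
(founders — offspring of ascertained trios are not an HWE sample), by a
1-df asymptotic chi-square; an exact test (enumeration of heterozygote
counts conditional on allele counts) is available behind the `hwe_exact`
flag for small cohorts. Monomorphic SNPs fit HWE trivially, pass, and are
flagged so downstream stages can drop them.

**Genomic control.** λ = median(χ²) / 0.4549 (the 1-df chi-square median).
Dividing all χ² by a positive constant is strictly monotone, so the
p-value *ordering* of SNPs — all the rank-based machinery uses — is
invariant under the correction; corrected p-values are emitted as an
optional extra column and never used for ranking.

**Mega-analysis.** Transmission counts are summed across cohorts over the
SNPs passing QC in *every* cohort, then the statistic is recomputed. The
TDT's validity under population structure is what licenses the pooling.

## Rank-based comparison

SNPs are ordered by ascending p; ties are broken by (chromosome, position)
so the order is reproducible across runs and platforms (the choice of
tie-break is arbitrary but must be deterministic). Top-n sets are compared
across populations against the model of independent uniform random subsets
of the shared-SNP universe N (default: SNPs passing QC in all compared
cohorts; configurable): expected pairwise overlap n_a·n_b/N, three-way
n_a·n_b·n_c/N². No significance test is attached to overlap counts beyond
observed-versus-expected; replication of a top-k set in another cohort at
threshold α is counted against the uniform-null expectation k·α.

## Gene mapping and gene-level p

A SNP belongs to a gene when it lies within the gene body or within 20 kb
of either end — the window within which most trait-associated variants fall.
User-facing arithmetic is 1-based inclusive and the boundary is inclusive at
exactly 20,000 bp; internally coordinates are BED-style 0-based half-open,
so the condition is `start − w ≤ pos₀ < end + w`. The gene's p-value is the
minimum over its mapped SNPs, uncorrected for gene size; the per-gene SNP
count is reported so size bias is visible, and the enrichment stage
corrects for it properly.

## Gene-set over-representation

Genes whose best mapped SNP is in the top-n set are *noteworthy* (this is
equivalent to "any SNP in the top-n", since the best SNP is the minimum-p
SNP; the equivalence is asserted in tests). Each gene set is scored by the
hypergeometric upper tail P(X ≥ observed) with the universe restricted to
genes having at least one mapped SNP — a gene with no SNP can never be
noteworthy, and counting it would deflate p.

Empirical significance comes from resampled null noteworthy lists of the
observed size. Two modes:

* `snp` (default): draw SNPs uniformly and accumulate their genes until the
  observed number of distinct genes is reached. Genes with more SNPs enter
  null lists proportionally more often, so the null carries the same
  gene-size bias as the observed list (the ALIGATOR construction of
  Holmans et al., which resamples SNPs precisely for this reason).
* `gene`: draw genes uniformly. Simpler, ignores size bias; retained
  because "gene re-sampling" is how such procedures are often described,
  and the two modes agree when every gene has one SNP (tested).

The empirical p is add-one and tie-inclusive, (1 + #{null ≥ obs})/(R + 1):
it can never be zero and never falls below 1/(R+1). Because the in-set
count is a small integer, ties between the observed and null counts are
common, and this formulation is therefore *conservative by construction* —
its null distribution is stochastically larger than uniform. The results
table also carries `emp_p_mid`, the mid-p variant that counts ties half,
which is the appropriate quantity for checking calibration of a discrete
Monte-Carlo test; inference and ranking use `emp_p`. Raw empirical p drives
the pathway ranking (ties broken by hypergeometric p, then name);
Benjamini–Hochberg q-values are reported alongside but do not reorder
anything.

## FST × DRP

DRP is the absolute difference between a SNP's p-value ranks in two
populations, after restricting both rankings to their shared SNPs and
re-ranking within the intersection (otherwise ranks from different-length
lists are incommensurable). The absolute value makes "DRP above its mean" a
two-sided discordance measure.

The default per-SNP FST is the Nei-style GST from allele frequencies,
(H_T − H_S)/H_T with H_T = 2p̄(1 − p̄) and H_S the mean within-population
heterozygosity: deterministic, bounded in [0, 1], zero for identical
frequencies, and defined to be 0 when H_T = 0 (monomorphic in both). The
Weir–Cockerham two-population estimator (sample-size corrected, possibly
negative, optionally clamped) is available because most real-data work uses
it; heterozygosity is taken at its Hardy–Weinberg expectation since trio
parents are the frequency source. The frequency source is configurable
(parents by default, or affected offspring).

Both variables are dichotomized at their means (strictly greater = high;
values at the mean fall in "low" — arbitrary, documented), and independence
is tested by a 1-df Pearson chi-square without continuity correction at the
SNP counts involved (a Yates flag exists). The summary reports the observed
and margins-expected counts of SNPs high on both variables; observed >
expected with a significant p indicates that ancestry-informative SNPs also
tend to differ in disease association.

**Recovering the simulator's F.** For two populations drawn independently
from the Balding–Nichols model at parameter F, per SNP
E[H_T − H_S] = F·p(1−p) and E[H_T] = 2p(1−p)(1 − F/2), so the
ratio-of-sums GST estimates F/(2 − F); `recover_fst_param` inverts this as
F = 2·GST/(1 + GST), correcting the familiar (r−1)/r attenuation of GST at
r = 2 populations. This closed form is exact in expectation, not a fitted
calibration.

## Synthetic study generator

The generator emulates a multi-population affected-offspring-trio GWAS:

* **Ancestral frequencies** uniform on [maf_low, maf_high] (default
  0.05–0.5, the range a genotyping array targets).
* **Population frequencies** from the Balding–Nichols Beta model,
  Beta(p(1−F)/F, (1−p)(1−F)/F): mean p, variance F·p(1−p), a single knob
  per population with a known FST target for recovery tests. Populations
  are conditionally independent given the ancestral frequency (star
  phylogeny).
* **Trios**: parents Hardy–Weinberg at the population frequencies; each
  parent transmits one allele, heterozygous parents transmitting the risk
  allele with probability τ at planted risk SNPs and ½ elsewhere. τ maps
  one-to-one onto the TDT's binomial parameter, so power is analytically
  checkable; no liability/ascertainment model is layered on top.
* **Missingness** uniform and independent per genotype call; Mendelian
  errors injectable at a rate (default 0) to exercise error handling.
* **Genes** packed without overlap (minimum gap enforced) on a small
  chromosome set; **gene sets** sampled from the annotation, with one set
  optionally containing a chosen fraction of the risk-harbouring genes.

Default cohort sizes mirror a three-population childhood-asthma trio study
(429/52/46 trios; F = 0.05/0.15/0.10, in the range of human continental
differentiation); the default marker panel is 20,000 SNPs — a desk-scale
stand-in for an array, chosen so a full default run completes in seconds
while top-1,000 sets remain a meaningful decile. What the generator does
*not* emulate: linkage disequilibrium (the pipeline nowhere requires it),
haplotype structure, imputation inputs, X chromosomes, genotyping batch
effects, or real ascertainment. Tests passing on this generator therefore
validate the *statistical machinery* — counting, ranking, expectations,
calibration, planted-signal recovery — not the biology of any real cohort.

## Numerical conventions and edge cases

* Genotypes are int8 allele-1 copy counts with −1 for missing; allele 1
  ("A") is the M1/risk allele, allele 2 ("B") the other; PED output uses
  A/B with "0" for missing.
* All randomness flows through `numpy.random.default_rng`; pipeline stages
  derive independent seeds from the master seed by SHA-256 of
  `"{seed}:{stage}"`, reduced below 2³¹.
* Undefined quantities (uninformative TDT, all-missing MAF, monomorphic
  FST pairs) are NaN-marked and excluded downstream with logged counts,
  never silently zeroed; degenerate 2×2 dichotomizations yield NaN p with a
  warning.
* Sorts use mergesort (stable) everywhere a tie-break matters.

## Test-scale choices

The heavy properties run at reduced but statistically adequate scale: TDT
null calibration at 10,000 SNPs × 200 trios; p-value uniformity at 5,000
common SNPs × 2,000 trios (enough informative transmissions that the
chi-square approximation's discreteness is negligible at the KS scale);
overlap Monte Carlo at n = 1,000 of N = 100,000 with 10,000 replicates;
planted-signal recovery at 10 replicates of three 1,000-trio cohorts on a
10,000-SNP panel; enrichment calibration at 500 sets × 200 resamples and
power at 10 replicates × 1,000 resamples; F recovery at 20,000 SNPs. These
sizes are the package's own defaults for its validation suite.

## Known limitations

* The Nei GST per-SNP values are downward-biased as estimates of the
  Balding–Nichols F at two populations; use `recover_fst_param` (or the
  Weir–Cockerham estimator) when the parameter itself is of interest.
* The hypergeometric over-representation test is the plain upper tail; no
  "modified" variant is implemented, and the resampling p is the quantity
  to report.
* Gene-level p has no gene-size correction by design; only the enrichment
  stage corrects for size bias.
* No LD, haplotype TDT, covariates, case-control mode, or X-chromosome
  handling.
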