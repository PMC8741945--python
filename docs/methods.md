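# Methods

## The problem setting

Livestock population studies often have very few samples per population —
two or three animals per named breed is common — which rules out classical
population-level diversity estimators that need large within-population
sample sizes. The individual-level alternative implemented here treats each
individual's distribution of SNPs across the genes of one autosome as an
ecological *assemblage*: the "species" are genes, the "abundance" of a gene
is how many variant alleles the individual carries in it. Diversity and
similarity then come from Hill-number theory, which needs no within-
population replication and captures how evenly variation is spread along a
chromosome.

## Synthetic cohort model

The generator produces the statistical structure the analysis assumes,
with exact ground truth for every planted feature.

**Allele frequencies.** A two-level Balding-Nichols hierarchy. Each site
draws an ancestral frequency p uniformly from a minor-allele window
(default [0.05, 0.5]). Each species branch draws
p_s ~ Beta(p(1−F_s)/F_s, (1−p)(1−F_s)/F_s), and each population within a
species repeats the step around p_s with its own F. F = 0 copies the
frequency exactly (handled without division); F = 1 degenerates to a
Bernoulli point mass (fixation). The Beta step preserves the mean and has
variance p(1−p)F, so F acts as the per-branch drift. Two levels are the
simplest structure that reproduces a strong species split plus weak
within-species clustering in PCA; a coalescent simulator would add realism
(shared drift covariance, realistic LD) the downstream estimators do not
need.

**Genotypes.** Unrelated individuals draw binomial(2, p_k) per site, i.e.
Hardy-Weinberg proportions within population. Planted relatives: a
*duplicate* copies its source row exactly (before missingness); a
*parent-offspring* child receives one allele drawn uniformly from the
parent's two and one allele binomial(1, p_k). Missingness is i.i.d. across
genotypes at a configurable rate (block missingness is out of scope). An
optional LD-block mode copies a block anchor column with a small flip rate,
purely to exercise the pruner; drift itself induces no LD here.

**Quality annotations.** Per-site QD, MQ, QUAL, FS, MQRankSum,
ReadPosRankSum and DP are drawn from fixed "passing" distributions placed
comfortably inside each filter's pass region (constants in
`simulate.ANNOTATION_DISTRIBUTIONS`), except for a planted failing
fraction per annotation drawn strictly beyond the threshold. This makes
filter truth exact by construction — the point of the generator is known
truth, not a model of a real caller's joint annotation distribution, which
is not identifiable from published summaries. DP (mean depth across
samples) is integral, since VCF reserves DP as an integer field; planted
depth failures sit below the fixed two-read floor, so they fail regardless
of the data-dependent upper bound.

**Default scale.** 10 autosomes × 2,000 sites (1 kb spacing), ten
weakly-diverged populations of three samples plus two reference populations
of a strongly diverged sister species (F_species = 0.3,
F_population = 0.02), one planted duplicate and one parent-offspring pair,
2% missingness, and 1–2% planted failures per annotation. This mirrors the
few-samples-per-population design the method targets while keeping a full
pipeline run to seconds. Genes tile each autosome at 50 kb.

**Determinism.** All draws come from one `numpy` Generator seeded by the
cohort seed; regeneration and re-emission are byte-identical.

## QC cascade

Sequential, in this order: the six annotation hard filters, the depth
window, sample QC, then MAF, site call rate, HWE and LD pruning. The
report records one row per stage so remaining-count columns are
well-defined; order matters and is intentionally explicit. Inequalities
are strict exactly as printed: QD < 2 fails and QD = 2 passes; MAF ≤ 0.05
fails; call rate ≤ 0.95 fails; HWE p < 1e-6 fails; r² > 0.1 triggers
pruning. Missing annotations never trigger a hard filter (the caller
convention for absent annotations). The depth window retains sites with
mean depth between 2 reads and the grand mean + 3 SD of per-site mean
depths, bounds inclusive; "depth across samples" is interpreted as the
per-site mean.

The population filters exist to decorrelate markers for PCA and kinship;
diversity profiling instead uses the *quality-filtered* site set (hard
filters + depth + sample QC, exposed as
`FilterReport.quality_retained_sites`), because MAF and LD filters would
systematically delete exactly the low-frequency, clustered variation the
diversity profiles are meant to measure.

**HWE exact test.** The conditional exact test: given the allele counts,
the probability of each compatible heterozygote count is
P(n_Aa) ∝ n! / (n_AA! n_Aa! n_aa!) · 2^n_Aa, and the p-value sums all
configurations no more probable than the observed one (two-sided).
Computed in log-space via `gammaln` with a 1 + 1e-12 relative guard on the
"≤ observed" comparison; monomorphic sites return p = 1. The test suite
checks every configuration with n ≤ 10 against a rational-arithmetic
enumeration oracle.

**LD pruning.** Greedy `indep-pairwise`-style: 50 kb windows advancing
10 kb within each chromosome; while any retained pair in the window has
r² > 0.1, the worst pair loses its lower-MAF member (tie: later position).
r² is the squared Pearson correlation of dosages over pairwise-complete
samples; zero variance or fewer than two complete observations makes it
undefined and it is treated as 0 with a warning. The post-condition — no
retained within-window pair above threshold — is asserted by brute force
in the tests.

**Sample QC.** Call rate ≤ 0.95 excludes a sample. IBS per pair is the
mean of (2 − |g_i − g_j|)/2 over pairwise-complete sites; pairs with
IBS ≥ 0.95 lose the lower-call-rate member (tie: later sample order).

## Kinship

KING-robust: Ф = (N_Aa,Aa − 2·N_AA,aa)/(N_Aa(i) + N_Aa(j)) over
pairwise-complete sites. The estimator needs no allele frequencies, is
exactly 0.5 for identical genotypes, ≈ 0.25 for parent-offspring, ≈ 0 for
unrelated pairs within a population, and goes negative for diverged pairs.
Degree bands: > 0.354 duplicate/MZ; (0.177, 0.354] first;
(0.0884, 0.177] second; (0.0442, 0.0884] third; otherwise unrelated. The
published bands are open intervals that leave boundary values unassigned;
boundaries here are assigned upward-inclusive (to the more distant
degree), a documented convention. Pairs with no heterozygous site in
either member are flagged undefined (NaN) rather than given a value.
Per-group summaries report mean ± SD over all within-group pairs.

## PCA

Sites are mean-imputed at missing calls, centred, optionally scaled
(centring only by default, the common choice for genotype matrices), and
decomposed by full SVD (scikit-learn's exact PCA). Constant sites after
imputation are dropped with a warning. Variance explained is λ_k/Σλ.
Component signs are arbitrary; all tests compare separation, not sign.

## Diversity

**Abundance.** counts_g = number of alternate-allele copies (0/1/2 per
site) the owner carries in gene g, missing calls contributing 0; a
"presence" mode scores ≥ 1 alternate allele as 1, the two differing exactly
at homozygous-alternate sites. Intergenic SNPs are ignored (abundance is
defined per gene). Pooled owners sum member counts. A profile with zero
total abundance on an autosome is unusable and is skipped with that
flagged.

**Hill numbers.** qD = (Σ p_g^q)^(1/(1−q)), with the exponential-Shannon
limit at q = 1; zero abundances are dropped. qD is non-increasing in q and
bounded by [1, S]; both are property-tested, as is continuity across
q = 1 (±1e-6 within 1e-4 of the limit).

**Partition.** Equal assemblage weights w = 1/N (individual totals differ
for technical depth/callability reasons, not biological ones, so
size-proportional weighting is rejected). Gamma is the Hill number of the
mean relative-abundance vector; alpha is
(1/N)·(Σ_k Σ_g (p_kg/N)^q)^(1/(1−q)) (exponential-entropy limit at q = 1);
beta = gamma/alpha ∈ [1, N], enforced within 1e-9 and snapped to the exact
boundary within 1e-12 so the similarity transforms hit 1 and 0 exactly.

**Similarity.** Cq = [(1/β)^(q−1) − (1/N)^(q−1)]/[1 − (1/N)^(q−1)],
Uq = [(1/β)^(1−q) − (1/N)^(1−q)]/[1 − (1/N)^(1−q)], both → 1 − ln β/ln N
at q = 1; Sq = (1/β − 1/N)/(1 − 1/N); Vq = 1 − (β − 1)/(N − 1). All four
are 1 iff beta = 1 and 0 at beta = N, verified against an independent
symbolic (sympy) evaluation.

**Analysis modes.** Alpha profiles per individual per autosome at
q ∈ {0,1,2,3,4}, then averaged across autosomes per individual. Beta and
similarity at q ∈ {1,2,3,4}: *within*-group mode uses a group's
individuals as the N assemblages; *between*-group mode compares pooled
group profiles (N = 2) for every unordered pair — matching the
one-value-per-pair reporting style — with a per-individual assemblage
option retained. Grouping is by population or species. Autosome averages
are plain means of per-autosome values. Genes with zero abundance in all
assemblages cannot affect any Hill number and drop out automatically.

## Group comparisons

Mann-Whitney U, two-sided, on autosome-averaged per-individual values:
exact by enumeration when n_a + n_b ≤ 12 with no ties, tie-corrected
normal approximation otherwise (scipy's implementation behind the module
surface). Raw p-values are reported without multiplicity adjustment,
matching the presentation style the tables follow; Benjamini-Hochberg is
available but off by default.

## What the generator does and does not emulate

Passing tests establish that the estimators recover *planted* structure:
drift-scaled divergence, Hardy-Weinberg genotypes, exact clones, Mendelian
first-degree pairs, annotation failures, rare variants. Real data differ
in ways the generator deliberately omits: reference-alignment bias (which
inflates SNP counts — hence alpha diversity — in the species more diverged
from the reference; synthetic species are symmetric, so the tests exercise
only the *ordering* of between- vs within-species beta/similarity, whose
synthetic effect sizes are much smaller than real ones), linkage beyond
the artificial block option, non-uniform gene annotation, joint
annotation/genotype error correlation, and block missingness. Numbers
computed on synthetic cohorts are therefore qualitative checks of the
machinery, not predictions of any real dataset's values.

## Problem sizes

The test and acceptance runs use deliberately small instances chosen to
exercise every code path at comfortable statistical margins: 20 seeded
cohorts of 20,000 sites for kinship-band recovery (duplicate Ф has SD
≈ 0.003 at that size, far from the 0.354 threshold); 20 seeds of the
default 38-sample, 20,000-site two-species cohort for the PCA/beta
contrast; 100–150 samples × 5,000 sites for the MAF and HWE filter
calibrations; exhaustive n ≤ 10 for the HWE oracle; 50-site instances for
the LD brute-force check.

## Known limitations

- The abundance counting rule (allele copies vs site presence) is a
  genuine degree of freedom in the individual-level framework; both are
  implemented, allele-copies is the default, and conclusions about
  ordering are insensitive to it in the synthetic checks.
- Within-group kinship summaries include all within-group pairs; with
  planted relatives present the mean is not an "unrelated background"
  estimate.
- The LD pruner is greedy like the tool it emulates; it guarantees the
  post-condition, not a maximum-size retained set.
- `diversity_analysis` at species level with very unequal group sizes
  (e.g. 32 vs 6) pools before comparing; pooled-profile beta then mostly
  reflects shared gene density, so between-species effects are small by
  construction in synthetic data.
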