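# Methods

This note documents the models, statistical procedures, defaults and known
limitations of `compscape`. It is the companion to the API documentation: the
*why* behind each numerical choice.

## Study design being modelled

The package targets a laboratory-evolution design in budding yeast: 187
haploid single-gene deletion genotypes, each with an initial growth-rate
defect of at least 10%, evolved in four independent replicate populations in
rich medium for 104 days (~400 generations, serial transfer every 2 days),
alongside 22 evolving wild-type control lineages. Fitness (relative growth
rate) is measured from plate-reader OD₆₀₀ curves at days 0, 26, 52, 78 and
104 with six technical replicates, of which at least four must survive
quality control. Downstream assays are whole-genome resequencing of evolved
clones and ancestors, two-colour expression arrays
(wild type / ancestor / evolved, 2 biological × 2 technical replicates),
colony-size profiling across 14 environments on 768-position agar arrays,
and a genome-scale genetic-interaction map.

## Growth-curve fitness (`growthfit`)

**Rate estimator.** The maximum specific growth rate is the steepest
least-squares slope of ln(OD − blank) over any contiguous window of
`window_points` readings (default 5, readings every 20 min), in h⁻¹. The
curve is flagged unusable when the OD never exceeds twice the blank or no
window of positive blank-corrected signal exists; flagged wells return NaN
rather than raising.

**Blank.** The blank is the *medium-only* optical baseline, supplied
explicitly or estimated per plate as the median OD of empty wells.
Subtracting the first reading instead (a common shortcut) removes the
inoculum OD along with the optical blank; the first log point becomes
undefined and the earliest window slopes are inflated without bound
(d/dt ln(e^{rt} − 1) → ∞ as t → 0), which a max-slope estimator would then
select. We therefore do not use first-reading blanking.

**Known bias.** On a logistic curve the log-slope is r(1 − x/K), so the
estimator is intrinsically biased low by roughly the mean relative population
size over the chosen window. With the default inoculum of the simulated
plates (blank-corrected initial OD 0.027, carrying capacity 1.0) the bias is
≈3%; it falls below 1% for dilute inocula (x₀/K ≲ 0.005). Because sample and
reference wells share the bias, it largely cancels in normalized rates (the
noise-free pipeline recovers fitness ratios to <1%).

**Neighbourhood normalization.** Each well's rate is divided by the median
rate of reference wells within a Manhattan radius (default 2) of its
position, excluding itself. The default radius is chosen for layouts in
which the reference strain occupies every (even, even) position — the
pattern produced when a 96-well all-reference plate is interleaved into a
384-well assay plate — so that every sample well has 2–4 references in
range. Wells with no reference in range fall back to the plate-wide
reference median, with a warning. The neighbourhood definition is recorded
in the output's metadata.

**Relative fitness.** Fitness of a strain at a timepoint is
median(normalized replicate rates) / median(wild-type normalized rates).
At day 0 the replicates of all isogenic lines of a genotype are pooled,
since those populations have no independent evolutionary history yet.
Records with fewer than four retained replicates are dropped and logged.

**Slow growers.** A genotype enters the evolution panel when its day-0
fitness is ≤0.9 *and* the one-tailed Wilcoxon rank-sum test against the
wild-type replicate rates is significant after Benjamini–Hochberg correction
at FDR 0.05. Benjamini–Hochberg is used for every multiple-testing
correction in the package.

## Compensation calling (`compcall`)

Per line, with Δ the knock-out's median normalized fitness and WT the
evolving controls':

- RFI = Δ_end/Δ_start − 1 (relative fitness improvement),
- RC = (Δ_end − Δ_start)/(WT_end − Δ_start) (relative compensation),

so RC = 0 means no improvement and RC = 1 means the line ended at the
evolving controls' fitness. RC is undefined (NaN, warned) when
WT_end = Δ_start. The RC form used here is the unique linear index with
those two anchor properties; variants that also adjust for WT_start exist,
but cannot be distinguished by the anchors alone.

A line is **compensated** iff (i) its improvement is significant — one-tailed
Wilcoxon rank-sum of end-day vs pooled start-day replicate fitness, BH at
FDR 0.05 — and (ii) its RFI exceeds the control cutoff μ̂ + z₁₋α·σ̂ from a
maximum-likelihood normal fit to the control-line RFIs (α = 0.05; σ̂ = 0
degenerates to the mean, warned). A genotype shows evidence of compensation
iff at least one of its lines is compensated.

**Calibration caveat (important).** The two criteria control the *per-line*
null rate at roughly α. Because a genotype is called on the best of its four
lines, the genotype-level null rate is ≈ 1 − (1 − α)⁴ ≈ 4α, further inflated
when replicate noise contributes relatively more variance to low-fitness
lines than to the controls that define the cutoff, and noisy because the
cutoff itself is estimated from only 22 control values. On null simulations
at the study's scale the package measures a genotype-level false-call rate
of ~0.3 (line-level ~0.1), and correspondingly overestimates the compensable
fraction by the null rate times the non-compensable share. This is a
property of the calling rule itself, reproduced faithfully; consumers who
need genotype-level error control should tighten α (e.g. Šidák,
1 − (1 − α)^{1/4}) before aggregating.

Supporting analyses: Cochran–Armitage chi-square trend test of compensated
proportion across ordered initial-fitness bins (equally spaced scores;
empty bins merged with a warning; equivalent to the 2×2 chi-square for two
bins); one-way ANOVA of per-line gains with genotype as factor; a
genotype-specificity randomization that categorizes genotypes as
none/mixed/all compensated and compares observed category counts with the
mean over shuffles of the line-level calls (chi-square, optional restriction
to an initial-fitness stratum); and a trajectory-saturation test — per-line,
per-interval one-sided Wilcoxon improvements (BH over all line × interval
tests), then, among lines with exactly one significant interval, a 1-df
chi-square of the final-interval count against the uniform expectation n/4.

## Mutation statistics (`mutstats`)

**Variant status.** A variant in an evolved clone is *de novo* when absent
from its own ancestor, *ancestral* when present in it, and *ambiguous*
(excluded from de-novo sets) when present only in other ancestors. Within
the ancestors, a variant private to one ancestor is a *secondary ancestor*
mutation (acquired after strain construction); one shared by several
ancestors is deletion-library background.

**Nonsynonymous excess.** For each observed coding substitution type
ref→alt, p_i is the fraction of coding positions carrying ref at which the
substitution changes the encoded amino acid (stop gains count as
nonsynonymous; nonsense is pooled with nonsynonymous throughout). The test
statistic is the observed count of amino-acid-changing substitutions; its
tail probability under random placement, P(X ≥ k) with
X = Σ Bernoulli(p_i), is computed *exactly* by the standard dynamic-
programming convolution (O(n²)). Mutations are treated as independent given
their substitution types. CNV records pass through the tables but are
excluded from SNP statistics.

**Parallelism.** Pairwise sharing of de-novo mutated-gene sets uses the
Jaccard index |A∩B|/|A∪B| (the denominator is not fixed by convention;
intersection/min is available via `method="min"`), averaged separately over
same-genotype and different-genotype line pairs. Pairs of two empty sets
are excluded and logged.

**Functional relatedness.** Over all (deleted gene, mutated gene) pairs with
annotation coverage, the statistic is the co-annotation fraction (complex or
category membership) or the mean pairwise similarity (genetic-interaction
profile or co-expression Pearson r). The null reassigns the *whole per-line
mutated-gene lists* to genotypes uniformly at random, preserving each line's
mutational burden. Enrichment is observed/mean(null); the p-value uses the
add-one permutation estimator (1 + #{null ≥ obs})/(1 + N), which is valid
(stochastically ≥ uniform under the null) and verified by calibration tests.
With a single genotype the shuffle is the identity; the test warns and
returns p = 1.

**Promoter enrichment.** Two-sided exact binomial test of the number of
mutations falling in promoter windows against the merged-window fraction of
the genome. The window is a configurable upstream stretch (the analysis
default is 500 bp; the synthetic genome uses 200 bp gaps-limited windows);
"promoter" is operational, not mechanistic.

**Paralogs.** A gene pair is a paralog pair iff BLAST E < 1e-8, alignment
length > 100 residues, sequence similarity > 30%, and neither gene is a
transposon element; records with missing fields are rejected and logged.

## Expression restoration (`exprrest`)

Input matrices are per-gene log₂ ratios against a common reference, with 2
biological × 2 technical replicates per strain. Technical replicates are
averaged within biological replicate before testing, so the DE test is a
two-sample t-test on two biological means per strain; a gene is DE between
two strains iff |mean log₂ difference| ≥ log₂ 1.7 and p < 0.05. Genes with
zero variance and equal means get p = 1.

Distance triangles are Euclidean distances between mean strain profiles over
the genes DE in ≥1 of the three pairwise comparisons, each divided by the
ancestor–wild-type distance (undefined and flagged when that distance is 0).
Replicate-noise radii are the distances between the two biological-replicate
means of each strain on the same normalized scale.

A gene counts as **restored** when it is DE in ancestor vs wild type *and*
DE in evolved vs ancestor with the opposite sign — a significant shift back
toward wild type at the full threshold, not merely a sign flip. The
robustness filter drops the union of supplied exclusion lists (CNV genes,
aneuploidy-responsive genes, growth-rate-correlated genes, stochastic
transcripts) and recomputes everything on the filtered set.

## Environmental profiling (`envprofile`)

Colony sizes on a plate are divided by exp(grand + row + column effect), a
surface fitted by Tukey additive median polish to the log sizes of the
interleaved reference colonies, then scaled so the median normalized
reference is 1. Rows/columns without references (the reference grid covers
only even positions) get linearly interpolated effects. Plates without
references are only median-scaled (warned); plates whose references are all
zero (failed pinning) are flagged and excluded.

Per line × environment, evolved (day 104) vs ancestor (day 0) replicate
sizes are compared by a two-sided Wilcoxon rank-sum test, BH-corrected
within each environment; significant calls take the sign of the median
change, the rest are "equal" (no equivalence test — "equal" means
not-significantly-different). Calls require ≥3 replicates on both days; the
experiment's own floor was 4 technical replicates. Note the granularity of
exact rank tests at such sizes: the two-sided 4-vs-4 minimum p is 0.0286,
so after BH correction across many pairs a 4-replicate design can only call
pairs when a large share of all pairs is truly changed; the recovery tests
therefore use 6 replicate plates.

CV analyses: per genotype and environment, CV = sd/mean of replicate-line
fitness (≥3 lines; mean 0 excluded). The selection-medium CVs are compared
with the per-genotype mean CV across the other media by a Wilcoxon rank-sum
test; a delta-method Z-test for two CVs, var(ĉv) ≈ cv²(0.5 + cv²)/n, is
provided for single comparisons; and the Spearman correlation of
per-genotype fitness gain with mean other-media CV quantifies the
gain–pleiotropy association.

## Suppression and epistasis (`suppress_epi`)

Deletion of B suppresses deletion of A iff F_A < F_B and F_AB > F_A + σ_A
(strict inequalities; σ_A is consumed as provided by the interaction map).
Per-gene suppressor fractions use all tested partners by default, or only
the gene's genetic interactions when an `is_interaction` column is supplied.
The fitness–suppression association is the Spearman correlation on the raw
per-gene values, with quartile-binned medians for display.

Epistasis uses the multiplicative null standard for fitness:
ε = F_ab − F_a·F_b after rescaling so F_wt = 1. A mutation shows a sign
change when its effect (beyond a tolerance) has opposite signs in the
wild-type and in the other mutation's background; one change → sign
epistasis, two → reciprocal sign, |ε| beyond tolerance without a change →
magnitude. Significance of background dependence is assessed by a bootstrap
percentile CI over replicate colony sizes for
(F_ab − F_a) − (F_b − F_wt), or by a one-sided Wilcoxon of double vs sicker
single (both offered; they answer slightly different questions).

## Synthetic data (`synthio`)

Every generator is a pure function of (parameters, seed) via
`numpy.random.default_rng`; identical inputs give byte-identical tables, and
with noise set to zero the emitted tables reproduce the ground truth
exactly.

**Evolution experiment.** Initial deletion fitness ~ U(0.5, 0.9) (controls
start at 1). Every line receives a *multiplicative* drift
~ N(0.05, 0.015) — generic adaptation proportional to current fitness, which
keeps null deletion lines exchangeable with controls on the RFI scale, the
premise of the control-based cutoff. Lines of compensable genotypes
(probability 0.68) additionally gain an *absolute* compensation effect
~ N(0.18, 0.09) truncated at 0. The defaults are solved from the design's
stated conditions: controls gain ~5%, deletion lines average ~23% RFI, 68%
of genotypes compensable; with E[1/f₀] = ln(0.9/0.5)/0.4 ≈ 1.47 this fixes
the effect mean at (0.23/1.47 − 0.05)/0.68 ≈ 0.18. Trajectories approach
the final fitness exponentially (τ = 30 days, normalized to complete at day
104), matching the observed saturating shape without asserting a mechanism.
Technical replicates add N(0, 0.02) noise — an assumption; the replicate
noise magnitude of the real assay is not published.

**Growth plates.** Logistic curves from inoculum OD 0.027 to carrying
capacity 1.0 on top of a constant blank (0.08), multiplicative reading
noise, readings every 20 min for 24 h; empty wells stay at blank.

**Mutation tables.** Synthetic ORFs are uniform random sense codons (no
stops), laid on one chromosome with fixed intergenic gaps. Per line, SNP
and indel counts are Poisson(6) and Poisson(0.5). Placement is uniform
along the genome by default (the promoter test's null); a coding SNP lands
in a gene functionally related to the deleted gene (same synthetic complex
of 4 or category of 10) with probability `functional_bias`, else uniformly.
Coding effects come from translating the mutated codon.

**Expression triplets.** The ancestor differs from wild type at `n_de` genes
by ±`effect_log2`; a `restoration_fraction` of those revert fully in the
evolved profile; iid Gaussian replicate noise.

**Colony plates.** True strain × environment effects, an exponential
row/column gradient, lognormal noise; the reference strain fills every
(even, even) position; ancestor and evolved units of a genotype share
plates.

**GI map.** Single-deletion fitness ~ U(0.4, 1); for each tested pair with
F_B > F_A the pair becomes a true suppressor with probability link(F_A)
(default: linear, rising as fitness falls), in which case F_AB is placed
above F_A + σ_A; non-suppressors get near-multiplicative F_AB capped below
the threshold.

**What the generators do not emulate** — and hence what passing tests do not
show about real data: mutation-rate heterogeneity along the genome and codon
bias; selection on individual mutations (the NS fraction of simulated SNPs
is the neutral expectation); array-specific dye and probe effects;
non-separable (non row+column) colony biases; linkage between the fitness,
mutation, expression and colony layers, which are generated independently;
and any population-genetic dynamics (trajectories are parametric, not
simulated forward).

## Acceptance checks

`tests/test_acceptance.py` verifies, at the study's scale: exact equality of
the site-probability enumeration with a brute-force translation oracle on a
~10 kb ORF set; agreement of the Poisson-binomial DP tail with a 10⁶-draw
Monte-Carlo oracle within 3 MC standard errors across 20 random
configurations; recovery of restoration fractions {0, 0.2, 1} within ±0.05
at 6000 genes; recovery of the suppression–fitness Spearman correlation
within ±0.1 of the link-implied value at 3880 genes; calibration of the
permutation p-values (one-sided KS vs uniform); and the caller's null
calibration and fraction recovery. The last two are expected to fail at the
genotype level for the structural reason documented above — the ≥1-of-4
aggregation rule does not inherit the per-line α — and are retained as
honest measurements rather than relaxed. `scripts/acceptance.py` recomputes
the headline quantities from scratch for any seed; with the problem sizes
above it completes in well under a minute.
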