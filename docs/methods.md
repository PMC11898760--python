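# Methods

`miage` implements the quantitative core of a longitudinal infant gut
microbiome maturation analysis: a microbiota-for-age model with
saturation correction, Dirichlet-multinomial mixture (DMM) community
typing, developmental-phase statistics, and count-based marker-gene
clade detection, together with a synthetic cohort generator that
supplies ground truth for every stage.

## Microbiota-for-age model

Chronological age (months) is regressed on species relative abundances
(percent scale) with a random forest (default 500 trees, seeded,
`max_features = 1/3`). We use a standard random forest rather than a
guided/regularized variant: per-split feature-gain penalties mainly
sparsify *which* species trees split on, not the predictions, and the
package provides explicit sparsity through stepwise panel selection
instead.

**Cross-validation is grouped by subject** (default 10 folds): all
longitudinal samples of an individual stay in one fold. Repeated
measures within a subject are strongly autocorrelated, so ungrouped CV
would leak identity and inflate performance; grouping is the
conservative choice. Model performance is the Spearman correlation
between held-out predictions pooled over folds and true ages.

**Saturation spline.** Forest predictions saturate at late ages (a
regression-to-the-mean compression at the edges of the training range
plus genuine flattening of the composition signal). We therefore fit a
cubic regression spline of predicted age on *true* age — B-spline basis
with internal knots at the training-age deciles, a second-difference
roughness penalty, and the penalty weight chosen by generalized
cross-validation over a 28-point log-spaced grid. The spline is fitted
on the *cross-validated* predictions, not in-sample ones, so the
expected-prediction curve is itself free of optimism (the in-sample
alternative would shift relative ages toward zero for the training
cohort). Queries outside the training-age domain are clamped to the
nearest endpoint with a warning.

**Relative microbiota age** of a sample is
`predict(profile) − spline(true age)` in months; negative values mean
the composition looks younger than expected at that age.

**Importances** are the decrease in residual sum of squares when
splitting on each species, summed over nodes and averaged over trees
(unnormalized, so the vector sums to the forest's mean total RSS
decrease). Ties in the ranking break lexicographically for
determinism.

**Minimal panels.** Species are added in order of decreasing importance
and the forest is retrained at each panel size with the *same* folds
and seed, stopping at the smallest prefix whose CV Spearman reaches 95%
(or 99%) of the full model's. Because any panel reaching the 99%
cutoff also reaches the 95% one, the stricter panel always contains the
looser one.

**Segmented slope.** Relative age is regressed on true age by OLS
separately for samples at or before and after an 18-month breakpoint,
with two-sided t-tests for zero slope. Sides with fewer than 3 samples
are reported as undefined (NaN). On a noise-free perfect fit the
standard error is zero; we then report p = 0 for a nonzero slope and
p = 1 for a zero one.

**Cross-cohort transfer** maps features by species lineage string:
species unseen at training time are dropped, trained species missing
from the new cohort are imputed at zero abundance.

## DMM community typing

Counts over a species panel (intended use: the 99%-performance panel of
the age model, via `Cohort.count_matrix`) are modelled as a K-component
mixture of Dirichlet-multinomials. Fitting is EM:

* E-step: posterior responsibilities from the full DM log-pmf
  (including the multinomial coefficient), via log-sum-exp;
* M-step: weights are mean responsibilities; each component's alpha
  vector takes 3 responsibility-weighted Minka digamma fixed-point
  steps, `α_j ← α_j · Σ_i r_i[ψ(x_ij+α_j) − ψ(α_j)] / Σ_i r_i[ψ(n_i+α_0)
  − ψ(α_0)]`, floored at 1e-10.

The fixed point is a minorize-maximize step, so the observed-data
log-likelihood is non-decreasing; the fitter *asserts* this at every
iteration (tolerance 1e-8 relative) and stops when the gain drops below
`tol` (default 1e-6) or at `max_iter` (default 500). Initialisation is
seeded k-means on count proportions followed by moment-matching
(cluster mean proportions × precision 10), which makes fits
deterministic in (data, seed) and invariant, up to component
relabelling, to species order.

Model size uses `BIC = −2 logL + p ln n` with `p = K(S+1) − 1` free
parameters (K alpha vectors of length S plus K−1 free weights); the
exact parameter count convention is stated here because BIC variants
differ. `select_k` refits every K per replicate with its own seed and
returns all replicate optima, not just the winner — BIC optima on
weakly separated community data are known to wobble by a few
components between runs, and hiding that would overstate certainty.

Assignment of new samples (including another cohort's) evaluates
posteriors under the *fixed* model — no refitting — with missing panel
species zero-filled; hard assignment is the highest-posterior
component, ties breaking to the lowest index. Occupancy tables bin
samples into 3-month half-open age bins, drop bins with fewer than 15
samples, order clusters by their peak bin, and suppress fractions below
4% in *display* output only — statistics always use the unfiltered
table.

## Developmental-phase statistics

Phases are half-open: developmental [0, 12), transitional [12, 18),
stable [18, 36) months; ages beyond 36 fall into stable with a warning.
Half-open boundaries keep month-12 and month-18 samples from being
double-counted and agree with the 3-month binning grid.

**Subject-aware inference.** Longitudinal samples are not independent,
so all cohort comparisons default to subject-level permutation tests:
the test statistic is computed on per-subject summaries (mean
abundance, presence indicator, mean richness) and cohort labels are
permuted across subjects, all of a subject's samples moving together
(999 permutations, seeded; p = (1+b)/(B+1)). This is calibrated by
construction and plays the role that binomial/Poisson/quantile
mixed-effects models with individual as the grouping unit play in
classical analyses of such designs.

**Differential abundance** between cohorts within a phase: species
below 0.01% mean abundance in both cohorts are excluded; log2 fold
change compares cohort means with a pseudo-count of 0.001% (one decade
below the abundance filter); q-values are Benjamini–Hochberg; the
volcano rule flags species with p < 0.05 *and* |log2FC| > 1. Fold
changes are of means (not medians or model coefficients); the choice is
recorded here and in the output column name.

**Oral fraction** sums genus-collapsed abundances over 13
oral-associated genera (Actinomyces, Leptotrichia, Campylobacter,
Fusobacterium, Neisseria, Corynebacterium, Rothia, Treponema,
Veillonella, Prevotella, Streptococcus, Capnocytophaga, Haemophilus); a
synonym map accepts the common misspellings "Camplyobacter" and
"Capnocytophage". Samples above 3.4% are flagged as putative
low-density (oral-dominated) gut communities.

**Fungal prevalence** collapses fungal lineages (kingdom Fungi, or
Eukaryota if so configured) by genus and counts a genus present for an
individual if detected in *any* of that individual's samples within the
phase; prevalence is the fraction of individuals. The any-sample rule
is the natural reading of per-individual prevalence for intermittently
shedding taxa.

**Exposure correlation**: per subject, the relative age at the last
sequenced sample against the count of antibiotic exposures at or before
that sample's age; Spearman across subjects.

## Marker-gene clade calling

Alignment records (read, marker, identity, aligned fraction, MAPQ,
multimapping flag) are filtered with strict-less-than discards:
multimapping reads, identity < 95%, aligned fraction < 0.5, MAPQ < 20.
A marker is present with ≥ 25 retained reads; a clade is present when
≥ 10% of its markers are present (both thresholds inclusive). Marker
sets must be disjoint across clades — a shared marker would make the
per-marker read threshold ambiguous. Consensus sequences take the
major allele per pileup position, masking positions with coverage < 5,
major−minor margin < 5 counts (a tie is margin 0, hence masked), and
the first and last 10 bases of the gene. The aligner itself is out of
scope: records arrive as TSV (or are simulated), which keeps the module
aligner-agnostic.

## Synthetic cohort generator

The generator emulates the structure the pipeline detects; its defaults
are the package's study conditions (200 subjects × 6 samples per
cohort, ages uniform on [0.5, 36] months, 50,000 reads per sample).

* **Trajectories.** 39 species: 10 age-discriminatory (7 adult-like
  taxa rising with logistic prevalence midpoints spread at 6–29 months
  — spread across the whole window so the composition keeps gaining
  age information into the third year, as a real age-discriminatory
  panel does — and 3 milk-adapted/early taxa declining), 8 stable, 15
  pure-noise, 4 oral-associated, 2 fungal. Mean log intensity moves
  linearly with age between per-species endpoints.
* **Composition.** Species presence is Bernoulli in the age-dependent
  prevalence; compositions are Dirichlet draws around the normalized
  mean intensity with precision 150 (moderate biological noise); counts
  are multinomial at the sequencing depth. This matches the DMM model
  class, so community-typing recovery tests are sharp.
* **Disease arm as a stalled clock.** The disease arm evaluates
  trajectories at an *effective age*: between 6 and 18 months the
  effective age falls behind by 0.5 months per month and stays 6
  months behind thereafter, and each antibiotic exposure deflects it a
  further 0.8 months. This mechanism — rather than directly asserting
  outcomes — produces negative relative age after the first year, a
  negative pre-18-month slope with a flat post-18 slope, and a
  negative correlation between cumulative exposures and final relative
  age. Additional arm effects: age-discriminatory intensities × 0.85,
  oral contamination re-scaled to 5% of the composition, fungal
  carriage probability raised from 0.15 to 0.5, exposures Poisson(2)
  per subject at ages uniform on [0, 18] (antibiotic courses
  concentrated in infancy), each knocking age-discriminatory species
  down to 30% for 3 months.
* **Neutrality knob.** With all effects at their neutral values the
  disease arm is distributionally identical to the healthy arm, which
  the A/B test exercises.
* The generator's ground truth (effective ages, an age-score covariate,
  exposure times, per-sample phylum totals, planted clades and marker
  sequences) is returned and JSON-serializable.

What the generator does *not* emulate: phylogenetic covariance between
species, compositional zero-inflation beyond Bernoulli presence,
sequencing batch effects, strain-level abundance variation, or
realistic read-level error profiles. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model
class, not robustness to every property of real stool metagenomes.

## Problem sizes and numerical choices

Default analyses run on 1,200-sample cohorts with ~39 species, chosen
so a full model fit with subject-grouped 10-fold CV completes in well
under a minute per fold on one core. DMM recovery uses 400 samples at
depth 5,000 over 8 species with K = 4 planted components. Permutation
tests use 999 permutations. All randomness flows through explicit
integer seeds (`numpy.random.default_rng` and scikit-learn
`random_state`); identical seed and data give bit-identical
importances, panels, mixtures, and simulations. Degenerate inputs
(constant ages, all-zero count rows, empty pileups, zero-variance
correlations) raise explicit errors rather than returning silent NaNs,
except where the contract specifies a warning (empty rank selections,
out-of-domain spline queries, ages past 36 months).

## Known limitations

* The forest compresses predictions at the extremes of the training-age
  range; the saturation spline corrects the *expected* curve but the
  per-sample compression still attenuates very large maturation delays.
* BIC-based K selection inherits the instability of EM local optima;
  `select_k` surfaces it but does not resolve it.
* The permutation backends test mean differences; they are not
  drop-in replacements for mixed-model effect *estimates* (only for
  their hypothesis tests).
* Fisher's exact test for clade prevalence is two-sided by default;
  the one-sided hypergeometric tail is available via ``alternative``.
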