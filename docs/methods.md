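# Methods

## Task model

The simulated paradigm is a two-person helping task under threat of shock.
Each subject completes `n_runs = 8` runs of `trials_per_run = 18` trials:
9 distal and 9 imminent per run, presented as two contiguous blocks, with
6 trials per threat level (safe / 1 shock / 2 shocks) per run, balanced
within blocks (3 per level per block). This yields 144 trials and 24 per
imminence x level cell. Which block comes first is randomized
independently per run and subject — the neutral choice, since no
counterbalancing scheme is prescribed for the block order. Level order is
shuffled within each block; run order effects are not modelled.

Contingencies on shock trials: choosing *help* leads to both participants
being shocked with probability `p_both_shocked_on_help = 0.70` (and
neither otherwise); choosing *no help* always shocks the co-participant
and never the participant; a missed response shocks both, on any trial.
Safe trials with a response shock nobody.

## Ratings

Post-scan ratings are latent Gaussians — baseline + threat-level effect +
imminence effect + noise — rounded to integers and clipped to the 9-point
scale. Distress ratings (one per trial, since each trial showed a unique
clip of the co-participant) use baseline 3.5, level effects (0, 1.5, 3.0),
imminence effect 1.0, noise SD 1.0. Felt-threat ratings (one per cue
image, i.e. per level x imminence cell) use baseline 2.0, level effects
(0, 2.5, 4.5), imminence effect 1.0 applied to shock cues only (a safe
cue signals no shock at either imminence), noise SD 1.0. Values were
chosen to produce ordered means well inside the scale so that rounding
and clipping rarely distort the planted effects; the clipping bound is
still exercised (a rating of 9 is reachable for high-threat imminent
cues).

Rounding to integers is deliberate: real 9-point ratings are discrete,
and the resulting ties in the behavioral RDMs are exactly the regime that
motivates tau-a (below).

## Planted voxel-pattern geometry

For subject *s*, region *r*, trial *t*, voxel *v*:

    beta[t, v] = a * z(threat_t) * u_v + d * z(distress_t) * w_v + eps,
    eps ~ N(0, noise_sd^2) i.i.d.

`u`, `w` are random unit-norm voxel patterns fixed per (subject, region);
`z(.)` standardizes the subject's own trial-level ratings across their
144 trials. The threat value of a trial is the subject's rating of that
trial's cue (its level at its imminence) — using the subject's own rating
rather than the nominal level keeps the recovery problem well-posed,
because the analysis compares neural RDMs to rating-derived RDMs.

Coding strengths are drawn per (subject, region) as `a, d ~ N(1.0, 0.5)`
truncated at zero. Truncation reflects an identifiability fact: the RDM
geometry depends on the coding strength only through `a^2`, so a sign
would be invisible to the analysis. Defaults `n_voxels = 100`,
`noise_sd = 0.15` put the expected signal fraction of a trial pattern,
roughly `a^2 / (a^2 + d^2 + n_voxels * noise_sd^2)`, near 20 % — a
deliberately favourable signal-to-noise regime chosen (together with the
decision-policy slope below) in a design-stage power analysis so that the
planted brain–behavior link is reliably recoverable from a 49-subject
cohort. Real trial-wise fMRI betas are far noisier; passing recovery here
validates the *pipeline*, not the detectability of such effects in any
given dataset.

## Decision policy

On shock trials, `P(help) = sigmoid(gamma0 + gamma1*a_target +
gamma2*imminent)` with defaults `(-2.75, 2.5, 0.5)`; `a_target` is the
subject's threat-coding strength in the target region (left amygdala by
default, the analysis's headline region). The intercept centres cohort
mean helping near 50 %, consistent with the task instruction to balance
help and no-help choices; `gamma1` plants the brain–behavior link;
`gamma2` plants a modest imminence effect so the imminence-preference
classification has a recoverable modal class. Misses default to
probability 0 (miss rates are not modelled); reaction times are a
constant-plus-noise placeholder, not a process model.

## Seed discipline

All generators derive their streams from one master seed through
`numpy.random.SeedSequence(seed, spawn_key=(stage, subject))`, giving
disjoint streams per stage and per subject. Every output is a pure
function of (parameters, seed); the CLI audit test checks byte-identical
output trees across reruns.

## RDMs

Neural RDMs: `1 − Pearson r` between the voxel vectors of every trial
pair, built separately for the 72 distal and 72 imminent trials. Entries
are clipped to [0, 2] and symmetrized against last-bit float asymmetry; a
constant voxel vector raises an error naming the trial rather than
propagating NaNs. Safe trials are included — ratings exist for safe
clips and cues, and their variance is essential when behavioral ratings
are discrete. Trials with missed responses also remain: the modelled
window is the threat cue, not the response. Ratings enter distances raw
(not standardized), and betas are correlated as supplied — any
first-level scaling is the caller's responsibility and no additional
normalization is applied.

Behavioral RDMs: absolute differences of scalar ratings. The threat RDM
takes at most 3 distinct nonzero values per condition (three cue ratings
per imminence), the distress RDM at most 8 — both are heavily tied.

## Second-order similarity

Kendall's τ between the vectorized strictly-lower triangles, aligned by
trial id (never by position). **tau-a** is the default: when a model RDM
predicts ties — as discrete-rating RDMs always do — tau-b's tie
correction rewards or punishes the tie structure itself, whereas tau-a
simply counts concordances over all pairs; tau-a is the standard
recommendation for comparing tied candidate RDMs to neural RDMs. tau-b is
available by flag and raises an explicit error for an all-tied input,
where it is undefined (tau-a returns 0 there: no concordant or discordant
pairs exist).

Implementation note: the pipeline computes ~10^6 taus on vectors of
length 2,556 in the recovery study, so the concordant-minus-discordant
count uses an exact O(n·k) binned sweep (k = number of distinct values of
the lower-cardinality vector, with exact handling of ties in both
vectors), jitted with numba when available and falling back to a pure
numpy implementation, and to `scipy.stats.kendalltau` when both vectors
have many distinct values. All paths are exact and are tested against
exhaustive O(n^2) pair enumeration.

## Regional models and FDR

Per region: OLS of overall helping % (0–100 scale, so slopes are in
percentage points) on `tau_threat`, `tau_distress`, imminence (0 =
distal, 1 = imminent) and an intercept; two rows per subject with a
duplicated outcome, exactly as the regional-model design implies. The
non-independence of the two rows is documented rather than corrected; a
cluster-robust (by subject) standard-error option exists but is off by
default. P-values use the t distribution with `n_rows − 4` degrees of
freedom. Rank-deficient designs raise a collinearity error instead of
returning pseudo-inverse estimates.

FDR: Benjamini–Hochberg step-up across the pool of slope coefficients of
all regional models — 3 slopes x 13 regions = 39 p-values with the
default region list; intercepts are excluded as non-substantive
(configurable to include them). A coefficient is flagged significant when
its adjusted p is strictly below α = 0.05.

## Predominance test

Whether a region represents threat-to-self or other's-distress more
strongly: two-sided Wilcoxon signed-rank on per-subject
`tau_threat − tau_distress` within each (region, condition) cell, BH-FDR
across the 26 cells. The test choice is a documented default (no test is
canonical here) and is swappable; all-zero differences return statistic 0
and p = 1 by convention, and fewer than 5 pairs raise an error. One
caveat of the generator: even with equal mean coding strengths the
discrete cue-based threat model can achieve slightly higher tau-a than
the trial-unique distress model (its planted signal is exactly
block-structured), so a balanced synthetic cohort is not a strict null
for this test — the null simulations used to validate its error rate
make the two tau families exchangeable instead.

## What the generator does and does not emulate

It emulates: the factorial trial structure and block design, the decision
contingencies, the manipulation-check structure of the ratings, discrete
rating scales, subject-specific representational geometry with a
brain–behavior coupling, and seed-exact reproducibility. It does not
emulate: BOLD time series, hemodynamic convolution or first-level GLM
estimation (patterns are generated directly at the beta level),
spatially or temporally correlated fMRI noise, voxel covariance
structure, inter-regional correlation of coding strengths, miss-rate or
reaction-time processes. Consequently, passing recovery tests shows the
pipeline is correct and well-calibrated, not that comparable effects are
detectable in real data at these sample sizes.

## Problem sizes used in the checks

The recovery study runs 200 planted and 200 null cohorts of 49 subjects,
13 regions and 100 voxels per region (the full default geometry); the
outcome-contingency check uses 10,000 simulated help trials; oracle
batteries use 1,000 random cases each for τ and FDR and 100 random
designs for OLS; the permutation check uses 500 label shuffles of a
72-trial RDM. These sizes keep the whole validation suite at a few
minutes on one CPU while leaving Monte-Carlo error well below the margins
being asserted.
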