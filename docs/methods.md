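# Methods

## Problem setting

A disease model cohort and its wild-type (WT) controls are phenotyped on a
standardized platform producing a numeric feature vector per animal
(locomotion, rearing, immobility, startle amplitude, latencies, ...).  A
drug library is profiled in WT animals against a shared vehicle group.  The
package answers two questions: *which library compounds are predicted to
reverse the model's behavioral signature?* (enrichment screen) and *how
separable are two groups, and how far has a treated group moved back toward
WT?* (decorrelated-space indices).

## Differential profiles and the disease signature

Per-feature contrasts use the Welch (unequal-variance) two-sample t
statistic, case minus control.  Welch is the default because behavioral
groups are small and variance heterogeneity between genotypes is the rule,
not the exception.  Features with zero variance in both groups get t = 0
and a flag rather than an exception — large behavioral feature sets
routinely contain constant features, and a screen should not die on them.
This convention applies even when the two constant groups differ in mean
(the statistic is undefined there; the flag marks the feature for
inspection).

The signature takes up to `k_per_tail` features per tail (default 20),
ordered by |t|, optionally thresholded by `min_abs_t` (default 0).  Both
knobs are exposed because rank-based and threshold-based selection are both
defensible; the default is pure rank selection.  Missing values are resolved
at load time by a configurable policy (`drop-feature` default,
`drop-sample`, or within-group `mean-impute`).

## The reversal score

Each drug-dose profile is ranked by t-score (descending; ties keep original
feature order, which is part of the contract since the enrichment score
depends on rank order).  The running enrichment score of a set walks the
ranking top to bottom: a member at rank *i* adds `|t_i|^w / Σ_members
|t|^w`, a non-member subtracts `1/(n − m)`.  Both masses total 1, so the
curve ends at 0; the enrichment score is the signed extremum (first
occurrence on magnitude ties, which pins the sign by position in the
degenerate case where the maximum and minimum tie exactly).  The
"theoretical maximum" curve is the walk the same set would trace if its
members occupied the top ranks with their own weights, largest first — an
upper envelope useful for plotting.

Both signature sets are scored on one ranking in a single pass, and the
combined statistic is `(ES_dec − ES_inc) / 2`: positive when
disease-increased features are pushed down *and* disease-decreased features
up.  When both extrema share a sign the drug shifted everything one way;
following connectivity-scoring convention the combined score is then 0.
The rule is a switch (`same_sign_zero`) because the raw symmetric score is
the right object for calibration studies (below).

`weight_exponent` defaults to 1 (score-weighted); 0 gives the classic
unweighted Kolmogorov–Smirnov form.

## Permutation null and multiple testing

The null permutes signature membership: random disjoint feature-set pairs
of the observed sizes, drawn uniformly from the ranked features, rescored
identically; `p = (1 + #{perm ≥ obs}) / (B + 1)` (one-sided toward
reversal, add-one estimator, so p ≥ 1/(B+1)).  Permuting features rather
than animals keeps the library screen independent of per-drug sample data
and is exact for the question "is this membership pattern surprising on
this profile".  Default B = 1,000; every screen seed is spawned
deterministically from one top-level seed.  Benjamini–Hochberg q-values are
reported within each stratum, but ranking is by score (q is advisory, as
the screen is a ranking exercise).  The feasibility requirement is
`k_inc + k_dec ≤ n`, the exact condition for disjoint resampling.

**Calibration.**  With signature membership drawn uniformly at random, the
add-one p of the raw symmetric score (same-sign rule off) is exactly
uniform on its grid — verified by a KS test over 1,000 replicate screens.
The same-sign rule deliberately creates an atom of zeros, so the *screening*
statistic is conservative, never anticonservative; the calibration is
stated for the continuous statistic the rule wraps.

## Decorrelated feature space (DRF)

Features are standardized on the pooled reference groups and the pooled
covariance is eigendecomposed.  The stored transform rows are the
orthonormal eigenvectors; projection divides each component by the square
root of its eigenvalue, so coordinates are *whitened* (identity pooled
covariance).  Components with eigenvalues below 1e-10 of the largest are
dropped; `variance_kept` (default 0.95) then keeps the smallest leading
set of components reaching that fraction of the remaining spectrum.
Retained components are re-ranked by |between-group Welch t| for display
(the 2D "cloud" plots use the top two); classification and projection use
all retained components.

Whitening is what makes the geometry meaningful: nearest-centroid
classification in whitened coordinates is linear discriminant analysis
under the decorrelated equal-covariance assumption, and the recovery
coordinate becomes invariant under any invertible affine map of the raw
features when no component is discarded (truncation is not
affine-equivariant, so exact invariance holds at `variance_kept = 1`).

A caveat worth knowing: at full rank with n_components ≈ n_samples − 1,
whitened nearest-centroid accuracy degrades (small near-zero eigenvalues
are noise directions inflated to unit variance — the classical peaking
phenomenon).  The 0.95 default exists for exactly this reason.

## Discrimination Index

For each of `n_subsamples` (default 200) stratified random splits, a
`holdout_fraction` (default 0.5) per group is held out, centroids are fit
on the rest, and held-out samples are classified by the nearer centroid.
The index is `max(50, 100 × mean accuracy)` — clamped at the no-separation
floor rather than folded.  Under exchangeable groups the mean index over
replicate datasets sits a few points above 50 (the clamp makes chance
fluctuation one-sided); the calibration check asserts the mean lies in
[50, 55].  The p-value permutes group labels over the pooled samples and
recomputes the index per permutation (add-one estimator, default 1,000
permutations).  The pooled standardization and eigendecomposition are
label-independent, so the fitted space is shared across permutations; every
label-dependent quantity is recomputed.

## Recovery Index

All samples are projected in whitened coordinates onto the axis through the
model and WT centroids, scaled so the model mean is exactly 0 and the WT
mean exactly 1.  Recovery is `100 × clamp(mean test coordinate, 0, 1)`;
the mean of per-sample projections equals the projection of the mean (the
map is affine), but per-sample projections are kept for the p-value and
export.  The p-value is a one-sided Welch t-test of test vs model
projections (alternative: shifted toward WT), floored at the smallest
positive float to stay in (0, 1]; if both projection sets are constant and
equal the p is 1 by convention.  Coincident model and WT means make the
axis undefined and raise an error.

## Synthetic cohorts: what they emulate and what they do not

The generator's defaults are the package's study conditions: 300 features
(the real platform produces over 2,000; a few hundred preserves the
many-correlated-features regime at desk scale), 40 affected features
(alternating sign, half increased, half decreased — latency-like features
flip sign in real data), disease effect 1.0 marginal SD, 10 latent factors
with loading 0.5 and unit noise (within-block correlation ≈ 0.2, across
blocks 0), and 20 animals per group — the typical screening group size in
this kind of platform, at which the top-2k signature features recover ≥80%
of the planted affected set.  Library archetypes: `reverser`
(−strength × disease effect), `mimic` (+), `partial` (reversal on a
fraction of affected features), `null`; dose scales strength linearly up to
the drug's largest listed dose, and all drug-doses within a library share
one vehicle group, mirroring single-vehicle screening designs.

The model is Gaussian with homogeneous noise.  Real behavioral features are
mixed-scale counts, rates and latencies with heavy tails, floor/ceiling
effects, and batch structure; none of that is emulated.  Passing tests
therefore demonstrate the *statistical machinery* — calibration, power on
planted truth, geometry, determinism — not robustness to real-data
pathologies.  Welch contrasts and the rank-based enrichment give some
inherent robustness to monotone distortions, but that claim is not tested
here.

## Problem sizes used in checks

The verification studies run at deliberately modest sizes chosen as the
smallest that make each property sharp: oracle agreement on 200 random
instances (n ≤ 50, sets ≤ 10); exhaustive-vs-Monte-Carlo agreement on
6-feature rankings (30 enumerable pairs, 10,000 draws); null calibration
over 1,000 replicate 30-feature screens at 199 permutations; planted
reverser power over 100 seeds with 51 drugs × 100 features; discrimination
calibration over 200 replicate null cohorts; and a two-stratum end-to-end
run executed twice and compared byte for byte.

## Known limitations

* The enrichment p is conditional on the drug's ranking; it does not model
  uncertainty in the drug's own t-scores (group sizes enter only through
  those scores).
* The same-sign rule makes the screening p conservative at 0-score drugs.
* Dose–response is not modeled; doses are independent rows by design.
* The decorrelation is a whitening of the pooled second moment; it does not
  attempt independent component analysis or any higher-order decoupling.
* Discrimination's label permutation reuses the label-independent pooled
  space; with grossly unbalanced groups the stratified holdout, not the
  space, is the binding approximation.
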