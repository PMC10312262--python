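# Methods

## Grouped behavioral PLS

The core operation relates a participant-by-edge connectivity matrix
**X** (edges = strict lower triangle of the parcel correlation matrix,
column-major order) to a participant-by-behavior matrix **Y**. Both are
z-scored column-wise *within each group* (sample SD, ddof = 1), the
within-group correlation blocks `R_g = Z_Y′ Z_X / (n_g − 1)` are stacked
young-above-old, and the stacked (G·B)×E matrix is decomposed by SVD.
Stacking within-group correlation blocks rather than taking one pooled
cross-product is what makes the behavior saliences group-specific — each LV
carries one loading per (group, behavior) pair, which is the quantity of
interest when asking how brain–behavior associations differ between
cohorts. Dividing by `n_g − 1` after z-scoring puts every entry of R on the
Pearson-correlation scale, so bootstrap intervals on the behavior side are
intervals on correlations.

Whether behavior is standardized within group or across the full sample is
genuinely open; within-group is the default (symmetric with X), and the
standardization helpers accept any grouping so the pooled variant is one
call away.

SVD signs are arbitrary, so each LV is reported with a fixed convention:
the largest-|u| entry is made positive and v flipped consistently. Tied
singular values are reported as computed and flagged in the run log; no
re-rotation is attempted.

Brain scores are `X_z · v` (standardized X projected onto the edge
saliences). Partial correlations between brain scores and behaviors
residualize both sides on an intercept-plus-covariates design via least
squares and test the residual correlation against t with n − 2 − c df.

## Resampling inference

**Permutation.** Rows of X are permuted across the whole sample (the
labels and Y stay put), X is re-standardized within group, R rebuilt, and
the singular values extracted; the l-th observed value is compared with the
l-th largest permuted values by rank. The p estimator is the plain
proportion `#{s_perm ≥ s_obs} / n_perm` — no +1 correction — because that
is the convention this analysis family reports; the (k+1)/(n+1) estimator
is available as an option, as is within-group permutation (the stricter
exchangeability assumption).

**Bootstrap.** Participants are resampled with replacement within group,
preserving group sizes so every block of R stays estimable. Each resampled
solution is aligned to the original by per-LV sign flip (dot product with
the original u); full orthogonal Procrustes alignment of the singular-vector
block is available for near-degenerate LVs but off by default. The SE of
each edge salience is the ddof-1 SD over resamples; the bootstrap ratio is
original salience / SE. Edges with zero SE get a NaN ratio (flagged and
excluded from thresholded maps) rather than an infinity. Resamples in which
any column becomes constant within a group are skipped and counted.
Behavior-correlation CIs are 2.5/97.5 percentiles of the aligned per-(group,
behavior) correlations between behavior and bootstrap brain scores.

## Network contribution

Edge saliences are aggregated to N×N network blocks twice: positive
(v > 0) and negative (v < 0) maps, each retained edge contributing v².
Block means divide by the number of retained edges by default (an
all-edges denominator is an option); empty blocks report 0 with a count.

The permutation test on thresholded bootstrap-ratio maps permutes the
parcel → network assignment (network sizes fixed) and recomputes block
means. Here the default denominator is *all* block edges, with
sub-threshold edges contributing zero: a retained-only mean is insensitive
under the label null whenever the retained ratios are homogeneous (wherever
a retained edge lands, the block mean is unchanged), whereas the all-edge
mean measures concentration of supra-threshold mass, which is what the
null actually randomizes. The negative map uses magnitudes of
below-threshold-negative ratios so the one-sided "null ≥ observed" p is
meaningful for both maps. On atlases small enough to enumerate, the test
can run exhaustively over distinct labelings.

## Cross-validation

Folds are group-stratified: each group is shuffled and dealt into k
near-equal folds, so every participant is tested exactly once and the
80/20 group proportions hold per fold at k = 5. Standardization parameters
(means/SDs per group and column) are estimated on the training folds only
and applied to the test rows — corrupting test rows cannot change any
train-side quantity, which the suite asserts directly.

Projection uses the only dimensionally consistent reading of the
train-test recipe: the held-out brain score is `X_test · v_train` (edge
side) and the held-out behavior score is `Y_test · u_train` using the
block of u matching the participant's group. Per fold, the two score
vectors are correlated pooling both groups' test participants (per-group
correlations are an option); both the fold-mean and the pooled-over-folds
correlation are reported, since "mean test correlation" is ambiguous
between the two. Significance permutes Y rows within group and re-runs the
entire procedure.

## Synthetic data

The generator emulates the target study design: two cohorts (128 young, 92
old), five behavioral measures with the published per-group means/SDs
(loneliness total 40.6 ± 9.4 vs 38.2 ± 8.5; eyes-task percent 74.4 ± 9.8 vs
69.2 ± 9.7; empathy questionnaire 39.1 ± 4.1 vs 38.8 ± 3.6; subscale item
means 2.7–3.1 ± 0.5–0.6), demographic covariates with group offsets
(education, neuroticism, cognition composite; site and gender as per-group
Bernoulli draws), and a six-network parcel atlas. The full-scale atlas has
323 parcels with per-network counts proportional to the canonical
400-parcel seven-network scheme after dropping the somatomotor network; a
25-parcel (300-edge) version with the same six networks is the desk-scale
default for tests and examples.

The data model is bilinear: participant i draws latent scores
`t_il ~ N(0,1)` per planted LV (independent across LVs — the simplest
structure matching the PLS model), and

```
x_i = Σ_l √s_l · t_il · v_l + ε,   y_i = Σ_l √s_l · t_il · u_{g(i),l} + ε
```

with unit-norm edge saliences v_l (rejected, not silently renormalized, if
not unit norm), group-specific unit-norm behavior saliences, and i.i.d.
Gaussian noise of SD `noise_sd` on both sides, so the within-group
population cross-covariance is `Σ_l s_l v_l u′_{g,l}`. Behavior columns are
affinely rescaled to the requested per-group moments *after* adding signal,
using the theoretical column SD — sample means remain stochastic (they
converge at the usual √n rate) and the correlation-scale structure that
PLS decomposes is untouched. Planted edge patterns concentrate their mass
in configured network blocks (visual–default and within-default in the
default config) so the network-contribution stage has signal to find.
Covariates have no planted effect on X unless requested, which isolates
confound-handling tests. One seeded generator stream per dataset with a
fixed draw order (latent scores, X noise, Y noise, covariates) makes every
dataset bit-reproducible; the null generator draws brain-side and
behavior-side latents independently, keeping marginals while removing all
cross-covariance.

**Signal calibration.** "Signal-to-noise 5×" is defined at the level where
the SVD competes: `calibrate_noise_sd` sets `noise_sd` so that the top
singular value of the population R (correlation-attenuated by noise on
both sides) is five times the typical top singular value of a same-shaped
null R (Monte-Carlo estimate on independent Gaussian data, deterministic
given the config seed). Defining the ratio on the raw `s / noise_sd` scale
instead would ignore that the null singular-value scale grows like
√E + √(G·B) over sample-size noise, making "5×" mean different things at
different matrix shapes. At the calibrated ratio, recovery of the planted
edge saliences at n = 220, E = 300 sits around |r| ≈ 0.93 ± 0.02 across
seeds.

What the generator does **not** emulate: fMRI time series (no
autocorrelation or hemodynamics), motion artifacts, parcel-boundary
estimation, or realistic between-behavior covariance beyond what the
planted LVs induce (a behavior-correlation parameter is deliberately left
to the planted structure by default). Passing tests therefore demonstrate
the statistical machinery — identifiability, calibration, leak-freedom —
not robustness to fMRI-specific artifacts.

## Numerical and design choices

- Correlations of parcel time series use the product-moment formula;
  constant series raise an error naming the parcel. No Fisher z-transform
  by default (an option), matching the plain-correlation convention.
- Edge order is column-major over the strict lower triangle:
  (1,0), (2,0), …, (P−1,0), (2,1), …; P = 323 gives E = 52003. Files use
  1-based parcel ids, memory 0-based.
- Participants are assembled young-block-first, stable by id within block;
  assembly is invariant to input order and refuses mismatched or duplicate
  ids by name.
- Two resting runs are assumed concatenated upstream; the pipeline accepts
  one series (or one matrix) per participant.
- Rows with missing covariates are kept for PLS (which needs only the five
  behavior measures) and dropped listwise for partial-correlation
  analyses.
- Questionnaire scoring: reverse-keyed items map x → min + max − x (an
  involution); the loneliness scale is scored on a 1–4 response range
  (configurable), eyes-task accuracy is reported on the percent scale, IRI
  subscales as item means. Welch's t is used where group variances clearly
  differ (non-integer df), pooled elsewhere; effect sizes are reported as
  |d|.
- Pipeline defaults mirror the reference analysis: 10,000 permutations,
  10,000 bootstrap resamples, ±1.96 bootstrap-ratio threshold, 1,000
  network-label permutations, 5 folds with 1,000 CV permutations. Tests
  and examples scale counts down (hundreds) to keep runs in seconds to
  minutes; the statistics are unchanged, only Monte-Carlo resolution.
- All pipeline randomness derives from one top-level seed partitioned per
  stage, so a fixed seed reproduces every numeric output byte-for-byte.

## Known limitations

- Only two groups are exercised by the test suite; the code paths are
  structurally G-group but untested beyond G = 2.
- The permutation null compares singular values by rank without
  re-alignment; with near-degenerate planted spectra, rank swapping can
  blur LV-specific p-values (the log flags ties).
- Bootstrap sign alignment is per-LV; heavily mixed resampled solutions
  are only handled by the optional Procrustes alignment.
- The behavioral generator draws covariates independently of the planted
  signal, so confound-adjustment operations can be verified for
  correctness but not for realistic confounding strength.
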