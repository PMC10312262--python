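# connpls

Grouped behavioral partial least squares (PLS) for connectome–behavior
analysis, with permutation, bootstrap, network-contribution, and
cross-validation inference — plus a synthetic-data generator with planted
latent structure so the whole pipeline can be validated without any
neuroimaging download.

## The problem

Studies of loneliness and empathy in young and older adults relate
resting-state functional connectivity (RSFC) — the parcel-by-parcel
correlation structure of spontaneous brain activity — to behavioral
measures: loneliness (UCLA-LS), emotion recognition (eyes task), self-report
empathy (TEQ), and the perspective-taking and empathic-concern subscales of
the IRI. With ~50,000 connectivity edges per participant and a handful of
behaviors across two age groups, the natural tool is behavioral PLS: a
singular value decomposition of the stacked within-group behavior–edge
correlation matrix.

## The model

Given a participant-by-edge matrix **X** and participant-by-behavior matrix
**Y**, each z-scored within group, the within-group correlation blocks are
stacked (young block above old) into **R** and decomposed,

```
R = X′Y = U S V′
```

Each latent variable (LV) pairs a behavioral profile (column of **U**: one
salience per group × behavior) with an edge pattern (column of **V**) that
maximally covary; `s²_l / Σ s²_k` is the fraction of brain–behavior
covariance LV *l* explains. Inference:

- **Permutation test** — rows of **X** are reordered, the decomposition
  re-run, and each observed singular value compared with the same-rank
  permuted values (p = proportion ≥ observed).
- **Bootstrap ratios** — participants resampled with replacement within
  group; each edge salience divided by its bootstrap SE gives a z-like
  reliability score, thresholded at ±1.96 (two-sided 95%).
- **Network contribution** — edge saliences (or thresholded bootstrap
  ratios) averaged into 6×6 within/between-network blocks and tested
  against a parcel-label permutation null.
- **Cross-validation** — 5-fold, group-stratified: held-out participants
  are projected onto training singular vectors and their brain-side and
  behavior-side scores correlated.

The synthetic module plants a known low-rank brain–behavior covariance
(bilinear model with unit-norm saliences and per-group behavior loadings),
emulating the study design it targets: 128 young + 92 old participants,
five behavioral measures with realistic per-group means/SDs, covariates,
and block-structured edge patterns on a six-network atlas.

## Worked example

```sh
python examples/01_simulate_and_recover.py
```

```
dataset: 220 participants x 300 edges
calibrated noise SD: 0.382
LV1 covariance explained: 89.3%
edge-salience recovery |r|:     0.940
behavior-salience recovery |r|: 0.943
```

One latent dimension was planted with its singular value calibrated to 5×
the null singular-value scale; the fitted LV1 recovers the planted edge and
behavior saliences with |r| ≈ 0.94 and absorbs ~89% of the brain–behavior
covariance. The other examples walk through resampling inference
(`02`), network-block tests (`03`, where the planted visual–default and
within-default blocks light up), cross-validation (`04`), and the
behavioral statistics (`05`).

A thin CLI covers the two shell use cases:

```sh
connpls simulate --seed 0 --output data/
connpls run --behavior data/behavior.csv --edges data/edges.tsv \
    --atlas data/atlas.tsv --n-perm 1000 --n-boot 1000 --seed 1 --output out/
```

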