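"""Significance and reliability of the latent variables by resampling.

Permutation: is LV1's singular value larger than chance pairings of brains
and behaviors?  Bootstrap: which edge saliences are stable across resampled
cohorts (|bootstrap ratio| > 1.96, the two-sided 95% normal critical value)?
Resampling counts are reduced from the conventional 10,000 to keep the
example fast.
"""

import numpy as np

import connpls as cp
import connpls.synthetic as syn

cfg = syn.default_config(networks=syn.SCALED_NETWORKS, planted_s=5.0, seed=0)
cfg = syn.calibrate_noise_sd(cfg)
ds, _, truth = syn.simulate_dataset(cfg)

perm = cp.permutation_test(ds.X, ds.Y, ds.groups, n_perm=500, seed=1)
print(f"LV1 singular value {perm.observed_s[0]:.2f}, "
      f"permutation p = {perm.p_perm[0]:.3f} (500 permutations)")
print(f"LV2 singular value {perm.observed_s[1]:.2f}, "
      f"permutation p = {perm.p_perm[1]:.3f}")

boot = cp.bootstrap(ds.X, ds.Y, ds.groups, n_boot=500, seed=2, n_lv=1)
bsr = boot.bootstrap_ratio[0]
reliable = np.isfinite(bsr) & (np.abs(bsr) > boot.threshold)
planted = np.abs(np.asarray(truth.planted_lvs[0].v))
top = np.argsort(planted)[-30:]  # the 30 strongest planted edges
print(f"\nedges with |bootstrap ratio| > {boot.threshold}: {reliable.sum()} / {bsr.size}")
print(f"of the 30 strongest planted edges, {reliable[top].sum()} are flagged reliable")
print()
print("A small permutation p says the brain-behavior pairing is not chance;")
print("the bootstrap ratio flags which individual edges carry it reliably.")
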