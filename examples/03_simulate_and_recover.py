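"""Simulate a three-study NB panel and recover the planted model ranking.

The simulator plants a reference effect vector (rho = 1) and two
comparison studies at concordance 0.8 and 0.2.  Counts are negative
binomial, the DE engine estimates fold changes and p-values per study,
and the L1 distance over shared genes should rank the rho = 0.8 model
closer to the reference — which we verify against the ground truth.
"""

import numpy as np

import transcord as tc

cfg = tc.SimConfig(n_genes=3000, n_per_group=6, f_de=0.1, seed=1)
res = tc.run_panel(cfg)

print(f"simulated {cfg.n_genes} genes, {cfg.n_per_group} animals/group, "
      f"concordances {dict(cfg.rho)}")
print("\nestimated ranking vs reference FL:")
for label, s in res.ranking:
    print(f"  {label}: S = {s:.1f}")

truth = res.truth
s_true = {
    lab: np.abs(truth.study_beta(lab) - truth.beta_ref).sum()
    for lab in ("CS", "HU")
}
print("\ntrue-effect distances (noise-free):")
for lab, s in sorted(s_true.items(), key=lambda t: t[1]):
    print(f"  {lab}: S_true = {s:.1f}")

recovered = res.ranking[0][0] == min(s_true, key=s_true.get)
print(f"\nplanted ordering recovered: {recovered}")
# The estimated S values sit well above the true ones because sampling
# noise in both fold-change estimates adds a positive amount per gene;
# the *ordering* is what the statistic is used for.
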