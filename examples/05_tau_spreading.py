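"""Fit the connectome-based pathology spreading model on synthetic data.

Generates a 40-region synthetic connectome with known spreading parameters
(retrograde / anterograde / spatial pathways, region-heterogeneous
coefficients), fits the model from four post-injection timepoints, and runs
the seed-specificity null test: refitting from random injection-site sets
must score worse than the true sites.
"""

import numpy as np

import netsde as ns
from netsde.tau import regional_loading

conn, obs, truth = ns.synthesize_connectome_and_pathology(
    n=40, n_seeds=5, noise=0.05, seed=1)
rep = ns.fit_tau(obs, conn)

u_true = regional_loading(truth, conn, obs.x0)
active = u_true > 0
rel = np.abs(rep.loading[active] - u_true[active]) / u_true[active]
print(f"fitted c_t = {rep.c_t:.3f} (generating {truth.c_t})")
print(f"median relative error of the regional loadings: {np.median(rel):.1%}")
print("per-timepoint R^2 (log pathology):",
      np.round(rep.score_per_timepoint, 3))

res = ns.seed_specificity_test(obs, conn, n_random=100, seed=2)
null_med = np.median(res.null_scores, axis=0)
print("seed-specificity null (100 random 5-site draws):")
for k, month in enumerate(obs.months):
    print(f"  month {month:.0f}: true sites {res.true_scores[k]:.3f} "
          f"vs null median {null_med[k]:.3f}")
print(f"true-site score percentile within the null: {res.percentile:.0f}%")
# the true injection sites should outscore the null at every timepoint:
# prediction quality is specific to where the pathology was actually seeded
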