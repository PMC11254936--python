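"""Full pipeline: single-trial snapshots -> trained components -> explicit SDE.

Simulates the built-in cubic-oscillator network (known sparse ground truth),
trains the three component models (self drift, pairwise interaction,
diffusion) by maximizing the Gaussian transition likelihood, distills the
total learned drift onto elementary library terms, and compares the result
with the generating equation via sMAPE (0 = identical equations; one
completely spurious or missing term among k costs 1/k).
"""

from netsde.benchmarks import recover_linear_cubic
from netsde.metrics import smape

out = recover_linear_cubic(seed=1, n=10, steps=5000, dt=0.01)

print("distilled equation:")
print(out["sde"].report())
print()
print("generating equation:")
print(out["reference"].report())
print()
print(f"sMAPE(distilled, generating) = {out['smape']:.4f}")
print("values below 0.1 indicate the correct support with accurate "
      "coefficients; this run's training used one trial of 5000 snapshots.")
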