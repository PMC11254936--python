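"""Simulate a stochastic bursting-neuron network and inspect its activity.

Builds a 20-node signed network (half excitatory, half inhibitory sources),
integrates three-variable neuron dynamics with synaptic coupling by
Euler-Maruyama, and prints summary statistics of the resulting activity.
"""

import numpy as np

import netsde as ns

topo = ns.generate_network("signed", n=20, density=0.15, seed=1)
exc_edges = (topo.link_types == "excitatory").sum()
inh_edges = (topo.link_types == "inhibitory").sum()
print(f"network: {topo.n} nodes, {exc_edges} excitatory and "
      f"{inh_edges} inhibitory links")

spec = ns.make_model("hindmarsh_rose")  # V_syn = +2 (exc) / -1.5 (inh)
rng = np.random.default_rng(0)
x0 = np.column_stack([rng.uniform(-1.5, 0.5, 20), rng.uniform(-8, 0, 20),
                      rng.uniform(1.8, 2.2, 20)])
series = ns.simulate(spec, topo, x0, steps=2000, dt=0.01, seed=2)

v = series.values
print(f"simulated {series.n_steps} snapshots at dt = {series.dt}")
print(f"membrane-potential range: [{v[:, :, 0].min():.2f}, {v[:, :, 0].max():.2f}]")
print(f"fraction of time above the synaptic gate threshold (x1 > 1): "
      f"{(v[:, :, 0] > 1).mean():.3f}")
# the gate fraction is the share of snapshots in which a neuron is spiking,
# i.e. actively driving its postsynaptic targets
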