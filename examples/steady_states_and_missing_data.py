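"""Steady-state augmentation and missing values.

Two features matter on real datasets: equilibrium measurements (an
unperturbed culture is a draw from the steady state, i.e. a point where
the drift vanishes) and missing entries.  This example simulates a
two-gene circuit, removes a few measurements, attaches the known steady
state, and runs a short chain on the result.
"""

import numpy as np

from gpgrn import (
    SamplerConfig,
    Series,
    TimeSeriesDataset,
    add_steady_states,
    normalize,
    random_network,
    run_mcmc,
    simulate_expression,
)
from gpgrn.synthetic import Protocol, steady_state

net = random_network(2, expected_in_degree=1.0, seed=3, n_edges=1)
proto = Protocol(duration=12.0, transient_discard=0.0, sample_interval=1.0, seed=3)
_, ds = simulate_expression(net, proto)

# knock out two measurements of gene 1 (NaN marks a missing value)
Y = ds.series[0].values.copy()
Y[3, 0] = np.nan
Y[7, 0] = np.nan
ds = TimeSeriesDataset([Series(ds.series[0].times, Y)], ds.gene_names)
print(f"measurements: {Y.shape[0]} points, "
      f"{int(np.isnan(Y).sum())} missing entries")

# the unperturbed equilibrium is a zero-drift observation for every gene
ss = steady_state(net)
ds = add_steady_states(ds, ss[None, :])
print("steady state attached:", np.round(ss, 3))

ds = normalize(ds)
cfg = SamplerConfig(n_iter=800, burn_in=300, thin=5, seed=3)
store = run_mcmc(ds, cfg)
cm = store.confidence()

np.set_printoptions(precision=2, suppress=True)
print("\nposterior link probabilities:")
print(cm.probs)
print("\nground truth:")
print(net.ground_truth)
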