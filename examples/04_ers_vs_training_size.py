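"""How training-set size affects rule-inference certainty (ERS size).

Re-runs rule inference on one simulated population downsampled to 1% and
50% of its cells, at full size, and augmented to 200% by resampling, and
prints the mean observed equivalent-rule-set size per training fraction.
Smaller ERS = the data constrained the rules more; with very few cells the
ERS stays near its maximum.
"""

from boolpath import ers_vs_cells, random_network, random_rules, sample_cells
from boolpath.synth import SyntheticScenario

net = random_network(n_nodes=8, edge_prob=0.35, seed=61)
scenario = SyntheticScenario(
    network=net, true_rules=random_rules(net, seed=62),
    n_cells_per_group=100, flip_noise=0.05, seed=63,
)
_, cells = sample_cells(scenario)

result = ers_vs_cells(net, cells, fractions=(0.01, 0.5, 1.0, 2.0), seed=64)
print(result.table.to_string(index=False))
print("\nmean observed ERS size by fraction of training cells:")
for frac in (0.01, 0.5, 1.0, 2.0):
    print(f"  {frac:>5.0%}: {result.mean_ers(frac):.2f}")
# Expect the 1% row to sit near the maximum ERS size (nothing learned) and
# the full-size run to be the most constrained.
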