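"""Synthetic ground-truth scenarios: networks, rules, and noisy cell samples.

A scenario fixes a random signed network, a ground-truth rule set drawn
from the sign-compatible candidate space, and a two-group cell population
sampled from the network's attractor states.  Each cell picks an attractor
(per-group mixture weights), one of its cycle states uniformly, and flips
each bit independently with a small probability — mimicking dropout and
stochastic expression around a steady state.  Continuous expression is laid
on top of the binary states multiplicatively with lognormal noise (zeros
stay zero, as in dropout-dominated droplet data); per-gene mean shifts
between the groups create a known contrast for pathway analysis.  Cells are
partitioned round-robin into four pseudo-subjects per group so that
subject-level contingency tables have a realistic shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .expression import BinaryExpressionMatrix, ExpressionMatrix
from .network import SignedNetwork
from .rules import RuleSet, enumerate_candidates
from .simulate import Attractor, enumerate_all_attractors

N_SUBJECTS_PER_GROUP = 4


def random_network(
    n_nodes: int,
    edge_prob: float = 0.25,
    inhibition_frac: float = 0.3,
    max_indegree: int = 3,
    seed: int = 0,
    max_retries: int = 50,
) -> SignedNetwork:
    """Random weakly-connected signed digraph with in-degree capped at 3.

    Each ordered pair gets an edge with probability ``edge_prob``; nodes
    exceeding the in-degree cap keep a random subset of parents.  Each edge
    is inhibitory with probability ``inhibition_frac``.  Resamples until
    weakly connected (bounded retries).
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    names = [f"G{i:02d}" for i in range(1, n_nodes + 1)]
    import networkx as nx

    for _ in range(max_retries):
        net = SignedNetwork(name=f"synthetic-{n_nodes}n-s{seed}")
        for n in names:
            net.graph.add_node(n)
        for v in names:
            parents = [u for u in names if u != v and rng.random() < edge_prob]
            if len(parents) > max_indegree:
                idx = rng.choice(len(parents), size=max_indegree, replace=False)
                parents = [parents[i] for i in sorted(idx)]
            for u in parents:
                sign = -1 if rng.random() < inhibition_frac else 1
                net.add_edge(u, v, sign)
        if net.graph.number_of_edges() and nx.is_weakly_connected(net.graph):
            return net
    raise RuntimeError(
        f"no weakly connected draw in {max_retries} tries; increase edge_prob"
    )


def random_rules(net: SignedNetwork, seed: int = 0) -> RuleSet:
    """Ground-truth rule set: each node uniform over its candidate space."""
    rng = np.random.default_rng(seed)
    rules = {}
    for node in net.nodes:
        cands = enumerate_candidates(node, net.regulators_of(node))
        rules[node] = cands[int(rng.integers(len(cands)))]
    return RuleSet(rules)


@dataclass
class SyntheticScenario:
    """A fully specified ground-truth generating process for one experiment."""

    network: SignedNetwork
    true_rules: RuleSet
    n_cells_per_group: int = 100
    flip_noise: float = 0.05
    mean_shift: Mapping[str, float] = field(default_factory=dict)
    attractor_mixture: tuple[Sequence[float], Sequence[float]] | None = None
    base_expression: float = 2.0
    lognormal_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.flip_noise < 0.5:
            raise ValueError("flip_noise must lie in [0, 0.5)")

    @property
    def attractors(self) -> list[Attractor]:
        """True attractors: exhaustive up to 16 nodes, else harvested.

        Larger networks sweep 4096 seeded random start states instead of
        the full state space; dominant attractors are found either way.
        """
        if getattr(self, "_attractors", None) is None:
            n = len(self.network.nodes)
            if n <= 16:
                atts = [a for a, _ in enumerate_all_attractors(self.true_rules)]
            else:
                from .simulate import CompiledRules, find_attractor

                rng = np.random.default_rng(self.seed ^ 0x5EED)
                compiled = CompiledRules.compile(self.true_rules)
                seen = {}
                for _ in range(4096):
                    start = tuple(int(v) for v in rng.integers(0, 2, size=n))
                    att = find_attractor(start, compiled, max_steps=500)
                    seen.setdefault(att.key, att)
                atts = [seen[k] for k in sorted(seen)]
            object.__setattr__(self, "_attractors", atts)
        return self._attractors

    def params_dict(self) -> dict:
        return {
            "network": self.network.name,
            "nodes": self.network.nodes,
            "n_cells_per_group": self.n_cells_per_group,
            "flip_noise": self.flip_noise,
            "mean_shift": dict(self.mean_shift),
            "base_expression": self.base_expression,
            "lognormal_sigma": self.lognormal_sigma,
            "seed": self.seed,
            "rules": {n: self.true_rules[n].expression for n in self.true_rules.nodes},
        }

    def save_params(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.params_dict(), fh, indent=2, sort_keys=True)


def sample_cells(
    scenario: SyntheticScenario,
) -> tuple[ExpressionMatrix, BinaryExpressionMatrix]:
    """Sample the two-group cell population a scenario describes.

    Returns the continuous matrix and its binarization (nonzero indicator
    of the continuous values equals the noisy binary states by
    construction).  Metadata records group, pseudo-subject, and the
    generating attractor's canonical key per cell.
    """
    import pandas as pd

    rng = np.random.default_rng(scenario.seed)
    nodes = scenario.network.nodes
    n = len(nodes)
    attractors = scenario.attractors
    k = len(attractors)
    if scenario.attractor_mixture is None:
        mixture = (np.full(k, 1 / k), np.full(k, 1 / k))
    else:
        mixture = tuple(np.asarray(w, dtype=float) for w in scenario.attractor_mixture)
        for w in mixture:
            if len(w) != k or not np.isclose(w.sum(), 1.0):
                raise ValueError("mixture weights must match attractor count and sum to 1")

    shift = np.array([scenario.mean_shift.get(g, 0.0) for g in nodes])
    gene_means = rng.uniform(0.5, 1.5, size=n)  # per-gene baseline spread

    binary_rows, cont_rows, meta_rows = [], [], []
    for gi, gname in enumerate(("g1", "g2")):
        for ci in range(scenario.n_cells_per_group):
            ai = int(rng.choice(k, p=mixture[gi]))
            att = attractors[ai]
            state = np.asarray(
                att.states[int(rng.integers(att.length))], dtype=np.int8
            )
            flips = rng.random(n) < scenario.flip_noise
            noisy = np.where(flips, 1 - state, state)
            level = scenario.base_expression + gene_means + (shift if gi == 0 else 0.0)
            cont = noisy * np.maximum(level, 0.05) * rng.lognormal(
                0.0, scenario.lognormal_sigma, size=n
            )
            binary_rows.append(noisy)
            cont_rows.append(cont)
            meta_rows.append(
                {
                    "cluster": "c0",
                    "subject": f"{gname}-s{ci % N_SUBJECTS_PER_GROUP + 1}",
                    "group": gname,
                    "true_attractor": att.key,
                }
            )

    cell_ids = [f"cell{i:05d}" for i in range(len(binary_rows))]
    meta = pd.DataFrame(meta_rows, index=pd.Index(cell_ids, name="cell"))
    cont = ExpressionMatrix(
        values=np.asarray(cont_rows),
        cell_ids=cell_ids,
        gene_symbols=list(nodes),
        metadata=meta,
    )
    binary = BinaryExpressionMatrix(
        values=np.asarray(binary_rows, dtype=np.int8),
        cell_ids=cell_ids,
        gene_symbols=list(nodes),
        metadata=meta.copy(),
        continuous=cont,
    )
    return cont, binary
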