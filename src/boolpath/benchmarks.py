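"""Reference in-silico experiments exercising the whole pipeline.

Each function sets up seeded synthetic study conditions, runs the relevant
pipeline stages, and returns a summary number: rule-recovery rate on
noise-free attractor-sampled cells, global-search optimality on exhaustively
checkable toys, bootstrap calibration and power for the pathway test,
attractor-assignment accuracy under bit-flip noise, and the response of
equivalent-rule-set size to training-set size.  They are used by the test
suite and the reproduction script; sizes are chosen so the full battery
runs on a laptop in minutes.
"""

from __future__ import annotations

import itertools

import pandas as pd

from .attractors import assign_cells
from .evaluation import ers_vs_cells
from .expression import concat_genes
from .inference import GAParams, infer, rule_fit_error
from .pathway import analyze_pathways, bootstrap_pvalue, importance_scores
from .rules import RuleSet
from .synth import SyntheticScenario, random_network, random_rules, sample_cells



def ga_optimality_rate(n_scenarios: int = 20, seed: int = 0) -> float:
    """Fraction of exhaustively checkable toys where the GA finds the optimum.

    Five-node networks with in-degree capped at 2 keep the rule-set product
    space at or below 4^5, small enough to enumerate; data are noise-free
    attractor samples, so the global minimum is attainable (and equals 0
    when the network's own attractors cover the cells).
    """
    from .rules import enumerate_candidates

    hits = 0
    for k in range(n_scenarios):
        s = seed * 131 + k
        net = random_network(5, edge_prob=0.35, seed=s, max_indegree=2)
        rules = random_rules(net, seed=s + 1)
        sc = SyntheticScenario(network=net, true_rules=rules,
                               n_cells_per_group=30, flip_noise=0.0, seed=s + 2)
        _, data = sample_cells(sc)
        cands = {n: enumerate_candidates(n, net.regulators_of(n)) for n in net.nodes}
        res = infer(net, data, ga_params=GAParams(seed=s + 3))
        best = None
        nodes = sorted(cands)
        for combo in itertools.product(*(range(len(cands[n])) for n in nodes)):
            rs = RuleSet({n: cands[n][i] for n, i in zip(nodes, combo)})
            err = rule_fit_error(rs, data)
            best = err if best is None else min(best, err)
            if best == 0:
                break
        achieved = min(res.ga_error, res.local_error)
        hits += achieved == best
    return hits / n_scenarios


def rule_recovery_rate(
    n_seeds: int = 20, n_nodes: int = 8, n_cells: int = 200, seed: int = 0
) -> float:
    """Fraction of nodes whose true rule lands in the inferred ERS.

    Cells are exact attractor states (no noise) of a random ground-truth
    rule set on random networks; recovery is pooled over all nodes of all
    replicates.
    """
    in_ers = total = 0
    for k in range(n_seeds):
        s = seed * 211 + k
        net = random_network(n_nodes, edge_prob=0.35, seed=s)
        rules = random_rules(net, seed=s + 1)
        sc = SyntheticScenario(network=net, true_rules=rules,
                               n_cells_per_group=n_cells // 2,
                               flip_noise=0.0, seed=s + 2)
        _, data = sample_cells(sc)
        res = infer(net, data, ga_params=GAParams(seed=s + 3))
        for n in net.nodes:
            total += 1
            ers_tables = {c.truth_table for c in res.rulespaces[n].ers}
            in_ers += rules[n].truth_table in ers_tables
    return in_ers / total


def _null_setup(seed: int, n_nodes: int = 8, n_cells_per_group: int = 50):
    net = random_network(n_nodes, edge_prob=0.35, seed=seed)
    rules = random_rules(net, seed=seed + 1)
    return net, rules


def null_rejection_rate(
    n_replicates: int = 200, B: int = 500, alpha: float = 0.05, seed: int = 0
) -> float:
    """Type-I error of the modulation bootstrap under label exchangeability.

    One fixed network and importance vector; each replicate draws a fresh
    two-group population with no group effect and tests the pathway.
    """
    net, rules = _null_setup(seed * 17 + 3)
    base = SyntheticScenario(network=net, true_rules=rules,
                             n_cells_per_group=50, flip_noise=0.05,
                             seed=seed * 17 + 5)
    _, data0 = sample_cells(base)
    res = infer(net, data0, ga_params=GAParams(seed=seed * 17 + 7))
    imp = importance_scores(res.simplest_ruleset(), res.rulespaces, data0).as_series()
    rejections = 0
    for r in range(n_replicates):
        sc = SyntheticScenario(network=net, true_rules=rules,
                               n_cells_per_group=50, flip_noise=0.05,
                               seed=seed * 100003 + 11 * r + 13)
        _, data = sample_cells(sc)
        _, p = bootstrap_pvalue(data, imp, net.nodes, B=B, seed=seed * 7919 + r)
        rejections += p < alpha
    return rejections / n_replicates


def shift_detection_rate(
    n_seeds: int = 20, shift: float = 2.0, B: int = 500, alpha: float = 0.05,
    seed: int = 0, n_cells_per_group: int = 100,
) -> tuple[float, float]:
    """Power and specificity of the pathway test with an injected group shift.

    Per replicate: two disjoint 8-node pathways share one cell population;
    only the target pathway's genes receive a group-1 mean shift.  Returns
    (fraction of replicates where the target's Bonferroni-adjusted p <
    alpha, fraction where the unshifted decoy stays above alpha).
    """
    detected = decoy_clean = 0
    for k in range(n_seeds):
        s = seed * 307 + 7 * k
        net_t = random_network(8, edge_prob=0.35, seed=s).renamed("T")
        net_d = random_network(8, edge_prob=0.35, seed=s + 1).renamed("D")
        rules_t = random_rules(net_t, seed=s + 2)
        rules_d = random_rules(net_d, seed=s + 3)
        sc_t = SyntheticScenario(network=net_t, true_rules=rules_t,
                                 n_cells_per_group=n_cells_per_group,
                                 flip_noise=0.05,
                                 mean_shift={g: shift for g in net_t.nodes},
                                 seed=s + 4)
        sc_d = SyntheticScenario(network=net_d, true_rules=rules_d,
                                 n_cells_per_group=n_cells_per_group,
                                 flip_noise=0.05, seed=s + 9)
        _, b_t = sample_cells(sc_t)
        _, b_d = sample_cells(sc_d)
        cells = concat_genes(b_t, b_d)
        res_t = infer(net_t, cells, ga_params=GAParams(seed=s + 5))
        res_d = infer(net_d, cells, ga_params=GAParams(seed=s + 6))
        _, allres = analyze_pathways([res_t, res_d], cells, alpha=alpha,
                                     B=B, seed=s + 7)
        by_name = {r.name: r for r in allres}
        detected += by_name[net_t.name].p_adjusted < alpha
        decoy_clean += by_name[net_d.name].p_adjusted >= alpha
    return detected / n_seeds, decoy_clean / n_seeds


def assignment_accuracy(
    n_seeds: int = 20, n_nodes: int = 10, n_cells: int = 100,
    flip_noise: float = 0.05, seed: int = 0,
) -> float:
    """Pooled fraction of cells assigned back to their generating attractor."""
    correct = total = 0
    for k in range(n_seeds):
        s = seed * 401 + k
        net = random_network(n_nodes, edge_prob=0.3, seed=s)
        rules = random_rules(net, seed=s + 1)
        sc = SyntheticScenario(network=net, true_rules=rules,
                               n_cells_per_group=n_cells // 2,
                               flip_noise=flip_noise, seed=s + 2)
        _, data = sample_cells(sc)
        asg = assign_cells(data, sc.attractors, nodes=net.nodes)
        truth = data.metadata["true_attractor"].to_numpy()
        correct += int((asg.table["attractor"].to_numpy() == truth).sum())
        total += data.n_cells
    return correct / total


def ers_size_vs_cells(
    n_seeds: int = 10, fractions=(0.01, 0.5, 1.0), seed: int = 0
) -> pd.DataFrame:
    """Mean observed ERS size per training fraction, replicated over seeds."""
    rows = []
    for k in range(n_seeds):
        s = seed * 503 + k
        net = random_network(8, edge_prob=0.35, seed=s)
        rules = random_rules(net, seed=s + 1)
        sc = SyntheticScenario(network=net, true_rules=rules,
                               n_cells_per_group=100, flip_noise=0.05,
                               seed=s + 2)
        _, data = sample_cells(sc)
        res = ers_vs_cells(net, data, fractions=fractions, seed=s + 3)
        for frac in fractions:
            rows.append({"seed": k, "fraction": frac,
                         "mean_ers": res.mean_ers(frac),
                         "mean_ers_k3": res.mean_ers(frac, indegree=3)})
    return pd.DataFrame(rows)
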