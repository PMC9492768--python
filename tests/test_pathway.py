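"""Uncertainty factor, perturbation importance, modulation metric, bootstrap test."""

import numpy as np
import pandas as pd
import pytest

from _helpers import make_binary
from boolpath.inference import GAParams, infer
from boolpath.pathway import (
    ContrastStats,
    analyze_pathways,
    bootstrap_pvalue,
    contrast_stats,
    importance_scores,
    modulation_score,
    uncertainty_factor,
)
from boolpath.rules import BooleanRule, RuleSet, RuleSpace, enumerate_candidates
from boolpath.synth import SyntheticScenario, random_network, random_rules, sample_cells


def _space(max_size: int, observed: int) -> RuleSpace:
    cands = enumerate_candidates("T", [("A", 1), ("B", 1), ("C", 1)])[:max_size]
    if len(cands) < max_size:
        raise AssertionError("fixture needs a larger candidate pool")
    return RuleSpace("T", cands, ers_indices=list(range(observed)))


@pytest.mark.parametrize(
    "max_size,observed,expected",
    [(17, 17, 1 / 17), (17, 1, 1.0), (4, 2, 0.75)],
)
def test_uncertainty_factor_closed_forms(max_size, observed, expected):
    assert uncertainty_factor(_space(max_size, observed)) == pytest.approx(expected)


CHAIN = RuleSet(
    {
        "A": BooleanRule("A", (("A", 1),), (0, 1), "A", 0),
        "B": BooleanRule("B", (("A", 1),), (0, 1), "A", 0),
    }
)


def _chain_spaces():
    return {
        "A": RuleSpace("A", enumerate_candidates("A", []), [0], 0.0),
        "B": RuleSpace("B", enumerate_candidates("B", [("A", 1)]), [0], 0.0),
    }


def test_importance_worked_example():
    """Perturbing the source of a 2-node chain moves both genes; the sink, one."""
    cells = make_binary([[0, 0]], ["A", "B"])
    imp = importance_scores(CHAIN, _chain_spaces(), cells)
    assert imp.raw.tolist() == [2.0, 1.0]
    assert imp.scaled.tolist() == [1.0, 0.5]


def test_importance_scaling_invariant_to_common_uncertainty_factor():
    cells = make_binary([[0, 0], [1, 1], [1, 0]], ["A", "B"])
    imp = importance_scores(CHAIN, _chain_spaces(), cells)
    halved = imp.raw / 2  # common factor on raw scores
    top = halved.max()
    assert np.allclose(halved / top, imp.scaled)


def test_importance_isolated_identity_node_scores_least():
    """A node nothing listens to cannot propagate its perturbation."""
    rules = RuleSet(
        {
            "A": BooleanRule("A", (("A", 1),), (0, 1), "A", 0),
            "B": BooleanRule("B", (("A", 1),), (0, 1), "A", 0),
            "Z": BooleanRule("Z", (("Z", 1),), (0, 1), "Z", 0),
        }
    )
    spaces = {
        "A": RuleSpace("A", enumerate_candidates("A", []), [0], 0.0),
        "B": RuleSpace("B", enumerate_candidates("B", [("A", 1)]), [0], 0.0),
        "Z": RuleSpace("Z", enumerate_candidates("Z", []), [0], 0.0),
    }
    cells = make_binary([[0, 0, 0], [1, 1, 1], [0, 1, 0]], ["A", "B", "Z"])
    imp = importance_scores(rules, spaces, cells)
    scores = dict(zip(imp.nodes, imp.scaled))
    assert scores["Z"] <= scores["A"] and scores["Z"] <= scores["B"]


def test_contrast_stats_identical_groups_zero_ra():
    states = [[1, 0]] * 4
    cont = [[2.0, 1.0]] * 4
    b = make_binary(states, ["A", "B"], groups=["g1", "g1", "g2", "g2"],
                    continuous=cont)
    st = contrast_stats(b)
    assert np.allclose(st.ra, 0)


def test_contrast_stats_substitution():
    cont = [[2.0], [2.0], [1.0], [1.0]]
    b = make_binary([[1]] * 4, ["A"], groups=["g1", "g1", "g2", "g2"],
                    continuous=cont)
    st = contrast_stats(b, pseudocount=0.01)
    assert st.ra[0] == pytest.approx(1.0)
    assert st.log2fc[0] == pytest.approx(np.log2(2.01 / 1.01))
    assert st.sigma[0] == pytest.approx(np.std([2, 2, 1, 1]))


def test_contrast_stats_requires_two_groups():
    b = make_binary([[1]] * 3, ["A"], groups=["g1", "g1", "g1"])
    with pytest.raises(ValueError, match="two groups"):
        contrast_stats(b)


def test_modulation_score_substitution_and_order_invariance():
    st = ContrastStats(
        genes=["A", "B"], ra=np.array([0.5, 0.2]), sigma=np.array([0.2, 1.0]),
        log2fc=np.array([1.0, -1.0]),
    )
    imp = pd.Series({"A": 1.0, "B": 0.5})
    assert modulation_score(st, imp, ["A"]) == pytest.approx(0.1)
    assert modulation_score(st, imp, ["A", "B"]) == pytest.approx(
        modulation_score(st, imp, ["B", "A"])
    )
    # constant gene (sigma 0) contributes nothing
    st.sigma[1] = 0.0
    assert modulation_score(st, imp, ["A", "B"]) == pytest.approx(0.1)


def _two_group_cells(shift, n=40, seed=0):
    rng = np.random.default_rng(seed)
    states = rng.integers(0, 2, size=(n, 3))
    cont = states * (2.0 + rng.lognormal(0, 0.2, size=(n, 3)))
    groups = ["g1"] * (n // 2) + ["g2"] * (n // 2)
    cont[: n // 2, 0] += shift * states[: n // 2, 0]
    return make_binary(states, ["A", "B", "C"], groups=groups, continuous=cont)


def test_bootstrap_seed_determinism():
    b = _two_group_cells(0.0)
    imp = pd.Series({"A": 1.0, "B": 0.5, "C": 0.2})
    r1 = bootstrap_pvalue(b, imp, ["A", "B", "C"], B=200, seed=7)
    r2 = bootstrap_pvalue(b, imp, ["A", "B", "C"], B=200, seed=7)
    assert r1 == r2


def test_bootstrap_detects_large_shift():
    b = _two_group_cells(50.0, n=60, seed=1)
    imp = pd.Series({"A": 1.0, "B": 0.1, "C": 0.1})
    _, p = bootstrap_pvalue(b, imp, ["A", "B", "C"], B=1000, seed=2)
    assert p <= 0.01


def test_bootstrap_ra_resample_scheme_runs():
    b = _two_group_cells(0.0)
    imp = pd.Series({"A": 1.0, "B": 0.5, "C": 0.2})
    m, p = bootstrap_pvalue(b, imp, ["A", "B", "C"], B=200, seed=3,
                            scheme="ra-resample")
    assert 0 < p <= 1


def test_bootstrap_rejects_small_B():
    b = _two_group_cells(0.0)
    imp = pd.Series({"A": 1.0, "B": 0.5, "C": 0.2})
    with pytest.raises(ValueError, match="B"):
        bootstrap_pvalue(b, imp, ["A"], B=50)


def _inferred_scenario(seed, shift=0.0, n_nodes=6):
    net = random_network(n_nodes, edge_prob=0.35, seed=seed)
    rules = random_rules(net, seed=seed + 1)
    sc = SyntheticScenario(
        network=net, true_rules=rules, n_cells_per_group=40,
        flip_noise=0.02,
        mean_shift={g: shift for g in net.nodes} if shift else {},
        seed=seed + 2,
    )
    _, binary = sample_cells(sc)
    res = infer(net, binary, ga_params=GAParams(seed=seed + 3))
    return res, binary


def test_analyze_pathways_bonferroni_direction_and_filter():
    res, binary = _inferred_scenario(5, shift=3.0)
    significant, allres = analyze_pathways([res], binary, B=200, seed=9, alpha=0.05)
    (r,) = allres
    assert r.p_adjusted == pytest.approx(min(1.0, r.p_value * 1))
    assert r.direction in ("up", "down")
    # direction matches the sign of the summed fold changes
    st = contrast_stats(binary)
    fc = sum(st.log2fc[st.genes.index(g)] for g in res.network.nodes)
    assert r.direction == ("up" if fc > 0 else "down")
    for s in significant:
        assert s.optimized and s.p_adjusted < 0.05


def test_analyze_pathways_unoptimized_excluded_even_if_significant():
    res, binary = _inferred_scenario(5, shift=3.0)
    # force every node's ERS to its full candidate space
    for rs in res.rulespaces.values():
        rs.ers_indices = list(range(rs.max_size))
    assert not res.optimized
    with pytest.raises(ValueError, match="no optimized pathway"):
        analyze_pathways([res], binary, B=200, seed=9)


def test_importance_not_pure_topology():
    """Two rule sets on one graph can rank nodes differently."""
    net = random_network(6, edge_prob=0.4, seed=17)
    cells_states = np.random.default_rng(3).integers(0, 2, size=(30, 6))
    cells = make_binary(cells_states, net.nodes)
    spaces = {
        n: RuleSpace(n, enumerate_candidates(n, net.regulators_of(n)),
                     ers_indices=[0])
        for n in net.nodes
    }
    orders = set()
    for seed in range(6):
        rules = random_rules(net, seed=seed)
        imp = importance_scores(rules, spaces, cells)
        orders.add(tuple(np.argsort(-imp.scaled)))
    assert len(orders) > 1
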