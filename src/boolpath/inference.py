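"""Rule determination: global genetic-algorithm search plus node-wise local search.

The inference problem: given a signed network and binarized cell states,
choose one update rule per node from the sign-compatible candidate space so
that the attractors reachable from the observed cell states resemble those
states.  The fit error of a rule set is

    sum over cells c of  min over attractor states a of
        sum over nodes n of |E[c,n] - A[c,n,a]|

where the attractor is reached by synchronous simulation started from the
cell's own binary state.  A genetic algorithm minimizes this global error;
a subsequent local search re-scores, for each node separately (holding all
other rules fixed), every candidate rule by the node-restricted error

    sum over cells c of  min over attractor states a of |E[c,n] - A[c,n,a]|

and returns the argmin set — the *equivalent rule set* (ERS).  An ERS
smaller than the full candidate space means the data constrained the rule;
such nodes (and pathways containing one) are called "optimized".

Cells with identical binary states share trajectories, so errors are
computed over distinct states with multiplicities; attractors are cached
per rule set.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .expression import BinaryExpressionMatrix
from .network import RegulatorAssignment, SignedNetwork, cap_indegree
from .rules import BooleanRule, RuleSet, RuleSpace, enumerate_candidates
from .simulate import CompiledRules, find_attractor

logger = logging.getLogger(__name__)

DEFAULT_MAX_STEPS = 100


@dataclass
class GAParams:
    """Hyperparameters for the global search.

    Conventional small-population settings: 24 individuals, up to 50
    generations with early stop after 10 without improvement, tournament
    selection of size 3, uniform crossover with probability 0.7, per-gene
    mutation probability 0.1, one elite survivor.
    """

    pop_size: int = 24
    n_gen: int = 50
    cx_prob: float = 0.7
    mut_prob: float = 0.1
    tournament_size: int = 3
    n_elite: int = 1
    stagnation_limit: int = 10
    n_restarts: int = 3
    seed: int = 0


@dataclass
class InferenceResult:
    """Everything rule determination produces for one pathway."""

    network: SignedNetwork
    rulespaces: dict[str, RuleSpace]
    ruleset: RuleSet  # local-search incumbent (simplest minimal-error rule per node)
    ga_error: float
    local_error: float
    seed: int
    ga_params: GAParams = field(default_factory=GAParams)

    @property
    def optimized(self) -> bool:
        """A pathway is optimized if any node's ERS shrank below its maximum."""
        return any(rs.optimized for rs in self.rulespaces.values())

    def simplest_ruleset(self) -> RuleSet:
        return RuleSet({n: rs.simplest_rule() for n, rs in self.rulespaces.items()})

    def to_json_dict(self) -> dict:
        return {
            "network": self.network.name,
            "seed": self.seed,
            "ga_error": self.ga_error,
            "local_error": self.local_error,
            "optimized": self.optimized,
            "nodes": {
                n: {
                    "max_size": rs.max_size,
                    "ers_size": rs.ers_size,
                    "ers_indices": list(rs.ers_indices),
                    "min_error": rs.min_error,
                    "optimized": rs.optimized,
                    "regulators": [list(p) for p in rs.candidates[0].regulators],
                    "candidates": [c.expression for c in rs.candidates],
                    "truth_tables": [list(c.truth_table) for c in rs.candidates],
                    "n_and_terms": [c.n_and_terms for c in rs.candidates],
                }
                for n, rs in sorted(self.rulespaces.items())
            },
        }


def inference_result_from_json(doc: dict, network: SignedNetwork) -> InferenceResult:
    """Rebuild an InferenceResult from its serialized form plus the network."""
    rulespaces = {}
    for n, d in doc["nodes"].items():
        regs = tuple((g, int(s)) for g, s in d["regulators"])
        cands = [
            BooleanRule(
                target=n,
                regulators=regs,
                truth_table=tuple(tt),
                expression=expr,
                n_and_terms=na,
            )
            for expr, tt, na in zip(
                d["candidates"], d["truth_tables"], d["n_and_terms"]
            )
        ]
        rulespaces[n] = RuleSpace(
            target=n,
            candidates=cands,
            ers_indices=list(d["ers_indices"]),
            min_error=float(d["min_error"]),
        )
    result = InferenceResult(
        network=network,
        rulespaces=rulespaces,
        ruleset=RuleSet({n: rs.simplest_rule() for n, rs in rulespaces.items()}),
        ga_error=float(doc.get("ga_error", float("nan"))),
        local_error=float(doc.get("local_error", float("nan"))),
        seed=int(doc.get("seed", 0)),
    )
    return result


def distinct_states(
    data: BinaryExpressionMatrix, nodes: Sequence[str]
) -> list[tuple[tuple[int, ...], int]]:
    """Distinct binary cell states over ``nodes``, with multiplicities."""
    arr = data.states_for(nodes)
    counts: dict[tuple[int, ...], int] = {}
    for row in arr:
        key = tuple(int(v) for v in row)
        counts[key] = counts.get(key, 0) + 1
    return sorted(counts.items())


class _ErrorEvaluator:
    """Caches attractors and fitness values across a GA run."""

    def __init__(
        self,
        candidates: dict[str, list[BooleanRule]],
        data: BinaryExpressionMatrix,
        max_steps: int = DEFAULT_MAX_STEPS,
    ):
        self.nodes = tuple(sorted(candidates))
        self.candidates = candidates
        self.states = distinct_states(data, self.nodes)
        self.max_steps = max_steps
        self._fitness_cache: dict[tuple[int, ...], float] = {}

    def ruleset(self, individual: Sequence[int]) -> RuleSet:
        return RuleSet(
            {n: self.candidates[n][i] for n, i in zip(self.nodes, individual)}
        )

    def attractors(self, compiled: CompiledRules):
        cache: dict[tuple[int, ...], np.ndarray] = {}
        for state, _ in self.states:
            if state not in cache:
                att = find_attractor(state, compiled, max_steps=self.max_steps)
                cache[state] = np.asarray(att.states, dtype=np.int8)
        return cache

    def total_error(self, individual: Sequence[int]) -> float:
        key = tuple(individual)
        if key in self._fitness_cache:
            return self._fitness_cache[key]
        compiled = CompiledRules.compile(self.ruleset(individual))
        atts = self.attractors(compiled)
        err = 0.0
        for state, count in self.states:
            cycle = atts[state]
            mism = np.abs(cycle - np.asarray(state, dtype=np.int8)).sum(axis=1)
            err += count * int(mism.min())
        self._fitness_cache[key] = err
        return err

    def node_errors(self, individual: Sequence[int], node_idx: int) -> float:
        """Node-restricted error for the rule currently at ``node_idx``."""
        compiled = CompiledRules.compile(self.ruleset(individual))
        atts = self.attractors(compiled)
        err = 0.0
        for state, count in self.states:
            cycle = atts[state]
            mism = np.abs(cycle[:, node_idx] - state[node_idx])
            err += count * int(mism.min())
        return err


def rule_fit_error(
    rules: RuleSet,
    data: BinaryExpressionMatrix,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> float:
    """Global fit error of a rule set against the observed binary states."""
    nodes = tuple(sorted(rules))
    compiled = CompiledRules.compile(rules)
    cache: dict[tuple[int, ...], np.ndarray] = {}
    err = 0.0
    for state, count in distinct_states(data, nodes):
        if state not in cache:
            att = find_attractor(state, compiled, max_steps=max_steps)
            cache[state] = np.asarray(att.states, dtype=np.int8)
        cycle = cache[state]
        mism = np.abs(cycle - np.asarray(state, dtype=np.int8)).sum(axis=1)
        err += count * int(mism.min())
    return err


def ga_search(
    candidates: dict[str, list[BooleanRule]],
    data: BinaryExpressionMatrix,
    params: GAParams | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> tuple[RuleSet, float, list[float]]:
    """Genetic-algorithm minimization of the global fit error.

    Individuals are vectors of candidate indices (one per node, nodes in
    alphabetical order).  Runs ``params.n_restarts`` independent seeded
    populations (stopping as soon as one reaches zero error) and keeps the
    best.  Returns the best rule set, its error, and that run's
    per-generation best-fitness trace (monotone non-increasing thanks to
    elitism).  Fully reproducible given ``params.seed``.
    """
    params = params or GAParams()
    ev = _ErrorEvaluator(candidates, data, max_steps=max_steps)
    sizes = [len(candidates[n]) for n in ev.nodes]
    space = 1
    for s in sizes:
        space *= s
    if space <= params.pop_size * params.n_gen:
        # the whole rule-set space costs less to enumerate than one GA run:
        # search it exactly instead
        import itertools as _it

        best_ind, best_err = None, None
        for combo in _it.product(*(range(s) for s in sizes)):
            err = ev.total_error(combo)
            if best_err is None or err < best_err:
                best_ind, best_err = combo, err
            if best_err == 0:
                break
        return ev.ruleset(best_ind), best_err, [best_err]
    best = None
    for r in range(max(1, params.n_restarts)):
        ruleset, err, trace = _ga_run(ev, candidates, params,
                                      seed=params.seed + 1000003 * r)
        if best is None or err < best[1]:
            best = (ruleset, err, trace)
        if best[1] == 0:
            break
    return best


def _ga_run(
    ev: "_ErrorEvaluator",
    candidates: dict[str, list[BooleanRule]],
    params: GAParams,
    seed: int,
) -> tuple[RuleSet, float, list[float]]:
    rng = random.Random(seed)
    nodes = ev.nodes
    sizes = [len(candidates[n]) for n in nodes]
    if any(s == 0 for s in sizes):
        raise ValueError("every node needs at least one candidate rule")

    def random_individual() -> list[int]:
        return [rng.randrange(s) for s in sizes]

    pop = [random_individual() for _ in range(params.pop_size)]
    fits = [ev.total_error(ind) for ind in pop]
    best_i = int(np.argmin(fits))
    best, best_fit = list(pop[best_i]), fits[best_i]
    trace = [best_fit]
    stagnant = 0

    for _gen in range(params.n_gen):
        if best_fit == 0 or stagnant >= params.stagnation_limit:
            break
        offspring = [list(best)]  # elite
        while len(offspring) < params.pop_size:
            a = _tournament(pop, fits, params.tournament_size, rng)
            b = _tournament(pop, fits, params.tournament_size, rng)
            child = list(a)
            if rng.random() < params.cx_prob:
                child = [
                    (a[i] if rng.random() < 0.5 else b[i]) for i in range(len(nodes))
                ]
            for i in range(len(nodes)):
                if rng.random() < params.mut_prob:
                    child[i] = rng.randrange(sizes[i])
            offspring.append(child)
        pop = offspring
        fits = [ev.total_error(ind) for ind in pop]
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best, best_fit = list(pop[gen_best]), fits[gen_best]
            stagnant = 0
        else:
            stagnant += 1
        trace.append(best_fit)

    return ev.ruleset(best), best_fit, trace


def _tournament(pop, fits, k: int, rng: random.Random) -> list[int]:
    picks = [rng.randrange(len(pop)) for _ in range(k)]
    return pop[min(picks, key=lambda i: fits[i])]


def local_search(
    node: str,
    incumbent: RuleSet,
    candidates: dict[str, list[BooleanRule]],
    data: BinaryExpressionMatrix,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> RuleSpace:
    """Node-restricted error for every candidate of ``node``, others fixed.

    Returns the node's RuleSpace with the ERS (all candidates achieving the
    minimal error) and the minimum itself.  Candidates are scored in their
    canonical expression-string order, which also fixes ERS ordering.
    """
    nodes = tuple(sorted(incumbent))
    node_idx = nodes.index(node)
    cand = candidates[node]
    states = distinct_states(data, nodes)
    errors = []
    for rule in cand:
        trial = dict(incumbent)
        trial[node] = rule
        compiled = CompiledRules.compile(trial)
        err = 0.0
        cache: dict[tuple[int, ...], np.ndarray] = {}
        for state, count in states:
            if state not in cache:
                att = find_attractor(state, compiled, max_steps=max_steps)
                cache[state] = np.asarray(att.states, dtype=np.int8)
            cycle = cache[state]
            err += count * int(np.abs(cycle[:, node_idx] - state[node_idx]).min())
        errors.append(err)
    min_err = min(errors)
    ers = [i for i, e in enumerate(errors) if e == min_err]
    return RuleSpace(
        target=node, candidates=cand, ers_indices=ers, min_error=float(min_err)
    )


def infer(
    net: SignedNetwork,
    data: BinaryExpressionMatrix,
    ga_params: GAParams | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
    assignments: list[RegulatorAssignment] | None = None,
    max_sweeps: int = 5,
) -> InferenceResult:
    """Full rule determination for one pathway.

    Orchestrates candidate enumeration over the in-degree-capped regulator
    assignments, the GA global search, then the sequential node-wise local
    search (nodes visited in descending out-degree, ties alphabetical,
    updating the incumbent only when its rule fell out of the minimum set,
    and sweeping the node order until the incumbent is stable).
    """
    ga_params = ga_params or GAParams()
    missing = [n for n in net.nodes if n not in data.gene_symbols]
    if missing:
        raise ValueError(f"data lacks network genes: {missing[:5]}")
    if assignments is None:
        assignments = cap_indegree(net, data)
    candidates = {
        a.target: enumerate_candidates(a.target, a.regulators) for a in assignments
    }
    incumbent, ga_error, _trace = ga_search(
        candidates, data, params=ga_params, max_steps=max_steps
    )

    order = sorted(net.nodes, key=lambda n: (-net.graph.out_degree(n), n))
    rulespaces: dict[str, RuleSpace] = {}
    incumbent = RuleSet(dict(incumbent))
    # sweep the nodes repeatedly until no rule changes (a plain coordinate
    # descent); the reported ERS comes from the final, stable context
    for _sweep in range(max_sweeps):
        changed = False
        for node in order:
            rs = local_search(node, incumbent, candidates, data, max_steps=max_steps)
            rulespaces[node] = rs
            # move the incumbent to a minimal-error rule, but keep its
            # current rule when that is already minimal: swapping rules
            # mid-sweep would perturb the context later nodes are scored in
            if incumbent[node].truth_table not in {c.truth_table for c in rs.ers}:
                incumbent[node] = rs.simplest_rule()
                changed = True
        if not changed:
            break

    local_error = rule_fit_error(incumbent, data, max_steps=max_steps)
    logger.info(
        "%s: GA error %.0f, post-local error %.0f, optimized=%s",
        net.name, ga_error, local_error, any(r.optimized for r in rulespaces.values()),
    )
    return InferenceResult(
        network=net,
        rulespaces=rulespaces,
        ruleset=incumbent,
        ga_error=float(ga_error),
        local_error=float(local_error),
        seed=ga_params.seed,
        ga_params=ga_params,
    )
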