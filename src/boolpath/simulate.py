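"""Deterministic synchronous Boolean simulation and attractor detection.

States are tuples of 0/1 over the network's nodes in a fixed alphabetical
order.  Updates are synchronous: every node reads the previous global state.
Because the update is deterministic on a finite state space, every
trajectory enters a cycle; cycle detection is by hashing visited states, so
true limit cycles are found exactly rather than approximated by a fixed
step budget (the default budget of 100 steps is retained as a guard).

Knock-in / knock-out perturbations clamp a node to 1 / 0: the clamp is
applied to the start state and re-applied after every update.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .rules import BooleanRule, RuleSet

State = tuple[int, ...]

DEFAULT_MAX_STEPS = 100


@dataclass(frozen=True)
class CompiledRules:
    """Rule set lowered to index arrays for fast stepping."""

    nodes: tuple[str, ...]
    reg_indices: tuple[tuple[int, ...], ...]
    truth_tables: tuple[tuple[int, ...], ...]

    @classmethod
    def compile(cls, rules: RuleSet | Mapping[str, BooleanRule]) -> "CompiledRules":
        nodes = tuple(sorted(rules))
        pos = {n: i for i, n in enumerate(nodes)}
        regs, tables = [], []
        for n in nodes:
            rule = rules[n]
            try:
                regs.append(tuple(pos[g] for g in rule.regulator_genes))
            except KeyError as exc:
                raise ValueError(
                    f"rule for {n} references {exc.args[0]}, absent from the rule set"
                ) from None
            tables.append(rule.truth_table)
        return cls(nodes=nodes, reg_indices=tuple(regs), truth_tables=tuple(tables))

    @property
    def n(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class Attractor:
    """A fixed point (cycle length 1) or limit cycle of the synchronous map.

    ``states`` is the cycle in temporal order starting from its
    rotation-minimal state, so equal cycles compare equal; ``key`` is a
    printable canonical encoding.  ``mean_state`` averages each node over
    the cycle and is the vector compared between knock-in and knock-out
    runs.  ``converged`` is False only if the step budget was exhausted
    before a revisit (possible only with a budget smaller than the
    trajectory's transient).
    """

    states: tuple[State, ...]
    converged: bool = True

    @property
    def key(self) -> str:
        return "|".join("".join(map(str, s)) for s in self.states)

    @property
    def length(self) -> int:
        return len(self.states)

    @property
    def mean_state(self) -> np.ndarray:
        return np.mean(self.states, axis=0)

    @staticmethod
    def canonical(cycle: Sequence[State], converged: bool = True) -> "Attractor":
        """Rotate the cycle so it starts at its lexicographically least state."""
        start = min(range(len(cycle)), key=lambda i: cycle[i])
        rotated = tuple(cycle[start:]) + tuple(cycle[:start])
        return Attractor(states=rotated, converged=converged)


def step(
    state: Sequence[int],
    rules: RuleSet | CompiledRules,
    clamps: Mapping[str, int] | None = None,
) -> State:
    """One synchronous update; clamped nodes are forced after the update."""
    compiled = rules if isinstance(rules, CompiledRules) else CompiledRules.compile(rules)
    if len(state) != compiled.n:
        raise ValueError(f"state length {len(state)} != node count {compiled.n}")
    nxt = _step_compiled(tuple(state), compiled, _clamp_items(compiled, clamps))
    return nxt


def _clamp_items(
    compiled: CompiledRules, clamps: Mapping[str, int] | None
) -> tuple[tuple[int, int], ...]:
    if not clamps:
        return ()
    pos = {n: i for i, n in enumerate(compiled.nodes)}
    return tuple((pos[g], int(v)) for g, v in sorted(clamps.items()))


def _step_compiled(
    state: State, compiled: CompiledRules, clamp_items: tuple[tuple[int, int], ...]
) -> State:
    nxt = []
    for regs, table in zip(compiled.reg_indices, compiled.truth_tables):
        idx = 0
        for r in regs:
            idx = (idx << 1) | state[r]
        nxt.append(table[idx])
    for i, v in clamp_items:
        nxt[i] = v
    return tuple(nxt)


def _apply_clamps(state: State, clamp_items: tuple[tuple[int, int], ...]) -> State:
    if not clamp_items:
        return state
    s = list(state)
    for i, v in clamp_items:
        s[i] = v
    return tuple(s)


def find_attractor(
    start: Sequence[int],
    rules: RuleSet | CompiledRules,
    clamps: Mapping[str, int] | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> Attractor:
    """Iterate from ``start`` until a state repeats; return the canonical cycle.

    With clamps, the clamp is applied to the start state as well, so the
    whole trajectory satisfies it.
    """
    compiled = rules if isinstance(rules, CompiledRules) else CompiledRules.compile(rules)
    clamp_items = _clamp_items(compiled, clamps)
    state = _apply_clamps(tuple(int(v) for v in start), clamp_items)
    seen: dict[State, int] = {state: 0}
    trajectory = [state]
    for t in range(1, max_steps + 1):
        state = _step_compiled(state, compiled, clamp_items)
        if state in seen:
            return Attractor.canonical(trajectory[seen[state] :])
        seen[state] = t
        trajectory.append(state)
    # unreachable with max_steps >= transient length; kept as a guard
    return Attractor(states=(state,), converged=False)


def enumerate_all_attractors(
    rules: RuleSet | CompiledRules, max_nodes: int = 20
) -> list[tuple[Attractor, int]]:
    """Exhaustive attractor set with basin sizes, for networks of <= 20 nodes.

    Sweeps all 2^n start states; intended as a brute-force oracle and for
    synthetic-scenario construction, not for large pathways.
    """
    compiled = rules if isinstance(rules, CompiledRules) else CompiledRules.compile(rules)
    n = compiled.n
    if n > max_nodes:
        raise ValueError(f"{n} nodes exceeds the {max_nodes}-node exhaustive limit")
    basins: dict[str, int] = {}
    attractors: dict[str, Attractor] = {}
    for code in range(2**n):
        start = tuple((code >> (n - 1 - j)) & 1 for j in range(n))
        att = find_attractor(start, compiled, max_steps=2**n + 1)
        basins[att.key] = basins.get(att.key, 0) + 1
        attractors.setdefault(att.key, att)
    return [(attractors[k], basins[k]) for k in sorted(attractors)]


def perturbation_attractors(
    cell_state: Sequence[int],
    rules: RuleSet | CompiledRules,
    node: str,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> tuple[Attractor, Attractor]:
    """(knock-in, knock-out) attractors from a cell state with ``node`` clamped.

    Knock-in clamps the node to 1, knock-out to 0; each run starts from the
    cell's observed binary state with the clamp already applied.
    """
    compiled = rules if isinstance(rules, CompiledRules) else CompiledRules.compile(rules)
    if node not in compiled.nodes:
        raise KeyError(f"{node} not in network")
    ki = find_attractor(cell_state, compiled, clamps={node: 1}, max_steps=max_steps)
    ko = find_attractor(cell_state, compiled, clamps={node: 0}, max_steps=max_steps)
    return ki, ko


def attractor_profile_table(attractors: Iterable[Attractor], nodes: Sequence[str]):
    """Node x attractor mean-activity table (rows: genes, columns: keys)."""
    import pandas as pd

    data = {a.key: a.mean_state for a in attractors}
    return pd.DataFrame(data, index=list(nodes))
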