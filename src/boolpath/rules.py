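"""Boolean update rules and the sign-compatible candidate rule space.

Each network node carries one Boolean update function over its (at most
three) signed regulators.  The candidate space for a node is the set of
distinct truth tables realizable by *read-once* AND/OR expressions over any
non-empty subset of the regulators, with each regulator's edge sign folded
into its literal (an inhibitor enters as ``not X``).  Read-once means each
regulator appears at most once in the expression; every such function is
unate (monotone per input after sign folding) and non-constant.

For in-degrees 1, 2 and 3 this grammar yields 1, 4 and 17 candidates
respectively; the three-input majority function is *not* read-once and is
deliberately outside the space.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence


@dataclass(frozen=True)
class BooleanRule:
    """A node's update function as a truth table over ordered signed regulators.

    ``truth_table[i]`` is the output for the regulator configuration whose
    bits are read most-significant-first in regulator order: with regulators
    ``(A, B)``, index 2 = ``A=1, B=0``.  ``expression`` is a canonical
    human-readable AND/OR form with signs folded in (e.g. ``"A and not B"``).
    """

    target: str
    regulators: tuple[tuple[str, int], ...]  # ((gene, sign), ...), sign in {+1, -1}
    truth_table: tuple[int, ...]
    expression: str
    n_and_terms: int = 0

    def __post_init__(self) -> None:
        k = len(self.regulators)
        if len(self.truth_table) != 2**k:
            raise ValueError(
                f"truth table for {self.target} has {len(self.truth_table)} "
                f"entries, expected {2 ** k}"
            )
        if any(v not in (0, 1) for v in self.truth_table):
            raise ValueError("truth table entries must be 0/1")

    @property
    def k(self) -> int:
        return len(self.regulators)

    @property
    def regulator_genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.regulators)

    @property
    def n_literals(self) -> int:
        return sum(1 for g in self.regulator_genes if _appears(self.expression, g))

    @property
    def is_identity(self) -> bool:
        """True for the hold-state rule given to in-degree-0 nodes."""
        return (
            self.k == 1
            and self.regulators[0][0] == self.target
            and self.truth_table == (0, 1)
        )

    def evaluate(self, inputs: Sequence[int]) -> int:
        """Output for raw (unfolded) regulator states, regulator order."""
        idx = 0
        for bit in inputs:
            idx = (idx << 1) | (1 if bit else 0)
        return self.truth_table[idx]

    def simplicity_key(self) -> tuple[int, int, str]:
        """Sort key for 'simplest rule': fewest ANDs, then literals, then text."""
        return (self.n_and_terms, self.n_literals, self.expression)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.target} = {self.expression}"


def _appears(expression: str, gene: str) -> bool:
    return gene in expression.replace("(", " ").replace(")", " ").split()


def _literal(gene: str, sign: int) -> str:
    return gene if sign > 0 else f"not {gene}"


def _read_once_forms(
    literals: tuple[tuple[str, int], ...],
) -> Iterator[tuple[str, int]]:
    """Yield (expression, n_and_terms) for read-once AND/OR forms.

    Recursively splits the literal multiset into a first literal plus a
    sub-expression; duplicates are removed downstream by truth table.
    """
    if len(literals) == 1:
        g, s = literals[0]
        yield _literal(g, s), 0
        return
    # split off each literal in turn, combine with each op
    for i in range(len(literals)):
        g, s = literals[i]
        rest = literals[:i] + literals[i + 1 :]
        for sub, sub_ands in _read_once_forms(rest):
            sub_wrapped = f"({sub})" if len(rest) > 1 else sub
            yield f"{_literal(g, s)} and {sub_wrapped}", sub_ands + 1
            yield f"{_literal(g, s)} or {sub_wrapped}", sub_ands
    # flat all-AND / all-OR are covered by the recursion above but in nested
    # form; emit flat canonical variants so the canonical strings read well
    lits = [_literal(g, s) for g, s in literals]
    yield " and ".join(lits), len(lits) - 1
    yield " or ".join(lits), 0


def _truth_table_of(
    expression: str, regulators: tuple[tuple[str, int], ...]
) -> tuple[int, ...]:
    k = len(regulators)
    genes = [g for g, _ in regulators]
    table = []
    for idx in range(2**k):
        env = {
            genes[j]: bool((idx >> (k - 1 - j)) & 1) for j in range(k)
        }
        table.append(int(eval(expression, {"__builtins__": {}}, env)))  # noqa: S307
    return tuple(table)


def enumerate_candidates(
    target: str, regulators: Sequence[tuple[str, int]]
) -> list[BooleanRule]:
    """All distinct candidate rules for a node with the given signed regulators.

    Regulators must already be in canonical (alphabetical) order and number
    at most three.  A node with no regulators receives the single identity
    rule: it holds its own state, acting as a boundary condition.

    Returns rules sorted by canonical expression string; the list length is
    the node's maximum equivalent-rule-set size.
    """
    return list(_enumerate_cached(target, tuple(regulators)))


@functools.lru_cache(maxsize=4096)
def _enumerate_cached(
    target: str, regulators: tuple[tuple[str, int], ...]
) -> tuple[BooleanRule, ...]:
    if len(regulators) > 3:
        raise ValueError(
            f"{target}: {len(regulators)} regulators exceed the in-degree cap "
            "of 3; apply the cap before enumeration"
        )
    if len(set(g for g, _ in regulators)) != len(regulators):
        raise ValueError(f"{target}: duplicate regulator genes")
    if not regulators:
        return (
            BooleanRule(
                target=target,
                regulators=((target, 1),),
                truth_table=(0, 1),
                expression=target,
                n_and_terms=0,
            ),
        )

    seen: dict[tuple[int, ...], tuple[str, int]] = {}
    for r in range(1, len(regulators) + 1):
        for subset in itertools.combinations(regulators, r):
            for expr, n_ands in _read_once_forms(subset):
                tt = _truth_table_of(expr, regulators)
                if tt not in seen or (len(expr), expr) < (
                    len(seen[tt][0]),
                    seen[tt][0],
                ):
                    seen[tt] = (expr, n_ands)
    rules = [
        BooleanRule(
            target=target,
            regulators=regulators,
            truth_table=tt,
            expression=expr,
            n_and_terms=n_ands,
        )
        for tt, (expr, n_ands) in seen.items()
    ]
    rules.sort(key=lambda rule: rule.expression)
    return tuple(rules)


@dataclass
class RuleSpace:
    """Candidate rules for one node plus its equivalent rule set (ERS).

    ``candidates`` is the full sign-compatible space (``max_size`` entries);
    ``ers_indices`` points at the candidates achieving the minimal
    node-local fit error; ``optimized`` records whether the data narrowed
    the space at all.
    """

    target: str
    candidates: list[BooleanRule]
    ers_indices: list[int] = field(default_factory=list)
    min_error: float = float("nan")

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError(f"{self.target}: empty candidate space")

    @property
    def max_size(self) -> int:
        return len(self.candidates)

    @property
    def ers(self) -> list[BooleanRule]:
        return [self.candidates[i] for i in self.ers_indices]

    @property
    def ers_size(self) -> int:
        return len(self.ers_indices)

    @property
    def optimized(self) -> bool:
        return 0 < self.ers_size < self.max_size

    def simplest_rule(self) -> BooleanRule:
        """The ERS member with fewest AND terms (ties: fewer literals, text)."""
        pool = self.ers if self.ers_indices else self.candidates
        return min(pool, key=BooleanRule.simplicity_key)


class RuleSet(dict):
    """Mapping node -> BooleanRule covering every node of a network."""

    def __init__(self, rules: dict[str, BooleanRule] | Sequence[BooleanRule]):
        if not isinstance(rules, dict):
            rules = {r.target: r for r in rules}
        super().__init__(rules)

    @property
    def nodes(self) -> list[str]:
        return sorted(self)

    def to_text(self) -> str:
        return "\n".join(f"{n} = {self[n].expression}" for n in self.nodes)
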