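"""Steady-state analysis: attractor harvesting, cell assignment, association tests.

Observed cells are hypothesized to lie near attractors of the underlying
signaling network.  Rule-inference uncertainty is propagated by sampling
rule sets from each node's equivalent rule set; simulations started from
every observed cell state then harvest the reachable attractors.  Each cell
is assigned to the attractor closest in Hamming distance (minimum over the
attractor's cycle states, restricted to network genes), and contingency
tests ask whether attractor occupancy depends on subject or contrast group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .expression import BinaryExpressionMatrix
from .rules import RuleSet, RuleSpace
from .simulate import Attractor, CompiledRules, find_attractor

logger = logging.getLogger(__name__)


def sample_rulesets(
    rulespaces: dict[str, RuleSpace], n: int = 10, seed: int = 0
) -> list[RuleSet]:
    """Draw ``n`` rule sets, each node's rule uniform over its ERS.

    Draws are independent per node and per rule set; duplicates are
    expected (and harmless) when equivalent rule sets are small.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(rulespaces)
    out = []
    for _ in range(n):
        rules = {}
        for node in nodes:
            rs = rulespaces[node]
            ers = rs.ers if rs.ers_indices else rs.candidates
            rules[node] = ers[int(rng.integers(len(ers)))]
        out.append(RuleSet(rules))
    return out


def harvest_attractors(
    rulesets: list[RuleSet],
    cells: BinaryExpressionMatrix,
    max_steps: int = 100,
) -> tuple[list[Attractor], dict[str, list[int]]]:
    """Attractors reached from every observed cell state under each rule set.

    Returns the deduplicated attractors (by canonical key) and a provenance
    map: attractor key -> indices of the rule sets that produced it.
    """
    if not rulesets:
        raise ValueError("no rule sets supplied")
    nodes = sorted(rulesets[0])
    from .inference import distinct_states

    states = distinct_states(cells, nodes)
    seen: dict[str, Attractor] = {}
    provenance: dict[str, list[int]] = {}
    for k, ruleset in enumerate(rulesets):
        compiled = CompiledRules.compile(ruleset)
        local: dict[tuple[int, ...], Attractor] = {}
        for state, _ in states:
            if state not in local:
                local[state] = find_attractor(state, compiled, max_steps=max_steps)
        for att in local.values():
            if att.key not in seen:
                seen[att.key] = att
                provenance[att.key] = []
            if k not in provenance[att.key]:
                provenance[att.key].append(k)
    attractors = [seen[k] for k in sorted(seen)]
    logger.info("harvested %d distinct attractors", len(attractors))
    return attractors, provenance


@dataclass
class AttractorAssignment:
    """Per-cell nearest attractor plus per-attractor occupancy summaries."""

    table: pd.DataFrame        # cell, attractor, distance, subject, group
    attractors: list[Attractor]
    nodes: list[str]
    counts: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.counts = self.table["attractor"].value_counts()

    @property
    def fractions(self) -> pd.Series:
        return self.counts / self.counts.sum()

    def profile_table(self) -> pd.DataFrame:
        """Gene x attractor mean activity (fractional for limit cycles)."""
        return pd.DataFrame(
            {a.key: a.mean_state for a in self.attractors}, index=self.nodes
        )


def assign_cells(
    cells: BinaryExpressionMatrix,
    attractors: list[Attractor],
    nodes: list[str] | None = None,
) -> AttractorAssignment:
    """Assign each cell to the nearest attractor by Hamming distance.

    Distance to an attractor is the minimum over its cycle states of the
    per-node mismatch count, restricted to network genes; ties go to the
    attractor with the smallest canonical key, so assignment does not
    depend on list order.
    """
    if not attractors:
        raise ValueError("no attractors to assign to")
    attractors = sorted(attractors, key=lambda a: a.key)
    nodes = nodes or sorted(cells.gene_symbols)
    cell_states = cells.states_for(nodes)
    # stack all cycle states with a map back to their attractor
    all_states, owner = [], []
    for i, att in enumerate(attractors):
        for s in att.states:
            all_states.append(s)
            owner.append(i)
    mat = np.asarray(all_states, dtype=np.int16)   # (n_states, n_nodes)
    owner = np.asarray(owner)

    rows = []
    meta = cells.metadata
    for ci in range(cells.n_cells):
        d = np.abs(mat - cell_states[ci]).sum(axis=1)
        # min distance per attractor, then smallest key (already sorted) wins
        best_idx = int(owner[int(np.argmin(d))])
        # argmin returns the first minimum; owners are ordered by key
        best_d = int(d.min())
        rows.append(
            {
                "cell": cells.cell_ids[ci],
                "attractor": attractors[best_idx].key,
                "distance": best_d,
                "subject": str(meta["subject"].iloc[ci]) if "subject" in meta else "",
                "group": str(meta["group"].iloc[ci]) if "group" in meta else "",
            }
        )
    return AttractorAssignment(
        table=pd.DataFrame(rows), attractors=attractors, nodes=list(nodes)
    )


def pool_rare(assignment_col: pd.Series, min_count: int = 5) -> pd.Series:
    """Relabel attractors carrying fewer than ``min_count`` cells as 'other'."""
    counts = assignment_col.value_counts()
    rare = set(counts[counts < min_count].index)
    return assignment_col.map(lambda a: "other" if a in rare else a)


@dataclass
class AssociationTest:
    variable: str
    chi2: float
    dof: int
    p_value: float
    table: pd.DataFrame
    note: str = ""


def association_tests(
    assignment: AttractorAssignment, min_count: int = 5
) -> list[AssociationTest]:
    """Pearson chi-square tests of attractor occupancy vs subject and group.

    Attractors with fewer than ``min_count`` assigned cells are pooled into
    an 'other' category first.  Degenerate tables (a single attractor or a
    single level of the covariate) are reported with a note instead of a
    statistic.  No continuity correction is applied.
    """
    df = assignment.table.copy()
    df["attractor"] = pool_rare(df["attractor"], min_count=min_count)
    out = []
    for var in ("subject", "group"):
        if var not in df.columns or df[var].nunique() < 2:
            out.append(
                AssociationTest(var, np.nan, 0, np.nan, pd.DataFrame(),
                                note=f"fewer than two {var} levels")
            )
            continue
        table = pd.crosstab(df["attractor"], df[var])
        if table.shape[0] < 2:
            out.append(
                AssociationTest(var, np.nan, 0, np.nan, table,
                                note="single attractor; test skipped")
            )
            continue
        chi2, p, dof, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
        out.append(AssociationTest(var, float(chi2), int(dof), float(p), table))
    return out
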