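"""Signed prior-knowledge networks: KGML / GraphML ingest, pruning, in-degree cap.

A prior-knowledge network (PKN) is a directed gene graph in which each edge
carries a sign: +1 for activation, -1 for inhibition.  PKNs typically come
from pathway databases (KEGG KGML files) or user-supplied GraphML.  Gene
symbols are uppercased on ingest and duplicate edges merged; if duplicates
disagree on sign, inhibition wins (conservative) and a warning is logged.

Rule inference considers at most three regulators per node.  Nodes with a
larger in-degree keep the three parents whose binarized expression has the
largest absolute Spearman correlation with the target's, a deterministic,
data-driven selection with alphabetical tie-breaking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import networkx as nx
import numpy as np
from lxml import etree
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .expression import BinaryExpressionMatrix

logger = logging.getLogger(__name__)

#: KGML relation subtypes with defined sign semantics
_KGML_ACTIVATING = {"activation", "expression"}
_KGML_INHIBITING = {"inhibition", "repression"}

#: accepted encodings of an edge sign in GraphML attributes
_SIGN_VALUES = {
    "a": 1, "activation": 1, "+": 1, "1": 1, "+1": 1,
    "i": -1, "inhibition": -1, "-": -1, "−": -1, "-1": -1,
}


class PathwaySkipped(Exception):
    """Raised when a pathway retains too few data-covered nodes to analyze."""


@dataclass(frozen=True)
class RegulatorAssignment:
    """A node's retained signed regulators, in canonical alphabetical order."""

    target: str
    regulators: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if len(self.regulators) > 3:
            raise ValueError(f"{self.target}: more than 3 regulators")
        genes = [g for g, _ in self.regulators]
        if genes != sorted(genes) or len(set(genes)) != len(genes):
            raise ValueError(f"{self.target}: regulators must be distinct and sorted")


@dataclass
class SignedNetwork:
    """Directed gene graph with activation (+1) / inhibition (-1) edge signs."""

    name: str
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @classmethod
    def from_edges(
        cls, name: str, edges: Iterable[tuple[str, str, int]],
        nodes: Iterable[str] = (),
    ) -> "SignedNetwork":
        net = cls(name=name)
        for n in nodes:
            net.graph.add_node(n.upper())
        for u, v, s in edges:
            net.add_edge(u, v, s)
        return net

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, int]]:
        return sorted(
            (u, v, d["sign"]) for u, v, d in self.graph.edges(data=True)
        )

    def add_edge(self, source: str, target: str, sign: int) -> None:
        """Add or merge an edge; conflicting duplicate signs resolve to -1."""
        if sign not in (1, -1):
            raise ValueError(f"sign must be +1/-1, got {sign!r}")
        u, v = source.upper(), target.upper()
        if self.graph.has_edge(u, v):
            old = self.graph[u][v]["sign"]
            if old != sign:
                logger.warning(
                    "%s: conflicting signs on %s->%s; keeping inhibition",
                    self.name, u, v,
                )
                self.graph[u][v]["sign"] = -1
            return
        self.graph.add_edge(u, v, sign=sign)

    def regulators_of(self, node: str) -> list[tuple[str, int]]:
        return sorted(
            (u, self.graph[u][node]["sign"]) for u in self.graph.predecessors(node)
        )

    def renamed(self, prefix: str) -> "SignedNetwork":
        """Copy with nodes renamed ``<prefix>01..``, preserving edges and signs."""
        mapping = {n: f"{prefix}{i:02d}" for i, n in enumerate(self.nodes, start=1)}
        return SignedNetwork.from_edges(
            f"{self.name}-{prefix}",
            [(mapping[u], mapping[v], s) for u, v, s in self.edges],
            nodes=mapping.values(),
        )

    # ---------------------------------------------------------------- I/O

    def to_graphml(self, path, sign_key: str = "signal") -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for u, v, s in self.edges:
            g.add_edge(u, v, **{sign_key: "a" if s > 0 else "i"})
        nx.write_graphml(g, path)

    def to_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\tsign\n")
            for u, v, s in self.edges:
                fh.write(f"{u}\t{v}\t{s:+d}\n")


def parse_kgml(source, name: str | None = None, strict: bool = False) -> SignedNetwork:
    """Parse a KEGG KGML document into a SignedNetwork.

    Gene entries (possibly listing several gene symbols) are expanded to
    their member symbols, each member inheriting every relation of its
    entry; group entries expand to their components likewise.  Relation
    subtypes map activation/expression -> +1 and inhibition/repression ->
    -1.  Subtypes without sign semantics (binding/association, indirect
    effect, ...) default to +1 with a warning, or are dropped when
    ``strict`` is set.

    ``source`` may be a path, file object, or XML string/bytes.
    """
    try:
        if isinstance(source, (str, bytes)) and (
            isinstance(source, bytes) or source.lstrip().startswith("<")
        ):
            root = etree.fromstring(
                source.encode() if isinstance(source, str) else source
            )
        else:
            root = etree.parse(source).getroot()
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed KGML: {exc}") from exc

    net = SignedNetwork(name=name or root.get("title") or root.get("name") or "pathway")

    # entry id -> list of gene symbols; KGML graphics names are comma lists
    # like "AKT1, PKB..."; use the first token of each comma-separated item
    entry_genes: dict[str, list[str]] = {}
    groups: dict[str, list[str]] = {}
    for entry in root.findall("entry"):
        eid = entry.get("id")
        etype = entry.get("type")
        if etype == "group":
            groups[eid] = [
                c.get("id") for c in entry.findall("component") if c.get("id")
            ]
            continue
        if etype not in ("gene", "compound", "ortholog"):
            continue
        graphics = entry.find("graphics")
        label = graphics.get("name") if graphics is not None else None
        if not label:
            label = entry.get("name", "")
        symbols = [
            item.strip().rstrip(".").split(" ")[0].upper()
            for item in label.split(",")
            if item.strip()
        ]
        if symbols:
            entry_genes[eid] = sorted(set(symbols))
            for s in entry_genes[eid]:
                net.graph.add_node(s)

    def members(eid: str) -> list[str]:
        if eid in groups:
            out: list[str] = []
            for cid in groups[eid]:
                out.extend(members(cid))
            return out
        return entry_genes.get(eid, [])

    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        sources, targets = members(e1), members(e2)
        if not sources or not targets:
            logger.warning(
                "%s: relation %s->%s references unknown entry; skipped",
                net.name, e1, e2,
            )
            continue
        subtypes = [st.get("name") for st in rel.findall("subtype")]
        sign = _kgml_sign(subtypes, net.name, strict)
        if sign is None:
            continue
        for u in sources:
            for v in targets:
                if u != v:
                    net.add_edge(u, v, sign)
    return net


def _kgml_sign(subtypes: Sequence[str], name: str, strict: bool) -> int | None:
    if any(s in _KGML_INHIBITING for s in subtypes):
        return -1
    if any(s in _KGML_ACTIVATING for s in subtypes):
        return 1
    if strict:
        logger.warning("%s: unsigned relation subtypes %s dropped (strict)", name, subtypes)
        return None
    logger.warning(
        "%s: relation subtypes %s have no sign semantics; defaulting to activation",
        name, subtypes,
    )
    return 1


def parse_graphml(
    source,
    name: str | None = None,
    sign_key: str = "signal",
    strict: bool = False,
) -> SignedNetwork:
    """Parse a GraphML network with a per-edge sign attribute.

    Accepted sign encodings: "a"/"i", "activation"/"inhibition", "+"/"-",
    1/-1.  A missing or unrecognized sign raises under ``strict`` and
    defaults to activation (with a warning) otherwise.  Undirected graphs
    are rejected under ``strict`` and treated as directed otherwise.
    """
    g = nx.read_graphml(source)
    if not g.is_directed():
        if strict:
            raise ValueError("GraphML graph is undirected; directed edges required")
        logger.warning("undirected GraphML; interpreting edges as directed")
        g = g.to_directed()
    net = SignedNetwork(name=name or getattr(g, "name", "") or "network")
    label = {n: str(d.get("name", n)) for n, d in g.nodes(data=True)}
    for n in g.nodes:
        net.graph.add_node(label[n].upper())
    for u, v, d in g.edges(data=True):
        raw = d.get(sign_key)
        if raw is None:
            if strict:
                raise ValueError(
                    f"edge {label[u]}->{label[v]} lacks sign attribute {sign_key!r}"
                )
            logger.warning(
                "edge %s->%s lacks sign attribute %r; defaulting to activation",
                label[u], label[v], sign_key,
            )
            sign = 1
        else:
            key = str(raw).strip().lower()
            if key not in _SIGN_VALUES:
                if strict:
                    raise ValueError(f"unrecognized sign value {raw!r}")
                logger.warning("unrecognized sign value %r; defaulting to activation", raw)
                sign = 1
            else:
                sign = _SIGN_VALUES[key]
        net.add_edge(label[u], label[v], sign)
    return net


def prune_to_dataset(
    net: SignedNetwork, genes: Iterable[str], min_nodes: int = 15
) -> SignedNetwork:
    """Restrict the network to genes measured in the dataset.

    Raises :class:`PathwaySkipped` when fewer than ``min_nodes`` nodes
    survive, signalling that the pathway should be excluded from analysis.
    """
    keep = {g.upper() for g in genes}
    if not keep:
        raise ValueError("empty gene set")
    surviving = [n for n in net.nodes if n in keep]
    if len(surviving) < min_nodes:
        raise PathwaySkipped(
            f"{net.name}: {len(surviving)} nodes covered by data "
            f"(< min_nodes={min_nodes})"
        )
    sub = SignedNetwork(name=net.name, graph=net.graph.subgraph(surviving).copy())
    return sub


def cap_indegree(
    net: SignedNetwork,
    binary_data: "BinaryExpressionMatrix | None" = None,
    k_max: int = 3,
) -> list[RegulatorAssignment]:
    """Retain at most ``k_max`` regulators per node.

    Over-connected nodes keep the parents with the largest |Spearman
    correlation| between parent and target binarized expression columns;
    zero-variance columns count as correlation 0 and ties break
    alphabetically, so the result is deterministic.  ``binary_data`` may be
    omitted if no node exceeds the cap.
    """
    assignments = []
    for node in net.nodes:
        regs = net.regulators_of(node)
        if len(regs) > k_max:
            if binary_data is None:
                raise ValueError(
                    f"{node} has in-degree {len(regs)} > {k_max}; binary data "
                    "needed for correlation-based selection"
                )
            y = binary_data.column(node)
            scored = []
            for gene, sign in regs:
                x = binary_data.column(gene)
                if x.std() == 0 or y.std() == 0:
                    rho = 0.0
                else:
                    rho = abs(stats.spearmanr(x, y).statistic)
                    if np.isnan(rho):
                        rho = 0.0
                scored.append((-rho, gene, sign))
            scored.sort()
            regs = sorted((g, s) for _, g, s in scored[:k_max])
        assignments.append(RegulatorAssignment(target=node, regulators=tuple(regs)))
    return assignments
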