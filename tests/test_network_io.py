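"""Prior-knowledge network ingest: KGML, GraphML, pruning, in-degree cap."""

import numpy as np
import pytest

from boolpath.network import (
    PathwaySkipped,
    SignedNetwork,
    cap_indegree,
    parse_graphml,
    parse_kgml,
    prune_to_dataset,
)
from boolpath.synth import random_network
from _helpers import make_binary

SIMPLE_KGML = """<?xml version="1.0"?>
<pathway name="path:min" title="minimal">
  <entry id="1" type="gene"><graphics name="A"/></entry>
  <entry id="2" type="gene"><graphics name="B"/></entry>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="{subtype}"/>
  </relation>
</pathway>
"""


@pytest.mark.parametrize(
    "subtype,sign", [("activation", 1), ("expression", 1), ("inhibition", -1), ("repression", -1)]
)
def test_kgml_relation_signs(subtype, sign):
    net = parse_kgml(SIMPLE_KGML.format(subtype=subtype))
    assert net.nodes == ["A", "B"]
    assert net.edges == [("A", "B", sign)]


def test_kgml_multi_gene_entry_expansion(toy_kgml):
    net = parse_kgml(toy_kgml)
    assert net.nodes == ["A1", "A2", "B", "C"]
    assert ("A1", "B", 1) in net.edges
    assert ("A2", "B", 1) in net.edges
    assert ("C", "B", -1) in net.edges


def test_kgml_unsigned_subtype_defaults_to_activation():
    net = parse_kgml(SIMPLE_KGML.format(subtype="binding/association"))
    assert net.edges == [("A", "B", 1)]
    strict = parse_kgml(SIMPLE_KGML.format(subtype="binding/association"), strict=True)
    assert strict.edges == []


def test_kgml_malformed_raises():
    with pytest.raises(ValueError, match="malformed KGML"):
        parse_kgml("<pathway><unclosed></pathway>")


def test_kgml_unknown_entry_relation_skipped():
    doc = SIMPLE_KGML.format(subtype="activation").replace(
        'entry1="1"', 'entry1="99"'
    )
    net = parse_kgml(doc)
    assert net.edges == []


def test_graphml_roundtrip(tmp_path):
    net = SignedNetwork.from_edges(
        "rt", [("A", "B", 1), ("B", "C", -1), ("C", "A", 1)]
    )
    p = tmp_path / "net.graphml"
    net.to_graphml(p)
    back = parse_graphml(str(p), name="rt")
    assert back.nodes == net.nodes
    assert back.edges == net.edges


def test_graphml_sign_encodings(tmp_path):
    import networkx as nx

    g = nx.DiGraph()
    g.add_edge("A", "B", signal="i")
    p = tmp_path / "g.graphml"
    nx.write_graphml(g, p)
    net = parse_graphml(str(p))
    assert net.edges == [("A", "B", -1)]


def test_graphml_missing_sign_strict_vs_permissive(tmp_path):
    import networkx as nx

    g = nx.DiGraph()
    g.add_edge("A", "B")
    p = tmp_path / "g.graphml"
    nx.write_graphml(g, p)
    assert parse_graphml(str(p)).edges == [("A", "B", 1)]
    with pytest.raises(ValueError, match="sign attribute"):
        parse_graphml(str(p), strict=True)


def test_graphml_undirected_strict_rejected(tmp_path):
    import networkx as nx

    g = nx.Graph()
    g.add_edge("A", "B", signal="a")
    p = tmp_path / "u.graphml"
    nx.write_graphml(g, p)
    with pytest.raises(ValueError, match="undirected"):
        parse_graphml(str(p), strict=True)


def test_duplicate_edges_merge_and_inhibition_wins():
    net = SignedNetwork(name="dup")
    net.add_edge("A", "B", 1)
    net.add_edge("A", "B", 1)
    assert net.edges == [("A", "B", 1)]
    net.add_edge("A", "B", -1)
    assert net.edges == [("A", "B", -1)]


def test_prune_to_dataset():
    net = SignedNetwork.from_edges("p", [("A", "B", 1), ("B", "C", 1)])
    pruned = prune_to_dataset(net, {"A", "B"}, min_nodes=2)
    assert pruned.nodes == ["A", "B"]
    assert pruned.edges == [("A", "B", 1)]
    # identity when everything is covered
    same = prune_to_dataset(net, {"A", "B", "C"}, min_nodes=2)
    assert same.edges == net.edges


def test_prune_skip_signal():
    net = SignedNetwork.from_edges("p", [("A", "B", 1), ("B", "C", 1)])
    with pytest.raises(PathwaySkipped):
        prune_to_dataset(net, {"A", "B"}, min_nodes=15)


def test_prune_never_adds_edges():
    for seed in range(5):
        net = random_network(12, edge_prob=0.3, seed=seed)
        keep = net.nodes[:8]
        try:
            pruned = prune_to_dataset(net, keep, min_nodes=2)
        except PathwaySkipped:
            continue
        assert set(pruned.edges) <= set(net.edges)


def test_cap_indegree_small_node_untouched():
    net = SignedNetwork.from_edges("c", [("B", "A", 1), ("C", "A", -1)])
    (a, b, c) = cap_indegree(net)
    assert a.target == "A" and a.regulators == (("B", 1), ("C", -1))
    assert b.regulators == () and c.regulators == ()


def test_cap_indegree_correlation_selection():
    """Five parents; the three mirroring the target exactly are kept."""
    rng = np.random.default_rng(0)
    target = rng.integers(0, 2, size=20)
    uncorr1 = np.array([0, 1] * 10)
    uncorr2 = np.array([1, 0] * 10)
    states = np.column_stack([uncorr1, uncorr2, target, target, target, target])
    genes = ["P1", "P2", "P3", "P4", "P5", "T"]
    data = make_binary(states, genes)
    net = SignedNetwork.from_edges(
        "cap", [(p, "T", 1) for p in ("P1", "P2", "P3", "P4", "P5")]
    )
    assignment = {a.target: a for a in cap_indegree(net, data)}["T"]
    assert tuple(g for g, _ in assignment.regulators) == ("P3", "P4", "P5")


def test_cap_indegree_zero_variance_ties_break_alphabetically():
    states = np.zeros((10, 6), dtype=int)
    states[:, 5] = [0, 1] * 5
    genes = ["P1", "P2", "P3", "P4", "P5", "T"]
    data = make_binary(states, genes)
    net = SignedNetwork.from_edges(
        "tie", [(p, "T", 1) for p in ("P1", "P2", "P3", "P4", "P5")]
    )
    assignment = {a.target: a for a in cap_indegree(net, data)}["T"]
    assert tuple(g for g, _ in assignment.regulators) == ("P1", "P2", "P3")


def test_cap_indegree_bounds_on_random_networks():
    for seed in range(20):
        net = random_network(15, edge_prob=0.4, seed=seed)
        for a in cap_indegree(net):
            assert len(a.regulators) <= 3


def test_gene_symbols_uppercased():
    net = SignedNetwork.from_edges("u", [("akt1", "Foxo1", 1)])
    assert net.nodes == ["AKT1", "FOXO1"]


def test_edge_tsv_export(tmp_path):
    net = SignedNetwork.from_edges("t", [("A", "B", -1)])
    p = tmp_path / "edges.tsv"
    net.to_edge_tsv(p)
    assert p.read_text() == "source\ttarget\tsign\nA\tB\t-1\n"
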