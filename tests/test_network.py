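"""Interolog transfer, overlay decoration, edge classes, subnetworks and
exports."""

import itertools
import random

import networkx as nx
import pytest

from thermophos.network import (BLACK, CIRCLE, CYAN, DIAMOND, GREEN, GREY,
                                OTHER, PURPLE, RECTANGLE, NodeDecoration,
                                TemplateEdge, build_graph, classify_edges,
                                decorate_nodes, export_network,
                                extract_subnetwork, read_graphml, render_svg,
                                summarize_pathways, transfer_network)
from .oracles import bfs_nodes_naive


def omap(**kwargs):
    return {t: (f"G_{t}", set(members)) for t, members in kwargs.items()}


def test_transfer_one_to_one():
    res = transfer_network([TemplateEdge("b", "p", "Y2H")],
                           omap(b={"B"}, p={"P"}))
    assert [(e.source, e.target) for e in res.edges] == [("B", "P")]
    (edge,) = res.edges
    assert edge.provenance[0].bait == "b"
    assert res.skipped == []


def test_transfer_skips_unmapped_bait_with_log():
    res = transfer_network([TemplateEdge("b", "p")], omap(p={"P"}))
    assert res.edges == []
    assert len(res.skipped) == 1 and "bait b" in res.skipped[0][1]


def test_transfer_expands_groups_combinatorially():
    """A bait group with two query members against a 1:1 prey yields exactly
    the Cartesian product, every edge sharing the template provenance."""
    template_edges = [TemplateEdge("b", "p"), TemplateEdge("p", "q")]
    mapping = omap(b={"B1", "B2"}, p={"P"}, q={"Q1", "Q2", "Q3"})
    res = transfer_network(template_edges, mapping)
    got = {(e.source, e.target) for e in res.edges}
    expected = set(itertools.product({"B1", "B2"}, {"P"})) | \
        set(itertools.product({"P"}, {"Q1", "Q2", "Q3"}))
    assert got == expected
    for e in res.edges:
        assert e.provenance[0] in template_edges


def test_transfer_completeness_under_perfect_map():
    """With a 1:1 map over every template protein, the number of inferred
    edges equals the number of template edges."""
    rnd = random.Random(5)
    proteins = [f"t{i}" for i in range(20)]
    edges = [TemplateEdge(*rnd.sample(proteins, 2)) for _ in range(30)]
    mapping = omap(**{t: {t.upper()} for t in proteins})
    res = transfer_network(edges, mapping)
    assert len(res.edges) == len(set((e.bait, e.prey) for e in edges))


def test_decorate_by_membership_hierarchy():
    decs = decorate_nodes(
        ["bi", "de", "other"],
        quant_conditions={"bi": {"LOW"}, "de": {"LOW", "HIGH"}},
        phospho_conditions={"bi": {"LOW"}},
        bilevel={"bi"}, de={"de", "bi"}, strong_fold={"bi"})
    assert decs["bi"].shape == CIRCLE and decs["bi"].border == CYAN
    # sectors ordered HIGH, OPT, LOW: low-only detection -> (F, F, T)
    assert decs["bi"].quant_sectors == (False, False, True)
    assert decs["bi"].phospho_sectors == (False, False, True)
    assert decs["de"].shape == RECTANGLE and decs["de"].border == GREY
    assert decs["other"].shape == DIAMOND and decs["other"].border == BLACK


def test_decorate_weak_fold_circle_is_pink():
    decs = decorate_nodes(["bi"], {}, {}, bilevel={"bi"}, de=set(),
                          strong_fold=set())
    assert decs["bi"].border == "PINK"


def shape_dec(acc, shape):
    return NodeDecoration(acc, shape, (False,) * 3, (False,) * 3, BLACK)


def test_classify_edges_covers_shape_grid():
    expected = {
        (CIRCLE, CIRCLE): GREEN,
        (CIRCLE, RECTANGLE): PURPLE, (RECTANGLE, CIRCLE): PURPLE,
        (CIRCLE, DIAMOND): OTHER, (DIAMOND, CIRCLE): OTHER,
        (RECTANGLE, RECTANGLE): OTHER, (RECTANGLE, DIAMOND): OTHER,
        (DIAMOND, RECTANGLE): OTHER, (DIAMOND, DIAMOND): OTHER,
    }
    for (sa, sb), cls in expected.items():
        g = nx.DiGraph()
        g.add_edge("u", "v")
        decs = {"u": shape_dec("u", sa), "v": shape_dec("v", sb)}
        assert classify_edges(g, decs)[("u", "v")] == cls, (sa, sb)


def test_classify_edges_requires_decorations():
    g = nx.DiGraph()
    g.add_edge("u", "v")
    with pytest.raises(KeyError):
        classify_edges(g, {"u": shape_dec("u", CIRCLE)})


def test_subnetwork_radius_zero_is_seed_only():
    g = nx.DiGraph([("a", "b"), ("b", "c")])
    sub = extract_subnetwork(g, "b", 0)
    assert set(sub.nodes) == {"b"} and sub.number_of_edges() == 0


def test_subnetwork_contains_template_partner():
    """Transferring the histidine-kinase → glutamate-synthase template edge
    puts the glutamate synthase node one hop from the Hik28 ortholog."""
    res = transfer_network(
        [TemplateEdge("NIES39_D04330", "NIES39_J05540", "Y2H")],
        omap(NIES39_D04330={"SPLC1_S041070"},
             NIES39_J05540={"SPLC1_S270380"}))
    g = build_graph(res.edges)
    sub = extract_subnetwork(g, "SPLC1_S041070", 1)
    assert "SPLC1_S270380" in sub.nodes


def test_subnetwork_matches_bfs_oracle():
    rnd = random.Random(21)
    nodes = [f"n{i}" for i in range(20)]
    edges = [tuple(rnd.sample(nodes, 2)) for _ in range(30)]
    g = nx.DiGraph(edges)
    seed = next(n for n in nodes if n in g)
    sub = extract_subnetwork(g, seed, 2)
    assert set(sub.nodes) == bfs_nodes_naive(edges, seed, 2)


def test_subnetwork_missing_seed_suggests_matches():
    g = nx.DiGraph([("SPLC1_S041070", "SPLC1_S270380")])
    with pytest.raises(KeyError, match="SPLC1_S041070"):
        extract_subnetwork(g, "SPLC1_S04107", 1)


def test_summarize_pathways_group_by():
    classes = {"A": "UP_UP", "B": "UP_UP", "C": "DOWN_DOWN", "D": "UP_UP"}
    annotation = {"A": {"Nitrogen metabolism"},
                  "B": {"Photosynthesis", "Ribosome"}}
    table = summarize_pathways(classes, annotation)
    assert table["UP_UP"]["pathways"] == \
        ["Nitrogen metabolism", "Photosynthesis", "Ribosome"]
    assert table["UP_UP"]["unannotated"] == 1  # D
    assert table["DOWN_DOWN"] == {"pathways": [], "unannotated": 1}

    # oracle: direct group-by enumeration on a random instance
    rnd = random.Random(4)
    accs = [f"p{i}" for i in range(30)]
    cls = {a: rnd.choice(["UP_UP", "DOWN_DOWN", "UP22_DOWN40"]) for a in accs}
    ann = {a: {rnd.choice(["x", "y", "z"])} for a in accs if rnd.random() < 0.7}
    table = summarize_pathways(cls, ann)
    for c in set(cls.values()):
        members = [a for a in accs if cls[a] == c]
        expected = sorted({p for a in members for p in ann.get(a, set())})
        assert table[c]["pathways"] == expected
        assert table[c]["unannotated"] == sum(1 for a in members
                                              if a not in ann)


def test_summarize_pathways_requires_some_annotation():
    with pytest.raises(ValueError):
        summarize_pathways({"A": "UP_UP"}, {"B": {"x"}})


def decorated_toy():
    g = nx.DiGraph([("A", "B"), ("B", "C")])
    decs = {"A": NodeDecoration("A", CIRCLE, (True, False, True),
                                (False, False, True), CYAN),
            "B": NodeDecoration("B", RECTANGLE, (True, False, False),
                                (False,) * 3, GREY),
            "C": shape_dec("C", DIAMOND)}
    classes = classify_edges(g, decs)
    return g, decs, classes


def test_svg_export_empty_and_single_node(tmp_path):
    empty = nx.DiGraph()
    svg = render_svg(empty, {}, {})
    assert svg.startswith("<svg") and svg.rstrip().endswith("</svg>")
    g = nx.DiGraph()
    g.add_node("solo")
    svg = render_svg(g, {"solo": shape_dec("solo", DIAMOND)}, {})
    assert svg.count("<polygon") == 1


def test_svg_export_is_deterministic(tmp_path):
    g, decs, classes = decorated_toy()
    a = tmp_path / "a.svg"
    b = tmp_path / "b.svg"
    export_network(g, decs, classes, a, "SVG", seed=7)
    export_network(g, decs, classes, b, "SVG", seed=7)
    assert a.read_bytes() == b.read_bytes()
    assert "#2e8b57" not in a.read_text()  # no green edge in this toy
    assert "#8a2be2" in a.read_text()      # circle-rectangle edge is purple


def test_graphml_round_trip_preserves_decorations(tmp_path):
    g, decs, classes = decorated_toy()
    path = tmp_path / "net.graphml"
    export_network(g, decs, classes, path, "GraphML")
    back = read_graphml(path)
    assert set(back.nodes) == set(g.nodes)
    assert set(back.edges) == set(g.edges)
    assert back.nodes["A"]["shape"] == CIRCLE
    assert back.nodes["A"]["quant_sectors"] == "101"
    assert back.nodes["A"]["phospho_sectors"] == "001"
    assert back.nodes["A"]["border"] == CYAN
    assert back["A"]["B"]["edge_class"] == PURPLE


def test_sif_export(tmp_path):
    g, decs, classes = decorated_toy()
    g.add_node("isolated")
    path = tmp_path / "net.sif"
    export_network(g, decs, classes, path, "SIF")
    lines = path.read_text().splitlines()
    assert "A\tpurple\tB" in lines
    assert "isolated" in lines


def test_unknown_export_format(tmp_path):
    g, decs, classes = decorated_toy()
    with pytest.raises(ValueError, match="unknown"):
        export_network(g, decs, classes, tmp_path / "x", "PDF")
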