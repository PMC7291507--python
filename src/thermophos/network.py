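"""Interolog PPI transfer and condition-overlay network reporting.

A curated template network of directed bait→prey interactions (e.g. from
*Synechocystis* yeast two-hybrid data) is transferred onto the query
species: a template edge (b, p) yields an inferred edge (B, P) for every
query-species pair of orthologs of b and p, each carrying full provenance.

Nodes are decorated in the published overlay scheme: six-sector circles for
bi-level regulated proteins (upper three sectors = quantitative-proteome
detection at HIGH/OPT/LOW, lower three = phosphoproteome detection, left to
right), striped rectangles for differentially expressed proteins, diamonds
otherwise. Circle borders are cyan when the protein passed the significant
>= 1.5-fold filter, pink below it; rectangles have grey borders, diamonds
black. Edges between two circles are green; circle–rectangle edges are
purple. Exports: GraphML and SIF (networkx) and deterministic SVG.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .quant import HIGH, LOW, OPT

CIRCLE = "CIRCLE"
RECTANGLE = "RECTANGLE"
DIAMOND = "DIAMOND"
CYAN = "CYAN"
PINK = "PINK"
GREY = "GREY"
BLACK = "BLACK"
GREEN = "GREEN"
PURPLE = "PURPLE"
OTHER = "OTHER"

#: Sector order, left to right, per the overlay legend.
SECTOR_ORDER = (HIGH, OPT, LOW)


@dataclass(frozen=True)
class TemplateEdge:
    bait: str
    prey: str
    evidence: str = ""

    @property
    def is_self(self) -> bool:
        return self.bait == self.prey


@dataclass(frozen=True)
class InferredEdge:
    source: str
    target: str
    provenance: tuple[TemplateEdge, str, str]  # (template edge, bait group, prey group)


@dataclass(frozen=True)
class NodeDecoration:
    accession: str
    shape: str
    quant_sectors: tuple[bool, bool, bool]    # (HIGH, OPT, LOW)
    phospho_sectors: tuple[bool, bool, bool]  # (HIGH, OPT, LOW)
    border: str


@dataclass
class TransferResult:
    edges: list[InferredEdge]
    skipped: list[tuple[TemplateEdge, str]] = field(default_factory=list)


def group_ortholog_map(groups) -> dict[str, tuple[str, set[str]]]:
    """template accession -> (group_id, query-species members) from
    :class:`~thermophos.orthology.OrthologGroup` objects whose members are
    (species, accession) pairs with species 'template' / 'query'."""
    mapping: dict[str, tuple[str, set[str]]] = {}
    for g in groups:
        query = {acc for sp, acc in g.members if sp == "query"}
        for sp, acc in g.members:
            if sp == "template":
                mapping[acc] = (g.group_id, query)
    return mapping


def rbh_ortholog_map(pairs: list[tuple[str, str]]) -> dict[str, tuple[str, set[str]]]:
    """template accession -> (pair tag, query members) from RBH (query,
    template) pairs."""
    mapping: dict[str, tuple[str, set[str]]] = {}
    for query, template in pairs:
        tag, members = mapping.get(template, (f"RBH:{template}", set()))
        members.add(query)
        mapping[template] = (tag, members)
    return mapping


def transfer_network(template_edges: list[TemplateEdge],
                     ortholog_map: dict[str, tuple[str, set[str]]]
                     ) -> TransferResult:
    """Transfer template edges through ortholog groups.

    For a template edge (b, p), every (B, P) with B in b's query members and
    P in p's query members is emitted once, with provenance. Edges whose
    bait or prey has no ortholog mapping are skipped and logged.
    """
    edges: list[InferredEdge] = []
    seen: set[tuple[str, str, str, str]] = set()
    skipped: list[tuple[TemplateEdge, str]] = []
    for te in template_edges:
        if te.bait not in ortholog_map:
            skipped.append((te, f"bait {te.bait} has no ortholog"))
            continue
        if te.prey not in ortholog_map:
            skipped.append((te, f"prey {te.prey} has no ortholog"))
            continue
        bait_gid, bait_members = ortholog_map[te.bait]
        prey_gid, prey_members = ortholog_map[te.prey]
        for b in sorted(bait_members):
            for p in sorted(prey_members):
                key = (b, p, te.bait, te.prey)
                if key in seen:
                    continue
                seen.add(key)
                edges.append(InferredEdge(b, p, (te, bait_gid, prey_gid)))
    return TransferResult(edges, skipped)


def build_graph(edges: list[InferredEdge],
                isolated_nodes: list[str] | None = None) -> nx.DiGraph:
    """Directed graph of inferred edges; optionally include unconnected
    proteins (drawn edgeless, as in the published figure)."""
    g = nx.DiGraph()
    for node in isolated_nodes or []:
        g.add_node(node)
    for e in edges:
        te, bait_gid, prey_gid = e.provenance
        g.add_edge(e.source, e.target, template_bait=te.bait,
                   template_prey=te.prey, evidence=te.evidence,
                   bait_group=bait_gid, prey_group=prey_gid)
    return g


def _sectors(conditions: set[str] | frozenset[str]) -> tuple[bool, bool, bool]:
    return tuple(c in conditions for c in SECTOR_ORDER)  # type: ignore[return-value]


def decorate_nodes(nodes, quant_conditions: dict[str, set[str]],
                   phospho_conditions: dict[str, set[str]],
                   bilevel: set[str], de: set[str],
                   strong_fold: set[str] | None = None
                   ) -> dict[str, NodeDecoration]:
    """Decorate nodes by membership: bi-level (circle) > differentially
    expressed (rectangle, grey border) > other (diamond, black border).

    ``strong_fold`` holds the bi-level accessions that met the significant
    >= 1.5-fold filter (cyan border); remaining circles are pink.
    """
    strong_fold = strong_fold if strong_fold is not None else bilevel
    out = {}
    for acc in nodes:
        if acc in bilevel:
            shape = CIRCLE
            border = CYAN if acc in strong_fold else PINK
        elif acc in de:
            shape, border = RECTANGLE, GREY
        else:
            shape, border = DIAMOND, BLACK
        out[acc] = NodeDecoration(
            acc, shape,
            _sectors(quant_conditions.get(acc, set())),
            _sectors(phospho_conditions.get(acc, set())),
            border)
    return out


def classify_edges(graph: nx.Graph,
                   decorations: dict[str, NodeDecoration]
                   ) -> dict[tuple[str, str], str]:
    """GREEN between two circles, PURPLE between a circle and a rectangle,
    OTHER otherwise. Symmetric in endpoint order."""
    classes = {}
    for u, v in graph.edges():
        for node in (u, v):
            if node not in decorations:
                raise KeyError(f"no decoration for node {node!r}")
        shapes = {decorations[u].shape, decorations[v].shape}
        if shapes == {CIRCLE}:
            cls = GREEN
        elif shapes == {CIRCLE, RECTANGLE}:
            cls = PURPLE
        else:
            cls = OTHER
        classes[(u, v)] = cls
    return classes


def extract_subnetwork(graph: nx.DiGraph, seed: str, radius: int) -> nx.DiGraph:
    """Breadth-first neighborhood of ``seed`` ignoring edge direction, with
    induced edges. An absent seed raises with the nearest accession
    matches."""
    if seed not in graph:
        close = difflib.get_close_matches(seed, list(graph.nodes), n=3)
        raise KeyError(f"seed {seed!r} not in network; nearest: {close}")
    nodes = nx.ego_graph(graph.to_undirected(as_view=True), seed,
                         radius).nodes
    return graph.subgraph(nodes).copy()


def summarize_pathways(classes_by_accession: dict[str, str],
                       annotation: dict[str, set[str]]
                       ) -> dict[str, dict]:
    """Per regulation class: the sorted set of pathways hit by >= 1 member,
    plus a count of unannotated members."""
    if not any(acc in annotation for acc in classes_by_accession):
        raise ValueError("annotation covers no node")
    table: dict[str, dict] = {}
    for acc, cls in sorted(classes_by_accession.items()):
        entry = table.setdefault(cls, {"pathways": set(), "unannotated": 0})
        paths = annotation.get(acc)
        if paths:
            entry["pathways"].update(paths)
        else:
            entry["unannotated"] += 1
    for entry in table.values():
        entry["pathways"] = sorted(entry["pathways"])
    return table


# --- export -----------------------------------------------------------------

def _attr_graph(graph: nx.DiGraph, decorations: dict[str, NodeDecoration],
                edge_classes: dict[tuple[str, str], str]) -> nx.DiGraph:
    g = graph.copy()
    for acc, dec in decorations.items():
        if acc in g:
            g.nodes[acc].update(
                shape=dec.shape, border=dec.border,
                quant_sectors="".join("1" if b else "0" for b in dec.quant_sectors),
                phospho_sectors="".join("1" if b else "0" for b in dec.phospho_sectors))
    for (u, v), cls in edge_classes.items():
        if g.has_edge(u, v):
            g[u][v]["edge_class"] = cls
    return g


def write_graphml(graph: nx.DiGraph, decorations, edge_classes,
                  path: str | Path) -> None:
    nx.write_graphml(_attr_graph(graph, decorations, edge_classes), str(path))


def read_graphml(path: str | Path) -> nx.DiGraph:
    return nx.read_graphml(str(path))


def write_sif(graph: nx.DiGraph, edge_classes, path: str | Path) -> None:
    lines = []
    for u, v in sorted(graph.edges()):
        rel = edge_classes.get((u, v), OTHER).lower()
        lines.append(f"{u}\t{rel}\t{v}")
    for node in sorted(n for n in graph.nodes if graph.degree(n) == 0):
        lines.append(node)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


_QUANT_FILL = {HIGH: "#f2a0c0", OPT: "#b8e4a0", LOW: "#7a9fe0"}
_PHOS_FILL = {HIGH: "#f5a623", OPT: "#3fa33f", LOW: "#35c4d7"}
_BORDER_FILL = {CYAN: "#00b7c3", PINK: "#f06292", GREY: "#808080",
                BLACK: "#000000"}
_EDGE_FILL = {GREEN: "#2e8b57", PURPLE: "#8a2be2", OTHER: "#999999"}


def _sector_path(cx: float, cy: float, r: float, start_deg: float,
                 end_deg: float) -> str:
    a0, a1 = np.deg2rad(start_deg), np.deg2rad(end_deg)
    x0, y0 = cx + r * np.cos(a0), cy + r * np.sin(a0)
    x1, y1 = cx + r * np.cos(a1), cy + r * np.sin(a1)
    return (f"M {cx:.2f},{cy:.2f} L {x0:.2f},{y0:.2f} "
            f"A {r:.2f},{r:.2f} 0 0 1 {x1:.2f},{y1:.2f} Z")


def _node_svg(acc: str, dec: NodeDecoration, x: float, y: float,
              r: float = 16.0) -> list[str]:
    border = _BORDER_FILL[dec.border]
    parts = []
    if dec.shape == CIRCLE:
        # upper sectors: quant (left->right HIGH, OPT, LOW); lower: phospho
        for i, cond in enumerate(SECTOR_ORDER):
            fill = _QUANT_FILL[cond] if dec.quant_sectors[i] else "#ffffff"
            start = 180.0 + 60.0 * i
            parts.append(f'<path d="{_sector_path(x, y, r, start, start + 60)}" '
                         f'fill="{fill}" stroke="{border}" stroke-width="1"/>')
        for i, cond in enumerate(SECTOR_ORDER):
            fill = _PHOS_FILL[cond] if dec.phospho_sectors[i] else "#ffffff"
            start = 120.0 - 60.0 * i
            parts.append(f'<path d="{_sector_path(x, y, r, start - 60, start)}" '
                         f'fill="{fill}" stroke="{border}" stroke-width="1"/>')
        parts.append(f'<circle cx="{x:.2f}" cy="{y:.2f}" r="{r:.2f}" '
                     f'fill="none" stroke="{border}" stroke-width="2"/>')
    elif dec.shape == RECTANGLE:
        w, h = 2.2 * r, 1.3 * r
        x0, y0 = x - w / 2, y - h / 2
        strip = w / 3
        for i, cond in enumerate(SECTOR_ORDER):
            fill = _QUANT_FILL[cond] if dec.quant_sectors[i] else "#ffffff"
            parts.append(f'<rect x="{x0 + i * strip:.2f}" y="{y0:.2f}" '
                         f'width="{strip:.2f}" height="{h:.2f}" fill="{fill}"/>')
        parts.append(f'<rect x="{x0:.2f}" y="{y0:.2f}" width="{w:.2f}" '
                     f'height="{h:.2f}" fill="none" stroke="{border}" '
                     'stroke-width="2"/>')
    else:
        pts = f"{x:.2f},{y - r:.2f} {x + r:.2f},{y:.2f} {x:.2f},{y + r:.2f} {x - r:.2f},{y:.2f}"
        parts.append(f'<polygon points="{pts}" fill="#ffffff" '
                     f'stroke="{border}" stroke-width="2"/>')
    parts.append(f'<text x="{x:.2f}" y="{y + r + 11:.2f}" font-size="8" '
                 f'text-anchor="middle" font-family="sans-serif">{acc}</text>')
    return parts


def render_svg(graph: nx.DiGraph, decorations: dict[str, NodeDecoration],
               edge_classes: dict[tuple[str, str], str],
               seed: int = 0, size: int = 640) -> str:
    """Deterministic SVG 1.1 rendering: spring layout with a fixed seed and
    iteration count, fixed-precision coordinates, sorted element order.
    Identical inputs and seed give byte-identical output."""
    header = (f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
              f'width="{size}" height="{size}" '
              f'viewBox="0 0 {size} {size}">')
    if len(graph) == 0:
        return header + "</svg>\n"
    pos = nx.spring_layout(graph, seed=seed, iterations=80)
    xs = np.array([p[0] for p in pos.values()])
    ys = np.array([p[1] for p in pos.values()])
    margin = 50.0
    span = size - 2 * margin

    def scale(val, lo, hi):
        if hi - lo < 1e-12:
            return margin + span / 2
        return margin + span * (val - lo) / (hi - lo)

    coords = {n: (scale(p[0], xs.min(), xs.max()),
                  scale(p[1], ys.min(), ys.max())) for n, p in pos.items()}
    parts = [header]
    for u, v in sorted(graph.edges()):
        cls = edge_classes.get((u, v), OTHER)
        (x0, y0), (x1, y1) = coords[u], coords[v]
        parts.append(f'<line x1="{x0:.2f}" y1="{y0:.2f}" x2="{x1:.2f}" '
                     f'y2="{y1:.2f}" stroke="{_EDGE_FILL[cls]}" '
                     'stroke-width="1.5"/>')
    for node in sorted(graph.nodes):
        dec = decorations.get(node)
        if dec is None:
            dec = NodeDecoration(node, DIAMOND, (False,) * 3, (False,) * 3, BLACK)
        x, y = coords[node]
        parts.extend(_node_svg(node, dec, x, y))
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def export_network(graph: nx.DiGraph, decorations, edge_classes,
                   path: str | Path, fmt: str, seed: int = 0) -> None:
    """Write the decorated network as SVG, GraphML or SIF."""
    fmt = fmt.upper()
    if fmt == "SVG":
        Path(path).write_text(render_svg(graph, decorations, edge_classes,
                                         seed=seed))
    elif fmt == "GRAPHML":
        write_graphml(graph, decorations, edge_classes, path)
    elif fmt == "SIF":
        write_sif(graph, edge_classes, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
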