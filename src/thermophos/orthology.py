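"""Cross-species orthology: local alignment, reciprocal best hits, Markov
clustering and domain-architecture confirmation.

Homology search here is exact Smith–Waterman local alignment with affine
gaps (BLOSUM62, gap open 11 / extend 1) rather than a seeded heuristic —
at desk-scale proteome sizes the exact dynamic program is affordable and
fully deterministic. Significance uses the Karlin–Altschul form
``E = K * m * n * exp(-lambda * S)`` with the published ungapped BLOSUM62
constants (lambda = 0.3176, K = 0.134); the search space is m x n per pair.

Ortholog pairs are reciprocal best hits (RBH) with both e-values strictly
below the threshold (default 1e-10). Orthologous groups come from Markov
clustering (MCL) of the -log10(e-value) weighted similarity graph —
iterative expansion/inflation of a column-stochastic matrix with
self-loops — and may be confirmed by domain-architecture similarity
(pairwise Jaccard of domain-token multisets >= 0.5). Ties are broken
lexicographically everywhere.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .quant import Thresholds

# Published ungapped Karlin-Altschul parameters for BLOSUM62.
BLOSUM62_LAMBDA = 0.3176
BLOSUM62_K = 0.134

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_VALID_RESIDUES = set(str(_BLOSUM62.alphabet))


@dataclass(frozen=True)
class SimilarityHit:
    query: str
    subject: str
    raw_score: float
    bit_score: float
    evalue: float


@dataclass
class OrthologGroup:
    group_id: str
    members: set[tuple[str, str]]  # (species, accession)
    confirmed: bool | None = None


def validate_sequence(seq: str, name: str = "sequence") -> None:
    for i, ch in enumerate(seq):
        if ch not in _VALID_RESIDUES:
            raise ValueError(
                f"invalid residue {ch!r} at position {i + 1} of {name}")
    if not seq:
        raise ValueError(f"{name} is empty")


def make_aligner(gap_open: float = 11.0, gap_extend: float = 1.0) -> Align.PairwiseAligner:
    """Local aligner with BLAST-style affine gap costs: a gap of length L
    costs gap_open + L * gap_extend."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def karlin_altschul_evalue(raw_score: float, search_space: float,
                           lam: float = BLOSUM62_LAMBDA,
                           k: float = BLOSUM62_K) -> tuple[float, float]:
    """(bit_score, evalue) for a raw alignment score.

    bit = (lambda * S - ln K) / ln 2 ; E = m*n * 2**(-bit).
    """
    bits = (lam * raw_score - math.log(k)) / math.log(2.0)
    evalue = search_space * 2.0 ** (-bits)
    return bits, evalue


def align_score(seq_a: str, seq_b: str,
                gap_open: float = 11.0, gap_extend: float = 1.0,
                search_space: float | None = None,
                query: str = "query", subject: str = "subject",
                aligner: Align.PairwiseAligner | None = None) -> SimilarityHit:
    """Smith–Waterman local alignment score with an e-value-like statistic.

    ``search_space`` defaults to len(a) * len(b).
    """
    validate_sequence(seq_a, query)
    validate_sequence(seq_b, subject)
    if aligner is None:
        aligner = make_aligner(gap_open, gap_extend)
    raw = float(aligner.score(seq_a, seq_b))
    if search_space is None:
        search_space = float(len(seq_a) * len(seq_b))
    bits, evalue = karlin_altschul_evalue(raw, search_space)
    return SimilarityHit(query, subject, raw, bits, evalue)


def all_vs_all_hits(proteome_a: dict[str, str], proteome_b: dict[str, str],
                    gap_open: float = 11.0, gap_extend: float = 1.0
                    ) -> list[SimilarityHit]:
    """Score every a-vs-b pair (one direction; SW scores are symmetric)."""
    aligner = make_aligner(gap_open, gap_extend)
    hits = []
    for qa in sorted(proteome_a):
        for sb in sorted(proteome_b):
            hits.append(align_score(proteome_a[qa], proteome_b[sb],
                                    query=qa, subject=sb, aligner=aligner))
    return hits


def _best_hits(hits: list[SimilarityHit]) -> dict[str, SimilarityHit]:
    """Best hit per query: highest raw score, ties to the lexicographically
    smallest subject accession."""
    best: dict[str, SimilarityHit] = {}
    for h in sorted(hits, key=lambda h: (h.query, -h.raw_score, h.subject)):
        best.setdefault(h.query, h)
    return best


def reciprocal_best_hits(proteome_a: dict[str, str],
                         proteome_b: dict[str, str],
                         thresholds: Thresholds | None = None,
                         hits: list[SimilarityHit] | None = None
                         ) -> list[tuple[str, str]]:
    """Ortholog pairs (a, b): b is a's best hit, a is b's best hit, and both
    e-values are strictly below ``rbh_evalue``.

    ``hits`` may carry a precomputed a-vs-b hit table to avoid re-alignment.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteome sets must be nonempty")
    thresholds = thresholds or Thresholds()
    if hits is None:
        hits = all_vs_all_hits(proteome_a, proteome_b)
    forward = _best_hits(hits)
    reverse = _best_hits([SimilarityHit(h.subject, h.query, h.raw_score,
                                        h.bit_score, h.evalue) for h in hits])
    pairs = []
    for a in sorted(proteome_a):
        fh = forward.get(a)
        if fh is None:
            continue
        rh = reverse.get(fh.subject)
        if rh is not None and rh.subject == a \
                and fh.evalue < thresholds.rbh_evalue \
                and rh.evalue < thresholds.rbh_evalue:
            pairs.append((a, fh.subject))
    return pairs


def similarity_graph(hits: list[SimilarityHit],
                     evalue_cutoff: float = 1e-10,
                     floor: float = 1e-300) -> nx.Graph:
    """Undirected graph weighted by -log10(e-value) for hits below the
    cutoff."""
    g = nx.Graph()
    for h in hits:
        if h.query == h.subject or h.evalue >= evalue_cutoff:
            continue
        w = -math.log10(max(h.evalue, floor))
        if not g.has_edge(h.query, h.subject) or \
                g[h.query][h.subject]["weight"] < w:
            g.add_edge(h.query, h.subject, weight=w)
    return g


@dataclass
class MCLResult:
    groups: list[OrthologGroup]
    converged: bool
    n_iter: int


def markov_cluster(graph: nx.Graph, inflation: float = 1.5,
                   max_iter: int = 100, tol: float = 1e-6,
                   species_of: dict[str, str] | None = None) -> MCLResult:
    """Markov clustering of a weighted similarity graph.

    Column-stochastic expansion (matrix squaring) and inflation (elementwise
    power then renormalisation) with self-loops set to each node's maximum
    incident weight, pruning entries below ``tol``. Attractor rows define
    the clusters; every node is assigned to exactly one group (unassigned
    nodes go to their strongest attractor; ties lexicographic).
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        return MCLResult([], True, 0)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w <= 0:
            raise ValueError("edge weights must be positive")
        m[idx[u], idx[v]] = m[idx[v], idx[u]] = w
    loop = m.max(axis=0)
    loop[loop == 0] = 1.0  # isolated nodes keep a unit self-loop
    np.fill_diagonal(m, loop)

    def normalize(a: np.ndarray) -> np.ndarray:
        cols = a.sum(axis=0)
        cols[cols == 0] = 1.0
        return a / cols

    m = normalize(m)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        expanded = m @ m
        inflated = normalize(expanded ** inflation)
        inflated[inflated < tol] = 0.0
        inflated = normalize(inflated)
        if np.abs(inflated - m).max() < tol:
            m = inflated
            converged = True
            break
        m = inflated

    # attractors: nodes with mass on their own diagonal
    attractors = [i for i in range(n) if m[i, i] > tol]
    clusters: list[set[int]] = []
    for a in attractors:
        members = {j for j in range(n) if m[a, j] > tol} | {a}
        merged = False
        for c in clusters:
            if c & members:
                c |= members
                merged = True
                break
        if merged:
            # merging may chain-connect earlier clusters
            clusters = _merge_overlaps(clusters)
        else:
            clusters.append(members)
    assigned = set().union(*clusters) if clusters else set()
    for j in range(n):
        if j not in assigned:
            col = m[:, j]
            if col.max() > 0:
                target = int(np.argmax(col))
                for c in clusters:
                    if target in c:
                        c.add(j)
                        break
                else:
                    clusters.append({j})
            else:
                clusters.append({j})
    clusters = _merge_overlaps(clusters)
    clusters.sort(key=lambda c: nodes[min(c)])

    species_of = species_of or {}
    groups = []
    for gi, c in enumerate(clusters, start=1):
        members = {(species_of.get(nodes[i], ""), nodes[i]) for i in c}
        groups.append(OrthologGroup(f"OG{gi:04d}", members))
    return MCLResult(groups, converged, it)


def _merge_overlaps(clusters: list[set[int]]) -> list[set[int]]:
    merged: list[set[int]] = []
    for c in clusters:
        c = set(c)
        absorbed = [m for m in merged if m & c]
        for m_ in absorbed:
            c |= m_
            merged.remove(m_)
        merged.append(c)
    return merged


def jaccard_multiset(a: list[str], b: list[str]) -> float:
    ca, cb = Counter(a), Counter(b)
    inter = sum((ca & cb).values())
    union = sum((ca | cb).values())
    return inter / union if union else 1.0


def confirm_group_domains(group: OrthologGroup,
                          architectures: dict[str, list[str]]
                          ) -> bool | None:
    """Confirm a group when all member pairs share similar domain
    architectures (multiset Jaccard >= 0.5). Returns ``None`` (unknown,
    distinct from False) when fewer than two members have architectures.
    """
    archs = [architectures[acc] for _, acc in sorted(group.members)
             if acc in architectures]
    if len(archs) < 2:
        return None
    for i in range(len(archs)):
        for j in range(i + 1, len(archs)):
            if jaccard_multiset(archs[i], archs[j]) < 0.5:
                return False
    return True
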