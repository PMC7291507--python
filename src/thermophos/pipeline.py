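"""End-to-end pipeline orchestration with a reproducible run manifest.

Stage order follows the analysis workflow: signal filter → differential
tests → regulation classes → phosphopeptide parse/filter/aggregate →
bi-level report → orthology (all-vs-all alignment, RBH, MCL) → interolog
transfer → node decoration/edge classes → exports. The manifest records the
package version, parameters, SHA-256 of every input file and per-stage
record counts, so identical configs yield identical manifests.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .bilevel import build_bilevel_report, identify_bilevel, write_bilevel_report
from .io import (read_abundance_tsv, read_domains_tsv, read_fasta,
                 read_pathway_annotation_tsv, read_phosphopeptides_tsv,
                 read_template_edges_tsv, write_expression_tsv, write_groups_tsv,
                 write_hits_tsv, write_json)
from .network import (TemplateEdge, build_graph, classify_edges,
                      decorate_nodes, export_network, group_ortholog_map,
                      transfer_network)
from .orthology import (all_vs_all_hits, confirm_group_domains, markov_cluster,
                        reciprocal_best_hits, similarity_graph)
from .phospho import HIGH_STRINGENCY, aggregate_sites, filter_stringency
from .quant import (Thresholds, apply_signal_threshold, classify_regulation,
                    cluster_expression_profiles, test_differential)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    abundance: Path
    phosphopeptides: Path
    out_dir: Path
    query_fasta: Path | None = None
    template_fasta: Path | None = None
    template_edges: Path | None = None
    domains: Path | None = None
    pathways: Path | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    stringency: str = HIGH_STRINGENCY
    gap_open: float = 11.0
    gap_extend: float = 1.0
    inflation: float = 1.5
    seed: int = 0
    run_orthology: bool = True
    run_network: bool = True
    run_clustering: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        paths = {k: Path(v) for k, v in raw.items()
                 if k in ("abundance", "phosphopeptides", "out_dir",
                          "query_fasta", "template_fasta", "template_edges",
                          "domains", "pathways") and v is not None}
        rest = {k: v for k, v in raw.items() if k not in paths}
        try:
            return cls(thresholds=thr, **paths, **rest)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def validate(self) -> None:
        required = {"abundance": self.abundance,
                    "phosphopeptides": self.phosphopeptides}
        optional = {"query_fasta": self.query_fasta,
                    "template_fasta": self.template_fasta,
                    "template_edges": self.template_edges,
                    "domains": self.domains, "pathways": self.pathways}
        for name, p in {**required, **{k: v for k, v in optional.items()
                                       if v is not None}}.items():
            if not Path(p).exists():
                raise ConfigError(f"input {name} does not exist: {p}")
        if self.run_orthology and not (self.query_fasta and self.template_fasta):
            raise ConfigError("orthology stage needs query and template FASTA")
        if self.run_network and not (self.run_orthology and self.template_edges):
            raise ConfigError("network stage needs orthology and template edges")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    manifest: dict = {
        "package": "thermophos",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "noise_multiplier": thr.noise_multiplier,
            "p_cutoff": thr.p_cutoff, "fc_cutoff": thr.fc_cutoff,
            "rbh_evalue": thr.rbh_evalue, "stringency": config.stringency,
            "gap_open": config.gap_open, "gap_extend": config.gap_extend,
            "inflation": config.inflation,
        },
        "inputs": {},
        "stages": {},
    }
    for name in ("abundance", "phosphopeptides", "query_fasta",
                 "template_fasta", "template_edges", "domains", "pathways"):
        p = getattr(config, name)
        if p is not None:
            manifest["inputs"][name] = _sha256(p)

    def stage(name):
        def deco(fn):
            try:
                manifest["stages"][name] = fn()
            except Exception as exc:  # noqa: BLE001 - abort with stage context
                raise StageError(name, exc) from exc
        return deco

    state: dict = {}

    @stage("signal_filter")
    def _():
        matrix = read_abundance_tsv(config.abundance)
        res = apply_signal_threshold(matrix, thr)
        state["matrix"] = res.matrix
        return {"n_measurements": int(matrix.data["intensity"].notna().sum()),
                "n_removed": res.n_removed}

    @stage("differential")
    def _():
        results = {}
        calls = {"UP": 0, "DOWN": 0}
        for stress in ("LOW", "HIGH"):
            res = test_differential(state["matrix"], stress, thr)
            results[f"{stress}_vs_OPT"] = {r.accession: r for r in res}
            for r in res:
                if r.call in calls:
                    calls[r.call] += 1
            write_expression_tsv(res, out / f"expression_{stress}_vs_OPT.tsv")
        state["expression"] = results
        return {"n_proteins": len(results["LOW_vs_OPT"]),
                "n_up_calls": calls["UP"], "n_down_calls": calls["DOWN"]}

    @stage("regulation_classes")
    def _():
        classes = {}
        for acc, low in state["expression"]["LOW_vs_OPT"].items():
            high = state["expression"]["HIGH_vs_OPT"][acc]
            classes[acc] = classify_regulation(low, high)
        state["classes"] = classes
        counts: dict[str, int] = {}
        for c in classes.values():
            counts[c] = counts.get(c, 0) + 1
        return {"class_counts": dict(sorted(counts.items()))}

    if config.run_clustering:
        @stage("expression_clustering")
        def _():
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dend = cluster_expression_profiles(state["matrix"])
            (out / "expression_dendrogram.nwk").write_text(dend.to_newick() + "\n")
            return {"n_clustered": len(dend.labels),
                    "n_excluded": len(dend.excluded)}

    @stage("phospho")
    def _():
        records = read_phosphopeptides_tsv(config.phosphopeptides)
        kept = filter_stringency(records, config.stringency)
        by_acc: dict[str, list] = {}
        for r in kept:
            by_acc.setdefault(r.accession, []).append(r)
        inventories = {acc: aggregate_sites(rs) for acc, rs in by_acc.items()}
        state["inventories"] = inventories
        n_sites = sum(inv.counts[3] for inv in inventories.values())
        return {"n_peptides": len(records), "n_pass_stringency": len(kept),
                "n_phosphoproteins": len(inventories), "n_sites": n_sites}

    @stage("bilevel")
    def _():
        expr_by_acc: dict[str, dict] = {}
        for contrast, results in state["expression"].items():
            for acc, r in results.items():
                expr_by_acc.setdefault(acc, {})[contrast] = r
        records = identify_bilevel(expr_by_acc, state["inventories"], thr)
        report = build_bilevel_report(records)
        write_bilevel_report(report, out / "bilevel_report.tsv",
                             out / "bilevel_totals.json")
        state["bilevel_records"] = records
        state["bilevel_report"] = report
        return {"n_candidates": len(records), "n_reported": len(report.rows),
                "site_totals": list(report.totals)}

    if config.run_orthology:
        @stage("orthology")
        def _():
            query = read_fasta(config.query_fasta)
            template = read_fasta(config.template_fasta)
            hits = all_vs_all_hits(query, template, config.gap_open,
                                   config.gap_extend)
            write_hits_tsv(hits, out / "similarity_hits.tsv")
            pairs = reciprocal_best_hits(query, template, thr, hits=hits)
            graph = similarity_graph(hits, evalue_cutoff=thr.rbh_evalue)
            species = {**{q: "query" for q in query},
                       **{t: "template" for t in template}}
            mcl = markov_cluster(graph, inflation=config.inflation,
                                 species_of=species)
            if config.domains:
                archs = read_domains_tsv(config.domains)
                for g in mcl.groups:
                    g.confirmed = confirm_group_domains(g, archs)
            write_groups_tsv(mcl.groups, out / "ortholog_groups.tsv")
            state["rbh_pairs"] = pairs
            state["groups"] = mcl.groups
            return {"n_hits": len(hits), "n_rbh_pairs": len(pairs),
                    "n_groups": len(mcl.groups),
                    "mcl_converged": mcl.converged}

    if config.run_network:
        @stage("network")
        def _():
            raw_edges = read_template_edges_tsv(config.template_edges)
            template_edges = [TemplateEdge(*e) for e in raw_edges]
            omap = group_ortholog_map(state["groups"])
            transfer = transfer_network(template_edges, omap)
            graph = build_graph(transfer.edges)
            bilevel = {r.accession for r in state["bilevel_records"]}
            strong = {r.accession for r in state["bilevel_records"] if r.reported}
            de = {acc for acc, res in state["expression"]["LOW_vs_OPT"].items()
                  if res.call in ("UP", "DOWN")}
            de |= {acc for acc, res in state["expression"]["HIGH_vs_OPT"].items()
                   if res.call in ("UP", "DOWN")}
            quant_conds = {acc: {c for c in ("LOW", "OPT", "HIGH")
                                 if len(state["matrix"].values(acc, c))}
                           for acc in graph.nodes}
            phos_conds = {acc: set(inv.conditions)
                          for acc, inv in state["inventories"].items()}
            decorations = decorate_nodes(graph.nodes, quant_conds, phos_conds,
                                         bilevel, de, strong)
            eclasses = classify_edges(graph, decorations)
            for fmt, fname in (("GraphML", "network.graphml"),
                               ("SIF", "network.sif"), ("SVG", "network.svg")):
                export_network(graph, decorations, eclasses, out / fname,
                               fmt, seed=config.seed)
            if config.pathways:
                annotation = read_pathway_annotation_tsv(config.pathways)
                if any(acc in annotation for acc in state["classes"]):
                    from .network import summarize_pathways

                    table = summarize_pathways(state["classes"], annotation)
                    write_json(table, out / "pathway_summary.json")
            n_classes: dict[str, int] = {}
            for cls in eclasses.values():
                n_classes[cls] = n_classes.get(cls, 0) + 1
            return {"n_template_edges": len(template_edges),
                    "n_inferred_edges": graph.number_of_edges(),
                    "n_skipped": len(transfer.skipped),
                    "edge_classes": dict(sorted(n_classes.items()))}

    write_json(manifest, out / "manifest.json")
    return manifest
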