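"""Readers and writers for the package's tabular and sequence formats.

All tables are UTF-8 TSV with a header row; missing values are empty
fields. FASTA goes through Bio.SeqIO and transparently handles ``.gz``.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .phospho import Phosphopeptide, parse_phosphopeptide, serialize_phosphopeptide
from .quant import AbundanceMatrix, ExpressionResult


def read_abundance_tsv(path: str | Path) -> AbundanceMatrix:
    """Read an abundance table (accession, condition, replicate, intensity,
    noise)."""
    df = pd.read_csv(path, sep="\t", dtype={"accession": str, "condition": str})
    df["replicate"] = df["replicate"].astype(int)
    for col in ("intensity", "noise"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return AbundanceMatrix(df)


def write_abundance_tsv(matrix: AbundanceMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_expression_tsv(results: Iterable[ExpressionResult],
                         path: str | Path) -> None:
    rows = [{
        "accession": r.accession, "contrast": r.contrast,
        "fold_change": r.fold_change, "log2_fc": r.log2_fc,
        "p_value": r.p_value, "call": r.call,
    } for r in results]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_expression_tsv(path: str | Path) -> list[ExpressionResult]:
    """Read expression results; rows without a ``call`` column get their
    call re-derived from fold change and p-value at default thresholds."""
    from .quant import make_result

    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        if "call" in df.columns:
            out.append(ExpressionResult(
                accession=str(r["accession"]), contrast=str(r["contrast"]),
                fold_change=float(r["fold_change"]),
                p_value=float(r["p_value"]), call=str(r["call"])))
        else:
            out.append(make_result(str(r["accession"]), str(r["contrast"]),
                                   float(r["fold_change"]),
                                   float(r["p_value"])))
    return out


def read_phosphopeptides_tsv(path: str | Path) -> list[Phosphopeptide]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for i, row in df.iterrows():
        records.append(parse_phosphopeptide(dict(row), row_id=f"{path}:{i + 2}"))
    return records


def write_phosphopeptides_tsv(records: Iterable[Phosphopeptide],
                              path: str | Path) -> None:
    rows = [serialize_phosphopeptide(r) for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly gzipped) FASTA into an ordered {id: sequence} dict."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return seqs


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    with opener(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_template_edges_tsv(path: str | Path) -> list[tuple[str, str, str]]:
    """Read bait→prey template edges: columns bait, prey, evidence."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [(r["bait"], r["prey"], r.get("evidence", ""))
            for _, r in df.iterrows()]


def write_template_edges_tsv(edges, path: str | Path) -> None:
    pd.DataFrame(edges, columns=["bait", "prey", "evidence"]) \
        .to_csv(path, sep="\t", index=False)


def read_pathway_annotation_tsv(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, set[str]] = {}
    for _, r in df.iterrows():
        if not r["pathway"]:
            raise ValueError(f"empty pathway name for {r['accession']}")
        out.setdefault(r["accession"], set()).add(r["pathway"])
    return out


def write_pathway_annotation_tsv(annotation: dict[str, set[str]],
                                 path: str | Path) -> None:
    rows = [{"accession": a, "pathway": p}
            for a in sorted(annotation) for p in sorted(annotation[a])]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_domains_tsv(path: str | Path) -> dict[str, list[str]]:
    """Domain architectures: columns accession, domains (space-separated,
    ordered)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return {r["accession"]: r["domains"].split() for _, r in df.iterrows()}


def write_hits_tsv(hits, path: str | Path) -> None:
    rows = [{"query": h.query, "subject": h.subject, "raw_score": h.raw_score,
             "bit_score": h.bit_score, "evalue": h.evalue} for h in hits]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_groups_tsv(groups, path: str | Path) -> None:
    rows = []
    for g in groups:
        for species, acc in sorted(g.members):
            rows.append({"group_id": g.group_id, "species": species,
                         "accession": acc,
                         "confirmed": "" if g.confirmed is None else g.confirmed})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON (sorted keys, fixed separators)."""
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
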