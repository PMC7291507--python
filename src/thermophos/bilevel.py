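"""Bi-level regulated protein identification and reporting.

A protein is *bi-level regulated* when it is regulated at both the
protein-expression level and the post-translational level: it appears in
the quantitative differential-expression results *and* carries detected
phosphosites. Candidates are the intersection of the two sets; the reported
tier additionally requires a significant >= 1.5-fold change (up or down) in
at least one stress contrast. In the original C1 study this narrowing takes
40 phosphorylated-and-quantified candidates down to the 31 reported
proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phospho import SiteInventory
from .quant import DOWN, UP, ExpressionResult, Thresholds


@dataclass
class BiLevelRecord:
    accession: str
    inventory: SiteInventory
    low_result: ExpressionResult | None
    high_result: ExpressionResult | None
    candidate: bool
    reported: bool
    ortholog_tag: str = ""


@dataclass
class BiLevelReport:
    rows: list[BiLevelRecord]
    #: (n_phosphopeptides, n_unique, pS, pT, pY, total_sites)
    totals: tuple[int, int, int, int, int, int] = (0, 0, 0, 0, 0, 0)


def _meets_reported_filter(result: ExpressionResult | None,
                           thresholds: Thresholds) -> bool:
    if result is None or not np.isfinite(result.fold_change):
        return False
    if result.fold_change <= 0 or not result.p_value <= thresholds.p_cutoff:
        return False
    return abs(np.log2(result.fold_change)) >= np.log2(thresholds.fc_cutoff)


def identify_bilevel(expression: dict[str, dict[str, ExpressionResult]],
                     inventories: dict[str, SiteInventory],
                     thresholds: Thresholds | None = None,
                     ortholog_tags: dict[str, str] | None = None
                     ) -> list[BiLevelRecord]:
    """Intersect expression results with phosphosite inventories.

    ``expression`` maps accession -> {"LOW_vs_OPT": result,
    "HIGH_vs_OPT": result}; either contrast may be absent. A protein is a
    candidate when present in both inputs, and reported when additionally
    one contrast shows |log2 FC| >= log2(fc_cutoff) with p <= p_cutoff.
    Output is sorted by accession. Phospho-only proteins are excluded.
    """
    thresholds = thresholds or Thresholds()
    ortholog_tags = ortholog_tags or {}
    records = []
    for acc in sorted(set(expression) & set(inventories)):
        low = expression[acc].get("LOW_vs_OPT")
        high = expression[acc].get("HIGH_vs_OPT")
        reported = (_meets_reported_filter(low, thresholds)
                    or _meets_reported_filter(high, thresholds))
        records.append(BiLevelRecord(
            accession=acc, inventory=inventories[acc],
            low_result=low, high_result=high,
            candidate=True, reported=reported,
            ortholog_tag=ortholog_tags.get(acc, "")))
    return records


def build_bilevel_report(records: list[BiLevelRecord]) -> BiLevelReport:
    """Assemble the report: reported rows (ascending accession) plus column
    totals computed by summation."""
    rows = sorted((r for r in records if r.reported), key=lambda r: r.accession)
    npep = sum(r.inventory.n_phosphopeptides for r in rows)
    nuniq = sum(r.inventory.n_unique_phosphopeptides for r in rows)
    ps = sum(r.inventory.counts[0] for r in rows)
    pt = sum(r.inventory.counts[1] for r in rows)
    py = sum(r.inventory.counts[2] for r in rows)
    return BiLevelReport(rows, (npep, nuniq, ps, pt, py, ps + pt + py))


def _call_of(result: ExpressionResult | None) -> str:
    return result.call if result is not None else ""


def report_to_frame(report: BiLevelReport) -> pd.DataFrame:
    rows = []
    for r in report.rows:
        ps, pt, py, total = r.inventory.counts
        conds = r.inventory.conditions
        rows.append({
            "accession": r.accession,
            "ortholog": r.ortholog_tag,
            "n_phosphopeptides": r.inventory.n_phosphopeptides,
            "n_unique_phosphopeptides": r.inventory.n_unique_phosphopeptides,
            "pS": ps, "pT": pt, "pY": py, "total_sites": total,
            "detected_22C": int("LOW" in conds),
            "detected_35C": int("OPT" in conds),
            "detected_40C": int("HIGH" in conds),
            "regulation_22C_vs_35C": _call_of(r.low_result),
            "regulation_40C_vs_35C": _call_of(r.high_result),
        })
    return pd.DataFrame(rows)


def write_bilevel_report(report: BiLevelReport, tsv_path: str | Path,
                         json_path: str | Path | None = None) -> None:
    """Write the report TSV plus a machine-readable JSON totals sidecar."""
    from .io import write_json

    frame = report_to_frame(report)
    frame.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        npep, nuniq, ps, pt, py, total = report.totals
        write_json({
            "n_proteins": len(report.rows),
            "n_phosphopeptides": npep,
            "n_unique_phosphopeptides": nuniq,
            "pS": ps, "pT": pt, "pY": py, "total_sites": total,
        }, json_path)
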