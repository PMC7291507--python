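"""Packaged worked-example data for the *A. platensis* C1 study.

Two fixtures ship with the package:

* ``c1_bilevel_phosphopeptides.tsv`` — the published bi-level report's 70
  phosphopeptide evidence rows for 31 proteins, in the package's
  phosphopeptide TSV dialect. Per-protein counts are derived from the rows
  themselves; their column sums reproduce the published totals row
  (70 phosphopeptides, 44 unique, 30 pS + 36 pT + 15 pY = 81 sites).
* ``c1_bilevel_expression_synthetic.tsv`` — the expression side of the same
  report. The publication prints only regulation *directions* per contrast,
  so this synthetic companion carries those directions with nominal
  magnitudes (FC 2.0 up / 0.5 down, p 0.01) that satisfy the significant
  >= 1.5-fold reported filter.

Also provided: the curated eight-site inventory of the multi-sensor hybrid
histidine kinase Hik28 (SPLC1_S041070), all detected only at 22 °C, and a
loader for the optional 527-protein high-stringency site list, which is an
external supplementary download and therefore degrades gracefully when
absent.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .bilevel import BiLevelRecord, identify_bilevel
from .io import read_expression_tsv, read_phosphopeptides_tsv
from .phospho import (PhosphoSite, Phosphopeptide, SiteInventory,
                      aggregate_sites, inventory_from_sites)
from .quant import ExpressionResult, Thresholds

HIK28_ACCESSION = "SPLC1_S041070"
#: Hik28 phosphosites (residue, 1-based position); detected at 22 °C only.
HIK28_SITE_LABELS = ("T598", "T793", "T837", "S805", "S911", "S976",
                     "S1136", "S1482")


def _data_path(name: str) -> Path:
    return Path(resources.files("thermophos").joinpath("data", name))  # type: ignore[arg-type]


def load_bilevel_example_phosphopeptides() -> list[Phosphopeptide]:
    return read_phosphopeptides_tsv(_data_path("c1_bilevel_phosphopeptides.tsv"))


def load_bilevel_example_expression() -> dict[str, dict[str, ExpressionResult]]:
    results = read_expression_tsv(_data_path("c1_bilevel_expression_synthetic.tsv"))
    out: dict[str, dict[str, ExpressionResult]] = {}
    for r in results:
        out.setdefault(r.accession, {})[r.contrast] = r
    return out


def load_bilevel_example_ortholog_tags() -> dict[str, str]:
    import pandas as pd

    df = pd.read_csv(_data_path("c1_bilevel_phosphopeptides.tsv"), sep="\t",
                     dtype=str, keep_default_na=False)
    return {r["accession"]: r["ortholog"] for _, r in df.iterrows()
            if r["ortholog"]}


def bilevel_example_inventories() -> dict[str, SiteInventory]:
    peptides = load_bilevel_example_phosphopeptides()
    by_acc: dict[str, list[Phosphopeptide]] = {}
    for p in peptides:
        by_acc.setdefault(p.accession, []).append(p)
    return {acc: aggregate_sites(recs) for acc, recs in by_acc.items()}


def bilevel_example_records(thresholds: Thresholds | None = None
                           ) -> list[BiLevelRecord]:
    """Run the bi-level identification on the packaged worked example."""
    return identify_bilevel(load_bilevel_example_expression(), bilevel_example_inventories(),
                            thresholds=thresholds,
                            ortholog_tags=load_bilevel_example_ortholog_tags())


def hik28_sites() -> list[PhosphoSite]:
    return [PhosphoSite(HIK28_ACCESSION, lab[0], int(lab[1:]),
                        frozenset({"LOW"}))
            for lab in HIK28_SITE_LABELS]


def hik28_inventory() -> SiteInventory:
    return inventory_from_sites(HIK28_ACCESSION, hik28_sites())


def load_high_stringency_sites(path: str | Path | None) -> list[PhosphoSite] | None:
    """Load a user-supplied high-stringency site list (TSV: accession,
    residue, position), e.g. the study's 527-protein supplementary table.

    Returns ``None`` when no path is given or the file does not exist —
    the list is distributed separately from this package.
    """
    if path is None:
        return None
    path = Path(path)
    if not path.exists():
        return None
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"accession": str, "residue": str})
    return [PhosphoSite(r["accession"], r["residue"], int(r["position"]))
            for _, r in df.iterrows()]
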