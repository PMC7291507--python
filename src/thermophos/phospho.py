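"""Phosphopeptide evidence parsing and per-protein phosphosite aggregation.

Phosphopeptides follow the lowercase-residue convention: a lowercase s/t/y
inside the peptide string marks a phosphorylated residue, and each mark is
paired with a site label such as ``T234t`` giving the residue identity and
its 1-based position in the *protein* sequence. Evidence rows also carry the
temperature conditions under which the peptide was detected and the mass
tolerances of the identifying search, which define the stringency tier:
high stringency is |precursor| <= 20 ppm and |product| <= 50 ppm, low
stringency is <= 50 / <= 100 ppm.

A protein's site inventory deduplicates sites by (residue, position) with a
union of detection conditions, and counts unique phosphopeptides by their
unmodified (case-insensitive) sequence.
"""

from __future__ import annotations

import math
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field

from .quant import CONDITIONS, HIGH, LOW, OPT

SITE_LABEL_RE = re.compile(r"([STY])(\d+)([sty])")

HIGH_STRINGENCY = "HIGH"
LOW_STRINGENCY = "LOW"
#: (precursor ppm, product ppm) bounds per stringency tier.
STRINGENCY_LIMITS = {HIGH_STRINGENCY: (20.0, 50.0),
                     LOW_STRINGENCY: (50.0, 100.0)}


class PhosphoParseError(ValueError):
    """Raised when a phosphopeptide row fails validation."""


@dataclass(frozen=True)
class PhosphoSite:
    accession: str
    residue: str  # S, T or Y
    position: int  # 1-based protein coordinate
    conditions: frozenset[str] = frozenset()

    @property
    def label(self) -> str:
        return f"{self.residue}{self.position}{self.residue.lower()}"


@dataclass(frozen=True)
class Phosphopeptide:
    accession: str
    peptide: str
    site_labels: tuple[tuple[str, int], ...]  # (residue, position)
    conditions_detected: frozenset[str]
    precursor_tol_ppm: float | None = None
    product_tol_ppm: float | None = None
    missed_cleavages: int = 0

    @property
    def base_sequence(self) -> str:
        """Unmodified peptide sequence (uppercase)."""
        return self.peptide.upper()


def parse_site_label(label: str) -> tuple[str, int]:
    m = SITE_LABEL_RE.fullmatch(label)
    if not m:
        raise PhosphoParseError(f"unparseable site label {label!r}")
    residue, pos, tail = m.group(1), int(m.group(2)), m.group(3)
    if tail != residue.lower():
        raise PhosphoParseError(
            f"site label {label!r}: trailing letter does not match residue")
    return residue, pos


def parse_phosphopeptide(row: dict, row_id: str | None = None) -> Phosphopeptide:
    """Validate and build a :class:`Phosphopeptide` from a raw record.

    ``row`` keys: accession, peptide, site_labels (space-separated string or
    list), cond_low/cond_opt/cond_high (truthy flags) or ``conditions``,
    optional precursor_ppm, product_ppm, missed_cleavages.

    Cross-validates the lowercase marks against the labels: the counts must
    agree and the i-th lowercase letter must be the lowercase form of the
    i-th label's residue.
    """
    rid = row_id or row.get("accession", "<row>")
    peptide = str(row.get("peptide", "") or "")
    if not peptide:
        raise PhosphoParseError(f"{rid}: empty peptide")
    if not peptide.upper().isalpha():
        raise PhosphoParseError(f"{rid}: non-letter character in peptide")
    labels_raw = row.get("site_labels", "")
    if isinstance(labels_raw, str):
        labels = labels_raw.split()
    else:
        labels = list(labels_raw)
    sites = tuple(parse_site_label(lab) for lab in labels)

    marks = [c for c in peptide if c in "sty"]
    if len(marks) != len(sites):
        raise PhosphoParseError(
            f"{rid}: {len(marks)} lowercase mark(s) but {len(sites)} label(s)")
    for mark, (residue, pos) in zip(marks, sites):
        if mark != residue.lower():
            raise PhosphoParseError(
                f"{rid}: lowercase {mark!r} does not match label residue "
                f"{residue}{pos}")

    if "conditions" in row:
        conds = frozenset(row["conditions"])
    else:
        flag = {LOW: row.get("cond_low"), OPT: row.get("cond_opt"),
                HIGH: row.get("cond_high")}
        conds = frozenset(c for c, v in flag.items()
                          if v not in (None, "", "0", 0, False))
    bad = conds - set(CONDITIONS)
    if bad:
        raise PhosphoParseError(f"{rid}: unknown condition(s) {sorted(bad)}")

    def _tol(key: str) -> float | None:
        v = row.get(key)
        if v in (None, ""):
            return None
        v = float(v)
        return None if math.isnan(v) else v

    mc = int(row.get("missed_cleavages", 0) or 0)
    if mc > 2:
        raise PhosphoParseError(f"{rid}: {mc} missed cleavages exceeds 2")
    return Phosphopeptide(
        accession=str(row["accession"]), peptide=peptide, site_labels=sites,
        conditions_detected=conds,
        precursor_tol_ppm=_tol("precursor_ppm"),
        product_tol_ppm=_tol("product_ppm"),
        missed_cleavages=mc)


def serialize_phosphopeptide(pep: Phosphopeptide) -> dict:
    """Inverse of :func:`parse_phosphopeptide` (lossless round trip)."""
    return {
        "accession": pep.accession,
        "peptide": pep.peptide,
        "site_labels": " ".join(f"{r}{p}{r.lower()}" for r, p in pep.site_labels),
        "cond_low": int(LOW in pep.conditions_detected),
        "cond_opt": int(OPT in pep.conditions_detected),
        "cond_high": int(HIGH in pep.conditions_detected),
        "precursor_ppm": pep.precursor_tol_ppm,
        "product_ppm": pep.product_tol_ppm,
        "missed_cleavages": pep.missed_cleavages,
    }


def filter_stringency(records: list[Phosphopeptide],
                      tier: str) -> list[Phosphopeptide]:
    """Keep records whose mass tolerances meet the requested tier.

    Records with missing tolerance metadata are excluded with a warning.
    The high-stringency result is always a subset of the low-stringency one.
    """
    if tier not in STRINGENCY_LIMITS:
        raise ValueError(f"tier must be HIGH or LOW, got {tier!r}")
    prec_max, prod_max = STRINGENCY_LIMITS[tier]
    kept, n_missing = [], 0
    for rec in records:
        if rec.precursor_tol_ppm is None or rec.product_tol_ppm is None:
            n_missing += 1
            continue
        if abs(rec.precursor_tol_ppm) <= prec_max and \
                abs(rec.product_tol_ppm) <= prod_max:
            kept.append(rec)
    if n_missing:
        warnings.warn(f"{n_missing} record(s) lacked tolerance metadata and "
                      "were excluded from stringency filtering")
    return kept


@dataclass
class SiteInventory:
    accession: str
    n_phosphopeptides: int = 0
    n_unique_phosphopeptides: int = 0
    sites: list[PhosphoSite] = field(default_factory=list)

    @property
    def counts(self) -> tuple[int, int, int, int]:
        """(pS, pT, pY, total) over distinct sites."""
        c = Counter(s.residue for s in self.sites)
        return (c["S"], c["T"], c["Y"], len(self.sites))

    @property
    def conditions(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for s in self.sites:
            out |= s.conditions
        return out


def aggregate_sites(records: list[Phosphopeptide],
                    accession: str | None = None) -> SiteInventory:
    """Collapse one protein's peptide evidence into a site inventory.

    Sites are deduplicated by (residue, position) and their detection
    conditions unioned across all peptides covering the site. The result is
    independent of input order.
    """
    accs = {r.accession for r in records}
    if len(accs) > 1:
        raise ValueError(f"records span multiple accessions: {sorted(accs)}")
    if accession is None:
        if not records:
            raise ValueError("empty input needs an explicit accession")
        accession = records[0].accession
    elif accs and accs != {accession}:
        raise ValueError(f"records belong to {accs.pop()!r}, not {accession!r}")

    site_conds: dict[tuple[str, int], set[str]] = {}
    for rec in records:
        for residue, pos in rec.site_labels:
            site_conds.setdefault((residue, pos), set()) \
                .update(rec.conditions_detected)
    sites = [PhosphoSite(accession, r, p, frozenset(cs))
             for (r, p), cs in sorted(site_conds.items(),
                                      key=lambda kv: (kv[0][1], kv[0][0]))]
    return SiteInventory(
        accession=accession,
        n_phosphopeptides=len(records),
        n_unique_phosphopeptides=len({r.base_sequence for r in records}),
        sites=sites)


def inventory_from_sites(accession: str,
                         sites: list[PhosphoSite]) -> SiteInventory:
    """Build an inventory from a curated site list (no peptide evidence)."""
    dedup: dict[tuple[str, int], set[str]] = {}
    for s in sites:
        if s.accession != accession:
            raise ValueError(f"site {s.label} belongs to {s.accession!r}")
        dedup.setdefault((s.residue, s.position), set()).update(s.conditions)
    merged = [PhosphoSite(accession, r, p, frozenset(cs))
              for (r, p), cs in sorted(dedup.items(),
                                       key=lambda kv: (kv[0][1], kv[0][0]))]
    return SiteInventory(accession, 0, 0, merged)


def site_type_ratio(sites: list[PhosphoSite]) -> tuple[float, float, float]:
    """(pS%, pT%, pY%) over distinct sites, rounded to one decimal."""
    distinct = {(s.accession, s.residue, s.position) for s in sites}
    if not distinct:
        raise ValueError("cannot compute a site-type ratio for an empty set")
    c = Counter(residue for _, residue, _ in distinct)
    n = len(distinct)
    return tuple(round(100.0 * c[r] / n, 1) for r in "STY")  # type: ignore[return-value]
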