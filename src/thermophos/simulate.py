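"""Synthetic study-design generator with planted ground truth.

Emulates the three-condition temperature-shift design (22/35/40 °C, three
biological replicates) end to end: log-normal protein abundances with
planted fold changes, a sub-floor stratum for the 3x-noise filter,
condition-dependent phosphopeptide detections emitted as tryptic fragments,
an orthologous proteome pair with controlled sequence divergence, and a
bait→prey template interaction network. Every sub-generator draws from a
child of one global seed (numpy SeedSequence spawning), so a dataset is
fully reproducible from its config.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .phospho import Phosphopeptide, parse_phosphopeptide
from .quant import CONDITIONS, HIGH, LOW, OPT, AbundanceMatrix

# Robinson & Robinson background amino-acid frequencies.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_FREQS = np.array([
    0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199, 0.05142,
    0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264, 0.05129, 0.07120,
    0.05841, 0.06441, 0.01330, 0.03216])
AA_FREQS = AA_FREQS / AA_FREQS.sum()

PATHWAY_NAMES = (
    "Metabolic pathways", "Ribosome", "Oxidative phosphorylation",
    "Photosynthesis", "Nitrogen metabolism",
    "Carbon fixation in photosynthetic organisms", "Carbon metabolism",
    "Biosynthesis of amino acids", "Purine metabolism",
    "Aminoacyl-tRNA biosynthesis")


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for dataset generation.

    Defaults mirror the experimental design: three conditions with three
    biological replicates, replicate noise of 0.2 on the log2 scale, planted
    effects of at least log2(1.5), and a 5% per-site ortholog divergence.
    """

    seed: int = 0
    n_proteins: int = 500
    n_template_proteins: int = 100
    ortholog_fraction: float = 0.8
    divergence: float = 0.05
    de_fraction: dict[str, float] = field(
        default_factory=lambda: {LOW: 0.1, HIGH: 0.1})
    log2_fc_range: tuple[float, float] = (math.log2(1.5), 2.0)
    replicate_sd: float = 0.2
    n_replicates: int = 3
    noise_floor: float = 100.0
    low_signal_fraction: float = 0.02
    phospho_fraction: float = 0.15
    sites_per_protein: tuple[int, int] = (1, 3)
    detection_prob: dict[str, float] = field(
        default_factory=lambda: {LOW: 0.8, OPT: 0.6, HIGH: 0.8})
    low_stringency_fraction: float = 0.2
    n_template_edges: int = 150
    seq_length_range: tuple[int, int] = (80, 200)

    def __post_init__(self) -> None:
        for frac in (self.ortholog_fraction, self.divergence,
                     self.phospho_fraction, self.low_signal_fraction,
                     *self.de_fraction.values(), *self.detection_prob.values()):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions/probabilities must be in [0, 1]")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        if self.sites_per_protein[0] < 1:
            raise ValueError("sites_per_protein minimum must be >= 1")


@dataclass
class SyntheticTruth:
    dataset_id: str
    #: contrast -> {accession: planted signed log2 fold change}
    de_log2fc: dict[str, dict[str, float]]
    #: planted sites: accession -> list of (residue, position, conditions)
    phospho_sites: dict[str, list[tuple[str, int, list[str]]]]
    ortholog_pairs: list[tuple[str, str]]  # (template, query)
    template_edges: list[tuple[str, str]]
    expected_bilevel: list[str]
    expected_transferred_edges: list[tuple[str, str]]
    n_low_signal_planted: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticDataset:
    config: SimConfig
    abundance: AbundanceMatrix
    phosphopeptides: list[Phosphopeptide]
    template_proteome: dict[str, str]
    query_proteome: dict[str, str]
    template_edges: list[tuple[str, str, str]]  # (bait, prey, evidence)
    pathway_annotation: dict[str, set[str]]
    truth: SyntheticTruth


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ORDER), size=length, p=AA_FREQS))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0:
        return seq
    out = list(seq)
    hits = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hits):
        choices = [a for a in AA_ORDER if a != seq[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def _tryptic_fragment(seq: str, pos0: int, max_missed: int = 2) -> tuple[str, int]:
    """Tryptic peptide (start0, sequence) covering 0-based position ``pos0``.

    Cleaves after K/R not followed by P; extends across at most
    ``max_missed`` internal cleavage sites to reach length >= 6.
    """
    cuts = [0] + [i + 1 for i in range(len(seq) - 1)
                  if seq[i] in "KR" and seq[i + 1] != "P"] + [len(seq)]
    seg = next(k for k in range(len(cuts) - 1)
               if cuts[k] <= pos0 < cuts[k + 1])
    start_seg = end_seg = seg
    while cuts[end_seg + 1] - cuts[start_seg] < 6 and \
            (end_seg - start_seg) < max_missed:
        if end_seg + 2 < len(cuts):
            end_seg += 1
        elif start_seg > 0:
            start_seg -= 1
        else:
            break
    start = cuts[start_seg]
    return seq[start:cuts[end_seg + 1]], start


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate all pipeline inputs plus the planted truth."""
    ss = np.random.SeedSequence(config.seed)
    (seq_ss, abund_ss, de_ss, phos_ss, edge_ss, path_ss) = ss.spawn(6)
    rng_seq = np.random.default_rng(seq_ss)
    rng_ab = np.random.default_rng(abund_ss)
    rng_de = np.random.default_rng(de_ss)
    rng_ph = np.random.default_rng(phos_ss)
    rng_ed = np.random.default_rng(edge_ss)
    rng_pa = np.random.default_rng(path_ss)

    lo, hi = config.seq_length_range
    template = {f"T{i:04d}": _random_sequence(rng_seq,
                                              int(rng_seq.integers(lo, hi + 1)))
                for i in range(1, config.n_template_proteins + 1)}
    n_orth = round(config.ortholog_fraction * config.n_template_proteins)
    if n_orth > config.n_proteins:
        raise ValueError("more planted orthologs than query proteins")
    query: dict[str, str] = {}
    ortholog_pairs = []
    t_names = sorted(template)
    for i in range(1, config.n_proteins + 1):
        qname = f"Q{i:04d}"
        if i <= n_orth:
            tname = t_names[i - 1]
            query[qname] = _mutate(rng_seq, template[tname], config.divergence)
            ortholog_pairs.append((tname, qname))
        else:
            query[qname] = _random_sequence(
                rng_seq, int(rng_seq.integers(lo, hi + 1)))
    q_names = sorted(query)

    # --- abundances with planted differential expression ------------------
    de_log2fc: dict[str, dict[str, float]] = {}
    for stress in (LOW, HIGH):
        n_de = round(config.de_fraction.get(stress, 0.0) * config.n_proteins)
        chosen = rng_de.choice(q_names, size=n_de, replace=False)
        fcs = rng_de.uniform(*config.log2_fc_range, size=n_de)
        signs = rng_de.choice([-1.0, 1.0], size=n_de)
        de_log2fc[f"{stress}_vs_{OPT}"] = {
            acc: float(s * f) for acc, f, s in zip(chosen, fcs, signs)}

    baselines = {acc: float(rng_ab.normal(17.0, 1.5)) for acc in q_names}
    rows = []
    for acc in q_names:
        for cond in CONDITIONS:
            shift = de_log2fc.get(f"{cond}_vs_{OPT}", {}).get(acc, 0.0) \
                if cond != OPT else 0.0
            for rep in range(1, config.n_replicates + 1):
                x = baselines[acc] + shift + rng_ab.normal(0.0, config.replicate_sd)
                rows.append((acc, cond, rep, float(2.0 ** x), config.noise_floor))
    frame = pd.DataFrame(rows, columns=list(AbundanceMatrix.COLUMNS))

    # plant a sub-floor stratum on proteins without planted effects so the
    # 3x-noise filter has known casualties that do not disturb DE recovery
    de_accs = set().union(*[set(d) for d in de_log2fc.values()]) \
        if de_log2fc else set()
    eligible = frame.index[~frame["accession"].isin(de_accs)]
    n_low = round(config.low_signal_fraction * len(frame))
    low_idx = rng_ab.choice(eligible, size=min(n_low, len(eligible)),
                            replace=False)
    frame.loc[low_idx, "intensity"] = rng_ab.uniform(
        0.0, 2.999 * config.noise_floor, size=len(low_idx))
    matrix = AbundanceMatrix(frame)

    # --- phosphopeptides ---------------------------------------------------
    n_phos = round(config.phospho_fraction * config.n_proteins)
    phospho_accs = sorted(rng_ph.choice(q_names, size=n_phos, replace=False))
    peptides: list[Phosphopeptide] = []
    planted_sites: dict[str, list[tuple[str, int, list[str]]]] = {}
    smin, smax = config.sites_per_protein
    conds_order = list(CONDITIONS)
    for acc in phospho_accs:
        seq = query[acc]
        sty = [i for i, a in enumerate(seq) if a in "STY"]
        if not sty:
            continue
        k = min(int(rng_ph.integers(smin, smax + 1)), len(sty))
        positions = sorted(rng_ph.choice(sty, size=k, replace=False))
        planted_sites[acc] = []
        for pos0 in positions:
            frag, start = _tryptic_fragment(seq, int(pos0))
            marked = "".join(
                c.lower() if start + j == pos0 else c
                for j, c in enumerate(frag))
            detected = [c for c in conds_order
                        if rng_ph.random() < config.detection_prob[c]]
            if not detected:
                detected = [LOW]
            residue = seq[pos0]
            label = f"{residue}{pos0 + 1}{residue.lower()}"
            if rng_ph.random() < config.low_stringency_fraction:
                prec = float(rng_ph.uniform(25.0, 45.0))
                prod = float(rng_ph.uniform(55.0, 95.0))
            else:
                prec = float(rng_ph.uniform(1.0, 15.0))
                prod = float(rng_ph.uniform(5.0, 40.0))
            base = marked.upper()
            mc = sum(1 for i in range(len(base) - 1)
                     if base[i] in "KR" and base[i + 1] != "P")
            row = {"accession": acc, "peptide": marked, "site_labels": label,
                   "conditions": detected, "precursor_ppm": prec,
                   "product_ppm": prod, "missed_cleavages": min(mc, 2)}
            peptides.append(parse_phosphopeptide(row, row_id=f"sim:{acc}"))
            planted_sites[acc].append((residue, int(pos0) + 1, detected))

    # --- template network --------------------------------------------------
    edges: list[tuple[str, str, str]] = []
    seen = set()
    while len(edges) < min(config.n_template_edges,
                           len(t_names) * (len(t_names) - 1)):
        b, p = rng_ed.choice(t_names, size=2, replace=False)
        if (b, p) not in seen:
            seen.add((b, p))
            edges.append((str(b), str(p), "Y2H"))

    mapped = {t for t, _ in ortholog_pairs}
    q_of = {t: q for t, q in ortholog_pairs}
    expected_edges = sorted((q_of[b], q_of[p]) for b, p, _ in edges
                            if b in mapped and p in mapped)

    annotation: dict[str, set[str]] = {}
    for acc in q_names:
        if rng_pa.random() < 0.5:
            k = int(rng_pa.integers(1, 3))
            annotation[acc] = set(rng_pa.choice(PATHWAY_NAMES, size=k,
                                                replace=False))

    fc_min = math.log2(1.5)
    strong = {acc for d in de_log2fc.values() for acc, fc in d.items()
              if abs(fc) >= fc_min}
    expected_bilevel = sorted(strong & set(planted_sites))

    truth = SyntheticTruth(
        dataset_id=f"thermophos-sim-{config.seed}",
        de_log2fc=de_log2fc,
        phospho_sites=planted_sites,
        ortholog_pairs=ortholog_pairs,
        template_edges=[(b, p) for b, p, _ in edges],
        expected_bilevel=expected_bilevel,
        expected_transferred_edges=expected_edges,
        n_low_signal_planted=len(low_idx))
    return SyntheticDataset(config, matrix, peptides, template, query,
                            edges, annotation, truth)


@dataclass
class StageRecovery:
    n_true: int
    n_called: int
    n_correct: int

    @property
    def sensitivity(self) -> float:
        return self.n_correct / self.n_true if self.n_true else 0.0

    @property
    def precision(self) -> float:
        return self.n_correct / self.n_called if self.n_called else 0.0


def _is_directional_hit(result, planted_log2fc: float,
                        p_cutoff: float = 0.05) -> bool:
    import numpy as _np

    if not (_np.isfinite(result.fold_change) and _np.isfinite(result.p_value)):
        return False
    if not result.p_value <= p_cutoff:
        return False
    return (result.fold_change > 1.0) == (planted_log2fc > 0)


def evaluate_recovery(truth: SyntheticTruth,
                      de_results: dict[str, dict] | None = None,
                      detected_sites: dict[str, list[tuple[str, int]]] | None = None,
                      rbh_pairs: list[tuple[str, str]] | None = None,
                      inferred_edges: list[tuple[str, str]] | None = None,
                      bilevel_reported: list[str] | None = None,
                      dataset_id: str | None = None,
                      p_cutoff: float = 0.05) -> dict[str, StageRecovery]:
    """Confusion counts per pipeline stage against the planted truth.

    ``de_results`` maps contrast -> {accession: ExpressionResult}. A planted
    protein counts as recovered when the test finds it significant
    (p <= ``p_cutoff``) in the planted direction — the significance step of
    the workflow; the 1.5-fold reporting filter is a separate downstream
    cut. The "called" denominator for precision is the set of significant
    directional findings. ``rbh_pairs`` are (query, template) as produced by
    reciprocal_best_hits with the query proteome first.
    """
    if dataset_id is not None and dataset_id != truth.dataset_id:
        raise ValueError(
            f"run {dataset_id!r} does not match truth {truth.dataset_id!r}")
    report: dict[str, StageRecovery] = {}
    if de_results is not None:
        import numpy as _np

        for contrast, planted in truth.de_log2fc.items():
            results = de_results.get(contrast, {})
            correct = sum(
                1 for acc, fc in planted.items()
                if acc in results and _is_directional_hit(results[acc], fc,
                                                          p_cutoff))
            n_called = sum(
                1 for r in results.values()
                if _np.isfinite(r.p_value) and r.p_value <= p_cutoff)
            report[f"de_{contrast}"] = StageRecovery(
                len(planted), n_called, correct)
    if detected_sites is not None:
        true_sites = {(acc, r, p) for acc, sites in truth.phospho_sites.items()
                      for r, p, _ in sites}
        found = {(acc, r, p) for acc, sites in detected_sites.items()
                 for r, p in sites}
        report["phospho_sites"] = StageRecovery(
            len(true_sites), len(found), len(true_sites & found))
    if rbh_pairs is not None:
        true_pairs = {(q, t) for t, q in truth.ortholog_pairs}
        got = set(rbh_pairs)
        report["rbh"] = StageRecovery(len(true_pairs), len(got),
                                      len(true_pairs & got))
    if inferred_edges is not None:
        expected = set(map(tuple, truth.expected_transferred_edges))
        got = set(inferred_edges)
        report["transfer"] = StageRecovery(len(expected), len(got),
                                           len(expected & got))
    if bilevel_reported is not None:
        expected = set(truth.expected_bilevel)
        got = set(bilevel_reported)
        report["bilevel"] = StageRecovery(len(expected), len(got),
                                          len(expected & got))
    return report
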