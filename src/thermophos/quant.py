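"""Quantitative label-free proteome analysis.

Protein abundances are MS intensities measured across three growth
temperatures of *Arthrospira platensis* C1 — a cold shift (22 °C), the
optimal temperature (35 °C) and a heat shift (40 °C) — with biological
replicates per condition. The analysis chain is:

1. signal-threshold filtering (intensities below ``noise_multiplier`` times
   the per-measurement noise estimate are treated as missing),
2. per-protein differential testing of each stress condition against the
   optimum (two-sided Student t-test on log2 intensities; fold change as the
   ratio of linear-scale means),
3. assignment of a cross-condition regulation class from the two contrasts,
4. average-linkage hierarchical clustering of mean log2 expression profiles.

Significance and fold-change thresholds are inclusive (p <= 0.05,
FC >= 1.5 or <= 1/1.5); the noise filter is strict (< 3x noise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

LOW = "LOW"
OPT = "OPT"
HIGH = "HIGH"
CONDITIONS = (LOW, OPT, HIGH)
#: Growth temperature (°C) represented by each condition label.
TEMPERATURES = {LOW: 22, OPT: 35, HIGH: 40}

UP = "UP"
DOWN = "DOWN"
NOT_SIGNIFICANT = "NOT_SIGNIFICANT"
UNTESTABLE = "UNTESTABLE"

REGULATION_CLASSES = (
    "UP_UP", "DOWN_DOWN", "UP22_DOWN40", "DOWN22_UP40",
    "LOW_ONLY_UP", "LOW_ONLY_DOWN", "HIGH_ONLY_UP", "HIGH_ONLY_DOWN",
    "NONE",
)


@dataclass(frozen=True)
class Thresholds:
    """Cut-offs used throughout the pipeline.

    noise_multiplier
        Signals lower than this multiple of the noise estimate are removed.
    p_cutoff, fc_cutoff
        Inclusive significance and linear fold-change cut-offs for calling
        a protein up-/down-regulated.
    rbh_evalue
        Strict upper bound on the e-value of a reciprocal best hit.
    adjust_pvalues
        Apply Benjamini–Hochberg correction before calling (off by default;
        the headline analysis uses raw p-values).
    """

    noise_multiplier: float = 3.0
    p_cutoff: float = 0.05
    fc_cutoff: float = 1.5
    rbh_evalue: float = 1e-10
    adjust_pvalues: bool = False

    def __post_init__(self) -> None:
        if min(self.noise_multiplier, self.p_cutoff, self.fc_cutoff,
               self.rbh_evalue) <= 0:
            raise ValueError("thresholds must be strictly positive")
        if self.fc_cutoff < 1:
            raise ValueError("fc_cutoff must be >= 1")


@dataclass
class AbundanceMatrix:
    """Long-format protein x (condition, replicate) intensity table.

    ``data`` columns: accession, condition, replicate, intensity, noise.
    Missing intensities are NaN. Intensities and noise share arbitrary MS
    units and must be nonnegative.
    """

    data: pd.DataFrame

    COLUMNS = ("accession", "condition", "replicate", "intensity", "noise")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"abundance table lacks columns: {sorted(missing)}")
        bad_cond = set(self.data["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown conditions: {sorted(bad_cond)}")
        present = self.data["intensity"].dropna()
        if (present < 0).any():
            raise ValueError("negative intensity encountered")
        dup = self.data.duplicated(["accession", "condition", "replicate"])
        if dup.any():
            raise ValueError("duplicate (accession, condition, replicate) rows")

    @property
    def proteins(self) -> list[str]:
        return sorted(self.data["accession"].unique())

    def values(self, accession: str, condition: str) -> np.ndarray:
        """Present (non-missing) intensities for one protein/condition."""
        sel = self.data[(self.data["accession"] == accession)
                        & (self.data["condition"] == condition)]
        return sel["intensity"].dropna().to_numpy(float)

    def condition_means(self, log2: bool = True) -> pd.DataFrame:
        """Per-protein mean profile across conditions (log2 by default)."""
        d = self.data.copy()
        if log2:
            d["intensity"] = np.log2(d["intensity"])
        wide = d.pivot_table(index="accession", columns="condition",
                             values="intensity", aggfunc="mean")
        return wide.reindex(index=self.proteins, columns=list(CONDITIONS))


@dataclass(frozen=True)
class ExpressionResult:
    accession: str
    contrast: str  # "LOW_vs_OPT" or "HIGH_vs_OPT"
    fold_change: float
    p_value: float
    call: str
    reason: str = ""

    @property
    def log2_fc(self) -> float:
        return float(np.log2(self.fold_change)) if self.fold_change > 0 else float("nan")


@dataclass
class FilterResult:
    matrix: AbundanceMatrix
    n_removed: int
    removed: list[tuple[str, str, int]] = field(default_factory=list)


def apply_signal_threshold(matrix: AbundanceMatrix,
                           thresholds: Thresholds | None = None) -> FilterResult:
    """Remove intensities strictly below ``noise_multiplier`` x noise.

    Values exactly at the threshold are kept. Every present intensity must
    come with a noise estimate; otherwise a :class:`ValueError` names the
    offending measurement.
    """
    thresholds = thresholds or Thresholds()
    d = matrix.data.copy()
    present = d["intensity"].notna()
    no_noise = present & d["noise"].isna()
    if no_noise.any():
        row = d[no_noise].iloc[0]
        raise ValueError(
            "missing noise estimate for measurement "
            f"({row['accession']}, {row['condition']}, rep {row['replicate']})")
    below = present & (d["intensity"] < thresholds.noise_multiplier * d["noise"])
    removed = [(r["accession"], r["condition"], int(r["replicate"]))
               for _, r in d[below].iterrows()]
    d.loc[below, "intensity"] = np.nan
    return FilterResult(AbundanceMatrix(d), int(below.sum()), removed)


def _two_sample_t(stress_log2: np.ndarray, opt_log2: np.ndarray) -> float:
    """Two-sided pooled-variance (Student) t-test p-value on log2 values."""
    if np.ptp(stress_log2) == 0 and np.ptp(opt_log2) == 0:
        # degenerate zero-variance case: identical means are maximally
        # non-significant, distinct means maximally significant
        return 1.0 if stress_log2[0] == opt_log2[0] else 0.0
    return float(stats.ttest_ind(stress_log2, opt_log2, equal_var=True).pvalue)


def test_against_zero(log2_values: np.ndarray) -> float:
    """One-group two-sided t-test of mean log2 signal against zero.

    Single-condition significance mode; not part of the stress-vs-optimum
    contrast path.
    """
    arr = np.asarray(log2_values, float)
    if arr.size < 2:
        raise ValueError("need at least two replicates")
    if np.ptp(arr) == 0:
        return 1.0 if arr[0] == 0 else 0.0
    return float(stats.ttest_1samp(arr, 0.0).pvalue)


def _assign_call(fc: float, p: float, thresholds: Thresholds) -> str:
    if p <= thresholds.p_cutoff:
        if fc >= thresholds.fc_cutoff:
            return UP
        if fc <= 1.0 / thresholds.fc_cutoff:
            return DOWN
    return NOT_SIGNIFICANT


def make_result(accession: str, contrast: str, fold_change: float,
                p_value: float, thresholds: Thresholds | None = None) -> ExpressionResult:
    """Build an :class:`ExpressionResult` from a precomputed FC/p pair."""
    thresholds = thresholds or Thresholds()
    return ExpressionResult(accession, contrast, fold_change, p_value,
                            _assign_call(fold_change, p_value, thresholds))


def test_differential(matrix: AbundanceMatrix, stress: str,
                      thresholds: Thresholds | None = None) -> list[ExpressionResult]:
    """Test every protein in ``stress`` against the optimal condition.

    Fold change is mean(stress)/mean(OPT) on linear intensities; the p-value
    comes from a two-sided pooled t-test on log2 intensities. Proteins with
    fewer than two present replicates in either condition are UNTESTABLE.
    """
    if stress not in (LOW, HIGH):
        raise ValueError(f"stress must be LOW or HIGH, got {stress!r}")
    thresholds = thresholds or Thresholds()
    contrast = f"{stress}_vs_{OPT}"
    results: list[ExpressionResult] = []
    for acc in matrix.proteins:
        sv = matrix.values(acc, stress)
        ov = matrix.values(acc, OPT)
        if len(sv) < 2 or len(ov) < 2:
            results.append(ExpressionResult(
                acc, contrast, float("nan"), float("nan"), UNTESTABLE,
                reason="fewer than 2 present replicates"))
            continue
        opt_mean = float(ov.mean())
        if opt_mean <= 0:
            results.append(ExpressionResult(
                acc, contrast, float("nan"), float("nan"), UNTESTABLE,
                reason="non-positive optimal-condition mean"))
            continue
        fc = float(sv.mean()) / opt_mean
        p = _two_sample_t(np.log2(sv), np.log2(ov))
        results.append(ExpressionResult(acc, contrast, fc, p,
                                        _assign_call(fc, p, thresholds)))
    if thresholds.adjust_pvalues:
        results = _bh_adjust(results, thresholds)
    return results


def _bh_adjust(results: list[ExpressionResult],
               thresholds: Thresholds) -> list[ExpressionResult]:
    testable = [i for i, r in enumerate(results) if r.call != UNTESTABLE]
    if not testable:
        return results
    adj = stats.false_discovery_control(
        [results[i].p_value for i in testable], method="bh")
    out = list(results)
    for i, q in zip(testable, adj):
        r = results[i]
        out[i] = replace(r, p_value=float(q),
                         call=_assign_call(r.fold_change, float(q), thresholds))
    return out


def one_way_anova(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Per-protein one-way ANOVA across the three conditions (log2 scale).

    Reported as a descriptive statistic; regulation calls derive from the
    pairwise contrasts.
    """
    rows = []
    for acc in matrix.proteins:
        groups = [np.log2(matrix.values(acc, c)) for c in CONDITIONS]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2 or all(np.ptp(g) == 0 for g in groups):
            rows.append((acc, float("nan"), float("nan")))
            continue
        f, p = stats.f_oneway(*groups)
        rows.append((acc, float(f), float(p)))
    return pd.DataFrame(rows, columns=["accession", "F", "p_value"])


def classify_regulation(low: ExpressionResult, high: ExpressionResult) -> str:
    """Map the (22 °C call, 40 °C call) pair onto a regulation class."""
    if low.accession != high.accession:
        raise ValueError(
            f"accession mismatch: {low.accession!r} vs {high.accession!r}")
    table = {
        (UP, UP): "UP_UP",
        (DOWN, DOWN): "DOWN_DOWN",
        (UP, DOWN): "UP22_DOWN40",
        (DOWN, UP): "DOWN22_UP40",
    }
    pair = (low.call, high.call)
    if pair in table:
        return table[pair]
    if low.call == UP:
        return "LOW_ONLY_UP"
    if low.call == DOWN:
        return "LOW_ONLY_DOWN"
    if high.call == UP:
        return "HIGH_ONLY_UP"
    if high.call == DOWN:
        return "HIGH_ONLY_DOWN"
    return "NONE"


@dataclass
class Dendrogram:
    """Average-linkage clustering result over per-condition mean profiles."""

    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    excluded: list[str] = field(default_factory=list)

    def merge_heights(self) -> list[float]:
        return [float(h) for h in self.linkage[:, 2]]

    def to_newick(self) -> str:
        """Serialize as Newick; branch lengths are merge-height differences
        so leaf-to-root depth equals the final merge height (ultrametric)."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height - 0.0:.6g}"
            inner = ",".join(rec(c, node.dist) for c in (node.left, node.right))
            return f"({inner}):{parent_height - node.dist:.6g}"

        root = tree
        inner = ",".join(rec(c, root.dist) for c in (root.left, root.right))
        return f"({inner});"


def cluster_expression_profiles(matrix: AbundanceMatrix) -> Dendrogram:
    """Agglomerative average-linkage clustering (Euclidean) of mean log2
    condition profiles. Proteins with any missing condition mean are
    excluded with a warning."""
    means = matrix.condition_means(log2=True)
    complete = means.dropna()
    excluded = sorted(set(means.index) - set(complete.index))
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} protein(s) with incomplete profiles: "
            f"{excluded[:5]}{'...' if len(excluded) > 5 else ''}")
    if len(complete) < 2:
        raise ValueError("need at least 2 proteins with complete profiles")
    z = hierarchy.linkage(complete.to_numpy(float), method="average",
                          metric="euclidean")
    return Dendrogram(list(complete.index), z, excluded)
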