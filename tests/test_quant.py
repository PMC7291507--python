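"""Quantitative-proteome stage: signal filter, differential tests,
regulation classes and expression clustering."""

import math

import numpy as np
import pytest

import dendropy

from thermophos.quant import (DOWN, NOT_SIGNIFICANT, UNTESTABLE, UP,
                              ExpressionResult, Thresholds,
                              apply_signal_threshold, classify_regulation,
                              cluster_expression_profiles, make_result)
from thermophos.quant import test_differential as run_differential
from .conftest import make_matrix, matrix_from_log2
from .oracles import average_linkage_naive, pooled_t_pvalue


@pytest.mark.parametrize("intensity,removed", [(299.0, True), (300.0, False),
                                               (300.5, False), (0.0, True)])
def test_signal_threshold_boundary_is_strict(intensity, removed):
    """Values strictly below 3x noise are removed; equality is kept."""
    m = make_matrix([("P1", "OPT", 1, intensity, 100.0)])
    res = apply_signal_threshold(m)
    assert res.n_removed == (1 if removed else 0)
    present = res.matrix.data["intensity"].notna().iloc[0]
    assert present != removed


def test_signal_threshold_removes_planted_count(rng):
    """A matrix with exactly 40 of 400 values planted below 3x noise loses
    exactly those 40."""
    noise = 50.0
    rows = []
    k = 0
    low_positions = set(rng.choice(400, size=40, replace=False))
    for p in range(100):
        for cond, rep in (("LOW", 1), ("OPT", 1), ("HIGH", 1), ("OPT", 2)):
            if k in low_positions:
                val = float(rng.uniform(0, 3 * noise * 0.999))
            else:
                val = float(rng.uniform(3 * noise, 10 * noise))
            rows.append((f"P{p:03d}", cond, rep, val, noise))
            k += 1
    res = apply_signal_threshold(make_matrix(rows))
    assert res.n_removed == 40


def test_signal_threshold_idempotent(rng):
    rows = [(f"P{i}", "OPT", 1, float(v), 100.0)
            for i, v in enumerate(rng.uniform(0, 1000, size=50))]
    once = apply_signal_threshold(make_matrix(rows))
    twice = apply_signal_threshold(once.matrix)
    assert twice.n_removed == 0
    assert once.matrix.data["intensity"].equals(twice.matrix.data["intensity"])


def test_signal_threshold_missing_noise_names_measurement():
    m = make_matrix([("P7", "HIGH", 2, 500.0, np.nan)])
    with pytest.raises(ValueError, match=r"P7.*HIGH.*2"):
        apply_signal_threshold(m)


def test_differential_identical_vectors_not_significant():
    m = matrix_from_log2({"P1": {"LOW": [10, 12, 11], "OPT": [10, 12, 11]}})
    (r,) = run_differential(m, "LOW")
    assert r.fold_change == pytest.approx(1.0)
    assert r.call == NOT_SIGNIFICANT


def test_differential_matches_closed_form_t():
    """FC and p for log2 {10,12,11} vs {20,22,21} reproduce the textbook
    pooled-t computation on those six numbers."""
    stress = [10.0, 12.0, 11.0]
    opt = [20.0, 22.0, 21.0]
    m = matrix_from_log2({"P1": {"LOW": stress, "OPT": opt}})
    (r,) = run_differential(m, "LOW")
    expected_fc = np.mean([2.0 ** v for v in stress]) / \
        np.mean([2.0 ** v for v in opt])
    assert r.fold_change == pytest.approx(expected_fc, rel=1e-12)
    assert r.fold_change < 1  # ~2**-10: strongly down
    assert r.p_value == pytest.approx(pooled_t_pvalue(stress, opt), rel=1e-9)
    assert r.call == DOWN


def test_thresholds_are_inclusive():
    """FC exactly 1.5 with p exactly 0.05 is still called UP."""
    r = make_result("P1", "LOW_vs_OPT", 1.5, 0.05)
    assert r.call == UP
    r = make_result("P1", "LOW_vs_OPT", 1.0 / 1.5, 0.05)
    assert r.call == DOWN
    assert make_result("P1", "LOW_vs_OPT", 1.49, 0.05).call == NOT_SIGNIFICANT
    assert make_result("P1", "LOW_vs_OPT", 1.5, 0.051).call == NOT_SIGNIFICANT


def test_fold_change_reciprocal_under_condition_swap(rng):
    """Swapping the roles of stress and optimum inverts the fold change."""
    m = matrix_from_log2({"P1": {"LOW": list(rng.normal(12, 1, 3)),
                                 "OPT": list(rng.normal(10, 1, 3))}})
    (fwd,) = run_differential(m, "LOW")
    swapped = m.data.copy()
    swapped["condition"] = swapped["condition"].map(
        {"LOW": "OPT", "OPT": "LOW"})
    (rev,) = run_differential(type(m)(swapped), "LOW")
    assert fwd.fold_change * rev.fold_change == pytest.approx(1.0, abs=1e-12)


def test_differential_untestable_cases():
    m = matrix_from_log2({"P1": {"LOW": [10.0], "OPT": [10, 11, 12]},
                          "P2": {"LOW": [10, 11], "OPT": [None, None, 11.0]}})
    res = {r.accession: r for r in run_differential(m, "LOW")}
    assert res["P1"].call == UNTESTABLE
    assert res["P2"].call == UNTESTABLE
    assert "replicates" in res["P1"].reason


def _expected_class(lc, hc):
    # independent hand enumeration of the 4x4 call grid
    if (lc, hc) == (UP, UP):
        return "UP_UP"
    if (lc, hc) == (DOWN, DOWN):
        return "DOWN_DOWN"
    if (lc, hc) == (UP, DOWN):
        return "UP22_DOWN40"
    if (lc, hc) == (DOWN, UP):
        return "DOWN22_UP40"
    if lc == UP:
        return "LOW_ONLY_UP"
    if lc == DOWN:
        return "LOW_ONLY_DOWN"
    if hc == UP:
        return "HIGH_ONLY_UP"
    if hc == DOWN:
        return "HIGH_ONLY_DOWN"
    return "NONE"


def test_classify_regulation_covers_full_call_grid():
    calls = (UP, DOWN, NOT_SIGNIFICANT, UNTESTABLE)
    for lc in calls:
        for hc in calls:
            low = ExpressionResult("P", "LOW_vs_OPT", 1.0, 1.0, lc)
            high = ExpressionResult("P", "HIGH_vs_OPT", 1.0, 1.0, hc)
            assert classify_regulation(low, high) == _expected_class(lc, hc)


def test_classify_regulation_rejects_accession_mismatch():
    low = ExpressionResult("A", "LOW_vs_OPT", 1.0, 1.0, UP)
    high = ExpressionResult("B", "HIGH_vs_OPT", 1.0, 1.0, UP)
    with pytest.raises(ValueError, match="mismatch"):
        classify_regulation(low, high)


def test_cluster_identical_profiles_merge_at_zero():
    m = matrix_from_log2({
        "A": {"LOW": [10.0], "OPT": [11.0], "HIGH": [12.0]},
        "B": {"LOW": [10.0], "OPT": [11.0], "HIGH": [12.0]},
        "C": {"LOW": [15.0], "OPT": [15.0], "HIGH": [15.0]}})
    dend = cluster_expression_profiles(m)
    first = dend.linkage[0]
    assert first[2] == pytest.approx(0.0)
    merged = {dend.labels[int(first[0])], dend.labels[int(first[1])]}
    assert merged == {"A", "B"}


def test_cluster_matches_naive_average_linkage(rng):
    profiles = {f"P{i}": list(rng.normal(12, 2, 3)) for i in range(5)}
    m = matrix_from_log2({acc: {"LOW": [p[0]], "OPT": [p[1]], "HIGH": [p[2]]}
                          for acc, p in profiles.items()})
    dend = cluster_expression_profiles(m)
    expected = average_linkage_naive(profiles)

    # replay scipy's merge list into member sets
    label = {i: frozenset([acc]) for i, acc in enumerate(dend.labels)}
    n = len(dend.labels)
    for step, (a, b, h, _) in enumerate(dend.linkage):
        sa, sb = label[int(a)], label[int(b)]
        ea, eb, eh = expected[step]
        assert {sa, sb} == {ea, eb}
        assert h == pytest.approx(eh, rel=1e-9)
        label[n + step] = sa | sb


def test_cluster_excludes_incomplete_profiles_with_warning():
    m = matrix_from_log2({
        "A": {"LOW": [10.0], "OPT": [11.0], "HIGH": [12.0]},
        "B": {"LOW": [9.0], "OPT": [10.0], "HIGH": [11.0]},
        "C": {"LOW": [None], "OPT": [None], "HIGH": [None]}})
    with pytest.warns(UserWarning, match="incomplete"):
        dend = cluster_expression_profiles(m)
    assert dend.excluded == ["C"]


def test_dendrogram_newick_is_parseable_and_ultrametric(rng):
    profiles = {f"P{i}": list(rng.normal(10, 1, 3)) for i in range(6)}
    m = matrix_from_log2({acc: {"LOW": [p[0]], "OPT": [p[1]], "HIGH": [p[2]]}
                          for acc, p in profiles.items()})
    dend = cluster_expression_profiles(m)
    tree = dendropy.Tree.get(data=dend.to_newick(), schema="newick")
    assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == \
        set(profiles)
    root_height = max(dend.merge_heights())
    for leaf in tree.leaf_node_iter():
        depth = leaf.edge.length or 0.0
        depth += sum(a.edge.length or 0.0 for a in leaf.ancestor_iter())
        # newick serialization keeps 6 significant digits
        assert depth == pytest.approx(root_height, rel=1e-4)


def test_thresholds_validation():
    with pytest.raises(ValueError):
        Thresholds(fc_cutoff=0.8)
    with pytest.raises(ValueError):
        Thresholds(p_cutoff=0.0)
    assert math.isclose(Thresholds().noise_multiplier, 3.0)
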