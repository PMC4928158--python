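"""Mutation-status grouping, preprocessing rules, and MWU scans."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from hotspots import (
    GeneAnnotation,
    Group,
    MutationRecord,
    VariantClass,
    assign_groups,
    association_scan,
    build_dataset,
    call_cn_events,
    log2_rpkm,
    mwu_test,
    simulate_feature_matrix,
)
from hotspots.detection import HotspotCall


class TestLog2Rpkm:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([0, 1, 4], [0, 0, 2]),
            ([2, 2], [1, 1]),
            ([0, 0, 8], [3, 3, 3]),
        ],
    )
    def test_zero_replacement_then_log2(self, values, expected):
        assert log2_rpkm(values) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            log2_rpkm([0.0, 0.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log2_rpkm([-1.0, 2.0])


class TestCnEvents:
    def test_strict_thresholds(self):
        cn = pd.DataFrame({"G1": [-1.2, -1.0, 0.0, 1.0, 1.3]},
                          index=[f"s{i}" for i in range(5)])
        calls = call_cn_events(cn)["G1"].tolist()
        assert calls == ["deletion", "neutral", "neutral", "neutral", "amplification"]


def _dataset():
    records = [
        MutationRecord("s_hot1", "A", "TP53", "17", 100, "C", "T",
                       VariantClass.MISSENSE, aa_position=175,
                       left_flank="A", right_flank="T"),
        MutationRecord("s_hot2", "A", "TP53", "17", 100, "C", "T",
                       VariantClass.MISSENSE, aa_position=175,
                       left_flank="A", right_flank="T"),
        MutationRecord("s_other", "A", "TP53", "17", 400, "G", "A",
                       VariantClass.MISSENSE, aa_position=213,
                       left_flank="C", right_flank="T"),
    ]
    samples = {s: "A" for s in
               ["s_hot1", "s_hot2", "s_other", "s_none1", "s_none2", "s_del"]}
    return build_dataset(records, samples,
                         {"TP53": GeneAnnotation("TP53", 393)},
                         apply_hypermutation_filter=False)


class TestAssignGroups:
    def test_three_way_partition(self):
        groups = assign_groups(_dataset(), "TP53", 175)
        assert groups["s_hot1"] == Group.HOTSPOT
        assert groups["s_other"] == Group.NON_HOTSPOT
        assert groups["s_none1"] == Group.NO_MUTATION
        assert len(groups) == 6  # partition covers every sample

    def test_cn_deletion_excluded_regardless_of_mutation(self):
        cn = pd.DataFrame({"TP53": [-2.0, 0.0]}, index=["s_hot1", "s_hot2"])
        groups = assign_groups(_dataset(), "TP53", 175,
                               exclude_cn_deleted=True, cn=cn)
        assert groups["s_hot1"] == Group.EXCLUDED
        assert groups["s_hot2"] == Group.HOTSPOT

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValueError, match="KRAS"):
            assign_groups(_dataset(), "KRAS", 12)


def midrank_enumeration_oracle(x, y):
    """Independent exact MWU oracle via midrank sums over all splits."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    sorted_vals = pooled[order]
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # midrank, 1-based
        i = j
    mean_w = n1 * (n + 1) / 2.0
    obs = abs(ranks[:n1].sum() - mean_w)
    hits = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mean_w) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestMwuTest:
    def test_minimal_exact_case(self):
        assert mwu_test([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_constant_groups(self):
        assert mwu_test([5, 5, 5], [5, 5, 5]) == 1.0

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(5)
        x = rng.normal(10, 1, 20)
        y = rng.normal(0, 1, 20)
        assert mwu_test(x, y) < 1e-5

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=5), rng.normal(size=9)
        assert mwu_test(x, y) == pytest.approx(mwu_test(y, x))

    def test_exact_branch_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for n1 in range(1, 6):
            for n2 in range(1, 11 - n1):
                for _ in range(3):
                    x = rng.integers(0, 4, size=n1).astype(float)  # ties likely
                    y = rng.integers(0, 4, size=n2).astype(float)
                    if np.all(np.concatenate([x, y]) == x[0] if n1 else False):
                        continue
                    assert mwu_test(x, y) == pytest.approx(
                        midrank_enumeration_oracle(x, y)
                    ), (list(x), list(y))

    def test_tie_free_exact_matches_scipy(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(8)
        for n1, n2 in [(2, 5), (3, 4), (4, 4), (5, 5)]:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert mwu_test(x, y) == pytest.approx(ref, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mwu_test([], [1.0])


def _assoc_setup(effect, seed, n_hot=10, n_non=10, n_none=20, n_features=50):
    """A one-gene cohort plus a feature matrix with a planted carrier shift."""
    mat, members, shifted = simulate_feature_matrix(
        {"hot": n_hot, "non": n_non, "none": n_none},
        effect_size=effect, n_features=n_features, seed=seed,
        n_effect_features=n_features,
    )
    mat.columns = ["G1"] + list(mat.columns[1:])  # gene-named feature
    records, samples = [], {}
    for s in mat.index:
        samples[s] = "A"
        if s in members["hot"]:
            records.append(MutationRecord(s, "A", "G1", "1", 30, "C", "T",
                                          VariantClass.MISSENSE, aa_position=10,
                                          left_flank="A", right_flank="T"))
        elif s in members["non"]:
            records.append(MutationRecord(s, "A", "G1", "1", 60, "G", "A",
                                          VariantClass.MISSENSE, aa_position=20,
                                          left_flank="C", right_flank="T"))
    ds = build_dataset(records, samples, {"G1": GeneAnnotation("G1", 100)},
                       apply_hypermutation_filter=False)
    call = HotspotCall(gene="G1", aa_position=10, tumor_type="A", k=1, x=1.0,
                       p_combined=1e-6, q=1e-5, contributing=(),
                       n_carrier_samples=n_hot)
    return ds, [call], mat


class TestAssociationScan:
    def test_planted_effect_detected(self):
        ds, calls, mat = _assoc_setup(effect=2.0, seed=1, n_hot=8)
        results = association_scan(calls, ds, mat[["G1"]])
        assert results  # gene-named feature matched
        assert all(r.p < 0.05 and r.direction == "higher" for r in results)

    def test_min_occurrence_skips_single_carrier(self):
        ds, calls, mat = _assoc_setup(effect=3.0, seed=2, n_hot=1)
        assert association_scan(calls, ds, mat[["G1"]]) == []

    def test_feature_map_matching_for_rppa(self):
        ds, calls, mat = _assoc_setup(effect=2.0, seed=3)
        mat = mat.rename(columns={"G1": "AKT_pT308"})
        none = association_scan(calls, ds, mat, kind="rppa")
        mapped = association_scan(calls, ds, mat, kind="rppa",
                                  feature_map={"G1": ["AKT_pT308"]})
        assert none == [] and len(mapped) == 2  # both comparisons

    def test_no_shared_samples_rejected(self):
        ds, calls, mat = _assoc_setup(effect=0.0, seed=4)
        mat.index = ["x" + s for s in mat.index]
        with pytest.raises(ValueError, match="shared"):
            association_scan(calls, ds, mat)

    def test_null_type_one_error_near_nominal(self):
        # 1000 independent null features through the full scan machinery
        ds, calls, mat = _assoc_setup(effect=0.0, seed=9, n_hot=10, n_non=15,
                                      n_none=20, n_features=1000)
        fmap = {"G1": [c for c in mat.columns if c != "G1"]}
        results = association_scan(calls, ds, mat, kind="rppa", feature_map=fmap)
        hot_vs_non = [r for r in results if r.comparison == "hotspot_vs_nonhotspot"]
        assert len(hot_vs_non) == 999
        rate = np.mean([r.p < 0.05 for r in hot_vs_non])
        assert 0.03 <= rate <= 0.07
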