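"""The hotspot statistic: Poisson tails, Fisher combination, BH, calling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hotspots import (
    GeneAnnotation,
    MutationRecord,
    VariantClass,
    bh_adjust,
    build_dataset,
    call_hotspots,
    combine_fisher,
    estimate_background,
    poisson_tail,
    score_positions,
)
from hotspots.subtypes import subtype_count_matrix


def brute_force_poisson_tail(o, lam, terms=200):
    """Direct pmf summation sum_{j>=O} e^-lam lam^j / j!."""
    term = math.exp(-lam)  # pmf at j = 0
    for j in range(1, o + 1):
        term *= lam / j
    total = 0.0
    for j in range(o, o + terms):
        total += term
        term *= lam / (j + 1)
    return min(total, 1.0)


def step_up_bh_oracle(pvals):
    """Independently coded BH step-up: q_(i) = min_{j>=i} p_(j) m / j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q


class TestPoissonTail:
    def test_empty_tail_identity(self):
        assert poisson_tail(0, 5.0) == 1.0

    @pytest.mark.parametrize(
        "o,lam,expected",
        [
            (1, 0.5, 1 - math.exp(-0.5)),
            (3, 0.1, 1 - math.exp(-0.1) * (1 + 0.1 + 0.005)),
        ],
    )
    def test_closed_forms(self, o, lam, expected):
        assert poisson_tail(o, lam) == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_grid(self):
        for o in range(21):
            for lam in (0.01, 0.1, 0.5, 1.0, 2.5, 5.0, 10.0):
                assert poisson_tail(o, lam) == pytest.approx(
                    brute_force_poisson_tail(o, lam), rel=1e-12
                )

    @given(st.integers(0, 30), st.floats(0.001, 20.0))
    @settings(max_examples=200)
    def test_monotone_in_observed(self, o, lam):
        assert poisson_tail(o + 1, lam) <= poisson_tail(o, lam)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            poisson_tail(-1, 1.0)
        with pytest.raises(ValueError):
            poisson_tail(1, -1.0)


class TestCombineFisher:
    @given(st.floats(1e-300, 1.0))
    @settings(max_examples=100)
    def test_identity_at_k1(self, p):
        _, combined = combine_fisher([p])
        assert combined == pytest.approx(p, rel=1e-9)

    def test_chi2_4df_closed_form(self):
        x, p = combine_fisher([0.1, 0.1])
        assert x == pytest.approx(9.2103404, rel=1e-6)
        assert p == pytest.approx(math.exp(-x / 2) * (1 + x / 2), rel=1e-12)
        assert p == pytest.approx(0.056052, rel=1e-4)

    def test_all_ones_boundary(self):
        x, p = combine_fisher([1.0, 1.0, 1.0])
        assert x == 0.0 and p == 1.0

    def test_matches_scipy_combine_pvalues(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ps = rng.uniform(1e-6, 1, size=rng.integers(1, 8))
            x, p = combine_fisher(ps)
            ref = stats.combine_pvalues(ps, method="fisher")
            assert x == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    @given(st.lists(st.floats(1e-12, 1.0), min_size=2, max_size=8))
    @settings(max_examples=100)
    def test_permutation_invariant(self, ps):
        assert combine_fisher(ps)[1] == pytest.approx(
            combine_fisher(list(reversed(ps)))[1], rel=1e-12
        )

    def test_zero_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            x, p = combine_fisher([0.0, 0.5])
        assert np.isfinite(x) and p > 0


class TestBhAdjust:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.5], [0.5]),
            ([0.05, 0.05], [0.05, 0.05]),
        ],
    )
    def test_hand_worked_step_up(self, pvals, expected):
        assert bh_adjust(pvals) == pytest.approx(expected)

    def test_matches_independent_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            assert bh_adjust(p) == pytest.approx(step_up_bh_oracle(list(p)))

    def test_monotone_with_input_ranks(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestEstimateBackground:
    def test_lambda_is_count_over_length(self, planted_dataset):
        counts = subtype_count_matrix(planted_dataset, "colorectal")
        bg, skipped = estimate_background(counts, planted_dataset.annotations)
        assert skipped == []
        row = bg[(bg.gene == "GENE1") & (bg.subtype == "missense_NoCpG_CGts")]
        assert row["lambda_per_aa"].iloc[0] == pytest.approx(
            row["E_total"].iloc[0] / 300
        )
        assert (bg["E_total"] > 0).all()  # zero-count pairs omitted

    def test_unannotated_gene_skipped_and_reported(self, planted_dataset):
        counts = subtype_count_matrix(planted_dataset, "colorectal")
        ann = {g: a for g, a in planted_dataset.annotations.items() if g != "GENE2"}
        with pytest.warns(UserWarning, match="GENE2"):
            bg, skipped = estimate_background(counts, ann)
        assert skipped == ["GENE2"]
        assert "GENE2" not in set(bg["gene"])


def _snv(sample, gene, aa, left="A", right="T"):
    return MutationRecord(
        sample, "T", gene, "1", aa * 3, "C", "T", VariantClass.MISSENSE,
        aa_position=aa, left_flank=left, right_flank=right,
    )


def _single_gene_dataset(n_background=4, n_hotspot=6, length=100):
    """10 missense NoCpG_CGts mutations in one gene, 6 stacked at AA 50."""
    records, samples = [], {}
    i = 0
    for aa in range(1, n_background + 1):
        records.append(_snv(f"s{i}", "G1", aa))
        samples[f"s{i}"] = "T"
        i += 1
    for _ in range(n_hotspot):
        records.append(_snv(f"s{i}", "G1", 50))
        samples[f"s{i}"] = "T"
        i += 1
    ann = {"G1": GeneAnnotation("G1", length)}
    return build_dataset(records, samples, ann, apply_hypermutation_filter=False)


class TestCallHotspots:
    def test_single_subtype_matches_poisson_closed_form(self):
        ds = _single_gene_dataset()
        scored = score_positions(ds, "T")
        row = scored[scored.aa_position == 50].iloc[0]
        # E = 10 over L = 100 -> lambda 0.1; O = 6
        assert row["k"] == 1
        expected = poisson_tail(6, 0.1)
        assert row["p_combined"] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(1.275e-9, rel=1e-3)

    def test_two_subtype_combination(self):
        # 3 missense (lambda 0.1) + 2 deletions (lambda 0.05) at one AA
        records, samples = [], {}
        i = 0
        for aa in [1, 2, 3, 4, 5, 6, 7, 20, 20, 20]:
            records.append(_snv(f"s{i}", "G1", aa))
            samples[f"s{i}"] = "T"
            i += 1
        for aa in [8, 9, 10, 20, 20]:
            records.append(
                MutationRecord(f"s{i}", "T", "G1", "1", aa * 3, "ACG", "-",
                               VariantClass.DELETION, aa_position=aa)
            )
            samples[f"s{i}"] = "T"
            i += 1
        ds = build_dataset(records, samples, {"G1": GeneAnnotation("G1", 100)},
                           apply_hypermutation_filter=False)
        scored = score_positions(ds, "T")
        row = scored[scored.aa_position == 20].iloc[0]
        assert row["k"] == 2
        assert row["x"] == pytest.approx(30.984, rel=1e-3)
        assert row["p_combined"] == pytest.approx(3.08e-6, rel=1e-2)

    def test_uniform_spread_produces_no_calls(self):
        records, samples = [], {}
        for i, aa in enumerate(range(1, 31)):
            records.append(_snv(f"s{i}", "G1", aa))
            samples[f"s{i}"] = "T"
        ds = build_dataset(records, samples, {"G1": GeneAnnotation("G1", 300)},
                           apply_hypermutation_filter=False)
        assert call_hotspots(ds, "T", alpha=0.001) == []

    def test_adding_observation_never_increases_combined_p(self):
        prev = None
        for n_hot in range(2, 9):
            ds = _single_gene_dataset(n_background=4, n_hotspot=n_hot)
            scored = score_positions(ds, "T")
            p = scored.loc[scored.aa_position == 50, "p_combined"].iloc[0]
            if prev is not None:
                assert p <= prev
            prev = p

    def test_calls_sorted_and_filtered(self, planted_dataset):
        calls = call_hotspots(planted_dataset, "colorectal", alpha=0.001)
        assert all(c.q < 0.001 for c in calls)
        qs = [c.q for c in calls]
        assert qs == sorted(qs)
        planted = {(c.gene, c.aa_position) for c in calls}
        assert {("GENE1", 150), ("GENE2", 77)} <= planted

    def test_unknown_tumor_type_raises(self, planted_dataset):
        with pytest.raises(KeyError):
            call_hotspots(planted_dataset, "nope")

    def test_pmf_mode_available(self):
        ds = _single_gene_dataset()
        tail = score_positions(ds, "T", p_mode="tail")
        pmf = score_positions(ds, "T", p_mode="pmf")
        # both flag the stacked position as the extreme one
        assert tail["p_combined"].idxmin() == pmf["p_combined"].idxmin()

    def test_gene_k_mode_adds_nonobserved_subtypes(self):
        ds = _single_gene_dataset()
        obs = score_positions(ds, "T", k_mode="observed")
        gene = score_positions(ds, "T", k_mode="gene")
        assert (gene["k"] >= obs["k"]).all()
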