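"""Rate aggregation: locus tables, oxidation filter, contexts, indels."""

import numpy as np
import pandas as pd
import pytest

from umierr.consensus import TYPE_LABELS
from umierr.rates import (
    SUBSTITUTION_TYPES,
    apply_oxidation_filter,
    context_rates,
    indel_rates,
    locus_totals,
    moving_average,
    per_locus_rates,
)


def make_calls(rows):
    """rows: (locus, e, type, expected_error[, is_insertion])."""
    df = pd.DataFrame(
        [(r + (False,))[:5] for r in rows],
        columns=["locus", "e", "type", "expected_error", "is_insertion"],
    )
    df["bin_id"] = np.arange(len(df))
    df["p_e"] = 0.0
    df["depth_template"] = 6
    df["depth_polymerized"] = 6
    df["type"] = pd.Categorical(df["type"], categories=TYPE_LABELS)
    return df


def table_for(rows, window_length=10, condition="1G-", replicate="rep1"):
    return per_locus_rates(make_calls(rows), window_length, condition, replicate)


def test_single_error_among_many_covering_bins():
    rows = [(0, 0, "none", 0.0)] * 9999 + [(0, 1, "A>G", 1.0)]
    table = table_for(rows)
    row = table[(table["locus"] == 0) & (table["type"] == "A>G")].iloc[0]
    assert row["coverage"] == 10000
    assert row["rate"] == pytest.approx(1e-4)


def test_zero_calls_nonzero_coverage_rate_zero():
    table = table_for([(3, 0, "none", 0.0)] * 50)
    assert (table[table["locus"] == 3]["rate"] == 0).all()
    assert set(table["locus"]) == {3}  # uncovered loci omitted


def test_type_none_mass_not_counted_as_substitution():
    # e=0 calls carry expected error P_E but contribute to no error type
    rows = [(0, 0, "none", 1e-6)] * 100
    table = table_for(rows)
    assert locus_totals(table, "substitution")["rate"].sum() == 0.0


def test_sum_over_types_equals_total(rng):
    rows = []
    for locus in range(5):
        rows += [(locus, 0, "none", 0.0)] * 200
        for t in rng.choice(SUBSTITUTION_TYPES, 4):
            rows.append((locus, 1, str(t), 1.0))
    table = table_for(rows)
    totals = locus_totals(table, "substitution")
    for locus in range(5):
        by_type = table[(table["locus"] == locus) & table["type"].isin(SUBSTITUTION_TYPES)]
        assert totals[totals["locus"] == locus]["rate"].iloc[0] == pytest.approx(
            by_type["rate"].sum()
        )


def test_rates_invariant_to_row_order(rng):
    rows = [(int(l), 1, "C>T", 1.0) for l in rng.integers(0, 10, 30)]
    rows += [(l, 0, "none", 0.0) for l in range(10)] * 40
    t1 = table_for(rows)
    shuffled = [rows[i] for i in rng.permutation(len(rows))]
    t2 = table_for(shuffled)
    merged = t1.merge(t2, on=["locus", "type"], suffixes=("_a", "_b"))
    assert np.allclose(merged["rate_a"], merged["rate_b"])


class TestOxidationFilter:
    def _table(self, ca_rate):
        n = 10000
        n_ca = int(round(ca_rate * n))
        rows = [(0, 1, "C>A", 1.0)] * n_ca + [(0, 0, "none", 0.0)] * (n - n_ca)
        rows += [(1, 0, "none", 0.0)] * n
        return table_for(rows)

    def test_hot_locus_excluded(self):
        filtered, excluded = apply_oxidation_filter(self._table(6e-4))
        assert excluded["1G-"] == [0]
        assert 0 not in set(filtered["locus"])
        assert 1 in set(filtered["locus"])

    def test_cold_locus_retained(self):
        filtered, excluded = apply_oxidation_filter(self._table(0.0))
        assert excluded["1G-"] == []
        assert set(filtered["locus"]) == {0, 1}

    def test_threshold_boundary_is_exclusive_below(self):
        _, excluded = apply_oxidation_filter(self._table(4e-4))
        assert excluded["1G-"] == []
        _, excluded = apply_oxidation_filter(self._table(5e-4))
        assert excluded["1G-"] == [0]

    def test_pooling_across_replicates(self):
        # one hot replicate + one cold replicate pool to a rate below cutoff
        t1 = table_for([(0, 1, "C>A", 1.0)] * 6 + [(0, 0, "none", 0.0)] * 9994, replicate="rep1")
        t2 = table_for([(0, 0, "none", 0.0)] * 10000, replicate="rep2")
        _, excluded = apply_oxidation_filter(pd.concat([t1, t2], ignore_index=True))
        assert excluded["1G-"] == []


class TestContextRates:
    def _uniform_table(self, window_length=10, rate=1e-4, cov=10000):
        n_err = int(rate * cov)
        rows = []
        for locus in range(window_length):
            rows += [(locus, 1, "A>G", 1.0)] * n_err
            rows += [(locus, 0, "none", 0.0)] * (cov - n_err)
        return table_for(rows, window_length)

    def test_uniform_rate_dinucleotide_is_twice(self):
        table = self._uniform_table()
        ctx = context_rates(table, "ACGTACGTAC", 2)
        assert len(ctx) == 9
        assert np.allclose(ctx["rate"], 2e-4)

    def test_trinucleotide_occurrence_count(self):
        table = self._uniform_table(window_length=175, cov=100)
        ctx = context_rates(table, "ACGT" * 43 + "ACG", 3)
        assert len(ctx) == 173

    def test_hot_locus_elevates_only_overlapping_kmers(self):
        table = self._uniform_table()
        hot = table_for([(4, 1, "A>G", 1.0)] * 50 + [(4, 0, "none", 0.0)] * 9950)
        combined = pd.concat(
            [table[table["locus"] != 4], hot[hot["locus"] == 4]], ignore_index=True
        )
        ctx = context_rates(combined, "ACGTACGTAC", 2)
        elevated = ctx[ctx["rate"] > 3e-4]["start"].tolist()
        assert sorted(elevated) == [3, 4]

    def test_k1_reproduces_per_locus_totals(self):
        table = self._uniform_table()
        ctx = context_rates(table, "ACGTACGTAC", 1)
        totals = locus_totals(table, "substitution").sort_values("locus")
        assert np.allclose(ctx.sort_values("start")["rate"], totals["rate"])


class TestMovingAverage:
    def test_constant_rates_undefined_correlation(self):
        profile, r = moving_average(np.full(10, 1e-4), "ACGTACGTAC", window=3)
        assert np.allclose(profile["mean_rate"], 1e-4)
        assert np.isnan(r)

    def test_pearson_extremes(self):
        seq = "ATGCGCATAT"  # varying GC
        is_gc = np.array([c in "GC" for c in seq], float)
        gc_profile = np.convolve(is_gc, np.ones(3) / 3, mode="valid")
        rates = np.convolve(is_gc, np.ones(3) / 3, mode="valid")
        # rates proportional to GC -> r = 1; anti-proportional -> r = -1
        _, r_pos = moving_average(is_gc, seq, window=3)
        _, r_neg = moving_average(-is_gc, seq, window=3)
        assert r_pos == pytest.approx(1.0)
        assert r_neg == pytest.approx(-1.0)
        assert np.ptp(gc_profile) > 0  # sanity: the toy input varies

    def test_hand_computed_window_means(self):
        rates = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10], dtype=float)
        profile, _ = moving_average(rates, "ACGTACGTAC", window=4)
        assert np.allclose(profile["mean_rate"], [2.5, 3.5, 4.5, 5.5, 6.5, 7.5, 8.5])

    def test_window_longer_than_region_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.ones(5), "ACGTA", window=6)


class TestIndelRates:
    def test_single_deletion_classified_by_base_and_neighbour(self):
        # window CTAAAAAAAA: deletion of T at locus 1, preceded by C
        rows = [(1, 1, "del:T", 1.0)] + [(1, 0, "none", 0.0)] * 9999
        for locus in [0] + list(range(2, 10)):
            rows += [(locus, 0, "none", 0.0)] * 10
        table = table_for(rows)
        out = indel_rates(table, "CTAAAAAAAA")
        row = out[(out["event"] == "deletion") & (out["base"] == "T") & (out["preceding"] == "C")]
        assert len(row) == 1
        assert row["rate"].iloc[0] == pytest.approx(1e-4)
        assert row["base_class"].iloc[0] == "pyrimidine"

    def test_no_indel_calls_empty_rates(self):
        table = table_for([(0, 0, "none", 0.0)] * 10)
        out = indel_rates(table, "A" * 10)
        assert (out["sum_expected"] == 0).all()

    def test_purine_pyrimidine_rollup(self):
        rows = [(1, 1, "del:C", 1.0)] * 2 + [(2, 1, "del:T", 1.0)] * 3
        for locus in range(10):
            rows += [(locus, 0, "none", 0.0)] * 1000
        table = table_for(rows)
        out = indel_rates(table, "ACTGACTGAC")
        pyr = out[(out["event"] == "deletion") & (out["base_class"] == "pyrimidine")]
        pur = out[(out["event"] == "deletion") & (out["base_class"] == "purine")]
        assert pyr["sum_expected"].sum() == pytest.approx(5.0)
        assert pur["sum_expected"].sum() == 0.0
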