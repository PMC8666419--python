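"""Statistics layer: imputation, exact nonparametric tests, fold change, PCR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from umierr.stats import (
    ConditionMatrix,
    StatError,
    compare_conditions,
    fold_change,
    impute_and_median,
    mann_whitney_u,
    pcr_error_propagation,
    wilcoxon_signed_rank,
)


def cm(rows, condition="1G-"):
    return ConditionMatrix(condition, pd.DataFrame(rows, columns=["rep1", "rep2", "rep3"]))


def signed_rank_enumeration_p(d):
    """Exact two-tailed signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.array(stats)
    mu = stats.mean()
    # two-tailed: mass at least as extreme (in |W - mu|) as observed
    return np.mean(np.abs(stats - mu) >= np.abs(w_obs - mu) - 1e-12)


def mwu_enumeration_p(x, y):
    """Exact two-tailed Mann-Whitney p by enumerating label assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = rankdata(pooled)

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    mu = len(x) * len(y) / 2
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n1)]
    us = np.array(us)
    return np.mean(np.abs(us - mu) >= np.abs(u_obs - mu) - 1e-12)


class TestImputation:
    def test_missing_cell_mean_of_remaining(self):
        out = impute_and_median(cm([[2e-5, np.nan, 4e-5]]))
        assert out.matrix.iloc[0, 1] == pytest.approx(3e-5)
        assert out.medians.iloc[0] == pytest.approx(3e-5)
        assert out.n_imputed == 1

    def test_zero_treated_as_missing(self):
        out = impute_and_median(cm([[2e-5, 0.0, 4e-5]]))
        assert out.matrix.iloc[0, 1] == pytest.approx(3e-5)

    def test_all_zero_locus_stays_zero(self):
        out = impute_and_median(cm([[0.0, 0.0, 0.0]]))
        assert (out.matrix.iloc[0] == 0).all()

    def test_complete_locus_unchanged(self):
        out = impute_and_median(cm([[1e-5, 1e-5, 1e-5]]))
        assert (out.matrix.iloc[0] == 1e-5).all()
        assert out.n_imputed == 0


class TestWilcoxon:
    def test_six_uniform_sign_distinct_differences_exact(self):
        x = np.zeros(6)
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert wilcoxon_signed_rank(x, y) == pytest.approx(0.03125)
        assert signed_rank_enumeration_p(y - x) == pytest.approx(0.03125)

    def test_identical_vectors_refused(self):
        x = np.arange(10.0)
        with pytest.raises(StatError):
            wilcoxon_signed_rank(x, x)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_branch_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=9)
        y = x + rng.normal(size=9)
        assert wilcoxon_signed_rank(x, y) == pytest.approx(
            signed_rank_enumeration_p(y - x), abs=1e-12
        )

    def test_symmetry(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(scale=0.5, size=40)
        assert wilcoxon_signed_rank(x, y) == pytest.approx(wilcoxon_signed_rank(y, x))

    def test_large_shift_detected(self, rng):
        x = rng.lognormal(sigma=0.3, size=175)
        y = x * 2.4
        assert wilcoxon_signed_rank(x, y) < 1e-10


class TestMannWhitney:
    def test_small_sample_exact_third(self):
        assert mann_whitney_u([1, 2], [3, 4]) == pytest.approx(1 / 3)
        assert mwu_enumeration_p(np.array([1.0, 2.0]), np.array([3.0, 4.0])) == pytest.approx(1 / 3)

    def test_identical_multisets_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert mann_whitney_u(x, x) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_exact_branch_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = rng.normal(loc=0.5, size=7)
        assert mann_whitney_u(x, y) == pytest.approx(mwu_enumeration_p(x, y), abs=1e-12)

    def test_symmetry(self, rng):
        x = rng.lognormal(size=50)
        y = rng.lognormal(mean=0.3, size=60)
        assert mann_whitney_u(x, y) == pytest.approx(mann_whitney_u(y, x))

    def test_empty_sample_rejected(self):
        with pytest.raises(StatError):
            mann_whitney_u([], [1.0])


class TestFoldChange:
    def test_identity(self):
        x = np.array([1.0, 2.0, 3.0])
        fc = fold_change(x, x)
        assert fc.mean_ratio == 1.0 and fc.median_ratio == 1.0

    def test_doubling(self):
        x = np.array([1.0, 2.0, 3.0])
        fc = fold_change(x, 2 * x)
        assert fc.mean_ratio == 2.0 and fc.median_ratio == 2.0

    def test_scaling_property(self, rng):
        x = rng.lognormal(size=30)
        for k in (0.5, 2.4):
            assert fold_change(x, k * x).mean_ratio == pytest.approx(k)

    def test_zero_denominators_skipped_and_counted(self):
        x = np.array([0.0, 1.0, 2.0])
        fc = fold_change(x, np.array([5.0, 2.0, 4.0]))
        assert fc.n_used == 2 and fc.n_skipped == 1 and fc.mean_ratio == 2.0

    def test_all_zero_denominators_rejected(self):
        with pytest.raises(StatError):
            fold_change(np.zeros(3), np.ones(3))


class TestPcrPropagation:
    def test_zero_error_rate(self):
        assert (pcr_error_propagation(0.0, 1000, 30) == 0).all()

    def test_zero_cycles(self):
        out = pcr_error_propagation(1e-4, 1000, 0)
        assert out.shape == (1,) and out[0] == 0.0

    def test_printed_value(self):
        out = pcr_error_propagation(1e-4, 1000, 30)
        assert out[-1] == pytest.approx(0.9503, abs=2e-4)

    def test_monotone_in_cycles_rate_and_length(self):
        f = pcr_error_propagation(1e-4, 1000, 30)
        assert (np.diff(f) > 0).all()
        assert pcr_error_propagation(2e-4, 1000, 30)[-1] > f[-1]
        assert pcr_error_propagation(1e-4, 2000, 30)[-1] > f[-1]


def test_compare_conditions_end_to_end(rng):
    base = rng.lognormal(mean=np.log(3e-5), sigma=0.2, size=(175, 3))
    mx = ConditionMatrix("1G-", pd.DataFrame(base, columns=["rep1", "rep2", "rep3"]))
    my = ConditionMatrix("uG-", pd.DataFrame(base * 2.4, columns=["rep1", "rep2", "rep3"]))
    res = compare_conditions(mx, my, paired=True)
    assert res.significant and res.test == "wilcoxon_signed_rank"
    assert res.fold.mean_ratio == pytest.approx(2.4, rel=1e-9)
    res_u = compare_conditions(mx, my, paired=False)
    assert res_u.test == "mann_whitney_u" and res_u.significant
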