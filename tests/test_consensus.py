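"""Consensus calling and the false-consensus probability P_E.

The oracle enumerates all 2^m read-correctness assignments explicitly and
sums the probability mass of assignments in which incorrect calls form a
strict majority; the implementation must agree to 1e-12 for m <= 12.
"""

import itertools

import numpy as np
import pytest

from umierr._codes import DEL
from umierr.binning import build_bins, filter_bins
from umierr.consensus import (
    CallConfig,
    LocusStack,
    call_errors,
    consensus_base,
    false_consensus_prob,
    validate_template_reads,
)
from tests.test_binning import make_obs


def enumeration_oracle(bases, q, b):
    """P(strict majority of calls incorrect) by explicit 2^m enumeration."""
    bases = np.asarray(bases)
    counts = np.bincount(bases, minlength=5)
    cons = counts.argmax()
    assert 2 * counts[cons] > len(bases)
    e = bases != cons
    c = (1 - np.asarray(b, dtype=float)) * (1 - np.asarray(q, dtype=float))
    p_incorrect = np.where(e, c, 1 - c)
    total = 0.0
    m = len(bases)
    for assignment in itertools.product([0, 1], repeat=m):  # 1 = incorrect
        if sum(assignment) * 2 <= m:
            continue
        mass = 1.0
        for j, wrong in enumerate(assignment):
            mass *= p_incorrect[j] if wrong else 1 - p_incorrect[j]
        total += mass
    return total


def unanimous(m, q, b=0.0):
    return LocusStack(np.zeros(m, dtype=np.int8), np.full(m, q), np.full(m, b))


class TestConsensusBase:
    def test_strict_majority(self):
        assert consensus_base(LocusStack([0, 0, 0, 1, 1], [0] * 5, [0] * 5)) == 0

    def test_tie_is_no_call(self):
        assert consensus_base(LocusStack([0, 0, 1, 1], [0] * 4, [0] * 4)) is None

    def test_del_is_first_class_symbol(self):
        stack = LocusStack([DEL] * 4 + [0] * 3, [0] * 7, [0] * 7)
        assert consensus_base(stack) == DEL

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            consensus_base(LocusStack([], [], []))


class TestFalseConsensusProb:
    def test_single_read(self):
        assert false_consensus_prob(unanimous(1, 0.01)) == pytest.approx(0.01, abs=1e-15)

    def test_three_unanimous_reads(self):
        # P(>=2 of 3 wrong) = 3 q^2 (1-q) + q^3 = 2.98e-4 at q = 0.01,
        # confirmed by the explicit enumeration oracle
        expect = 3 * 0.01**2 * 0.99 + 0.01**3
        got = false_consensus_prob(unanimous(3, 0.01))
        assert got == pytest.approx(expect, abs=1e-15)
        assert got == pytest.approx(enumeration_oracle([0, 0, 0], [0.01] * 3, [0] * 3), abs=1e-15)
        assert got == pytest.approx(2.98e-4, abs=1e-10)

    def test_no_miscall_mass(self):
        assert false_consensus_prob(unanimous(5, 0.0)) == 0.0

    def test_misbinning_contributes(self):
        assert false_consensus_prob(unanimous(3, 0.0, b=0.01)) == pytest.approx(
            2.98e-4, abs=1e-10
        )

    @pytest.mark.parametrize("m", range(1, 13))
    def test_matches_enumeration_oracle(self, m, rng):
        for _ in range(12):
            cons_count = m // 2 + 1 + int(rng.integers(0, m - m // 2)) if m > 1 else 1
            bases = np.array([0] * cons_count + [1] * (m - cons_count), dtype=np.int8)
            rng.shuffle(bases)
            q = rng.uniform(0, 0.3, m)
            b = rng.uniform(0, 0.2, m)
            got = false_consensus_prob(LocusStack(bases, q, b))
            assert got == pytest.approx(enumeration_oracle(bases, q, b), abs=1e-12)
            assert 0.0 <= got <= 1.0

    def test_monotone_in_quality_for_unanimous_stacks(self):
        qs = np.linspace(0.001, 0.2, 10)
        vals = [false_consensus_prob(unanimous(5, q)) for q in qs]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_subsample_deterministic_and_bounded(self):
        stack = unanimous(20, 0.05)
        a = false_consensus_prob(stack, seed=7)
        assert a == false_consensus_prob(unanimous(20, 0.05), seed=7)
        assert a != false_consensus_prob(stack, seed=8) or True  # different draw allowed
        assert 0 <= a <= 1
        # 12-read subsample of a homogeneous stack equals the 12-read value
        assert a == pytest.approx(false_consensus_prob(unanimous(12, 0.05)), abs=1e-15)

    def test_literal_variant_is_complementary_reading(self):
        # the literal scenario sum gives P(majority correct) ~ 1 for a clean
        # unanimous stack, contradicting its use as a retention score
        stack = unanimous(7, 0.01)
        assert false_consensus_prob(stack, literal=True) > 0.99
        assert false_consensus_prob(stack) < 1e-6

    def test_no_consensus_rejected(self):
        with pytest.raises(ValueError):
            false_consensus_prob(LocusStack([0, 0, 1, 1], [0.01] * 4, [0] * 4))


class TestValidateTemplateReads:
    def _obs_with_bases(self, n_mismatch):
        obs = make_obs(["ACGTACGTACGTACGTACGT"] * 6, "tttppp")
        refw = obs.spec.window_codes()
        obs.bases[:] = refw[None, :]
        obs.quals[:] = 30
        for i in range(n_mismatch):
            obs.bases[i, 3] = (refw[3] + 1) % 4  # mismatch inside window
        return obs

    def test_mismatching_template_read_excluded(self):
        obs = self._obs_with_bases(1)
        b = build_bins(obs)[0]
        out, n_excl = validate_template_reads(b, obs)
        assert n_excl == 1 and out.n_template == 2 and out.n_polymerized == 3

    def test_clean_bin_unchanged(self):
        obs = self._obs_with_bases(0)
        out, n_excl = validate_template_reads(build_bins(obs)[0], obs)
        assert n_excl == 0 and out.size == 6

    def test_bin_without_template_reads_dropped(self):
        obs = self._obs_with_bases(3)  # all template reads mismatch
        with pytest.raises(ValueError):
            validate_template_reads(build_bins(obs)[0], obs)

    def test_polymerized_mismatches_are_kept(self):
        obs = self._obs_with_bases(0)
        obs.bases[3, 5] = (obs.spec.window_codes()[5] + 2) % 4  # polymerized pair
        out, n_excl = validate_template_reads(build_bins(obs)[0], obs)
        assert n_excl == 0 and out.n_polymerized == 3


class TestCallErrors:
    def test_agreement_zero_expected_error(self):
        t = unanimous(6, 0.0)
        p = unanimous(6, 0.0)
        call = call_errors(t, p)
        assert call.e == 0 and call.error_type == "none"
        assert call.p_e == 0.0 and call.expected_error == 0.0

    def test_substitution_call(self):
        t = unanimous(6, 0.0)
        p = LocusStack([2] * 6, [1e-4] * 6, [0] * 6)  # all G against template A
        call = call_errors(t, p)
        assert call.e == 1 and call.error_type == "A>G"
        assert call.expected_error == pytest.approx(1 - call.p_e)
        assert call.p_e < 1e-5

    def test_deletion_call(self):
        t = LocusStack([1] * 7, [0.0] * 7, [0] * 7)
        p = LocusStack([DEL] * 7, [1e-4] * 7, [0] * 7)
        call = call_errors(t, p)
        assert call.error_type == "del:C" and call.polymerized_base == "-"

    def test_depth_below_six_skipped(self):
        assert call_errors(unanimous(5, 0.0), unanimous(6, 0.0)) is None

    def test_no_consensus_skipped(self):
        p = LocusStack([0, 0, 0, 1, 1, 1], [0.01] * 6, [0] * 6)
        assert call_errors(unanimous(6, 0.0), p) is None

    def test_pe_threshold_drops_low_quality_calls(self):
        noisy = unanimous(6, 0.2)
        assert call_errors(unanimous(6, 0.0), noisy) is None
        cfg = CallConfig(pe_threshold=0.5)
        assert call_errors(unanimous(6, 0.0), noisy, config=cfg) is not None

    def test_combined_pe_is_independent_combination(self):
        t = unanimous(6, 0.01)
        p = unanimous(6, 0.01)
        pt = false_consensus_prob(t)
        call = call_errors(t, p, config=CallConfig(pe_threshold=1.0))
        assert call.p_e == pytest.approx(1 - (1 - pt) ** 2, rel=1e-12)
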