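"""Kinetic metrics: probabilities, commit-time curves, detailed balance,
free energy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinseq.discretize import StateSequence
from kinseq.errors import PreconditionError
from kinseq.kinetics import (
    commit_time_counts,
    compare_curves,
    default_commit_grid,
    detailed_balance_report,
    ensemble_commit_curves,
    free_energy_1d,
    state_probabilities,
)
from kinseq.pipeline import sample_markov_chain


def brute_force_commit_counts(tokens, i, j, tau, rule="min"):
    """Independent oracle: enumerate all adjacent run pairs."""
    runs = []
    for t in tokens:
        if runs and runs[-1][0] == t:
            runs[-1][1] += 1
        else:
            runs.append([t, 1])
    count = 0
    for a in range(len(runs) - 1):
        (s1, l1), (s2, l2) = runs[a], runs[a + 1]
        if s1 == i and s2 == j:
            dwell = min(l1, l2) if rule == "min" else l1
            if dwell >= tau:
                count += 1
    return count


def seq_of(tokens, n_states=None):
    tokens = np.asarray(tokens)
    return StateSequence(tokens, n_states or int(tokens.max()) + 1)


class TestStateProbabilities:
    def test_small_example(self):
        table = state_probabilities(seq_of([0, 1, 1]))
        assert table.probabilities[0] == pytest.approx(1 / 3)
        assert table.probabilities[1] == pytest.approx(2 / 3)

    def test_identical_members_have_zero_stderr(self):
        s = seq_of([0, 1, 0, 1, 1])
        table = state_probabilities([s, s, s])
        np.testing.assert_allclose(table.stderr, 0.0, atol=1e-15)

    def test_uniform_iid_within_three_stderr(self):
        rng = np.random.default_rng(0)
        members = [seq_of(rng.integers(0, 3, 30_000), 3) for _ in range(5)]
        table = state_probabilities(members)
        assert np.all(
            np.abs(table.probabilities - 1 / 3) < 3 * np.maximum(table.stderr, 1e-4)
        )

    def test_empty_sequence_rejected(self):
        with pytest.raises(PreconditionError):
            state_probabilities(seq_of([], 2))


class TestCommitTimeCounts:
    def test_worked_example(self):
        s = seq_of([0, 0, 1, 0, 0, 0, 1, 1])
        c01 = commit_time_counts(s, (0, 1), [1, 2])
        c10 = commit_time_counts(s, (1, 0), [1, 2])
        np.testing.assert_array_equal(c01, [2, 1])
        np.testing.assert_array_equal(c10, [1, 0])

    def test_constant_sequence_has_zero_counts(self):
        s = seq_of([1] * 50, 2)
        np.testing.assert_array_equal(
            commit_time_counts(s, (0, 1), [1, 2, 3]), 0.0
        )

    def test_monotone_non_increasing_in_tau(self):
        rng = np.random.default_rng(1)
        s = seq_of(rng.integers(0, 3, 5000), 3)
        for pair in [(0, 1), (1, 2), (2, 0)]:
            c = commit_time_counts(s, pair, range(1, 20))
            assert np.all(np.diff(c) <= 0)

    @given(st.lists(st.integers(0, 2), min_size=2, max_size=60), st.integers(1, 5))
    @settings(max_examples=80, deadline=None)
    def test_matches_brute_force_oracle(self, tokens, tau):
        s = seq_of(tokens, 3)
        for (i, j) in [(0, 1), (1, 0), (0, 2), (2, 1)]:
            got = commit_time_counts(s, (i, j), [tau])[0]
            assert got == brute_force_commit_counts(tokens, i, j, tau)

    def test_pre_dwell_rule(self):
        tokens = [0, 0, 0, 1, 0]
        s = seq_of(tokens, 2)
        assert commit_time_counts(s, (0, 1), [3], rule="pre")[0] == 1
        assert commit_time_counts(s, (0, 1), [3], rule="min")[0] == 0

    def test_tau_one_counts_sum_to_token_changes(self):
        rng = np.random.default_rng(2)
        tokens = rng.integers(0, 4, 3000)
        s = seq_of(tokens, 4)
        total = sum(
            commit_time_counts(s, (i, j), [1])[0]
            for i in range(4)
            for j in range(4)
            if i != j
        )
        assert total == np.count_nonzero(np.diff(tokens))

    def test_invalid_tau_rejected(self):
        with pytest.raises(PreconditionError):
            commit_time_counts(seq_of([0, 1]), (0, 1), [0])


class TestDetailedBalance:
    def test_reversible_chain_not_flagged(self):
        # symmetric T => reversible; forward/backward statistics agree
        T = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
        members = [
            seq_of(sample_markov_chain(T, 20_000, seed=s), 3) for s in range(6)
        ]
        curves = ensemble_commit_curves(members, commit_grid=range(1, 15))
        report = detailed_balance_report(curves)
        assert not any(r.flagged for r in report.values())

    def test_equal_curves_have_zero_asymmetry(self):
        # starts and ends in 0: forward and backward counts equal exactly
        s = seq_of([0, 1] * 100 + [0], 2)
        curves = ensemble_commit_curves([s, s], commit_grid=[1, 2])
        report = detailed_balance_report(curves)
        assert report[(0, 1)].max_z == 0.0
        assert not report[(0, 1)].flagged

    def test_alternation_edge_artifact_not_flagged(self):
        # fwd exceeds bwd by exactly one event per member; with ~200 events
        # that is far inside counting noise
        s = seq_of([0, 1] * 100, 2)
        curves = ensemble_commit_curves([s, s, s], commit_grid=[1])
        report = detailed_balance_report(curves)
        assert not report[(0, 1)].flagged

    def test_driven_cycle_is_flagged(self):
        # circulating probability flux 0 -> 1 -> 2 -> 0: the canonical
        # detailed-balance violation
        rng = np.random.default_rng(7)
        members = []
        for _ in range(3):
            toks = np.repeat(np.tile([0, 1, 2], 200), rng.integers(1, 4, 600))
            members.append(seq_of(toks, 3))
        curves = ensemble_commit_curves(members, commit_grid=range(1, 4))
        report = detailed_balance_report(curves)
        assert any(r.flagged for r in report.values())

    def test_one_way_conversion_scales_as_sqrt_members(self):
        # each member shows exactly one 0 -> 1 conversion and never returns;
        # the pooled z is sqrt(m), crossing the threshold at m >= 10
        def z_for(m):
            members = [
                seq_of([0] * (500 + 7 * k) + [1] * (500 - 7 * k), 2)
                for k in range(m)
            ]
            curves = ensemble_commit_curves(members, commit_grid=range(1, 5))
            return detailed_balance_report(curves)[(0, 1)]
        assert not z_for(5).flagged
        assert z_for(12).flagged
        assert z_for(12).max_z == pytest.approx(np.sqrt(12))

    def test_missing_reverse_curve_rejected(self):
        s = seq_of([0, 1, 0], 2)
        curves = ensemble_commit_curves([s], pairs=[(0, 1)], commit_grid=[1])
        with pytest.raises(PreconditionError):
            detailed_balance_report(curves)


class TestFreeEnergy:
    def test_uniform_counts_give_flat_profile(self):
        x = np.repeat([0.1, 0.35, 0.6, 0.85], 100)
        prof = free_energy_1d(x, n_bins=4)
        np.testing.assert_allclose(prof.free_energy, 0.0, atol=1e-12)

    def test_two_bin_log_ratio(self):
        c = 1000
        n0 = int(round(np.exp(-1.0) * c))
        x = np.concatenate([np.zeros(n0), np.ones(c)])
        prof = free_energy_1d(x, n_bins=2)
        assert prof.free_energy[1] == 0.0
        assert prof.free_energy[0] == pytest.approx(1.0, abs=2e-3)

    def test_gaussian_well_recovers_quadratic(self):
        kappa = 4.0
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 1.0 / np.sqrt(kappa), 200_000)
        prof = free_energy_1d(x, n_bins=25)
        mask = prof.occupied & (np.abs(prof.bin_centers) < 0.8)
        expected = 0.5 * kappa * prof.bin_centers[mask] ** 2
        expected -= expected.min()
        np.testing.assert_allclose(
            prof.free_energy[mask], expected, atol=0.12
        )

    def test_empty_bins_masked_not_interpolated(self):
        x = np.concatenate([np.zeros(50), np.ones(50) * 10])
        prof = free_energy_1d(x, n_bins=10)
        assert not prof.occupied[4]
        assert np.isnan(prof.free_energy[4])

    def test_minimum_is_zero(self):
        rng = np.random.default_rng(4)
        prof = free_energy_1d(rng.standard_normal(5000), n_bins=12)
        assert np.nanmin(prof.free_energy) == pytest.approx(0.0, abs=1e-12)


class TestCompareCurves:
    def _curves(self, seed, n=20_000, members=4):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        seqs = [
            seq_of(sample_markov_chain(T, n, seed=seed * 100 + s), 2)
            for s in range(members)
        ]
        return ensemble_commit_curves(seqs, commit_grid=range(1, 12))

    def test_identical_curves_agree_fully(self):
        c = self._curves(1)
        res = compare_curves(c[(0, 1)], c[(0, 1)])
        assert res.agreement == 1.0
        assert res.max_z == 0.0

    def test_statistical_replicas_agree(self):
        a = self._curves(2)
        b = self._curves(3)
        res = compare_curves(a[(0, 1)], b[(0, 1)])
        assert res.agreement >= 0.9

    def test_gross_mismatch_fails(self):
        a = self._curves(4)
        # a chain with 5x the transition rate: curves differ strongly
        T_fast = np.array([[0.5, 0.5], [0.6, 0.4]])
        fast = [
            seq_of(sample_markov_chain(T_fast, 20_000, seed=s), 2)
            for s in range(4)
        ]
        b = ensemble_commit_curves(fast, commit_grid=range(1, 12))
        res = compare_curves(a[(0, 1)], b[(0, 1)])
        assert res.agreement < 0.5

    def test_grid_mismatch_rejected(self):
        a = self._curves(5)
        s = seq_of([0, 1] * 50, 2)
        b = ensemble_commit_curves([s], commit_grid=[1, 2])
        with pytest.raises(PreconditionError):
            compare_curves(a[(0, 1)], b[(0, 1)])


def test_default_commit_grid_uses_run_length_quantile():
    s = seq_of([0] * 100 + [1] * 100 + [0] * 5, 2)
    grid = default_commit_grid([s])
    assert grid[0] == 1
    assert grid[-1] <= 100
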