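"""Spike conversion: quantile detection, tolerance matching, beta search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from rssrm.conversion import (
    ConversionConfig,
    greedy_match,
    max_tolerance,
    potentials_to_spikes,
    select_beta,
    tolerant_spike_train,
)
from rssrm.izhikevich import SpikeTrain
from rssrm.metrics import precision_recall_f1


def oracle_max_matching_size(a, b, tau):
    """Maximum bipartite matching size with |a_i - b_j| <= tau edges."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    adj = (np.abs(a[:, None] - b[None, :]) <= tau).astype(int)
    if adj.sum() == 0:
        return 0
    m = maximum_bipartite_matching(csr_matrix(adj), perm_type="column")
    return int(np.sum(m >= 0))


class TestPotentialsToSpikes:
    def test_threshold_is_the_inflated_quantile(self, rng):
        u = rng.normal(size=400)
        train = potentials_to_spikes(u, r=0.10, beta=1.5, dt=1.0)
        q = np.quantile(u, 0.85)  # r*beta = 15% above the 85th quantile
        expect = {
            t for t in range(1, 399)
            if u[t] > q and u[t] > u[t - 1] and u[t] >= u[t + 1]
        }
        assert set(train.times.astype(int)) == expect

    def test_constant_potential_never_spikes(self):
        train = potentials_to_spikes(np.full(50, 2.0), r=0.1, beta=1.0, dt=1.0)
        assert train.n_spikes == 0

    def test_isolated_peak_is_the_single_spike(self):
        train = potentials_to_spikes(
            np.array([0.0, 0.0, 10.0, 0.0, 0.0]), r=0.2, beta=1.0, dt=1.0
        )
        assert list(train.times) == [2.0]

    def test_plateau_spikes_once_at_its_left_edge(self):
        u = np.array([0.0, 6.0, 6.0, 6.0, 0.0, 0.0])
        train = potentials_to_spikes(u, r=0.5, beta=1.0, dt=1.0)
        assert list(train.times) == [1.0]

    def test_endpoints_never_spike(self):
        u = np.array([9.0, 0.0, 0.0, 9.0])
        train = potentials_to_spikes(u, r=0.24, beta=1.0, dt=1.0)
        assert train.n_spikes == 0

    def test_saturated_firing_ratio_rejected(self):
        with pytest.raises(ValueError):
            potentials_to_spikes(np.zeros(10), r=0.5, beta=2.0, dt=1.0)

    @given(beta=st.lists(st.floats(1.0, 9.0), min_size=2, max_size=6))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_raising_beta_weakly_increases_spike_count(self, beta):
        rng = np.random.default_rng(7)
        u = rng.normal(size=300)
        counts = [
            potentials_to_spikes(u, r=0.05, beta=b, dt=1.0).n_spikes
            for b in sorted(beta)
        ]
        assert all(c1 <= c2 for c1, c2 in zip(counts, counts[1:]))


class TestMaxTolerance:
    def test_worked_example_upper_bound(self):
        res = max_tolerance([3.0, 15.0], [1.0, 10.0], dt=1.0)
        assert res.tau_upper_bound == pytest.approx(14.0)

    def test_identical_sets_need_no_tolerance(self):
        res = max_tolerance([2.0, 7.0], [2.0, 7.0], dt=0.5)
        assert res.tau_max == 0.0
        assert len(res.matching) == 2

    def test_single_pair_two_ms_apart(self):
        res = max_tolerance([5.0], [7.0], dt=1.0)
        assert res.tau_max == pytest.approx(2.0)

    def test_cap_clips_and_flags(self):
        res = max_tolerance([0.0], [100.0], dt=1.0, cap=30.0)
        assert res.capped and res.tau_max == 30.0
        assert len(res.matching) == 0

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            max_tolerance([], [1.0], dt=1.0)

    @given(
        a=st.lists(st.integers(0, 40), min_size=1, max_size=6),
        b=st.lists(st.integers(0, 40), min_size=1, max_size=6),
        tau=st.integers(0, 12),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_greedy_matching_is_maximum(self, a, b, tau):
        a, b = sorted(set(a)), sorted(set(b))
        got = len(greedy_match(np.array(a, float), np.array(b, float), tau))
        assert got == oracle_max_matching_size(a, b, tau)

    @given(
        a=st.lists(st.integers(0, 30), min_size=1, max_size=5),
        b=st.lists(st.integers(0, 30), min_size=1, max_size=5),
    )
    @settings(deadline=None, max_examples=150, derandomize=True)
    def test_tau_max_equals_brute_force_sweep(self, a, b):
        """Smallest dt multiple at which the smaller set is fully matched."""
        a, b = sorted(set(a)), sorted(set(b))
        res = max_tolerance(a, b, dt=1.0)
        need = min(len(a), len(b))
        swept = next(
            k for k in range(0, 70)
            if oracle_max_matching_size(a, b, k) >= need
        )
        assert res.tau_max == pytest.approx(float(swept))


class TestTolerantTrain:
    def test_zero_tolerance_keeps_the_prediction(self):
        out = tolerant_spike_train([3.0], [1.0, 10.0], tau=0.0, n_steps=20, dt=1.0)
        assert list(out.times) == [1.0, 10.0]

    def test_matched_spikes_move_onto_true_times(self):
        out = tolerant_spike_train(
            [3.0, 15.0], [1.0, 10.0], tau=2.0, n_steps=20, dt=1.0
        )
        assert list(out.times) == [3.0, 10.0]

    def test_tolerance_at_tau_max_matches_every_partner(self, rng):
        a = np.sort(rng.choice(60, size=5, replace=False)).astype(float)
        b = np.sort(rng.choice(60, size=4, replace=False)).astype(float)
        res = max_tolerance(a, b, dt=1.0)
        out = tolerant_spike_train(a, b, res.tau_max, n_steps=60, dt=1.0)
        assert sum(t in a for t in out.times) >= min(len(a), len(b))

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            tolerant_spike_train([1.0], [1.0], tau=-1.0, n_steps=5, dt=1.0)


class TestSelectBeta:
    def _truth(self, times, n, dt=1.0):
        return SpikeTrain.from_times(times, n_steps=n, dt=dt)

    def test_single_element_grid_is_chosen(self, rng):
        u = rng.normal(size=100)
        u[50] += 10
        truth = self._truth([50.0], 100)
        best = select_beta(u, truth, ConversionConfig(beta_grid=(1.2,)), dt=1.0)
        assert best["beta"] == 1.2

    def test_perfect_prediction_ties_break_to_smallest_beta(self):
        u = np.zeros(100)
        u[[20, 60]] = 5.0
        truth = self._truth([20.0, 60.0], 100)
        cfg = ConversionConfig(beta_grid=tuple(np.linspace(1.0, 1.5, 11)))
        best = select_beta(u, truth, cfg, dt=1.0)
        assert best["beta"] == 1.0
        assert best["f1"] == 1.0

    def test_grid_search_matches_exhaustive_oracle(self, rng):
        u = rng.normal(size=200)
        truth = self._truth(np.sort(rng.choice(np.arange(1, 199), 8, False)).astype(float), 200)
        cfg = ConversionConfig(beta_grid=tuple(np.linspace(1.0, 8.0, 9)))
        best = select_beta(u, truth, cfg, dt=1.0)
        # exhaustive re-evaluation of the same grid
        scores = {}
        for b in cfg.beta_grid:
            raw = potentials_to_spikes(u, truth.r, b, dt=1.0)
            if raw.n_spikes == 0:
                scores[b] = 0.0
                continue
            tol = max_tolerance(truth.times, raw.times, dt=1.0)
            adj = tolerant_spike_train(truth.times, raw.times, tol.tau_max, 200, 1.0)
            scores[b] = precision_recall_f1(truth.indicator, adj.indicator).f1
        assert best["f1"] == pytest.approx(max(scores.values()))

    def test_infeasible_inflations_are_skipped(self):
        u = np.zeros(10)
        u[5] = 1.0
        truth = SpikeTrain.from_times([4.0], n_steps=10, dt=1.0)
        cfg = ConversionConfig(beta_grid=(1.0, 50.0))  # r=0.1: beta=50 invalid
        best = select_beta(u, truth, cfg, dt=1.0)
        assert best["beta"] == 1.0

    def test_f1_non_decreasing_in_tolerance(self, rng):
        a = np.sort(rng.choice(80, size=6, replace=False)).astype(float)
        b = np.sort(rng.choice(80, size=6, replace=False)).astype(float)
        truth = SpikeTrain.from_times(a, n_steps=80, dt=1.0)
        f1s = []
        for tau in range(0, 50, 5):
            adj = tolerant_spike_train(a, b, float(tau), n_steps=80, dt=1.0)
            f1s.append(precision_recall_f1(truth.indicator, adj.indicator).f1)
        assert all(x <= y + 1e-12 for x, y in zip(f1s, f1s[1:]))
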