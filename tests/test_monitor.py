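"""Run-length decision rule: detection curves, false alarms, waiting times."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import erdmonitor as em
from erdmonitor.monitor import MonitorResult


def enumerate_detection(p, n, k):
    """Brute-force oracle: sum the probability of every 0/1 sequence of
    length n that contains a run of >= k ones, cumulatively per trial."""
    out = np.zeros(n)
    for bits in range(2**n):
        seq = [(bits >> i) & 1 for i in range(n)]
        prob = np.prod([p if b else 1 - p for b in seq])
        run = 0
        first = 0
        for t, b in enumerate(seq, start=1):
            run = run + 1 if b else 0
            if run >= k:
                first = t
                break
        if first:
            out[first - 1 :] += prob
    return out


class TestFprRun:
    def test_printed_example(self):
        assert em.fpr_run(0.92, 4) == pytest.approx(4.096e-5, rel=1e-12)

    def test_edge_rates(self):
        assert em.fpr_run(1.0, 4) == 0.0
        assert em.fpr_run(0.0, 4) == 1.0

    @given(p=st.floats(0, 1), k=st.integers(1, 8))
    @settings(derandomize=True, max_examples=50)
    def test_single_window_identity(self, p, k):
        """(1−p)^k equals the detection probability of a k-run of failures
        in exactly one k-trial window."""
        assert em.fpr_run(p, k) == pytest.approx(
            em.detection_prob_analytic(1 - p, k, k)[-1], abs=1e-12
        )


class TestAnalyticCurve:
    def test_impossible_before_k_trials(self):
        curve = em.detection_prob_analytic(0.9, 10, k=4)
        assert np.all(curve[:3] == 0)

    def test_certain_with_perfect_rate(self):
        curve = em.detection_prob_analytic(1.0, 4, k=4)
        assert curve[-1] == pytest.approx(1.0)

    def test_first_window_value(self):
        curve = em.detection_prob_analytic(0.92, 4, k=4)
        assert curve[-1] == pytest.approx(0.92**4, abs=1e-15)

    def test_matches_exhaustive_enumeration_n12(self):
        got = em.detection_prob_analytic(0.92, 12, k=4)
        want = enumerate_detection(0.92, 12, 4)
        assert np.max(np.abs(got - want)) < 1e-12

    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5, 0.7, 0.9])
    @pytest.mark.parametrize("n,k", [(8, 3), (10, 4), (14, 4)])
    def test_enumeration_grid(self, p, n, k):
        got = em.detection_prob_analytic(p, n, k)
        want = enumerate_detection(p, n, k)
        assert np.max(np.abs(got - want)) < 1e-12

    @given(p=st.floats(0.05, 0.95), q=st.floats(0.05, 0.95))
    @settings(derandomize=True, max_examples=40)
    def test_monotone_in_p_and_n(self, p, q):
        lo, hi = sorted((p, q))
        a = em.detection_prob_analytic(lo, 12, 4)
        b = em.detection_prob_analytic(hi, 12, 4)
        assert np.all(b - a >= -1e-12)  # monotone in p
        assert np.all(np.diff(a) >= -1e-15)  # monotone in n


class TestMonteCarlo:
    def test_agrees_with_analytic_within_3_se(self):
        curve, se = em.detection_prob_mc(0.92, 18, 4, n_sims=100_000, seed=3)
        exact = em.detection_prob_analytic(0.92, 18, 4)
        assert np.all(np.abs(curve - exact) <= 3 * np.maximum(se, 1e-4))

    def test_perfect_rate_is_step_function(self):
        curve, se = em.detection_prob_mc(1.0, 8, 4, n_sims=500, seed=0)
        assert np.all(curve[:3] == 0) and np.all(curve[3:] == 1) and np.all(se == 0)

    def test_se_shrinks_like_root_n(self):
        c1, se1 = em.detection_prob_mc(0.6, 10, 3, n_sims=2000, seed=1)
        c2, se2 = em.detection_prob_mc(0.6, 10, 3, n_sims=8000, seed=1)
        mid = 5  # a trial index with non-degenerate probability
        assert se2[mid] == pytest.approx(se1[mid] / 2, rel=0.25)

    def test_reproducible(self):
        a = em.detection_prob_mc(0.8, 10, 4, n_sims=1000, seed=9)[0]
        b = em.detection_prob_mc(0.8, 10, 4, n_sims=1000, seed=9)[0]
        assert np.array_equal(a, b)


class TestExtendObserved:
    def test_all_correct_detects_at_trial_four(self):
        seqs = [np.ones(9, int)] * 5
        res = em.extend_observed_curve(seqs, p_hat=0.9, extra_trials=9, n_sims=50, seed=0)
        assert res.cumulative_detection[2] == 0
        assert res.cumulative_detection[3] == pytest.approx(1.0)
        assert np.all(res.cumulative_detection[3:] == 1.0)

    def test_consistent_with_analytic_for_bernoulli_outcomes(self):
        p = 0.92
        rng = np.random.default_rng(5)
        seqs = list((rng.random((400, 9)) < p).astype(int))
        res = em.extend_observed_curve(seqs, p_hat=p, extra_trials=9, n_sims=200, seed=1)
        exact = em.detection_prob_analytic(p, 18, 4)
        se = np.maximum(res.se, 1e-3)
        assert np.all(np.abs(res.cumulative_detection - exact) <= 3.5 * se)

    def test_zero_extra_trials_truncates(self):
        seqs = [np.array([1, 1, 1, 0, 1, 1, 1, 1, 0])]
        res = em.extend_observed_curve(seqs, p_hat=0.5, extra_trials=0, n_sims=10, seed=0)
        assert len(res.cumulative_detection) == 9
        assert res.cumulative_detection[-1] == pytest.approx(1.0)  # run at trials 5-8

    def test_empty_observations_error(self):
        with pytest.raises(ValueError, match="no observed"):
            em.extend_observed_curve([], p_hat=0.9)

    def test_streak_carry_option(self):
        # 3 trailing hits + continuation: carrying the streak detects sooner
        seqs = [np.array([0, 0, 0, 0, 0, 0, 1, 1, 1])] * 200
        carry = em.extend_observed_curve(seqs, p_hat=1.0, extra_trials=2, n_sims=1, seed=0)
        reset = em.extend_observed_curve(
            seqs, p_hat=1.0, extra_trials=2, n_sims=1, seed=0, carry_streak=False
        )
        assert carry.cumulative_detection[9] == pytest.approx(1.0)
        assert reset.cumulative_detection[-1] == pytest.approx(0.0)


class TestWaitingTime:
    def test_geometric_case(self):
        # a = 1-p = 0.5, k=1: expected waiting time 2 trials
        assert em.expected_time_to_false_alarm(0.5, k=1, trial_duration_s=1.0) == pytest.approx(2.0)

    def test_deterministic_run(self):
        assert em.expected_time_to_false_alarm(0.0, k=4, trial_duration_s=8.0) == pytest.approx(32.0)

    def test_printed_rate_example_against_markov_solve(self):
        """p=0.92, k=4: ≈26536 trials ≈ 212287 s (≈59 h); oracle is the
        linear first-passage system E_i = 1 + a·E_{i+1} + (1−a)·E_0."""
        secs = em.expected_time_to_false_alarm(0.92, k=4, trial_duration_s=8.0)
        assert secs / 8.0 == pytest.approx(26535.94, rel=1e-6)
        a, k = 0.08, 4
        A = np.zeros((k, k))
        for i in range(k):
            A[i, i] = 1.0
            if i + 1 < k:
                A[i, i + 1] -= a
            A[i, 0] -= 1 - a
        expected_trials = np.linalg.solve(A, np.ones(k))[0]
        assert secs == pytest.approx(expected_trials * 8.0, rel=1e-8)

    def test_waiting_time_matches_simulation(self):
        """Mean of simulated first-run waiting times agrees with the closed
        form (vectorized Bernoulli streams, streak carry across chunks)."""
        a, k, n_sims, chunk = 0.08, 4, 1500, 40_000
        rng = np.random.default_rng(11)
        waits = np.zeros(n_sims)
        pending = np.arange(n_sims)
        streak = np.zeros(n_sims, int)
        offset = 0
        while pending.size:
            x = rng.random((pending.size, chunk)) < a
            st = streak[pending]
            first = np.zeros(pending.size, int)
            for t in range(chunk):
                st = (st + 1) * x[:, t]
                hit = (first == 0) & (st >= k)
                first[hit] = t + 1
            done = first > 0
            waits[pending[done]] = offset + first[done]
            streak[pending[~done]] = st[~done]
            pending = pending[~done]
            offset += chunk
        closed = em.expected_time_to_false_alarm(1 - a, k=k, trial_duration_s=1.0)
        assert waits.mean() == pytest.approx(closed, rel=0.08)

    def test_perfect_rate_never_false_alarms(self):
        assert math.isinf(em.expected_time_to_false_alarm(1.0))

    def test_from_window_fpr(self):
        hours = em.time_to_false_alarm_from_window_fpr(0.0003) / 3600.0
        assert hours == pytest.approx(8.527, rel=1e-3)

    def test_first_alarm_latency(self):
        assert em.first_alarm_latency_s(4, 8.0) == 32.0


class TestMonitorResult:
    def test_rejects_decreasing_curve(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            MonitorResult(np.array([0, 0, 0, 0.5, 0.4]), None, 0.0, 1.0, "analytic")

    def test_rejects_detection_before_k(self):
        with pytest.raises(ValueError, match="impossible"):
            MonitorResult(np.array([0.2, 0.3, 0.4, 0.5]), None, 0.0, 1.0, "analytic", k=4)

    def test_times_axis(self):
        r = MonitorResult(np.array([0.0, 0.0, 0.0, 0.4]), None, 0.0, 1.0, "analytic")
        assert np.array_equal(r.times_s, [8.0, 16.0, 24.0, 32.0])
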