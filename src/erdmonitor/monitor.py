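"""The "four-in-a-row" monitor decision layer.

A warning is emitted only after k (default 4) consecutive single-trial
'movement' classifications.  With per-trial classification rate p and 8-s
trials this module computes:

* the per-window false-positive rate (1−p)^k — the probability that one
  window of k no-movement trials is entirely misclassified,
* the exact cumulative probability of a true detection within n trials
  (streak-state Markov recursion over the current run length),
* Monte-Carlo versions of the curve, including the continuation of observed
  per-sequence classifier outcomes beyond the recorded nine trials,
* the expected waiting time until the first false alarm, from the classical
  closed form for the first run of k failures in Bernoulli trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DecisionConfig",
    "MonitorResult",
    "fpr_run",
    "detection_prob_analytic",
    "detection_prob_mc",
    "extend_observed_curve",
    "expected_time_to_false_alarm",
    "time_to_false_alarm_from_window_fpr",
    "first_alarm_latency_s",
]


@dataclass
class DecisionConfig:
    """Run-length rule parameters."""

    k: int = 4
    trial_duration_s: float = 8.0
    p: float | None = None  # per-trial classification rate, set per analysis

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("run length k must be >= 1")
        if self.trial_duration_s <= 0:
            raise ValueError("trial_duration_s must be positive")
        if self.p is not None and not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")


@dataclass
class MonitorResult:
    """Detection curve plus false-alarm summary for one setting."""

    cumulative_detection: np.ndarray  # per trial index, length n_trials
    se: np.ndarray | None
    fpr_per_window: float
    expected_time_to_false_alarm_s: float
    method: str
    trial_duration_s: float = 8.0
    k: int = 4

    def __post_init__(self) -> None:
        c = np.asarray(self.cumulative_detection, dtype=float)
        if np.any(c < -1e-12) or np.any(c > 1 + 1e-12):
            raise ValueError("cumulative detection outside [0, 1]")
        if np.any(np.diff(c) < -1e-12):
            raise ValueError("cumulative detection must be non-decreasing")
        if self.k >= 1 and np.any(c[: self.k - 1] > 1e-12):
            raise ValueError(f"detection before trial {self.k} is impossible")
        self.cumulative_detection = c

    @property
    def times_s(self) -> np.ndarray:
        return (np.arange(len(self.cumulative_detection)) + 1) * self.trial_duration_s


def _check_p(p: float) -> float:
    p = float(p)
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    return p


def fpr_run(p: float, k: int = 4) -> float:
    """False-positive probability of one k-trial window: (1 − p)^k."""
    return (1.0 - _check_p(p)) ** int(k)


def detection_prob_analytic(p: float, n_trials: int, k: int = 4) -> np.ndarray:
    """Exact P(a run of ≥k successes occurs within the first n trials).

    Streak-state Markov recursion: states are the current success streak
    0..k−1 plus an absorbing 'detected' state; each Bernoulli(p) trial
    advances or resets the streak.  Returns the cumulative probability after
    trials 1..n_trials.
    """
    p = _check_p(p)
    k = int(k)
    if k < 1:
        raise ValueError("k must be >= 1")
    n_trials = int(n_trials)
    state = np.zeros(k + 1)
    state[0] = 1.0
    out = np.empty(n_trials)
    for t in range(n_trials):
        new = np.zeros_like(state)
        new[k] = state[k] + state[k - 1] * p
        new[1:k] = state[0:k - 1] * p
        new[0] = state[:k].sum() * (1.0 - p)
        state = new
        out[t] = state[k]
    return out


def _runs_detect(outcomes: np.ndarray, k: int, initial_streaks: np.ndarray | None = None):
    """Per-sequence first trial index (1-based) at which a run of k ones
    completes, or 0 if never.  ``outcomes``: (n_seq, n_trials) of {0,1}."""
    n_seq, n_trials = outcomes.shape
    streak = np.zeros(n_seq, dtype=int) if initial_streaks is None else initial_streaks.copy()
    first = np.zeros(n_seq, dtype=int)
    for t in range(n_trials):
        streak = (streak + 1) * outcomes[:, t]
        hit = (first == 0) & (streak >= k)
        first[hit] = t + 1
    return first, streak


def detection_prob_mc(
    p: float, n_trials: int, k: int = 4, n_sims: int = 10000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo estimate of the cumulative detection curve ± its binomial
    standard error, from ``n_sims`` simulated Bernoulli(p) sequences."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    p = _check_p(p)
    rng = np.random.default_rng(seed)
    outcomes = (rng.random((n_sims, int(n_trials))) < p).astype(np.int8)
    first, _ = _runs_detect(outcomes, int(k))
    detected_by = np.zeros(int(n_trials))
    for t in range(1, int(n_trials) + 1):
        detected_by[t - 1] = np.mean((first > 0) & (first <= t))
    se = np.sqrt(detected_by * (1 - detected_by) / n_sims)
    return detected_by, se


def extend_observed_curve(
    observed_outcomes_per_sequence,
    p_hat: float,
    extra_trials: int = 9,
    n_sims: int = 1000,
    seed: int = 0,
    k: int = 4,
    trial_duration_s: float = 8.0,
    carry_streak: bool = True,
) -> MonitorResult:
    """Empirical detection curve from recorded per-trial classifications,
    extended past the recorded trials by Monte-Carlo continuation.

    ``observed_outcomes_per_sequence``: iterable of equal-length binary
    arrays (1 = trial classified as movement), one per recorded movement
    sequence.  The first part of the curve is the observed fraction of
    sequences with a completed k-run; each sequence still undetected at the
    end of its recording is continued for ``extra_trials`` Bernoulli(p_hat)
    trials, ``n_sims`` times.  ``carry_streak=False`` resets the running
    streak at the continuation boundary.
    """
    seqs = [np.asarray(s, dtype=int).ravel() for s in observed_outcomes_per_sequence]
    if not seqs:
        raise ValueError("no observed sequences given")
    n_obs = len(seqs[0])
    if any(len(s) != n_obs for s in seqs) or n_obs == 0:
        raise ValueError("sequences must be non-empty and of equal length")
    p_hat = _check_p(p_hat)
    outcomes = np.stack(seqs)
    first, streak = _runs_detect(outcomes, int(k))
    n_seq = len(seqs)
    n_total = n_obs + int(extra_trials)

    curve = np.zeros(n_total)
    for t in range(1, n_obs + 1):
        curve[t - 1] = np.mean((first > 0) & (first <= t))

    if extra_trials > 0:
        undet = first == 0
        rng = np.random.default_rng(seed)
        tail = np.zeros(int(extra_trials))
        if undet.any():
            init = streak[undet] if carry_streak else np.zeros(undet.sum(), dtype=int)
            for _ in range(int(n_sims)):
                sim = (rng.random((int(undet.sum()), int(extra_trials))) < p_hat).astype(np.int8)
                f2, _ = _runs_detect(sim, int(k), initial_streaks=init)
                for t in range(1, int(extra_trials) + 1):
                    tail[t - 1] += np.sum((f2 > 0) & (f2 <= t))
            tail /= n_sims * n_seq
        curve[n_obs:] = curve[n_obs - 1] + tail
    # binomial SE over sequences for the observed part, MC-dominated afterwards
    se = np.sqrt(np.clip(curve * (1 - curve), 0, None) / n_seq)
    return MonitorResult(
        curve, se, fpr_run(p_hat, k),
        expected_time_to_false_alarm(p_hat, k, trial_duration_s),
        method="hybrid", trial_duration_s=trial_duration_s, k=k,
    )


def expected_time_to_false_alarm(
    p: float, k: int = 4, trial_duration_s: float = 8.0
) -> float:
    """Expected seconds until the first run of k misclassified no-movement
    trials, for per-trial classification rate p.

    With per-trial miss probability a = 1 − p, the expected number of trials
    to the first run of k failures is E[T] = (1 − a^k) / ((1 − a) a^k);
    ``inf`` when p = 1 (a false alarm never occurs), k trials when p = 0.
    """
    p = _check_p(p)
    a = 1.0 - p
    if a == 0.0:
        return math.inf
    if a == 1.0:
        return k * trial_duration_s
    trials = (1.0 - a**k) / ((1.0 - a) * a**k)
    return trials * trial_duration_s


def time_to_false_alarm_from_window_fpr(
    fpr_window: float, k: int = 4, trial_duration_s: float = 8.0
) -> float:
    """Expected time to the first false alarm given the per-window FPR a^k.

    Inverts the window rate to the per-trial miss probability a and applies
    the run-waiting-time closed form.
    """
    if not 0 < fpr_window <= 1:
        raise ValueError("fpr_window must be in (0, 1]")
    a = fpr_window ** (1.0 / k)
    return expected_time_to_false_alarm(1.0 - a, k, trial_duration_s)


def first_alarm_latency_s(k: int = 4, trial_duration_s: float = 8.0) -> float:
    """Earliest possible warning: k consecutive trials must complete."""
    return k * trial_duration_s
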