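"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ContinuousRecording", "EpochSet", "FeatureMatrix", "MOVEMENT", "NO_MOVEMENT"]

MOVEMENT = "movement"
NO_MOVEMENT = "no_movement"

#: Event table columns: cue and instruction events with paradigm bookkeeping.
EVENT_COLUMNS = ("onset_s", "duration_s", "kind", "condition", "block", "sequence", "trial")


@dataclass
class ContinuousRecording:
    """A multichannel recording (µV) with timed paradigm events.

    ``events`` is a DataFrame with columns ``onset_s, duration_s, kind,
    condition, block, sequence, trial``; ``kind`` is ``'cue'`` or
    ``'instruction'``, blocks and sequences are 1-based, ``trial`` is the
    1-based trial number within its sequence (0 for instructions).
    """

    data: np.ndarray  # (n_channels, n_samples), µV
    sample_rate_hz: float
    labels: tuple[str, ...]
    events: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = tuple(self.labels)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.labels):
            raise ValueError("data must be (n_channels, n_samples) matching labels")
        missing = set(EVENT_COLUMNS) - set(self.events.columns)
        if missing:
            raise ValueError(f"events missing columns: {sorted(missing)}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def cues(self) -> pd.DataFrame:
        return self.events[self.events["kind"] == "cue"].reset_index(drop=True)


@dataclass
class EpochSet:
    """Trials cut relative to cue onset.

    ``data`` is (n_trials, n_channels, n_samples) in µV; ``times`` holds the
    per-sample offsets in seconds relative to cue onset.  ``labels`` are the
    per-trial conditions; ``block`` and ``sequence`` index the experimental
    structure (used for block calibration and leakage-free fold assignment).
    """

    data: np.ndarray
    times: np.ndarray
    channels: tuple[str, ...]
    labels: np.ndarray  # condition per trial
    block: np.ndarray
    sequence: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.channels = tuple(self.channels)
        self.labels = np.asarray(self.labels)
        self.block = np.asarray(self.block, dtype=int)
        self.sequence = np.asarray(self.sequence, dtype=int)
        n_tr, n_ch, n_sa = self.data.shape
        if n_ch != len(self.channels) or n_sa != len(self.times):
            raise ValueError("EpochSet shape mismatch")
        if not (len(self.labels) == len(self.block) == len(self.sequence) == n_tr):
            raise ValueError("per-trial metadata length mismatch")
        bad = set(np.unique(self.labels)) - {MOVEMENT, NO_MOVEMENT}
        if bad:
            raise ValueError(f"unknown condition labels: {bad}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select_trials(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            self.data[mask], self.times, self.channels, self.labels[mask],
            self.block[mask], self.sequence[mask], self.sample_rate_hz,
        )

    def channel(self, label: str) -> np.ndarray:
        return self.data[:, self.channels.index(label), :]


@dataclass
class FeatureMatrix:
    """Trials × spectral features with (channel, band, period) metadata.

    ``index`` is a list of ``(channel, (low_hz, high_hz), period)`` tuples,
    one per column; band edges are half-open ``[low, high)``.
    """

    values: np.ndarray  # (n_trials, n_features)
    index: list[tuple]
    labels: np.ndarray
    block: np.ndarray
    sequence: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.index):
            raise ValueError("feature matrix / index mismatch")
        self.labels = np.asarray(self.labels)
        self.block = np.asarray(self.block, dtype=int)
        self.sequence = np.asarray(self.sequence, dtype=int)

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [
            f"{ch}_{low:g}-{high:g}Hz_{period}" for ch, (low, high), period in self.index
        ]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "condition", self.labels)
        df.insert(1, "block", self.block)
        df.insert(2, "sequence", self.sequence)
        return df
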