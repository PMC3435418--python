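"""Synthetic EEG sessions with movement-related ERD/ERS structure.

The generator emulates a cued synchronous movement paradigm: sequences of
nine consecutive trials, each trial a 3-s auditory cue preceded by a silence
of random duration between 4 and 6 s; four experimental blocks, each with
four sequences per condition in randomized order, giving 144 trials per
condition at the defaults; 256 Hz sampling.

Signal model (per channel, all components independent across channels):

* broadband 1/f ("pink") Gaussian background noise,
* band-limited mu (8–12 Hz) and beta (17–23 Hz) oscillations with random
  phase (narrowband Gaussian processes),
* an amplitude envelope applied to the whole sensorimotor band (the pink
  component between the mu lower edge and the beta upper edge, plus both
  oscillators): during movement trials the in-band power drops by the ERD
  depth from cue onset until ``erd_extension_s`` past cue offset, then
  rebounds above baseline by the ERS gain for ~2.5 s (post-movement
  synchronization),
* optional broadband >25 Hz noise added only during movement cues, mimicking
  EMG contamination of scalp channels during executed movement.

``erd_depth`` and ``ers_gain`` are calibrated quantities: they equal the
average fractional change in sensorimotor band power over the fixed analysis
windows 0–4 s (ERD) and 4–6 s (ERS) relative to no-movement trials, at a
channel with spatial weight 1, measured in sensor space.  Envelope ramps are
placed so the window averages are exact (see docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import MOVEMENT, NO_MOVEMENT, ContinuousRecording
from .layout import ElectrodeLayout, default_layout

__all__ = ["GeneratorConfig", "schedule_session", "synthesize", "simulate_session", "default_spatial_profile"]

logger = logging.getLogger(__name__)

#: ERD persists past cue offset (task response time); onset of the power
#: rebound and end of the ERD envelope.
_RAMP_S = 0.3
_ERS_DURATION_S = 2.5
_EMG_CUTOFF_HZ = 25.0


def default_spatial_profile(labels) -> dict[str, float]:
    """Motor-cortex effect topography: 1.0 at C3/C4, 0.5 at Cz and their
    immediate neighbours, 0.1 elsewhere."""
    near = {
        "Cz", "C1", "C2", "C5", "C6",
        "FC3", "FC4", "CP3", "CP4", "FC1", "FC2", "CP1", "CP2",
    }
    out = {}
    for l in labels:
        if l in ("C3", "C4"):
            out[l] = 1.0
        elif l in near:
            out[l] = 0.5
        else:
            out[l] = 0.1
    return out


@dataclass
class GeneratorConfig:
    """Paradigm timing and ERD/ERS signal parameters.

    Effect sizes default to the grand-average values the pipeline is meant
    to reproduce: a 30.4% mu/beta power decrease during movement and a 27.4%
    post-movement rebound at full-weight channels.
    """

    sample_rate_hz: float = 256.0
    n_blocks: int = 4
    sequences_per_block_per_condition: int = 4
    trials_per_sequence: int = 9
    cue_s: float = 3.0
    silence_range_s: tuple[float, float] = (4.0, 6.0)
    erd_depth: float = 0.304
    ers_gain: float = 0.274
    erd_extension_s: float = 0.5
    mu_band_hz: tuple[float, float] = (8.0, 12.0)
    beta_band_hz: tuple[float, float] = (17.0, 23.0)
    spatial_profile: dict[str, float] | None = None  # None -> default topography
    noise_exponent: float = 1.0
    emg_contamination: float = 0.0
    seed: int = 0
    # amplitude scales (µV RMS); uniform across channels
    background_rms_uv: float = 10.0
    mu_rms_uv: float = 4.0
    beta_rms_uv: float = 2.0
    instruction_s: float = 2.0
    inter_sequence_gap_s: float = 3.0

    def validate(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        for name in ("n_blocks", "sequences_per_block_per_condition", "trials_per_sequence"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.cue_s <= 0 or self.instruction_s < 0 or self.inter_sequence_gap_s < 0:
            raise ValueError("durations must be positive")
        lo, hi = self.silence_range_s
        if not (0 < lo <= hi):
            raise ValueError("silence_range_s must satisfy 0 < lo <= hi")
        if not 0 <= self.erd_depth < 1:
            raise ValueError("erd_depth must be in [0, 1)")
        if self.ers_gain < 0 or self.emg_contamination < 0:
            raise ValueError("ers_gain and emg_contamination must be >= 0")
        if not 0 <= self.erd_extension_s <= 1 - _RAMP_S / 2:
            raise ValueError("erd_extension_s must be in [0, 0.85]")
        if self._erd_depth_instantaneous() >= 1:
            raise ValueError("erd_depth too large for this erd_extension_s (instantaneous depth >= 1)")
        for band in (self.mu_band_hz, self.beta_band_hz):
            if not (0 < band[0] < band[1] < self.sample_rate_hz / 2):
                raise ValueError(f"band {band} must lie inside (0, Nyquist)")

    @property
    def trials_per_condition(self) -> int:
        return self.n_blocks * self.sequences_per_block_per_condition * self.trials_per_sequence

    def _erd_depth_instantaneous(self) -> float:
        # calibration: the ERD analysis window runs to 1 s past cue offset,
        # the envelope only to erd_extension_s past it
        return self.erd_depth * (self.cue_s + 1.0) / (self.cue_s + self.erd_extension_s)


def schedule_session(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Lay out instruction and cue events for one session.

    Within each block the movement / no-movement sequences are shuffled.
    Returns the event table described in :class:`ContinuousRecording`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.silence_range_s
    rows = []
    t = 2.0  # lead-in so the first baseline window fits
    seq_counter = 0
    for block in range(1, config.n_blocks + 1):
        conditions = [MOVEMENT, NO_MOVEMENT] * config.sequences_per_block_per_condition
        rng.shuffle(conditions)
        for condition in conditions:
            seq_counter += 1
            rows.append((t, config.instruction_s, "instruction", condition, block, seq_counter, 0))
            t += config.instruction_s
            for trial in range(1, config.trials_per_sequence + 1):
                t += rng.uniform(lo, hi)
                rows.append((t, config.cue_s, "cue", condition, block, seq_counter, trial))
                t += config.cue_s
            t += config.inter_sequence_gap_s
    events = pd.DataFrame(
        rows,
        columns=["onset_s", "duration_s", "kind", "condition", "block", "sequence", "trial"],
    )
    if not events["onset_s"].is_monotonic_increasing:
        raise AssertionError("schedule is not strictly increasing in time")
    return events


def _band_mask(freqs: np.ndarray, low: float, high: float) -> np.ndarray:
    return (freqs >= low) & (freqs < high)


def _modulation_envelope(config: GeneratorConfig, events: pd.DataFrame, n: int) -> np.ndarray:
    """Relative in-band power change m(t): −d during ERD spans, +g during ERS
    spans of movement cues, 0 elsewhere.  Linear power ramps of width
    ``_RAMP_S``; ramp placement keeps the 0–4 s / 4–6 s window averages at
    exactly −erd_depth / +ers_gain."""
    fs = config.sample_rate_hz
    t = np.arange(n) / fs
    m = np.zeros(n)
    d = config._erd_depth_instantaneous()
    g = config.ers_gain
    r = _RAMP_S

    def ramp_box(t0, t1, up_center, down_center):
        """Envelope 0→1→0 with linear ramps of width r centred as given."""
        e = np.clip((t - (up_center - r / 2)) / r, 0.0, 1.0)
        e *= np.clip(((down_center + r / 2) - t) / r, 0.0, 1.0)
        return e

    cues = events[(events["kind"] == "cue") & (events["condition"] == MOVEMENT)]
    for onset in cues["onset_s"].to_numpy():
        erd_end = onset + config.cue_s + config.erd_extension_s
        # ERD: at full depth from cue onset; down-ramp centred on erd_end
        erd = ramp_box(onset, erd_end, onset - r / 2, erd_end)
        # ERS: up-ramp centred on erd_end, flat through cue_s+3, ramp out after
        ers_end = onset + config.cue_s + 3.0
        ers = ramp_box(erd_end, ers_end, erd_end, ers_end + r / 2)
        m += -d * erd + g * ers
    return m


def _emg_envelope(config: GeneratorConfig, events: pd.DataFrame, n: int) -> np.ndarray:
    fs = config.sample_rate_hz
    t = np.arange(n) / fs
    e = np.zeros(n)
    cues = events[(events["kind"] == "cue") & (events["condition"] == MOVEMENT)]
    for onset in cues["onset_s"].to_numpy():
        e = np.maximum(e, np.clip((t - onset) / 0.1, 0, 1) * np.clip((onset + config.cue_s - t) / 0.1, 0, 1))
    return e


def _colored_noise(rng: np.random.Generator, n: int, fs: float, exponent: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return rfft frequencies and the spectrum of one 1/f^exponent noise
    realization (unnormalized)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    return freqs, spec * shape, white


def _narrowband(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spec[~_band_mask(freqs, *band)] = 0.0
    x = np.fft.irfft(spec, n)
    rms = x.std()
    return x / rms if rms > 0 else x


def synthesize(
    config: GeneratorConfig,
    schedule: pd.DataFrame,
    layout: ElectrodeLayout | None = None,
) -> ContinuousRecording:
    """Render a continuous multichannel recording for the given schedule.

    Reproducible: identical config, schedule and layout give bit-identical
    output.  Channels are drawn independently (no volume conduction).
    """
    config.validate()
    if layout is None:
        layout = default_layout()
    profile = config.spatial_profile
    if profile is None:
        profile = default_spatial_profile(layout.labels)
    missing = [l for l in layout.labels if l not in profile]
    if missing:
        raise ValueError(f"spatial_profile missing channels: {missing}")

    fs = config.sample_rate_hz
    cues = schedule[schedule["kind"] == "cue"]
    t_end = float((schedule["onset_s"] + schedule["duration_s"]).max()) + 8.0
    n = int(round(t_end * fs))

    m = _modulation_envelope(config, schedule, n)
    emg_env = _emg_envelope(config, schedule, n) if config.emg_contamination > 0 else None
    mod_band = (config.mu_band_hz[0], config.beta_band_hz[1])

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(layout.labels))
    data = np.empty((len(layout.labels), n))
    for i, label in enumerate(layout.labels):
        rng = np.random.default_rng(children[i])
        freqs, spec, _ = _colored_noise(rng, n, fs, config.noise_exponent)
        in_mask = _band_mask(freqs, *mod_band)
        pink_in = np.fft.irfft(np.where(in_mask, spec, 0), n)
        pink_out = np.fft.irfft(np.where(in_mask, 0, spec), n)
        scale = config.background_rms_uv / np.sqrt(pink_in.var() + pink_out.var())
        pink_in *= scale
        pink_out *= scale
        mu = config.mu_rms_uv * _narrowband(rng, n, fs, config.mu_band_hz)
        beta = config.beta_rms_uv * _narrowband(rng, n, fs, config.beta_band_hz)
        w = profile[label]
        envelope = np.sqrt(np.clip(1.0 + w * m, 0.0, None))
        x = pink_out + envelope * (pink_in + mu + beta)
        if emg_env is not None:
            in_power = pink_in.var() + config.mu_rms_uv**2 + config.beta_rms_uv**2
            emg_rms = np.sqrt(config.emg_contamination * in_power)
            hp_spec = np.fft.rfft(rng.standard_normal(n))
            hp_spec[freqs < _EMG_CUTOFF_HZ] = 0.0
            emg = np.fft.irfft(hp_spec, n)
            emg *= emg_rms / emg.std()
            x = x + emg_env * emg
        data[i] = x

    logger.info(
        "synthesized %d channels x %.0f s at %g Hz (%d cues)",
        data.shape[0], n / fs, fs, len(cues),
    )
    return ContinuousRecording(data, fs, layout.labels, schedule.copy())


def simulate_session(
    config: GeneratorConfig,
    layout: ElectrodeLayout | None = None,
    seed: int | None = None,
) -> ContinuousRecording:
    """Schedule and synthesize one session in a single call."""
    if seed is not None:
        config = replace(config, seed=int(seed))
    schedule = schedule_session(config)
    return synthesize(config, schedule, layout=layout)
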