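# Methods

## The problem and the pipeline

The package models a cued, synchronous movement-detection monitor: a
patient is instructed to (attempt to) move during periodically played 3-s
sounds; a classifier decides per trial whether the EEG shows the movement
signature; and a run-length rule converts the per-trial stream into a
warning with a very low false-alarm rate.  Five stages are implemented and
tested independently: synthetic session generation, preprocessing, spectral
feature extraction, classification, and the monitor decision layer.

## Synthetic session generator

**Paradigm timing.** Sequences of `trials_per_sequence` (default 9) trials;
each trial is a `cue_s` = 3 s cue preceded by a silence drawn uniformly
from `silence_range_s` = [4, 6] s, so mean trial spacing is 8 s.  Each of
`n_blocks` = 4 blocks holds `sequences_per_block_per_condition` = 4
sequences per condition in randomized order: 144 trials per condition at
the defaults.  A 2-s instruction precedes each sequence and a short gap
separates sequences.

**Signal model.** Per channel, independently:

* broadband Gaussian noise with a 1/f^`noise_exponent` amplitude spectrum
  (default exponent 1), scaled to `background_rms_uv` = 10 µV RMS;
* narrowband mu (8–12 Hz, 4 µV RMS) and beta (17–23 Hz, 2 µV RMS)
  Gaussian oscillations with random phase;
* an amplitude envelope applied to the whole sensorimotor band — the part
  of the background between the mu lower edge and the beta upper edge,
  plus both oscillators.  During movement trials the in-band *power* is
  scaled by `1 − w·d` from cue onset until `erd_extension_s` = 0.5 s past
  cue offset (ERD) and by `1 + w·g` from there until 3 s past cue offset
  (ERS rebound), where `w` is the channel's `spatial_profile` weight
  (1.0 at C3/C4, 0.5 at Cz and immediate neighbours, 0.1 elsewhere);
* optionally, >25 Hz broadband noise added only during movement cues
  (`emg_contamination` × in-band power), so experiments restricting the
  frequency range to ≤24 Hz genuinely exclude muscle artifact.

Modulating the whole band rather than only the two oscillator peaks makes
the generator's effect size well defined for *any* measurement band inside
the range — which is how broadband desynchronization appears in real
sensorimotor recordings — and avoids an effect size that depends on the
overlap between oscillator and analysis bands.

**Calibration.** `erd_depth` and `ers_gain` are defined as the average
fractional change of in-band power over the fixed analysis windows
(ERD: 0–4 s, ERS: 4–6 s relative to cue onset) at a full-weight channel,
measured in sensor space.  Internally the instantaneous ERD depth is
`d·(cue_s + 1)/(cue_s + erd_extension_s)` because the envelope is active
for a slightly shorter span than the analysis window; power-envelope ramps
(0.3 s, linear in power) are centred on the span edges so window averages
are exact.  Defaults `erd_depth = 0.304` and `ers_gain = 0.274` are the
grand-average effect sizes the pipeline is expected to recover.  The
calibration is stated sensor-space: the generator draws channels
independently (no volume conduction), so re-referencing mixes independent
signals and a Laplacian-referenced measurement would dilute the calibrated
depth — one of the ways the generator is *less* realistic than scalp EEG.

**Determinism.** All randomness flows from `seed` through
`numpy.random.SeedSequence` children (one per channel), so identical
configurations give bit-identical recordings.

**What passing tests do not show.** The generator has no volume
conduction, no eye/cardiac artifacts, no non-stationarity across blocks,
and its trials are exchangeable.  Pipeline performance on it demonstrates
correctness of the computations and sensible scaling with effect size, not
clinical-grade classification rates on human EEG.

## Preprocessing

Canonical order (one entry point, `preprocess`): epoch → montage subset →
linear detrend → surface Laplacian.  Channel removal precedes all signal
processing, so the Laplacian is computed on the reduced electrode set.

* **Epochs** cover −1.5…+6 s around cue onset (the ERD window 0–4 s — the
  cue plus one second for the response-time extension of the ERD — and the
  ERS window 4–6 s both lie inside).  Trials whose window leaves the
  recording are dropped and logged.
* **Detrending** removes the per-channel least-squares line
  (`scipy.signal.detrend`).
* **Surface Laplacian**: spherical-spline construction with spline order
  `m = 4`, 50 Legendre terms and smoothing `λ = 1e−5` (the method's
  published defaults; the choice is configurable).  The kernels are

      g(x) = 1/4π Σₙ (2n+1)/(n(n+1))^m Pₙ(x),
      h(x) = −1/4π Σₙ (2n+1)/(n(n+1))^(m−1) Pₙ(x),

  summed with the Legendre recurrence; coefficients solve the smoothed
  interpolation system with the Σc = 0 constraint.  The operator is a
  precomputed matrix, hence exactly linear and reference-invariant.  The
  unit test oracle is an independent term-by-term series implementation.
* **Montages**: `set9` is the fixed motor set C3, C4, Cz, F3, F4, P3, P4,
  T7, T8.  The 18/12/6-channel sets are defined symmetrically around
  C3/C4/Cz from standard 10/20 labels (set18: the three 6-electrode
  fronto-central/central/centro-parietal rows; set12: set9 plus Fz, FC3/4,
  CP3/4 minus T7/T8 — see `layout.py` for the exact lists) since only the
  9-channel membership is fixed by the protocol.  `laplacianC3` holds C3
  plus its four-electrode neighbourhood FC3/C5/C1/CP3 — five electrodes,
  conventionally called a "4-channel" derivation after the surrounding
  ring — and reduces to a single spline-Laplacian (or, behind a flag,
  Hjorth-difference) C3 channel.
* The packaged electrode layout is a 64-channel 10/20 file with positions
  normalized to the unit sphere; users may substitute their own.

## Spectral features

Welch PSD with a hann taper on 50 %-overlapping segments of
125/250/500/1000 ms (frequency resolution 8/4/2/1 Hz), density-normalized
so the integral equals the variance.  Only samples inside a period feed its
estimate — segments never straddle the 4-s ERD/ERS boundary.  Features are
linear band powers (mean density × width) on half-open bands of
`band_width_hz` tiling `range_hz` (e.g. 8–12, 12–16, 16–20, 20–24 for the
default 4-Hz bands on 8–24 Hz); a log10 option exists but is off by
default.  Combined-period features are the concatenation of the ERD and
ERS blocks: 9 × 4 × 2 = 72 features in the default configuration.

**ERD/ERS quantification** (`band_power_change`) reports
`100·(mean_move − mean_rest)/mean_rest` over per-trial band powers with a
delta-method standard error.  It defaults to 1-s Welch windows (1 Hz
resolution) regardless of the classifier's feature resolution: at 4-Hz
resolution the hann kernel leaks power from the steep, unmodulated <8 Hz
1/f background into the 10–14 Hz estimate and biases the measured percent
change by about 3 points; at 1 Hz resolution the estimator is unbiased.
Quantification and feature extraction are different estimation problems
and get different defaults.

Time-frequency maps normalize short-time power per channel and frequency
by the mean power in the −1.5…−0.5 s pre-cue baseline and report relative
change (negative = ERD, positive = ERS), averaged over trials.  Relative
change (not dB) is used throughout.

## Classifier

The rLLR minimizes the L2-penalized logistic negative log-likelihood (the
offset is unpenalized) by Newton iterations with step halving; convergence
is declared when the Newton decrement or the relative NLL change falls
below `tol = 1e−8`.  The problem is strictly convex, so the optimum is
unique — verified by multi-start tests and an independent scikit-learn fit.

Numerical choices:

* **Standardization.** Features are z-scored with training-set statistics
  (re-estimated inside every fold/block).  Raw band powers span orders of
  magnitude across channels and bands, which would make a single λ
  scale-dependent.
* **λ = 1 by default**; `select_lambda` offers a nested 5-fold grid search
  over {0.01, 0.1, 1, 10, 100}.
* **Fold assignment** is at the sequence level by default (all nine trials
  of a sequence share a fold) so that slowly varying session state cannot
  leak between training and test; `unit="trial"` reproduces the more
  common trial-level protocol.  Folds are stratified by condition,
  non-overlapping and exhaustive.
* **Block calibration** trains on block 1 only and reports pooled and
  per-block rates on the remaining blocks, emulating a 10–15-minute
  pre-operative calibration session.
* **Chance threshold**: the smallest rate c/n with exact binomial tail
  P(X ≥ c | n, ½) ≤ α (default α = 0.01).  At n = 100 this is 0.63
  (P(X ≥ 63) = 0.0060; one count fewer gives 0.0105 > α).

## Monitor decision layer

A warning requires `k = 4` consecutive 'movement' classifications of 8-s
trials; the earliest possible warning is therefore 32 s after movement
onset.

* **Exact detection curve**: streak-state Markov recursion over the
  current run length (states 0…k−1 plus absorption), exact to machine
  precision; validated against exhaustive enumeration of all 2ⁿ outcome
  sequences for n ≤ 14.
* **Monte-Carlo curve** and the **continuation of observed outcomes**:
  recorded per-sequence classifier outcomes give the empirical curve up to
  nine trials; undetected sequences are continued with Bernoulli(p̂) trials
  (p̂ defaults to the block-calibration rate).  The running streak carries
  across the continuation boundary by default (`carry_streak=False`
  resets it); the default treats the monitoring stream as continuous.
* **False alarms**: the per-window rate is `(1 − p)⁴` — the probability
  that one window of four no-movement trials is entirely misclassified.
  The expected time to the *first* false alarm uses the run-waiting-time
  closed form `E[T] = (1 − a⁴)/((1 − a) a⁴)` trials (a = 1 − p), e.g.
  26 535.9 trials ≈ 59 h at p = 0.92, and 8.5 h when inverted from a
  0.03 % per-window rate.  Both quantities are exposed; reports label
  which is used.  (The 1/FPR window approximation gives 7.4 h for the
  same operating point — the closed form is exact and slightly larger
  because windows overlap.)

## Problem sizes and defaults in the tests

The unit and property tests run reduced-scale sessions (two blocks, two
sequences per block per condition, 128 Hz, nine channels) chosen to give
stable statistics within seconds; the parameter-recovery check uses the
full 144-trials-per-condition session at 256 Hz on a single channel, and
the end-to-end test runs the complete default-scale configuration
(288 trials, 64 recorded → 9 analyzed channels, 256 Hz).  All seeds are
fixed in the tests; the generator defaults themselves are the study-scale
conditions described above.

## Known limitations

* No volume conduction or realistic artifact models in the generator; the
  Laplacian's benefit on synthetic data is therefore not representative.
* Only the spline and Hjorth Laplacian references are provided (no CAR or
  bipolar options), and no artifact rejection is performed.
* The classifier is intentionally limited to rLLR; the probability output
  is computed but not used for graded confidence.
* The monitor analysis is for the cued synchronous paradigm only —
  asynchronous (uncued) detection is out of scope.
* The EDF writer emits plain 16-bit EDF with one-second records and
  requires an integer number of samples per second.
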