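"""Generate a synthetic cued-movement EEG session and inspect its structure.

The generator reproduces the experimental paradigm: four blocks, each with
four 9-trial sequences per condition ('movement' vs 'no movement'), a 3-s
auditory cue per trial preceded by 4-6 s of silence, 256 Hz sampling, and
mu/beta desynchronization (ERD) plus a post-movement rebound (ERS)
concentrated over the motor cortex.
"""

import erdmonitor as em

config = em.GeneratorConfig(seed=42)
layout = em.default_layout()
recording = em.simulate_session(config, layout=layout)

cues = recording.cues()
print(f"channels:            {len(recording.labels)}")
print(f"duration:            {recording.duration_s / 60:.1f} min")
print(f"cues per condition:  {cues.groupby('condition').size().to_dict()}")
silences = cues.groupby("sequence")["onset_s"].diff().dropna() - config.cue_s
print(f"silence range:       {silences.min():.2f}-{silences.max():.2f} s")

# 288 cues (144 per condition) spread over ~40 minutes; every inter-trial
# silence falls inside the configured 4-6 s interval.
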