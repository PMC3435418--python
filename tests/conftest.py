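import numpy as np
import pytest

import erdmonitor as em

SET9 = ("C3", "C4", "Cz", "F3", "F4", "P3", "P4", "T7", "T8")


@pytest.fixture(scope="session")
def layout64():
    return em.default_layout()


@pytest.fixture(scope="session")
def layout9(layout64):
    return layout64.subset(SET9)


def make_session(layout, *, fs=128.0, blocks=2, spc=2, seed=0, **kwargs):
    cfg = em.GeneratorConfig(
        sample_rate_hz=fs, n_blocks=blocks, sequences_per_block_per_condition=spc,
        seed=seed, **kwargs,
    )
    return cfg, em.simulate_session(cfg, layout=layout)


@pytest.fixture(scope="session")
def small_session(layout9):
    """A reduced-scale session with the default (calibrated) effect sizes:
    2 blocks x 2 sequences/condition x 9 trials = 72 trials, 128 Hz, set9."""
    return make_session(layout9, seed=7)


@pytest.fixture(scope="session")
def small_features(small_session, layout9):
    _, rec = small_session
    epochs = em.preprocess(rec, layout9, montage="set9")
    return em.extract_features(epochs, em.SpectralConfig())
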