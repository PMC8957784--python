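"""Shared fixtures: synthetic assets are generated once per session."""

import numpy as np
import pytest

import ssinva

FS = 16000  # render tests run at a reduced rate to keep convolutions cheap


@pytest.fixture(scope="session")
def word_set():
    return ssinva.generate_word_set(sample_rate=FS, seed=1)


@pytest.fixture(scope="session")
def level_map():
    return ssinva.LevelMap()


@pytest.fixture(scope="session")
def eq_tokens(word_set, level_map):
    tokens, _ = ssinva.equalize_word_levels(
        word_set, target_rms=level_map.rms_for_spl(level_map.word_level_db_spl)
    )
    return tokens


@pytest.fixture(scope="session")
def hrir_set():
    return ssinva.generate_spherical_hrir_set(sample_rate=FS)


@pytest.fixture(scope="session")
def babble():
    return ssinva.generate_babble(6.0, sample_rate=FS, seed=11)


@pytest.fixture(scope="session")
def rendered_trial(eq_tokens, hrir_set, babble, level_map):
    toks = list(eq_tokens.values())
    return ssinva.render_trial(
        toks[0], toks[1], -90.0, -60.0, babble.waveform, hrir_set, level_map,
        snr_db=0.0, seed=5,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """12 simulated participants, 1 run per block (288 trials each)."""
    logs, obs = ssinva.simulate_cohort(12, seed=42, runs_per_block=1)
    return logs, obs


def rms_db(x):
    return 20.0 * np.log10(np.sqrt(np.mean(np.square(x))))
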