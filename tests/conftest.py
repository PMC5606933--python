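import warnings

import numpy as np
import pytest

from reachdec import pipeline
from reachdec.simulate import preset, simulate_session


@pytest.fixture(scope="session")
def preset1_small():
    """Preset-1 session, 7 trials per direction (21 trials) — shared by
    TF/onset/decoding tests to amortize simulation cost."""
    cfg = preset(1, seed=2, n_trials_per_direction=7)
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def emg1(preset1_small):
    rec, _ = preset1_small
    return pipeline.emg_onsets_for(rec)


@pytest.fixture(scope="session")
def emap1(preset1_small, emg1):
    rec, _ = preset1_small
    return pipeline.erders_map(rec, emg1.onsets)


@pytest.fixture(scope="session")
def bands1(emap1):
    return pipeline.select_subject_bands(emap1)


@pytest.fixture(scope="session")
def decoding1(preset1_small, emg1, bands1):
    rec, _ = preset1_small
    gamma, alphabeta = bands1
    dirs = pipeline.trial_directions(rec, emg1.onsets)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.prepare_decoding(
            rec, emg1.onsets, emg1.offsets, dirs, alphabeta, gamma
        )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
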