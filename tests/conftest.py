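import numpy as np
import pytest

from fovealoc.synthetic import (SessionSpec, SFLTrialSpec, make_fixation_sessions,
                                make_sfl_trials)


@pytest.fixture(scope="session")
def two_day_session():
    """Two days of default fixation runs with a known PRL."""
    spec = SessionSpec(prl=(2.0, -1.0), seed=42)
    traces, truth = make_fixation_sessions(spec, n_days=2)
    return spec, traces, truth


@pytest.fixture(scope="session")
def sfl_trials_1500():
    """1500 fixation-judgment trials with known SFL and slopes."""
    spec = SFLTrialSpec(sfl=(1.5, -0.8), n_trials=1500, seed=7)
    trials, truth = make_sfl_trials(spec)
    return spec, trials, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
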