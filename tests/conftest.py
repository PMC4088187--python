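import numpy as np
import pytest

from smrdyn.datatypes import ParadigmSpec
from smrdyn.simulate import ParticipantProfile, generate_participant


@pytest.fixture(scope="session")
def paradigm():
    return ParadigmSpec()


def make_profile(**overrides):
    defaults = dict(
        participant_id="A01",
        group="A",
        age=30.0,
        gender="F",
        n_trials_per_condition=5,
        baseline_amp=5.0,
        erd_depth=0.4,
        plv_target=0.6,
        switch_rate=4.0,
        noise_amp=1.5,
    )
    defaults.update(overrides)
    return ParticipantProfile(**defaults)


@pytest.fixture(scope="session")
def small_recording(paradigm):
    return generate_participant(make_profile(), paradigm, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
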