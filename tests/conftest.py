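import pytest

from cadenza.ic import compute_ic_profiles
from cadenza.ppm import PPM
from cadenza.stimuli import (
    build_stimulus_set,
    encode_motor,
    encode_structural,
    motor_alphabet,
    structural_alphabet,
)


@pytest.fixture(scope="session")
def stim_set():
    """The default stimulus design (seed 0)."""
    return build_stimulus_set(seed=0)


@pytest.fixture(scope="session")
def struct_model(stim_set):
    corpus = [encode_structural(s) for s in stim_set.training_corpus]
    return PPM(corpus, structural_alphabet(), max_order=4).fit()


@pytest.fixture(scope="session")
def motor_model(stim_set):
    corpus = [encode_motor(s) for s in stim_set.training_corpus]
    return PPM(corpus, motor_alphabet(), max_order=4).fit()


@pytest.fixture(scope="session")
def ic_profiles(struct_model, motor_model, stim_set):
    return compute_ic_profiles(struct_model, motor_model, stim_set)
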