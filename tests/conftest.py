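import numpy as np
import pandas as pd
import pytest

from otiskit.presets import paper_preset, null_preset
from otiskit.simulate import generate_cohort
from otiskit.models import build_frame


@pytest.fixture(scope="session")
def preset_small():
    return paper_preset(n_per_group=150, seed=11)


@pytest.fixture(scope="session")
def cohort_small(preset_small):
    return generate_cohort(preset_small, seed=11)


@pytest.fixture(scope="session")
def preset_big():
    return paper_preset(n_per_group=2000, seed=5)


@pytest.fixture(scope="session")
def cohort_big(preset_big):
    return generate_cohort(preset_big, seed=5)


@pytest.fixture(scope="session")
def frame_big(cohort_big):
    return build_frame(cohort_big)


@pytest.fixture(scope="session")
def null_cohort_small():
    return generate_cohort(null_preset(n_per_group=60, seed=21), seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
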