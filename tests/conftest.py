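import numpy as np
import pytest

import ildtax as it


@pytest.fixture(scope="session")
def axis():
    return it.make_axis()


@pytest.fixture(scope="session")
def prototypes(axis):
    return it.make_prototypes(axis)


@pytest.fixture(scope="session")
def perturbed_prototypes(prototypes):
    return it.perturb_panels(prototypes, it.PerturbationConfig(seed=7, floor=0.1))


@pytest.fixture(scope="session")
def survey():
    """Default 208-cell surrogate survey with the seven planted groups."""
    ds, labels = it.simulate_survey(it.SurveyConfig(seed=11))
    return ds, labels


@pytest.fixture(scope="session")
def noiseless_survey():
    cfg = it.SurveyConfig(noise_sd=0.0, amplitude_jitter=0.0, seed=3)
    ds, labels = it.simulate_survey(cfg)
    return ds, labels
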