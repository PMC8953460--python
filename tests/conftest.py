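import numpy as np
import pytest
from hypothesis import settings

import antapbpk as ap
from antapbpk.engine import build_model, elephant1_regimen, simulate
from antapbpk.population import PopulationSpec, generate_population, run_virtual_trial

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def parent():
    return ap.antazoline()


@pytest.fixture(scope="session")
def metabolite():
    return ap.hydroxyantazoline()


@pytest.fixture(scope="session")
def subject():
    return ap.reference_subject()


@pytest.fixture(scope="session")
def kp_parent(parent):
    return ap.predict_kp_set(parent)


@pytest.fixture(scope="session")
def kp_metabolite(metabolite):
    return ap.predict_kp_set(metabolite)


@pytest.fixture(scope="session")
def model(parent, metabolite, subject, kp_parent, kp_metabolite):
    return build_model(parent, metabolite, subject, kp_parent, kp_metabolite)


@pytest.fixture(scope="session")
def sim_100mg(model):
    """Dense noise-free 48-h simulation of a single 100-mg dose."""
    return simulate(model, elephant1_regimen(), duration=48.0)


@pytest.fixture(scope="session")
def trial_100(parent, metabolite):
    """100-subject virtual trial, single 100-mg dose, 48 h."""
    spec = PopulationSpec(n_subjects=100, seed=1)
    return run_virtual_trial(generate_population(spec), parent, metabolite,
                             elephant1_regimen(), duration=48.0)
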