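import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

import sepeffects as se  # noqa: E402


@pytest.fixture(scope="session")
def fig4a_model():
    return se.scenario_preset("fig4a")


@pytest.fixture(scope="session")
def fig4a_cohort(fig4a_model):
    return se.simulate_two_arm(fig4a_model, 2000, seed=0)


@pytest.fixture(scope="session")
def fig4a_fits(fig4a_cohort):
    return se.fit_nuisance(fig4a_cohort)


@pytest.fixture(scope="session")
def fig8a_model():
    return se.scenario_preset("fig8a")


@pytest.fixture(scope="session")
def fig8a_cohort(fig8a_model):
    # censoring + a baseline covariate; sized so every visited stratum carries
    # events in both arms (in-sample positivity for the exact-equality checks)
    return se.simulate_two_arm(fig8a_model, 20000, seed=2)


@pytest.fixture(scope="session")
def fig8a_fits(fig8a_cohort):
    return se.fit_nuisance(fig8a_cohort)


ASSIGNMENTS = [(0, 0), (0, 1), (1, 0), (1, 1)]
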