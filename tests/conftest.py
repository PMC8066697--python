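import pytest
from hypothesis import settings

from renalcea.config import default_config
from renalcea.pipeline import build_diet_model
from renalcea.synthetic import default_calibration, simulate_event_times

settings.register_profile("suite", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("suite")

#: cohort size per adherence group for the fitted fixtures: large enough for
#: stable Weibull estimates, small enough to fit in seconds
FIXTURE_N = 4000
FIXTURE_SEED = 7


@pytest.fixture()
def config():
    return default_config()


def _model(diet):
    cfg = default_config()
    datasets = simulate_event_times(default_calibration(diet), n=FIXTURE_N,
                                    seed=FIXTURE_SEED)
    return build_diet_model(diet, cfg, datasets)


@pytest.fixture(scope="session")
def dash_model():
    return _model("dash")


@pytest.fixture(scope="session")
def potassium_model():
    return _model("potassium")
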