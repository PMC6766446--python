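import logging

import pytest

from eednet.config import SimConfig
from eednet.preprocess import build_analytic
from eednet.simulate import generate_cohort
from eednet.truth import default_truth

logging.getLogger("eednet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def calibrated_cohort():
    """A calibrated 7-site cohort (150 children/site) from the default truth."""
    cfg = SimConfig(children_per_site=150, seed=7)
    truth = default_truth(cfg.calibration, cfg.sites)
    return cfg, generate_cohort(cfg, truth)


@pytest.fixture(scope="session")
def preprocessed(calibrated_cohort):
    _, cohort = calibrated_cohort
    return cohort, build_analytic(cohort, reference_site="BRF")
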