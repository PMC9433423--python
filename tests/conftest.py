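import numpy as np
import pytest

from noxpipe import CohortConfig, PipelineConfig, generate_cohort
from noxpipe.pipeline import extract_features


def null_config(n_infants: int, seed: int) -> CohortConfig:
    """Condition-exchangeable cohort: every effect scale zero."""
    return CohortConfig(
        n_infants=n_infants, seed=seed,
        effect_scales={"erp": 0.0, "heart_rate": 0.0, "emg": 0.0,
                       "brow_bulge": 0.0})


@pytest.fixture(scope="session")
def pcfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_table(pcfg):
    """Feature table of a default 47-infant cohort (all 20 predictors)."""
    records = generate_cohort(CohortConfig(n_infants=47, seed=9))
    return extract_features(records, pcfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
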