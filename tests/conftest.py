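import numpy as np
import pytest
from hypothesis import settings

from trialgen.synthetic import CohortConfig, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

#: r² map giving the confounded traits a realistic mid-range PGS proxy value.
CONFOUNDED_R2 = {"t2d": 0.4, "bmi": 0.4, "hba1c": 0.3, "chd": 0.3}


def confounded_config(n: int = 40_000, seed: int = 7, **overrides) -> CohortConfig:
    """A cohort with confounding by indication: the same latent traits drive
    initiation, drug choice and the outcome hazard."""
    r2 = {t: 0.1 for t in CohortConfig().trait_names}
    r2.update(CONFOUNDED_R2)
    defaults = dict(
        n_individuals=n,
        pgs_confounder_r2=r2,
        initiation_log_odds={"t2d": 1.0, "bmi": 0.7, "hba1c": 0.5},
        prescription_log_odds={"bmi": 0.5, "chd": 0.4},
        true_treatment_log_hr=np.log(0.7),
        baseline_hazard=0.08,
        confounder_log_hr={"t2d": 0.3, "bmi": 0.3, "chd": 0.4},
        seed=seed,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


def randomized_config(n: int = 20_000, seed: int = 11, **overrides) -> CohortConfig:
    """Arm assignment independent of every latent trait (an RCT-like cohort)."""
    defaults = dict(
        n_individuals=n,
        initiation_log_odds={},
        prescription_log_odds={},
        true_treatment_log_hr=0.0,
        baseline_hazard=0.08,
        confounder_log_hr={},
        seed=seed,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def confounded_cohort():
    return generate_cohort(confounded_config())


@pytest.fixture(scope="session")
def randomized_cohort():
    return generate_cohort(randomized_config())
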