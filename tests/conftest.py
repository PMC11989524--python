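import pytest

from dischargerx.comorbidity import default_code_map
from dischargerx.engine import RuleConfig
from dischargerx.simulate import default_config, generate_cohort


@pytest.fixture(scope="session")
def code_map():
    return default_code_map()


@pytest.fixture(scope="session")
def rules():
    return RuleConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """Synthetic cohort at desk scale, shared across read-only tests."""
    return generate_cohort(default_config(n_pre=300, n_post=300, seed=20230401))


@pytest.fixture(scope="session")
def study_scale_cohort():
    """Synthetic cohort at the study's printed group sizes."""
    return generate_cohort(default_config(n_pre=1318, n_post=970, seed=20230401))
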