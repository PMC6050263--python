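import numpy as np
import pytest

from endofactor import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small, fast cohort with clear structure for pipeline-level tests."""
    cfg = SyntheticConfig(n_subjects=60, n_edges=20, n_properties_true=4,
                          n_factors_true=2, dirichlet_concentration=0.3,
                          mean_active_properties=1.5, noise_scale=0.2,
                          site_count=2, site_effect_scale=0.05,
                          label_flip_rate=0.2, seed=42)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
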