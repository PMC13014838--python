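import numpy as np
import pytest

from ckm_topics import DiseaseSpec, GenConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small, fully observed 3-topic cohort with one planted disease."""
    cfg = GenConfig(
        n_participants=600,
        n_features=12,
        K_true=3,
        topic_sharpness=0.2,
        alpha_gen=0.3,
        disease_specs=[DiseaseSpec("t2dm", -2.0, [3.0, 0.0, -3.0])],
        seed=42,
    )
    cohort, binned, truth = generate_cohort(cfg)
    return cfg, cohort, binned, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
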