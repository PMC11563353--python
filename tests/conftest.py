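import numpy as np
import pytest

from oralfluor.config import build_cohort_items, config_from_dict
from oralfluor.features import build_feature_stacks
from oralfluor.preprocess import PreprocessConfig, preprocess
from oralfluor.simulate import default_effect_config, simulate_patient


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale pipeline config used by most integration tests."""
    return config_from_dict(
        {
            "simulation": {"n_patients": 10, "image_shape": [16, 16]},
            "classifier": {"pixel_cap": 300},
            "seed": 11,
        }
    )


@pytest.fixture(scope="session")
def small_items(small_config):
    """Featurized 10-patient synthetic cohort (shared, read-only)."""
    return build_cohort_items(small_config)


@pytest.fixture(scope="session")
def sample_pair():
    """One preprocessed lesion/healthy pair plus its feature stacks."""
    cfg = default_effect_config(n_patients=2, image_shape=(20, 20), seed=5)
    sample = simulate_patient(cfg, 0, "SCC")
    (lc, lm), (hc, hm) = preprocess(sample, PreprocessConfig())
    lesion_stack, healthy_stack = build_feature_stacks(lc, lm, hc, hm)
    return {
        "sample": sample,
        "lesion": (lc, lm),
        "healthy": (hc, hm),
        "lesion_stack": lesion_stack,
        "healthy_stack": healthy_stack,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
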