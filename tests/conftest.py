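import numpy as np
import pytest
from hypothesis import settings

from gaitscore import ScorerParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from gaitscore.synth import FeatureGenSpec, SignalGenSpec, generate_features, generate_imu_trial


@pytest.fixture
def default_params():
    return ScorerParams(w=np.zeros(3), c=0.0)


@pytest.fixture(scope="session")
def clean_feature_table():
    """Zero-noise feature table with known generating structure (30 subjects)."""
    spec = FeatureGenSpec(n_per_level={0: 10, 1: 10, 2: 10}, seed=0)
    return generate_features(spec)


@pytest.fixture(scope="session")
def clean_trial():
    """Zero-noise two-shank IMU trial with analytic ground truth."""
    spec = SignalGenSpec(stride_m=1.20, mh_m=0.25, height_m=1.6, seed=1)
    return generate_imu_trial(spec)
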