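import numpy as np
import pytest
from hypothesis import settings

from ntcp_albi import CohortSpec, RiskMechanism, build_feature_matrix, generate_cohort
from ntcp_albi.clinical import FEATURE_PRESETS

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """n=300 synthetic cohort shared by model-level tests."""
    records, labels, risks = generate_cohort(CohortSpec(n_patients=300), RiskMechanism(), seed=42)
    return records, labels, risks


@pytest.fixture(scope="session")
def small_features(small_cohort):
    records, labels, _ = small_cohort
    feats = sorted(set(FEATURE_PRESETS["selected_plr"]) | set(FEATURE_PRESETS["selected_tree"]))
    X = build_feature_matrix(records, feats)
    y = labels["albi1plus"].astype(bool).to_numpy()
    return X, y


#: tiny hyperparameter grids for tests exercising fitting logic, not grid search
FAST_GRIDS = {
    "plr": {"C": (1.0,)},
    "rf": {"max_depth": (5,), "max_features": ("sqrt",)},
    "gbt": {"learning_rate": (0.1,), "max_depth": (2,)},
}
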