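import numpy as np
import pandas as pd
import pytest

from dbsa import FeatureMatrix, SimulationConfig, generate_cohort


def make_matrix(values, groups, feature_names=None, **extra_meta):
    """Small FeatureMatrix fixture helper."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    ids = [f"s{i:03d}" for i in range(n)]
    meta = {
        "group": list(groups),
        "sex": extra_meta.pop("sex", ["F"] * n),
        "age_months": extra_meta.pop("age_months", [6.0] * n),
        "treatment": extra_meta.pop("treatment", ["none"] * n),
        "dose_mg_per_kg": extra_meta.pop("dose_mg_per_kg", [0.0] * n),
    }
    meta.update(extra_meta)
    metadata = pd.DataFrame(meta, index=pd.Index(ids))
    names = feature_names or [f"f{j}" for j in range(values.shape[1])]
    return FeatureMatrix(ids, metadata, values, names)


@pytest.fixture
def rng():
    return np.random.default_rng(20230725)


@pytest.fixture
def small_cohort():
    """Two-group cohort with a clear planted effect, small enough for speed."""
    cfg = SimulationConfig(
        n_features=40, n_affected=10, effect_size=2.0, n_factors=5, n_per_group=12, seed=11
    )
    matrix, truth = generate_cohort(cfg)
    return cfg, matrix, truth
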