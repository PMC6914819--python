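import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import metabotraj as mt

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_study():
    """One default simulated study (both segments, mild drift, a few
    effects) shared by read-only tests."""
    cfg = mt.SimulationConfig(
        n_metabolites=20,
        seed=11,
        effect_spec={
            "m001": {"background": 0.3},
            "m002": {"stage": 0.25},
            "m003": {"genotype:stage": 0.3},
        },
    )
    matrix, design, truth = mt.simulate_study(cfg)
    return cfg, matrix, design, truth


@pytest.fixture(scope="session")
def lumbar_scaled(default_study):
    """Normalized -> log10 -> scaled lumbar segment of the default study."""
    _, matrix, design, _ = default_study
    model = mt.fit_drift(matrix, design, smoothing=10.0)
    norm = mt.correct_drift(matrix, model)
    seg = norm.subset_samples((design.table["segment"] == "lumbar").to_numpy())
    study = seg.subset_samples(seg.design.is_study())
    logged = mt.log_transform(study)
    scaled, params = mt.uv_scale(logged)
    return study, logged, scaled, params
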