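import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cghdiv import (
    DISTANT_PROFILE,
    GeneratorConfig,
    generate_feature_annotations,
    normalize_loess_conserved,
    simulate_scans,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A distant-species contrast small enough for fast end-to-end tests."""
    cfg = GeneratorConfig(seed=7, n_features=1500, n_arrays=8, conserved_n=200)
    ann, truth = generate_feature_annotations(cfg, DISTANT_PROFILE)
    scans = simulate_scans(ann, truth, cfg)
    return cfg, ann, truth, scans


@pytest.fixture(scope="session")
def small_rm(small_dataset):
    _, ann, _, scans = small_dataset
    return normalize_loess_conserved(scans, ann)


@pytest.fixture()
def pct_id(small_dataset):
    _, ann, _, _ = small_dataset
    return ann.set_index("feature_id")["true_pct_id"]
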