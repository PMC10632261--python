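import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cprkit as ck
from cprkit.config import GeneratorParams

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ccc_subject():
    """Full 20-min CCC subject with default noise and artifact."""
    cfg = ck.ExperimentConfig(cpr_mode="ccc", seed=101)
    vent, hemo, abg, truth = ck.simulate_subject(cfg)
    return cfg, vent, hemo, abg, truth


@pytest.fixture(scope="session")
def t302_subject():
    """Full 20-min 30:2 subject with default noise and artifact."""
    cfg = ck.ExperimentConfig(cpr_mode="302", seed=102)
    vent, hemo, abg, truth = ck.simulate_subject(cfg)
    return cfg, vent, hemo, abg, truth


@pytest.fixture(scope="session")
def ccc_noise_free():
    """Noise- and artifact-free CCC subject (extraction oracle)."""
    cfg = ck.ExperimentConfig(cpr_mode="ccc", seed=103)
    params = GeneratorParams.for_mode("ccc").noise_free()
    vent, hemo, abg, truth = ck.simulate_subject(cfg, params)
    return cfg, vent, hemo, abg, truth


@pytest.fixture(scope="session")
def t302_noise_free():
    cfg = ck.ExperimentConfig(cpr_mode="302", seed=104)
    params = GeneratorParams.for_mode("302").noise_free()
    vent, hemo, abg, truth = ck.simulate_subject(cfg, params)
    return cfg, vent, hemo, abg, truth
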