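import logging
from dataclasses import replace

import numpy as np
import pytest

from skatesurv import synthetic_tags as synth

logging.getLogger("skatesurv").setLevel(logging.ERROR)


def pilot(regime: str, **overrides) -> synth.RegimeConfig:
    """5-day scheduled-detachment variant of a regime config (cheap tests)."""
    cfg = default = synth.default_regime_config(regime)
    cfg = replace(default, deployment_days=5, detach="scheduled", **overrides)
    return cfg


@pytest.fixture(scope="session")
def small_cohort():
    """Five 30-day tags (2 survivors, 3 dead) used by several pipeline tests."""
    return synth.simulate_cohort(
        {"survivor_active": 2, "dead_plateau": 2, "control_dead": 1}, seed=11
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
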