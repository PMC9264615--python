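import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from nanopbpk import (
    NanoKineticParams,
    TISSUES,
    default_params,
    default_physiology,
)


@pytest.fixture(scope="session")
def phys():
    return default_physiology()


@pytest.fixture
def params_iv():
    return default_params(5.0, "iv")


def inert_params(**overrides) -> NanoKineticParams:
    """Parameter set with every transfer/elimination pathway switched off
    (distribution coefficients 1, capacities finite); individual rates are
    switched back on via keyword overrides, e.g. ``inert_params(k_feces=0.3)``
    or ``inert_params(k_max={"gi": 0.5})``."""
    base = NanoKineticParams(
        distribution={t: 1.0 for t in TISSUES},
        permeability={t: 0.0 for t in TISSUES},
        k_max={t: 0.0 for t in TISSUES},
        a_cap={t: 1.0 for t in TISSUES},
        k_release={t: 0.0 for t in TISSUES},
    )
    for name, value in overrides.items():
        if isinstance(value, dict):
            getattr(base, name).update(value)
        else:
            setattr(base, name, value)
    base.validate()
    return base


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
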