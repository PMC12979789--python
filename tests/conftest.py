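import numpy as np
import pandas as pd
import pytest

from metascope.synthetic_data import SMOLT_TRAITS, SynthConfig, gen_environment
from metascope.traits import TraitSet


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_env():
    """Two water years, three sites, deterministic."""
    cfg = SynthConfig(seed=11, n_years=2, n_sites=3)
    return gen_environment(cfg)


@pytest.fixture
def smolt_traits():
    return SMOLT_TRAITS


@pytest.fixture
def flat_traits():
    """Temperature-insensitive traits: O2crit = exp(A) everywhere."""
    return TraitSet(label="flat", A=np.log(5.0), E=0.0)


def make_respirometry(n=30, lifestage="smolt", population="fall", A=14.81, E=0.33,
                      alpha=0.0, ref_mass=0.02, masses=None, temps=None, seed=0):
    """Noiseless respirometry frame from known Arrhenius truth."""
    from metascope.envio import inverse_temperature

    r = np.random.default_rng(seed)
    masses = r.uniform(0.015, 0.03, n) if masses is None else np.asarray(masses, float)
    temps = r.uniform(8, 25, n) if temps is None else np.asarray(temps, float)
    o2crit = np.exp(A - E * inverse_temperature(temps)) * (masses / ref_mass) ** alpha
    smr = np.full(n, 100.0)
    return pd.DataFrame(
        {
            "fish_id": [f"x{i}" for i in range(n)],
            "lifestage": lifestage,
            "population": population,
            "species": "chinook",
            "mass_kg": masses,
            "test_temp_C": temps,
            "smr": smr,
            "mmr": 21.0 * smr / o2crit,
            "mmr_method": "swim",
        }
    )
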