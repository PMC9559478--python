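import numpy as np
import pandas as pd
import pytest

from grassmilk import simdata
from grassmilk.schema import TraitSchema, TraitSpec, default_schema


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_dataset():
    """20 farms x 2 years of default (strong-effect) records."""
    records, meteo, farms = simdata.generate_dataset(20, 2, seed=11)
    return records, meteo, farms


@pytest.fixture(scope="session")
def flat_meteo():
    """A meteorology table with constant THI, isolating the seasonal ramp."""
    meteo = simdata.simulate_meteo(1, seed=3)
    meteo = meteo.copy()
    meteo["thi"] = 60.0
    return meteo


def sparse_signal_schema(n_signal: int = 10, n_total: int = 48) -> TraitSchema:
    """A schema where exactly ``n_signal`` traits respond to grass."""
    traits = []
    for j in range(n_total):
        mult = 1.8 if j < n_signal else 1.0
        traits.append(TraitSpec(f"t{j:02d}", "unit", 10.0, 1.0, mult))
    return TraitSchema(traits=tuple(traits))
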