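import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tropicatch import thermal_mtc

settings.register_profile(
    "default",
    deadline=None,
    max_examples=50,
    # read-only fixtures are safe to share across generated examples
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def toy_matrix() -> pd.DataFrame:
    """4 years x 3 species, strictly positive."""
    return pd.DataFrame(
        [[10.0, 5.0, 1.0], [8.0, 6.0, 2.0], [6.0, 7.0, 4.0], [4.0, 8.0, 8.0]],
        index=pd.Index([2000, 2001, 2002, 2003], name="year"),
        columns=pd.Index(["A", "B", "C"], name="species"),
    )


@pytest.fixture
def toy_table() -> thermal_mtc.ThermalAffinityTable:
    return thermal_mtc.classify_affinity({"A": 20.0, "B": 24.0, "C": 28.0})


def random_matrix(
    rng: np.random.Generator, n_years: int = 8, n_species: int = 5
) -> pd.DataFrame:
    """Strictly positive random biomass matrix."""
    return pd.DataFrame(
        rng.lognormal(3.0, 1.0, size=(n_years, n_species)),
        index=pd.Index(2000 + np.arange(n_years), name="year"),
        columns=pd.Index([f"S{i}" for i in range(n_species)], name="species"),
    )
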