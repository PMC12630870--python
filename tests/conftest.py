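import numpy as np
import pandas as pd
import pytest

from ndmap.atlas import Atlas
from ndmap.simulate import SimulationConfig, simulate_atlas, simulate_connectome


@pytest.fixture(scope="session")
def atlas26() -> Atlas:
    """Desk-scale parcellation: 20 cortical + 6 subcortical regions."""
    return simulate_atlas(20, 6, seed=11)


@pytest.fixture(scope="session")
def connectome26(atlas26):
    return simulate_connectome(atlas26, density=0.35, seed=12)


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: results are order-independent
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def patients_table():
    """Minimal patient table with alternating focus sides."""
    n = 8
    return pd.DataFrame({
        "subject_id": [f"p{i}" for i in range(n)],
        "group": "TLE",
        "site": "site1",
        "age": np.linspace(20, 55, n),
        "sex": [0, 1] * (n // 2),
        "focus": ["left", "right"] * (n // 2),
    })
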