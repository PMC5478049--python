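import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gmherit import Pedigree

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_pedigree():
    """6 specimens, 2 colonies, 3 patrilines."""
    return Pedigree(pd.DataFrame({
        "specimen_id": ["a", "b", "c", "d", "e", "f"],
        "colony_id": ["C1", "C1", "C1", "C2", "C2", "C2"],
        "patriline_id": ["P1", "P1", "P2", "P3", "P3", "P3"],
    }))


def make_pedigree(n, n_patrilines, colony="C1", prefix="S"):
    base, rem = divmod(n, n_patrilines)
    counts = [base + (1 if i < rem else 0) for i in range(n_patrilines)]
    pats = np.repeat([f"P{i + 1}" for i in range(n_patrilines)], counts)
    return Pedigree(pd.DataFrame({
        "specimen_id": [f"{prefix}{i}" for i in range(n)],
        "colony_id": colony,
        "patriline_id": pats,
    }))


@pytest.fixture
def pedigree_factory():
    return make_pedigree
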