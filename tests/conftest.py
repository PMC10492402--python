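import numpy as np
import pandas as pd
import pytest

from agep4 import SimulationConfig, simulate_study
from agep4.pedigree import Pedigree


@pytest.fixture(scope="session")
def worked_example_visits() -> pd.DataFrame:
    """Four textbook animals spanning every censoring pattern:
    A left-censored, B and C interval-censored, D right-censored."""
    rows = [
        ("A", "E", 280, True), ("A", "M", 310, True), ("A", "L", 340, True),
        ("B", "E", 350, False), ("B", "M", 380, True), ("B", "L", 410, True),
        ("C", "E", 300, False), ("C", "M", 330, False), ("C", "L", 360, True),
        ("D", "E", 330, False), ("D", "M", 360, False), ("D", "L", 390, False),
    ]
    return pd.DataFrame(rows, columns=["animal_id", "visit_index", "age_at_visit", "bp4_elevated"])


@pytest.fixture(scope="session")
def trio_pedigree() -> Pedigree:
    """Two unrelated founders and their offspring."""
    return Pedigree(["S1", "D1", "A1"], np.array([-1, -1, 0]), np.array([-1, -1, 1]))


@pytest.fixture(scope="session")
def small_study():
    """One modest simulated herd study shared across tests."""
    cfg = SimulationConfig(
        n_herds=8, herd_size_mean=40, herd_size_sd=10, n_sires=16, seed=11
    )
    return simulate_study(cfg)


def random_pedigree(n: int, seed: int, p_founder: float = 0.3) -> Pedigree:
    """Random valid pedigree: each non-founder picks two earlier parents."""
    rng = np.random.default_rng(seed)
    sire = [-1]
    dam = [-1]
    for i in range(1, n):
        if rng.random() < p_founder or i < 2:
            sire.append(-1)
            dam.append(-1)
        else:
            s, d = rng.choice(i, size=2, replace=False)
            sire.append(int(s))
            dam.append(int(d))
    ids = [f"P{i}" for i in range(n)]
    return Pedigree(ids, np.array(sire), np.array(dam))
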