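import numpy as np
import pandas as pd
import pytest

from marelife import (
    SimulationConfig,
    compute_kinship,
    simulate_careers,
    simulate_pedigree,
    simulate_phenotypes,
)


def make_pedigree(rows):
    """rows: (animal_id, sire_id, dam_id, birth_year, sex)"""
    return pd.DataFrame(
        rows, columns=["animal_id", "sire_id", "dam_id", "birth_year", "sex"]
    )


@pytest.fixture
def fullsib_pedigree():
    # 1 x 2 -> 3, 4 (full sibs); 1 x 5 -> 6 (half sib of 3/4)
    return make_pedigree(
        [
            (1, 0, 0, 1990, "M"),
            (2, 0, 0, 1990, "F"),
            (5, 0, 0, 1990, "F"),
            (3, 1, 2, 1995, "M"),
            (4, 1, 2, 1995, "F"),
            (6, 1, 5, 1996, "F"),
        ]
    )


@pytest.fixture
def inbred_pedigree():
    # full-sib mating (7) and parent-offspring mating (8)
    return make_pedigree(
        [
            (1, 0, 0, 1990, "M"),
            (2, 0, 0, 1990, "F"),
            (3, 1, 2, 1995, "M"),
            (4, 1, 2, 1995, "F"),
            (7, 3, 4, 2000, "F"),
            (8, 1, 4, 2001, "F"),
        ]
    )


SMALL_CFG = dict(
    n_founders=150,
    n_generations=8,
    n_recorded_mares_target=800,
    sires_per_generation=15,
)


@pytest.fixture(scope="session")
def small_population():
    cfg = SimulationConfig(seed=11, **SMALL_CFG)
    ped, truth = simulate_pedigree(cfg)
    return cfg, ped, truth


@pytest.fixture(scope="session")
def small_events(small_population):
    cfg, ped, truth = small_population
    return simulate_careers(ped, truth, cfg)


@pytest.fixture(scope="session")
def small_phenotypes(small_population):
    cfg, ped, truth = small_population
    return simulate_phenotypes(ped, truth, cfg)


@pytest.fixture(scope="session")
def small_kinship(small_population):
    _, ped, _ = small_population
    return compute_kinship(ped)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
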