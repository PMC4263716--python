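import numpy as np
import pandas as pd
import pytest

from awmnet.simulate import SimConfig, simulate_cross


def small_sim_config(seed: int = 7, **overrides) -> SimConfig:
    """A fast, reduced-scale cross: 3 chromosomes x 60 SNPs, ~130 phenotyped."""
    defaults = dict(
        seed=seed,
        n_founders_breedA=3,
        n_founders_breedB=30,
        generation_sizes={"f1": 12, "f2": 20, "bc1": 80, "bc": 30, "f3": 20},
        n_chromosomes=3,
        snps_per_chromosome=60,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    return simulate_cross(small_sim_config())


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def toy_pedigree(rows):
    """rows: list of (id, sire, dam); sex/generation filled trivially."""
    return pd.DataFrame(
        [(i, s, d, 1, "G") for i, s, d in rows],
        columns=["individual_id", "sire_id", "dam_id", "sex", "generation"],
    )
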