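import numpy as np
import pandas as pd
import pytest

from refmix.data_model import collapse_wells
from refmix.simulate import (
    SimulationConfig,
    simulate_mixture_phase,
    simulate_profiling_phase,
)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def profiling_wells(sim_config) -> pd.DataFrame:
    return simulate_profiling_phase(sim_config, seed=42)


@pytest.fixture(scope="session")
def profiles(profiling_wells) -> pd.DataFrame:
    """Collapsed (plate-averaged) pure-cell-line profiles."""
    return collapse_wells(profiling_wells.drop(columns="at_ceiling"))


@pytest.fixture(scope="session")
def rna_mixture_wells(sim_config) -> pd.DataFrame:
    return simulate_mixture_phase(sim_config, "rna_mixture", seed=43)


@pytest.fixture(scope="session")
def rna_mixtures(rna_mixture_wells) -> pd.DataFrame:
    return collapse_wells(rna_mixture_wells.drop(columns="at_ceiling"))


@pytest.fixture(scope="session")
def cell_mixtures(sim_config) -> pd.DataFrame:
    wells = simulate_mixture_phase(sim_config, "cell_mixture", seed=44)
    return collapse_wells(wells.drop(columns="at_ceiling"))
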