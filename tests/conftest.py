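import numpy as np
import pandas as pd
import pytest

from glycodacomp import (
    GlycanTable,
    SimulationSpec,
    StudyDesign,
    benchmark_fpr_sensitivity,
    simulate_profiles,
)


@pytest.fixture
def small_table() -> GlycanTable:
    """3 features x 2 samples on the percent scale."""
    df = pd.DataFrame([[50.0, 40.0], [30.0, 40.0], [20.0, 20.0]],
                      index=["Ga", "Gb", "Gc"], columns=["S1", "S2"])
    return GlycanTable(df, scale="relative_percent")


@pytest.fixture
def two_group_design() -> StudyDesign:
    return StudyDesign(group_of={"S1": "A", "S2": "B"})


@pytest.fixture
def sim20():
    """Simulated two-group glycome, 20 samples per group, fixed seed."""
    spec = SimulationSpec(n_per_group=(20, 20), seed=7)
    table, design, truth = simulate_profiles(spec)
    return table, design, truth


def random_composition_table(n_features: int, n_samples: int, seed: int,
                             sigma: float = 1.0) -> GlycanTable:
    """Random strictly positive percent-scale table (lognormal profiles)."""
    rng = np.random.default_rng(seed)
    vals = rng.lognormal(0.0, sigma, size=(n_features, n_samples))
    vals = vals / vals.sum(axis=0) * 100.0
    df = pd.DataFrame(vals,
                      index=[f"G{i}" for i in range(n_features)],
                      columns=[f"S{j}" for j in range(n_samples)])
    return GlycanTable(df, scale="relative_percent")


@pytest.fixture(scope="session")
def benchmark_curves() -> pd.DataFrame:
    """One shared sweep of the simulation benchmark (10 reps x 4 sizes)."""
    return benchmark_fpr_sensitivity(sample_sizes=(5, 10, 20, 40),
                                     replicates=10, seed=1)
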