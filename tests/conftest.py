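import numpy as np
import pandas as pd
import pytest

from divpart import CommunityMatrix, PredictorTable, SimulationConfig, gen_dataset


@pytest.fixture(scope="session")
def small_community() -> CommunityMatrix:
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 30, size=(10, 20)).astype(float)
    counts[counts < 5] = 0.0
    counts[:, 0] += 1.0  # keep every site non-empty
    return CommunityMatrix(
        [f"S{i}" for i in range(10)], [f"G{j}" for j in range(20)], counts
    )


@pytest.fixture(scope="session")
def default_dataset():
    """16-site dataset with a strong climatic effect on diversity."""
    return gen_dataset(SimulationConfig(effect_sizes={"climatic": 2.0}, seed=7))


@pytest.fixture(scope="session")
def env16(default_dataset) -> PredictorTable:
    return default_dataset.env


@pytest.fixture()
def three_set_env() -> PredictorTable:
    """Minimal 2+2+2-variable table, one variable set per predictor group."""
    rng = np.random.default_rng(3)
    sites = [f"S{i}" for i in range(30)]
    df = pd.DataFrame(
        rng.standard_normal((30, 6)),
        index=sites,
        columns=["c1", "c2", "s1", "s2", "h1", "h2"],
    )
    labels = {"c1": "climatic", "c2": "climatic", "s1": "soil", "s2": "soil",
              "h1": "historical", "h2": "historical"}
    return PredictorTable(sites, df, labels)
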