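import numpy as np
import pandas as pd
import pytest

from triomix import FeatureTable, SyntheticConfig, generate_study


def small_config(seed: int = 7) -> SyntheticConfig:
    """A reduced cohort for fast unit tests (full scale lives in acceptance)."""
    return SyntheticConfig(
        n_uc=20,
        n_ctrl=15,
        n_features={"bacteria": 60, "fungi": 25, "metabolite": 30},
        n_markers={"bacteria": 6, "fungi": 4, "metabolite": 5},
        n_planted_edges=4,
        depth_range=(2000, 20000),
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_study():
    return generate_study(small_config())


@pytest.fixture()
def toy_counts():
    """4 features x 4 samples count table with hand-checkable structure."""
    df = pd.DataFrame(
        [[1, 0, 0, 0], [2, 3, 0, 0], [3, 4, 5, 0], [4, 5, 6, 7]],
        index=[f"f{i}" for i in range(4)],
        columns=[f"s{j}" for j in range(4)],
    )
    return FeatureTable(df, omic="bacteria", value_kind="count")


def random_table(rng: np.random.Generator, n_feat=10, n_samp=5, omic="bacteria"):
    values = rng.integers(0, 50, size=(n_feat, n_samp))
    df = pd.DataFrame(
        values,
        index=[f"f{i}" for i in range(n_feat)],
        columns=[f"s{j}" for j in range(n_samp)],
    )
    return FeatureTable(df, omic=omic, value_kind="count")
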