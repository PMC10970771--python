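import numpy as np
import pandas as pd
import pytest

from mircog import synthio


@pytest.fixture(scope="session")
def validation_data():
    """One default synthetic validation cohort (wells + clinical table)."""
    design = synthio.ValidationDesign(seed=20240321)
    return synthio.generate_validation(design)


@pytest.fixture(scope="session")
def small_discovery():
    """A small discovery dataset with two planted contrasts."""
    design = synthio.DiscoveryDesign(
        n_per_group={"HC": 10, "PDND": 12, "PD-MCI": 10, "PDD": 8},
        p_mirnas=120,
        batch_sizes=(20, 20),
        planted=[
            synthio.PlantedEffect(3, "PD-MCI", "PDND", 1.5),
            synthio.PlantedEffect(7, "PD-MCI", "PDND", -1.5),
        ],
        seed=11,
    )
    return synthio.generate_discovery(design)


def planted_selector_instance(seed, n=60, p=500, n_planted=6, effect=1.0):
    """Standardized design with planted group-mean shifts, as a DataFrame."""
    rng = np.random.default_rng(seed)
    n_case = min(23, n // 2)  # 23 vs 37 at the default n = 60
    y = np.array([1] * n_case + [0] * (n - n_case))
    X = rng.normal(size=(n, p))
    for j in range(n_planted):
        X[y == 1, j] += effect
    values = pd.DataFrame(
        X.T, index=[f"m{j}" for j in range(p)], columns=[f"s{i}" for i in range(n)]
    )
    labels = pd.Series(y, index=values.columns)
    return values, labels
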