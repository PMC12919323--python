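import numpy as np
import pandas as pd
import pytest

from standgrowth import InventoryTable, default_profiles


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_table():
    """A tiny two-species inventory with two synthetic covariates."""
    rng = np.random.default_rng(7)
    n = 40
    dbh = rng.uniform(5, 35, n)
    df = pd.DataFrame({
        "species": ["Spruce"] * (n // 2) + ["Poplar"] * (n // 2),
        "dbh_cm": dbh,
        "height_m": 2.0 + 0.5 * dbh + rng.normal(0, 1, n),
        "age_yr": rng.uniform(10, 100, n),
        "dem": 1000 + 30 * dbh + rng.normal(0, 100, n),
        "p": rng.uniform(150, 400, n),
    })
    return InventoryTable(df)


def make_csv(path, rows, header="species,dbh_cm,height_m,age_yr"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path
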