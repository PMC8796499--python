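from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from detanon import MicrodataTable, birth_cohort_config, simulate_cohort


@pytest.fixture
def small_table() -> MicrodataTable:
    """A 40-row mixed table with two continuous and two binary columns."""
    rng = np.random.default_rng(2024)
    df = pd.DataFrame(
        {
            "x": rng.normal(10, 2, 40),
            "y": rng.lognormal(1, 0.5, 40),
            "g": np.repeat(["a", "b"], 20),
            "h": np.tile(["u", "v"], 20),
        }
    )
    roles = {"x": "continuous", "y": "continuous", "g": "categorical", "h": "categorical"}
    return MicrodataTable(df, roles)


@pytest.fixture(scope="session")
def cohort500() -> MicrodataTable:
    return simulate_cohort(birth_cohort_config(n=500, seed=7))


def make_synthetic_titanic(n: int = 480, seed: int = 5) -> pd.DataFrame:
    """A schema-compatible stand-in for the Kaggle Titanic training table.

    Synthetic: generated from simple random draws, with all 12 columns, a
    block of missing Age cells, and every Pclass x Sex x Family combination
    populated. It mimics the file's *shape* only — none of the published
    Titanic results are expected from it.
    """
    rng = np.random.default_rng(seed)
    pclass = rng.choice([1, 2, 3], size=n, p=[0.25, 0.2, 0.55])
    sex = rng.choice(["male", "female"], size=n, p=[0.65, 0.35])
    sibsp = rng.poisson(0.5, n)
    parch = rng.poisson(0.4, n)
    age = np.round(rng.gamma(9, 3.3, n), 1)
    age[rng.random(n) < 0.2] = np.nan
    fare = np.round(rng.lognormal(2.9, 0.9, n), 4)
    logit = 1.2 - 0.8 * (pclass - 1) - 2.0 * (sex == "male")
    survived = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    df = pd.DataFrame(
        {
            "PassengerId": np.arange(1, n + 1),
            "Survived": survived,
            "Pclass": pclass,
            "Name": [f"Passenger, No. {i}" for i in range(1, n + 1)],
            "Sex": sex,
            "Age": age,
            "SibSp": sibsp,
            "Parch": parch,
            "Fare": fare,
            "Ticket": [f"T{i:05d}" for i in range(n)],
            "Cabin": [None] * n,
            "Embarked": rng.choice(["S", "C", "Q"], size=n),
        }
    )
    # guarantee every Pclass x Sex x Family stratum is populated
    fill = []
    for pc in (1, 2, 3):
        for sx in ("male", "female"):
            for fam in (0, 1):
                fill.extend([(pc, sx, fam)] * 4)
    for row, (pc, sx, fam) in enumerate(fill):
        df.loc[row, ["Pclass", "Sex", "SibSp", "Parch"]] = [pc, sx, fam, 0]
    df["Pclass"] = df["Pclass"].astype(int)
    return df


@pytest.fixture
def synthetic_titanic(tmp_path) -> str:
    path = tmp_path / "synthetic_titanic.csv"
    make_synthetic_titanic().to_csv(path, index=False)
    return str(path)
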