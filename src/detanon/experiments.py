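"""Sensitivity-analysis sweeps and the Titanic replication recipe.

The sweeps quantify the risk-utility trade-off of deterministic k-NN
microaggregation on simulated cohorts: for a grid of neighbourhood sizes k
(or sample sizes n), many cohorts are simulated, anonymised and scored with
every metric in the package, and the per-grid-point mean and standard
deviation across replicates are reported. The qualitative expectations are

* utility loss (U, delta, standardised coefficient differences) grows with
  k and shrinks with n;
* disclosure risk (risk1) shrinks with k and grows with n, because denser
  data put centroids closer to the records they replace.

``replicate_titanic`` packages the worked example on the public Kaggle
Titanic training table (891 passengers, 12 columns): preprocessing,
k = 3 anonymisation of Age and Fare, a survival logistic regression fitted
to both tables, and the full utility and risk reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .anonymiser import AnonymisationConfig, AnonymisationResult, anonymise
from .cohort import CohortSimConfig, simulate_cohort
from .risk import RiskParams, RiskReport, risk_report
from .table import MicrodataTable
from .utility import UtilityReport, utility_report

logger = logging.getLogger(__name__)


@dataclass
class SweepResult:
    """Mean +- sd of every metric across replicates at one grid value."""

    grid_name: str  # "k" or "n"
    value: int
    reps: int
    metrics: dict[str, tuple[float, float]]  # name -> (mean, sd)

    def mean(self, name: str) -> float:
        return self.metrics[name][0]


def sweep_to_frame(results: Sequence[SweepResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row: dict = {r.grid_name: r.value, "reps": r.reps}
        for name, (mean, sd) in r.metrics.items():
            row[f"{name}_mean"] = mean
            row[f"{name}_sd"] = sd
        rows.append(row)
    return pd.DataFrame(rows)


def _replicate_metrics(
    table: MicrodataTable,
    k: int,
    risk_params: RiskParams,
) -> dict[str, float]:
    """Anonymise one simulated cohort and score it with every metric.

    The analysis-specific comparison mirrors a typical cohort analysis: a
    linear model of the first continuous variable on the remaining
    continuous variables plus the stratum indicators.
    """
    result = anonymise(table, AnonymisationConfig(k=k))
    outcome = table.continuous_columns[0]
    covariates = table.continuous_columns[1:] + table.categorical_columns
    rep = utility_report(table, result.anonymised, outcome, covariates, family="linear")
    risk = risk_report(table, result.anonymised, risk_params)
    out = {"U": rep.propensity.U, "risk1": risk.risk1, "risk2": risk.risk2}
    out |= {f"delta_{name}": value for name, value in rep.deltas.items()}
    assert rep.comparison is not None
    out |= {
        f"d_{name}": float(d)
        for name, d in zip(rep.comparison.names, rep.comparison.d)
        if name != "Intercept"
    }
    return out


def _aggregate(
    grid_name: str, value: int, per_rep: list[dict[str, float]]
) -> SweepResult:
    names = per_rep[0].keys()
    metrics = {
        name: (
            float(np.mean([m[name] for m in per_rep])),
            float(np.std([m[name] for m in per_rep], ddof=1)) if len(per_rep) > 1 else 0.0,
        )
        for name in names
    }
    return SweepResult(grid_name=grid_name, value=value, reps=len(per_rep), metrics=metrics)


def _check_k_feasible(config: CohortSimConfig, k: int, n: int) -> None:
    smallest = min(config.stratum_sizes(n).values())
    if k > smallest:
        raise ValueError(
            f"k={k} exceeds the smallest stratum ({smallest} records at n={n})"
        )


def sweep_k(
    config: CohortSimConfig,
    k_values: Sequence[int],
    reps: int = 20,
    seed: int = 0,
    risk_params: RiskParams | None = None,
) -> list[SweepResult]:
    """Risk-utility metrics as a function of the neighbourhood size k.

    The same ``reps`` simulated cohorts (seeded from ``seed``) are
    anonymised at every k, so grid points are compared on paired data.
    """
    if reps < 1:
        raise ValueError("at least one replicate is required")
    risk_params = risk_params or RiskParams()
    for k in k_values:
        _check_k_feasible(config, k, config.n)
    tables = [
        simulate_cohort(config, seed=child)
        for child in np.random.SeedSequence(seed).spawn(reps)
    ]
    results = []
    for k in k_values:
        per_rep = [_replicate_metrics(t, k, risk_params) for t in tables]
        results.append(_aggregate("k", k, per_rep))
        logger.info("sweep_k k=%d: U=%.3g risk1=%.3g", k,
                    results[-1].mean("U"), results[-1].mean("risk1"))
    return results


def sweep_n(
    config: CohortSimConfig,
    n_values: Sequence[int],
    k: int = 5,
    reps: int = 20,
    seed: int = 0,
    risk_params: RiskParams | None = None,
) -> list[SweepResult]:
    """Risk-utility metrics as a function of the sample size n, at fixed k."""
    if reps < 1:
        raise ValueError("at least one replicate is required")
    risk_params = risk_params or RiskParams()
    for n in n_values:
        _check_k_feasible(config, k, n)
    ss = np.random.SeedSequence(seed)
    results = []
    for n, child in zip(n_values, ss.spawn(len(n_values))):
        per_rep = [
            _replicate_metrics(simulate_cohort(config, n=n, seed=rep_seed), k, risk_params)
            for rep_seed in child.spawn(reps)
        ]
        results.append(_aggregate("n", n, per_rep))
        logger.info("sweep_n n=%d: U=%.3g risk1=%.3g", n,
                    results[-1].mean("U"), results[-1].mean("risk1"))
    return results


# ---------------------------------------------------------------------------
# Titanic replication
# ---------------------------------------------------------------------------

TITANIC_COLUMNS = [
    "PassengerId", "Survived", "Pclass", "Name", "Sex", "Age",
    "SibSp", "Parch", "Fare", "Ticket", "Cabin", "Embarked",
]


@dataclass
class TitanicReport:
    """Everything the Titanic worked example produces."""

    original: MicrodataTable
    anonymisation: AnonymisationResult
    utility: UtilityReport
    risk: RiskReport
    n_imputed_age: int
    stratum_sizes: dict[tuple, int] = field(default_factory=dict)

    @property
    def anonymised(self) -> MicrodataTable:
        return self.anonymisation.anonymised


def prepare_titanic(raw: pd.DataFrame) -> tuple[MicrodataTable, int]:
    """Preprocess the Kaggle training table for anonymisation.

    Drops Ticket, Cabin and Embarked (not used to model survival) and the
    direct identifier Name; fills missing Age with the median of the
    observed ages; recodes SibSp + Parch into a binary Family indicator.
    The result has four categorical variables (Survived, Pclass, Sex,
    Family) and two continuous ones (Age, Fare). Returns the prepared table
    and the number of imputed Age cells.
    """
    missing = [c for c in TITANIC_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"not a Kaggle Titanic training table; missing column(s): {missing}")
    df = raw.copy()
    n_missing_age = int(df["Age"].isna().sum())
    df["Age"] = df["Age"].fillna(df["Age"].median())
    df["Family"] = np.where(df["SibSp"] + df["Parch"] > 0, "yes", "no")
    keep = ["PassengerId", "Survived", "Pclass", "Sex", "Age", "Fare", "Family"]
    roles = {
        "PassengerId": "id",
        "Survived": "categorical",
        "Pclass": "categorical",
        "Sex": "categorical",
        "Age": "continuous",
        "Fare": "continuous",
        "Family": "categorical",
    }
    return MicrodataTable(df[keep], roles), n_missing_age


def replicate_titanic(
    path: str | Path,
    k: int = 3,
    risk_params: RiskParams | None = None,
) -> TitanicReport:
    """Run the full worked example on the Kaggle Titanic training CSV.

    Stratifies on Pclass x Sex x Family (12 observed strata; the sensitive
    outcome Survived is kept out of the quasi-identifier set), anonymises
    Age and Fare with the given k, fits the survival logistic regression
    ``Survived ~ Pclass + Sex + Age + Fare + Family`` to the original and
    the anonymised table, and assembles the utility and risk reports.
    """
    raw = pd.read_csv(path)
    table, n_imputed = prepare_titanic(raw)
    config = AnonymisationConfig(k=k, stratify_on=["Pclass", "Sex", "Family"])
    result = anonymise(table, config)
    utility = utility_report(
        table, result.anonymised,
        outcome="Survived",
        covariates=["Pclass", "Sex", "Age", "Fare", "Family"],
        family="logistic",
    )
    risk = risk_report(table, result.anonymised, risk_params or RiskParams())
    sizes = {key: len(rows) for key, rows in result.partition.groups.items()}
    logger.info("Titanic: %d strata (min %d), U=%.6g, risk1=%.4g, risk2=%.4g",
                len(sizes), min(sizes.values()), utility.propensity.U,
                risk.risk1, risk.risk2)
    return TitanicReport(
        original=table,
        anonymisation=result,
        utility=utility,
        risk=risk,
        n_imputed_age=n_imputed,
        stratum_sizes=sizes,
    )
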