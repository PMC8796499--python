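"""Utility-loss metrics for anonymised microdata.

Three complementary measures, from coarsest to most targeted:

* **Global propensity-score utility U.** Stack the original and anonymised
  tables vertically, label the anonymised half 1 and the original half 0,
  and fit a logistic regression of the label on all variables. With fitted
  probabilities p_i and anonymised fraction c (0.5 here, since both halves
  have n rows),

      U = (1/N) * sum_i (p_i - c)^2,        N = 2n.

  U = 0 when the two halves are statistically indistinguishable (no utility
  lost) and approaches its supremum 1/4 when the model can separate them
  perfectly (all utility lost).

* **Variable-specific delta.** For one continuous variable, the mean squared
  original-to-anonymised displacement divided by the sample variance of the
  original variable. delta = 0.4 reads: 60% of the anonymised variable's
  variability is inherited from the data, 40% was introduced by
  anonymisation.

* **Analysis-specific standardised coefficient difference.** Fit the same
  regression model to both tables and compare each coefficient in units of
  the original estimate's standard error:

      d = |beta_or - beta_an| / SE(beta_or),

  together with a check that the two Wald confidence intervals overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .table import MicrodataTable

_SEPARATION_TOL = 1e-8


class SeparationWarning(UserWarning):
    """The propensity model separated the two halves perfectly."""


@dataclass
class PropensityResult:
    U: float
    scores: np.ndarray = field(repr=False)
    N: int
    c: float = 0.5
    separated: bool = False


@dataclass
class CoefficientComparison:
    """Per-coefficient comparison of a model fitted to both tables."""

    names: list[str]
    beta_or: np.ndarray
    se_or: np.ndarray
    beta_an: np.ndarray
    se_an: np.ndarray
    d: np.ndarray
    ci_overlaps: np.ndarray
    level: float = 0.95

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate_original": self.beta_or,
                "se_original": self.se_or,
                "estimate_anonymised": self.beta_an,
                "se_anonymised": self.se_an,
                "std_difference": self.d,
                "ci_overlap": self.ci_overlaps,
            },
            index=self.names,
        )


def _design_matrix(tables: Sequence[MicrodataTable]) -> pd.DataFrame:
    """Stack tables vertically and dummy-encode the categorical block.

    Dummy coding uses the first observed level of each categorical column as
    the reference. Both halves are encoded together, so levels align by
    construction.
    """
    first = tables[0]
    for t in tables[1:]:
        if (t.continuous_columns != first.continuous_columns
                or t.categorical_columns != first.categorical_columns):
            raise ValueError("tables must share column names and roles")
    stacked = pd.concat(
        [t.data[first.continuous_columns + first.categorical_columns] for t in tables],
        ignore_index=True,
    )
    X = pd.get_dummies(
        stacked, columns=first.categorical_columns, drop_first=True, dtype=float
    )
    return sm.add_constant(X.astype(float), has_constant="add")


def propensity_utility(
    original: MicrodataTable, anonymised: MicrodataTable
) -> PropensityResult:
    """Global propensity-score utility loss U of an anonymised table.

    The label (1 = anonymised half) is regressed on all variables — main
    effects, categoricals dummy-encoded — by maximum-likelihood logistic
    regression. If the model separates the halves perfectly the MLE does
    not exist; the guard then reports the supremum U = 1/4 with a warning
    rather than failing.
    """
    if original.n != anonymised.n:
        raise ValueError("original and anonymised tables must have the same row count")
    X = _design_matrix([original, anonymised])
    y = np.r_[np.zeros(original.n), np.ones(anonymised.n)]
    N = len(y)

    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        scores = np.asarray(fit.predict(X))
        if not fit.mle_retvals.get("converged", True):
            raise ValueError(
                "propensity logistic regression did not converge: "
                f"{fit.mle_retvals}"
            )
        if np.max(np.abs(scores - y)) < _SEPARATION_TOL:
            separated = True
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        separated = True
        scores = y.astype(float)

    if separated:
        scores = y.astype(float)
        warnings.warn(
            "the propensity model separates original from anonymised rows "
            "perfectly; reporting the utility-loss supremum U = 1/4",
            SeparationWarning,
            stacklevel=2,
        )
    U = float(np.mean((scores - 0.5) ** 2))
    return PropensityResult(U=U, scores=scores, N=N, c=0.5, separated=separated)


def delta_metric(x_or: np.ndarray, x_an: np.ndarray) -> float:
    """Standardised mean squared displacement of one continuous variable."""
    x_or = np.asarray(x_or, dtype=float)
    x_an = np.asarray(x_an, dtype=float)
    if x_or.shape != x_an.shape or x_or.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if x_or.size < 2:
        raise ValueError("at least two observations are required")
    var = float(np.var(x_or, ddof=1))
    if var <= 0:
        raise ValueError("the original variable has zero variance")
    return float(np.mean((x_or - x_an) ** 2) / var)


def coefficient_difference(
    beta_or: np.ndarray, se_or: np.ndarray, beta_an: np.ndarray
) -> np.ndarray:
    """Elementwise |beta_or - beta_an| / SE(beta_or)."""
    beta_or, se_or, beta_an = map(lambda a: np.asarray(a, dtype=float),
                                  (beta_or, se_or, beta_an))
    if not (beta_or.shape == se_or.shape == beta_an.shape):
        raise ValueError("coefficient and standard-error vectors must be aligned")
    if np.any(se_or <= 0):
        raise ValueError("standard errors must be positive")
    return np.abs(beta_or - beta_an) / se_or


def ci_overlap(
    beta_or: np.ndarray,
    se_or: np.ndarray,
    beta_an: np.ndarray,
    se_an: np.ndarray,
    level: float = 0.95,
) -> np.ndarray:
    """Whether the two Wald intervals beta +- z*SE intersect (closed)."""
    z = stats.norm.ppf(0.5 + level / 2)
    beta_or, se_or, beta_an, se_an = map(
        lambda a: np.asarray(a, dtype=float), (beta_or, se_or, beta_an, se_an)
    )
    if np.any(se_or <= 0) or np.any(se_an <= 0):
        raise ValueError("standard errors must be positive")
    lo1, hi1 = beta_or - z * se_or, beta_or + z * se_or
    lo2, hi2 = beta_an - z * se_an, beta_an + z * se_an
    return (lo1 <= hi2) & (lo2 <= hi1)


def fit_comparison_model(
    table: MicrodataTable,
    outcome: str,
    covariates: Sequence[str],
    family: str = "linear",
):
    """Fit the analyst's intended regression model to one table.

    ``family='linear'`` is ordinary least squares; ``'logistic'`` is
    maximum-likelihood logistic regression (the outcome must be binary).
    Categorical covariates are treatment-coded against their first level.
    Returns the statsmodels results object (``params``, ``bse``, ...).
    """
    if family not in ("linear", "logistic"):
        raise ValueError(f"unknown family {family!r}")
    missing = [c for c in [outcome, *covariates] if c not in table.data.columns]
    if missing:
        raise ValueError(f"model references absent column(s): {missing}")
    terms = [
        f"C({c})" if c in table.categorical_columns else c for c in covariates
    ]
    df = table.data.copy()
    if outcome in table.categorical_columns or family == "logistic":
        df[outcome] = pd.to_numeric(df[outcome], errors="raise")
        if family == "logistic" and not set(np.unique(df[outcome])) <= {0, 1}:
            raise ValueError("logistic regression requires a binary 0/1 outcome")
    formula = f"Q('{outcome}') ~ " + " + ".join(terms)
    model = smf.logit(formula, df) if family == "logistic" else smf.ols(formula, df)
    fit = model.fit(disp=0) if family == "logistic" else model.fit()
    if family == "logistic" and not fit.mle_retvals.get("converged", True):
        raise ValueError("logistic model did not converge (separation or rank deficiency)")
    if np.any(~np.isfinite(fit.bse)):
        raise ValueError("model is rank deficient: non-finite standard errors")
    return fit


def compare_models(
    original: MicrodataTable,
    anonymised: MicrodataTable,
    outcome: str,
    covariates: Sequence[str],
    family: str = "linear",
    level: float = 0.95,
) -> CoefficientComparison:
    """Fit the same model to both tables and compare every coefficient."""
    fit_or = fit_comparison_model(original, outcome, covariates, family)
    fit_an = fit_comparison_model(anonymised, outcome, covariates, family)
    if list(fit_or.params.index) != list(fit_an.params.index):
        raise ValueError("model terms differ between tables (level mismatch?)")
    beta_or, se_or = fit_or.params.to_numpy(), fit_or.bse.to_numpy()
    beta_an, se_an = fit_an.params.to_numpy(), fit_an.bse.to_numpy()
    return CoefficientComparison(
        names=list(fit_or.params.index),
        beta_or=beta_or,
        se_or=se_or,
        beta_an=beta_an,
        se_an=se_an,
        d=coefficient_difference(beta_or, se_or, beta_an),
        ci_overlaps=ci_overlap(beta_or, se_or, beta_an, se_an, level),
        level=level,
    )


@dataclass
class UtilityReport:
    """Bundle of all three utility-loss measures for one anonymisation."""

    propensity: PropensityResult
    deltas: dict[str, float]
    comparison: CoefficientComparison | None = None

    def to_dict(self) -> dict:
        out: dict = {
            "U": self.propensity.U,
            "separated": self.propensity.separated,
            "delta": dict(self.deltas),
        }
        if self.comparison is not None:
            out["coefficients"] = {
                name: {
                    "estimate_original": float(b0),
                    "se_original": float(s0),
                    "estimate_anonymised": float(b1),
                    "std_difference": float(d),
                    "ci_overlap": bool(o),
                }
                for name, b0, s0, b1, d, o in zip(
                    self.comparison.names,
                    self.comparison.beta_or,
                    self.comparison.se_or,
                    self.comparison.beta_an,
                    self.comparison.d,
                    self.comparison.ci_overlaps,
                )
            }
        return out


def utility_report(
    original: MicrodataTable,
    anonymised: MicrodataTable,
    outcome: str | None = None,
    covariates: Sequence[str] | None = None,
    family: str = "linear",
) -> UtilityReport:
    """Compute U and per-variable delta, plus the model comparison if asked."""
    deltas = {
        c: delta_metric(original.data[c].to_numpy(), anonymised.data[c].to_numpy())
        for c in original.continuous_columns
    }
    comparison = None
    if outcome is not None:
        if covariates is None:
            raise ValueError("covariates are required when an outcome is given")
        comparison = compare_models(original, anonymised, outcome, covariates, family)
    return UtilityReport(
        propensity=propensity_utility(original, anonymised),
        deltas=deltas,
        comparison=comparison,
    )
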