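"""Robust-Mahalanobis disclosure-risk metrics for paired microdata.

The attack model asks: after anonymisation, is a record's released vector
still so close to its original value that an intruder gains information?
Outliers deserve wider tolerance than points in the centre of the data
cloud, so the acceptance region around each original record scales with its
(squared) robust Mahalanobis distance from the multivariate centre:

* **risk1** — per record i and variable j, build the interval
  ``[x_ij - w1*RMD2_i, x_ij + w1*RMD2_i]``; the intervals form a box around
  the original vector. A record is *risky* if its anonymised vector lies
  inside the box on every dimension. risk1 is the proportion of risky rows.
* **risk2** — a risky record is *unsafe* if fewer than m other anonymised
  records lie within Euclidean distance w2 of its anonymised vector (no
  crowd to hide in). risk2 is the proportion of unsafe rows, so risk2 <=
  risk1 by construction.

Location and scatter default to the Minimum Covariance Determinant (MCD)
estimator so that outliers do not inflate their own distances; a classical
mean/covariance mode exists for hand-checkable examples and tiny n. With a
fixed seed the MCD, and hence the whole report, is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.covariance import MinCovDet

from .table import MicrodataTable

DEFAULT_MCD_SEED = 42


@dataclass
class RiskParams:
    """Tuning knobs of the risk metrics, chosen by the data custodian.

    ``w1`` scales the per-record box half-width (in data units per unit of
    squared Mahalanobis distance); ``w2`` is the closeness radius in data
    units; ``m`` is the number of nearby anonymised records needed to call a
    risky record safe again.
    """

    w1: float = 0.01
    w2: float = 0.05
    m: int = 1
    mode: str = "robust"  # robust (MCD) | classical
    seed: int = DEFAULT_MCD_SEED

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("w1 and w2 must be non-negative")
        if self.m < 1:
            raise ValueError("m must be a positive integer")
        if self.mode not in ("robust", "classical"):
            raise ValueError(f"unknown covariance mode {self.mode!r}")


@dataclass
class RiskReport:
    rmd2: np.ndarray = field(repr=False)
    risky: np.ndarray = field(repr=False)
    unsafe: np.ndarray = field(repr=False)
    risk1: float
    risk2: float
    params: RiskParams

    @property
    def n_risky(self) -> int:
        return int(self.risky.sum())

    @property
    def n_unsafe(self) -> int:
        return int(self.unsafe.sum())

    def to_dict(self) -> dict:
        return {
            "risk1": self.risk1,
            "risk2": self.risk2,
            "n_risky": self.n_risky,
            "n_unsafe": self.n_unsafe,
            "w1": self.params.w1,
            "w2": self.params.w2,
            "m": self.params.m,
            "mode": self.params.mode,
        }

    def flags_frame(self) -> pd.DataFrame:
        """Per-row flags for export/plotting of the risky observations."""
        return pd.DataFrame(
            {"rmd2": self.rmd2, "risky": self.risky, "unsafe": self.unsafe}
        )



def _as_matrix(X) -> np.ndarray:
    """Coerce input to an n x p float matrix; a 1-D vector becomes n x 1."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        return X.reshape(-1, 1)
    if X.ndim != 2:
        raise ValueError("expected a vector or matrix of observations")
    return X

def robust_mahalanobis(
    X: np.ndarray, mode: str = "robust", seed: int = DEFAULT_MCD_SEED
) -> np.ndarray:
    """Squared (robust) Mahalanobis distance of each row from the centre.

    Robust mode uses the MCD location/scatter with its default coverage
    fraction, seeded for determinism; classical mode uses the sample mean
    and covariance (ddof=1).
    """
    X = _as_matrix(X)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than continuous variables ({p})")
    if mode == "robust":
        mcd = MinCovDet(random_state=seed).fit(X)
        return np.asarray(mcd.mahalanobis(X), dtype=float)
    centre = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1).reshape(p, p)
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("sample covariance is singular") from exc
    diff = X - centre
    return np.einsum("ij,jk,ik->i", diff, prec, diff)


def risk1(
    X_orig: np.ndarray,
    X_anon: np.ndarray,
    params: RiskParams,
    rmd2: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Proportion of anonymised rows inside their original record's box."""
    X_orig = _as_matrix(X_orig)
    X_anon = _as_matrix(X_anon)
    if X_orig.shape != X_anon.shape:
        raise ValueError("original and anonymised matrices must have equal shape")
    if rmd2 is None:
        rmd2 = robust_mahalanobis(X_orig, params.mode, params.seed)
    half_width = params.w1 * np.asarray(rmd2)[:, None]
    risky = np.all(np.abs(X_anon - X_orig) <= half_width, axis=1)
    return float(risky.mean()), risky


def risk2(
    X_anon: np.ndarray, params: RiskParams, risky: np.ndarray
) -> tuple[float, np.ndarray]:
    """Risky rows lacking m close anonymised neighbours (within w2)."""
    X_anon = _as_matrix(X_anon)
    risky = np.asarray(risky, dtype=bool)
    unsafe = np.zeros_like(risky)
    idx = np.flatnonzero(risky)
    if idx.size:
        d = cdist(X_anon[idx], X_anon)
        close = (d <= params.w2).sum(axis=1) - 1  # exclude the row itself
        unsafe[idx] = close < params.m
    return float(unsafe.mean()), unsafe


def risk_report(
    original: MicrodataTable | np.ndarray,
    anonymised: MicrodataTable | np.ndarray,
    params: RiskParams | None = None,
) -> RiskReport:
    """Full disclosure-risk assessment of a paired original/anonymised set."""
    params = params or RiskParams()
    X_or = original.continuous.to_numpy() if isinstance(original, MicrodataTable) else _as_matrix(original)
    X_an = anonymised.continuous.to_numpy() if isinstance(anonymised, MicrodataTable) else _as_matrix(anonymised)
    rmd2 = robust_mahalanobis(X_or, params.mode, params.seed)
    r1, risky = risk1(X_or, X_an, params, rmd2=rmd2)
    r2, unsafe = risk2(X_an, params, risky)
    return RiskReport(rmd2=rmd2, risky=risky, unsafe=unsafe, risk1=r1, risk2=r2,
                      params=params)
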