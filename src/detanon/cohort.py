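"""Seeded simulation of non-normal multivariate microdata with strata.

The generator emulates an epidemiological cohort: a few continuous
biomarkers with realistic skewness and kurtosis, plus binary categorical
variables whose combinations define strata with fixed population
proportions. It serves two purposes: the data-generating mechanism for the
sensitivity analyses (effect of k and of sample size on risk and utility),
and a download-free fixture factory for the test suite.

Non-normality is produced with the Fleishman power method and its
multivariate extension by Vale and Maurelli: each variable is a cubic
polynomial of a standard normal,

    Y = a + b*Z + c*Z^2 + d*Z^3,      a = -c,

with coefficients solved so that Y has mean 0, variance 1 and the target
skewness and *excess* kurtosis (normal = 0). Correlated variables are
obtained by drawing the underlying normals with an "intermediate"
correlation chosen so the transformed variables hit the target correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .table import MicrodataTable


@dataclass(frozen=True)
class MomentSpec:
    """Target moments of one continuous variable.

    ``kurtosis`` is the excess kurtosis (0 for a normal). The pair
    (skewness, kurtosis) must lie in the Fleishman-feasible region; roughly,
    excess kurtosis cannot be far below ``1.64 * skewness**2 - 1.22``.
    """

    name: str
    mean: float
    sd: float
    skewness: float = 0.0
    kurtosis: float = 0.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"{self.name}: sd must be positive")


@dataclass(frozen=True)
class FleishmanCoefficients:
    a: float
    b: float
    c: float
    d: float

    def transform(self, z: np.ndarray) -> np.ndarray:
        return self.a + z * (self.b + z * (self.c + z * self.d))


def _fleishman_system(x: np.ndarray, skew: float, ekurt: float) -> np.ndarray:
    b, c, d = x
    return np.array([
        b * b + 6 * b * d + 2 * c * c + 15 * d * d - 1.0,
        2 * c * (b * b + 24 * b * d + 105 * d * d + 2) - skew,
        24 * (b * d + c * c * (1 + b * b + 28 * b * d)
              + d * d * (12 + 48 * b * d + 141 * c * c + 225 * d * d)) - ekurt,
    ])


def fleishman_coefficients(
    skewness: float, kurtosis: float, tol: float = 1e-10
) -> FleishmanCoefficients:
    """Solve the Fleishman moment system for (a, b, c, d), a = -c.

    Started from the normal solution (b, c, d) = (1, 0, 0); infeasible
    moment pairs (e.g. excess kurtosis below the Fleishman bound) make the
    system unsolvable and raise a ValueError.
    """
    if skewness == 0.0 and kurtosis == 0.0:
        return FleishmanCoefficients(0.0, 1.0, 0.0, 0.0)
    sol = optimize.root(
        _fleishman_system, x0=np.array([1.0, 0.0, 0.0]),
        args=(skewness, kurtosis), method="hybr", tol=1e-13,
    )
    residual = np.max(np.abs(_fleishman_system(sol.x, skewness, kurtosis)))
    if not sol.success or residual > tol:
        raise ValueError(
            f"no Fleishman solution for skewness={skewness}, excess "
            f"kurtosis={kurtosis} (residual {residual:.2e}); the pair is "
            "outside the feasible region or the solver did not converge"
        )
    b, c, d = sol.x
    return FleishmanCoefficients(a=-c, b=b, c=c, d=d)


def intermediate_correlation(
    rho_target: float,
    coeffs_i: FleishmanCoefficients,
    coeffs_j: FleishmanCoefficients,
) -> float:
    """Correlation of the underlying normals that yields ``rho_target``.

    Solves the Vale–Maurelli cubic
    ``rho = r*(b_i b_j + 3 b_i d_j + 3 d_i b_j + 9 d_i d_j)
    + r^2 * 2 c_i c_j + r^3 * 6 d_i d_j`` for the real root r in [-1, 1].
    """
    if abs(rho_target) > 1:
        raise ValueError("target correlation must lie in [-1, 1]")
    if rho_target == 0.0:
        return 0.0
    bi, ci, di = coeffs_i.b, coeffs_i.c, coeffs_i.d
    bj, cj, dj = coeffs_j.b, coeffs_j.c, coeffs_j.d
    c1 = bi * bj + 3 * bi * dj + 3 * di * bj + 9 * di * dj
    c2 = 2 * ci * cj
    c3 = 6 * di * dj
    roots = np.roots([c3, c2, c1, -rho_target])
    real = roots[np.abs(roots.imag) < 1e-9].real
    admissible = real[np.abs(real) <= 1 + 1e-9]
    if admissible.size == 0:
        raise ValueError(
            f"no admissible intermediate correlation for target {rho_target}"
        )
    return float(np.clip(admissible[np.argmin(np.abs(admissible - rho_target))], -1, 1))


def simulate_nonnormal(
    specs: Sequence[MomentSpec],
    rho: np.ndarray | None,
    n: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> np.ndarray:
    """Draw an n x p matrix with the target moments and correlations.

    Draws correlated standard normals at the intermediate correlations,
    applies each variable's Fleishman polynomial, and affinely maps each
    column to its target mean and sd. Fully determined by the seed.
    """
    p = len(specs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rho is None:
        rho = np.eye(p)
    rho = np.asarray(rho, dtype=float)
    if rho.shape != (p, p) or not np.allclose(rho, rho.T):
        raise ValueError("rho must be a symmetric p x p matrix")
    coeffs = [fleishman_coefficients(s.skewness, s.kurtosis) for s in specs]
    inter = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            inter[i, j] = inter[j, i] = intermediate_correlation(
                rho[i, j], coeffs[i], coeffs[j]
            )
    try:
        L = np.linalg.cholesky(inter)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "the intermediate correlation matrix is not positive definite; "
            "soften the target correlations or apply a nearest-PD repair "
            "before simulating"
        ) from exc
    Z = rng.standard_normal((n, p)) @ L.T
    X = np.empty_like(Z)
    for j, (spec, cf) in enumerate(zip(specs, coeffs)):
        X[:, j] = spec.mean + spec.sd * cf.transform(Z[:, j])
    return X


def apportion(n: int, proportions: Sequence[float]) -> list[int]:
    """Integer stratum sizes by largest-remainder apportionment.

    Each stratum gets floor(n * proportion); remaining units go to the
    largest fractional remainders (ties to the earlier stratum). The sizes
    always sum to n and each differs from n * proportion by less than 1.
    """
    props = np.asarray(proportions, dtype=float)
    if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be non-negative and sum to 1")
    raw = n * props
    sizes = np.floor(raw + 1e-9).astype(int)  # guard exact products from FP dust
    remainder = raw - sizes
    for idx in np.argsort(-remainder, kind="stable")[: n - sizes.sum()]:
        sizes[idx] += 1
    if (sizes == 0).any():
        raise ValueError(
            f"stratum size 0 at n={n}; increase n or merge the smallest strata"
        )
    return sizes.tolist()


@dataclass
class CohortSimConfig:
    """Everything needed to simulate one stratified cohort.

    ``strata`` maps each stratum's tuple of category labels (one label per
    name in ``categorical_names``) to its population proportion. ``specs``
    are the per-variable moment targets, shared across strata unless
    ``per_stratum_specs`` overrides them, and ``rho`` is the target
    correlation matrix of the continuous block.
    """

    n: int
    categorical_names: Sequence[str]
    strata: Mapping[tuple, float]
    specs: Sequence[MomentSpec]
    rho: np.ndarray | None = None
    per_stratum_specs: Mapping[tuple, Sequence[MomentSpec]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for labels in self.strata:
            if len(labels) != len(self.categorical_names):
                raise ValueError("each stratum key needs one label per categorical")
        if abs(sum(self.strata.values()) - 1.0) > 1e-9:
            raise ValueError("stratum proportions must sum to 1")

    def stratum_sizes(self, n: int | None = None) -> dict[tuple, int]:
        keys = list(self.strata)
        sizes = apportion(n or self.n, [self.strata[k] for k in keys])
        return dict(zip(keys, sizes))

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "categorical_names": list(self.categorical_names),
            "strata": {"|".join(map(str, k)): v for k, v in self.strata.items()},
            "specs": [vars(s) for s in self.specs],
            "rho": None if self.rho is None else np.asarray(self.rho).tolist(),
            "seed": self.seed,
        }


def simulate_cohort(
    config: CohortSimConfig,
    n: int | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> MicrodataTable:
    """Simulate one stratified cohort as a :class:`MicrodataTable`.

    Stratum sizes come from largest-remainder apportionment; within each
    stratum the continuous block is simulated independently (per-stratum
    moment targets when provided, the shared targets otherwise) and the
    categorical columns carry the stratum labels. ``n`` and ``seed``
    override the config for sweep use.
    """
    n = n or config.n
    base = seed if seed is not None else config.seed
    ss = base if isinstance(base, np.random.SeedSequence) else np.random.SeedSequence(base)
    sizes = config.stratum_sizes(n)
    child_seeds = ss.spawn(len(sizes))
    frames = []
    for (labels, size), child in zip(sizes.items(), child_seeds):
        specs = (config.per_stratum_specs or {}).get(labels, config.specs)
        X = simulate_nonnormal(specs, config.rho, size, np.random.default_rng(child))
        frame = pd.DataFrame(X, columns=[s.name for s in specs])
        for name, label in zip(config.categorical_names, labels):
            frame[name] = label
        frames.append(frame)
    data = pd.concat(frames, ignore_index=True)
    roles = {s.name: "continuous" for s in config.specs}
    roles |= {name: "categorical" for name in config.categorical_names}
    return MicrodataTable(data[list(roles)], roles)


def birth_cohort_config(n: int = 500, seed: int = 0) -> CohortSimConfig:
    """A 1958-birth-cohort-style simulation setting.

    Four non-normal biomarkers (fasting glucose, HDL cholesterol, height,
    weight) over the four sex-by-smoking strata with proportions
    40.6 / 9.2 / 38.6 / 11.6 %, mirroring the published complete-case
    stratum shares of the cohort. The moment and correlation targets are
    *synthetic placeholders* at physiologically plausible values — the
    cohort's real moments are restricted data and are not reproduced here —
    so analyses driven by this config probe qualitative behaviour, not the
    cohort's numeric results.
    """
    specs = [
        MomentSpec("glucose", mean=5.4, sd=0.9, skewness=1.5, kurtosis=4.0),
        MomentSpec("hdl", mean=1.5, sd=0.4, skewness=0.8, kurtosis=1.0),
        MomentSpec("height", mean=168.0, sd=9.0, skewness=0.1, kurtosis=-0.2),
        MomentSpec("weight", mean=76.0, sd=14.0, skewness=0.9, kurtosis=1.5),
    ]
    rho = np.array([
        [1.00, -0.15, 0.05, 0.25],
        [-0.15, 1.00, 0.05, -0.25],
        [0.05, 0.05, 1.00, 0.45],
        [0.25, -0.25, 0.45, 1.00],
    ])
    strata = {
        ("male", "non-smoker"): 0.406,
        ("male", "smoker"): 0.092,
        ("female", "non-smoker"): 0.386,
        ("female", "smoker"): 0.116,
    }
    return CohortSimConfig(
        n=n,
        categorical_names=["sex", "smoker"],
        strata=strata,
        specs=specs,
        rho=rho,
        seed=seed,
    )
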