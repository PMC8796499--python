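"""Deterministic k-NN microaggregation of continuous microdata.

The anonymiser replaces each record's continuous values by the centroid of
the record and its k-1 nearest neighbours, searched within the stratum of
records sharing the same categorical profile, and then restores each
variable's original scale. The procedure has five steps:

1. **Standardise** every continuous variable to zero mean and unit sample
   standard deviation (z-scores), so Euclidean distance weighs variables
   equally.
2. **Stratify** the rows by all observed combinations of the categorical
   variables, and verify k-anonymity of the strata (every combination occurs
   at least k times). Violations can be resolved by suppression or by a
   user-supplied merge map of category levels.
3. For each record, locate its **k-1 nearest neighbours** (Euclidean
   distance on the standardised scale) within its stratum.
4. Replace each record by the per-dimension mean (**centroid**) of its
   k-member neighbour set, and pool all strata back into one table in the
   original row order.
5. **Re-scale and re-centre**: multiply each masked variable by the ratio of
   the original to the masked standard deviation and add the original mean,
   applied to the whole dataset at once (never per stratum). Each anonymised
   variable therefore has exactly the original standard deviation and
   approximately the original mean.

Everything is deterministic: identical input and configuration give
bit-identical output. Categorical columns are never modified (only checked
for k-anonymity); only the continuous block is perturbed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .table import MicrodataTable

logger = logging.getLogger(__name__)

StratumKey = tuple


class SmallStratumError(ValueError):
    """A stratum violates k-anonymity and the policy forbids repair."""


@dataclass
class StandardisationParams:
    """Per-column mean and sample standard deviation on the original scale."""

    mu: pd.Series
    s: pd.Series

    def __post_init__(self) -> None:
        bad = self.s[self.s <= 0]
        if len(bad):
            raise ValueError(
                f"zero-variance continuous column(s): {list(bad.index)}; "
                "constant columns cannot be standardised — exclude or recode them"
            )


@dataclass
class StratumPartition:
    """Disjoint row-index sets keyed by categorical profile."""

    columns: list[str]
    groups: dict[StratumKey, np.ndarray]

    def sizes(self) -> dict[StratumKey, int]:
        return {k: len(v) for k, v in self.groups.items()}

    @property
    def n_strata(self) -> int:
        return len(self.groups)

    def min_size(self) -> int:
        return min(len(v) for v in self.groups.values())


@dataclass
class AnonymisationConfig:
    """Tuning parameters of the five-step procedure.

    ``k`` is both the k-anonymity threshold for the categorical strata and
    the neighbour-set size of the microaggregation. k >= 3 is recommended
    for release: with k = 2 an attacker who knows a centroid together with
    the mean and variance of the pair that produced it could recover the
    exact original values. k = 1 (the identity transform) is permitted for
    testing.
    """

    k: int = 3
    stratify_on: Sequence[str] | None = None  # None -> all categorical columns
    small_stratum_policy: str = "error"  # error | suppress | merge_map
    merge_map: Mapping[str, Mapping[str, str]] | None = None
    continuous_imputation: str = "median"  # median | mean | complete_case
    categorical_imputation: str = "extra_level"  # extra_level | complete_case
    missing_label: str = "(missing)"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if self.small_stratum_policy not in ("error", "suppress", "merge_map"):
            raise ValueError(f"unknown small_stratum_policy {self.small_stratum_policy!r}")
        if self.small_stratum_policy == "merge_map" and not self.merge_map:
            raise ValueError("small_stratum_policy='merge_map' requires a merge_map")
        if self.continuous_imputation not in ("median", "mean", "complete_case"):
            raise ValueError(f"unknown continuous imputation {self.continuous_imputation!r}")
        if self.categorical_imputation not in ("extra_level", "complete_case"):
            raise ValueError(f"unknown categorical imputation {self.categorical_imputation!r}")


@dataclass
class AnonymisationResult:
    """An anonymised table plus full provenance of how it was produced."""

    anonymised: MicrodataTable
    config: AnonymisationConfig
    params: StandardisationParams
    partition: StratumPartition
    neighbour_sets: list[np.ndarray] = field(repr=False, default_factory=list)
    suppressed_rows: np.ndarray | None = None


# ---------------------------------------------------------------------------
# step 0: imputation
# ---------------------------------------------------------------------------

def impute(table: MicrodataTable, config: AnonymisationConfig) -> MicrodataTable:
    """Fill (or drop) missing cells according to the configured policy.

    Continuous columns are filled with the per-column median or mean of the
    observed values; categorical columns receive a designated missing level.
    ``complete_case`` drops every row with a missing cell in the affected
    block instead.
    """
    df = table.data.copy()
    cont, cat = table.continuous_columns, table.categorical_columns

    fully_missing = [c for c in cont if df[c].isna().all()]
    if fully_missing:
        raise ValueError(f"continuous column(s) entirely missing: {fully_missing}")

    drop = pd.Series(False, index=df.index)
    if config.continuous_imputation == "complete_case":
        drop |= df[cont].isna().any(axis=1)
    else:
        fn = pd.Series.median if config.continuous_imputation == "median" else pd.Series.mean
        for c in cont:
            if df[c].isna().any():
                filled = fn(df[c].dropna())
                n_miss = int(df[c].isna().sum())
                df[c] = df[c].fillna(filled)
                logger.info("imputed %d missing cells in %r with %s=%r",
                            n_miss, c, config.continuous_imputation, filled)
    if config.categorical_imputation == "complete_case":
        drop |= df[cat].isna().any(axis=1)
    else:
        for c in cat:
            if df[c].isna().any():
                df[c] = df[c].astype(object).where(df[c].notna(), config.missing_label)
    if drop.any():
        df = df.loc[~drop]
        logger.info("complete-case filtering dropped %d rows", int(drop.sum()))
    return MicrodataTable(df, dict(table.roles))


# ---------------------------------------------------------------------------
# step 1: standardisation
# ---------------------------------------------------------------------------

def zscore_standardise(
    table: MicrodataTable,
) -> tuple[MicrodataTable, StandardisationParams]:
    """Centre each continuous column to mean 0 and scale to sample sd 1."""
    x = table.continuous
    mu = x.mean()
    s = x.std(ddof=1).fillna(0.0)  # n == 1 -> sd NaN -> rejected below
    params = StandardisationParams(mu=mu, s=s)
    z = (x - mu) / s
    return table.with_continuous(z), params


# ---------------------------------------------------------------------------
# step 2: stratification and k-anonymity
# ---------------------------------------------------------------------------

def stratify(
    table: MicrodataTable, stratify_on: Sequence[str] | None = None
) -> StratumPartition:
    """Partition rows by every observed combination of categorical levels.

    Unobserved combinations are not materialised. With no categorical
    columns the whole table forms a single stratum.
    """
    cols = list(stratify_on) if stratify_on is not None else table.categorical_columns
    bad = [c for c in cols if c not in table.categorical_columns]
    if bad:
        raise ValueError(f"stratification column(s) not declared categorical: {bad}")
    if not cols:
        return StratumPartition(columns=[], groups={(): np.arange(table.n)})
    codes = pd.MultiIndex.from_frame(table.data[cols].astype(object))
    groups: dict[StratumKey, np.ndarray] = {}
    order: dict[StratumKey, list[int]] = {}
    for pos, key in enumerate(codes):
        key = tuple(key)
        order.setdefault(key, []).append(pos)
    for key in sorted(order, key=lambda t: tuple(map(str, t))):
        groups[key] = np.asarray(order[key], dtype=int)
    return StratumPartition(columns=cols, groups=groups)


def check_k_anonymity(
    partition: StratumPartition, k: int
) -> tuple[bool, list[tuple[StratumKey, int]]]:
    """Return whether every stratum has at least k rows, plus the violators."""
    if k < 1:
        raise ValueError("k must be >= 1")
    violators = [(key, len(rows)) for key, rows in partition.groups.items()
                 if len(rows) < k]
    return (not violators), violators


def enforce_k_anonymity(
    table: MicrodataTable,
    partition: StratumPartition,
    k: int,
    policy: str,
    merge_map: Mapping[str, Mapping[str, str]] | None = None,
) -> tuple[MicrodataTable, StratumPartition, np.ndarray]:
    """Repair k-anonymity violations by suppression or category merging.

    Returns the repaired table, its re-computed partition and the positional
    indices (into the input table) of any suppressed rows. A k-anonymous
    input is returned unchanged.
    """
    ok, violators = check_k_anonymity(partition, k)
    if ok:
        return table, partition, np.empty(0, dtype=int)
    if policy == "error":
        raise SmallStratumError(
            f"{len(violators)} stratum/strata violate {k}-anonymity: "
            f"{[(key, size) for key, size in violators]}; choose a smaller k, "
            "merge categories, or allow suppression"
        )
    if policy == "suppress":
        drop = np.concatenate([partition.groups[key] for key, _ in violators])
        keep = np.setdiff1d(np.arange(table.n), drop)
        if keep.size == 0:
            raise SmallStratumError("suppression would remove every row")
        repaired = MicrodataTable(table.data.iloc[keep], dict(table.roles))
        logger.info("suppressed %d rows in %d under-sized strata", drop.size, len(violators))
        return repaired, stratify(repaired, partition.columns), np.sort(drop)
    if policy == "merge_map":
        if not merge_map:
            raise ValueError("merge_map policy requires a merge map")
        df = table.data.copy()
        for col, mapping in merge_map.items():
            if col not in partition.columns:
                raise ValueError(f"merge_map column {col!r} is not a stratification column")
            df[col] = df[col].astype(object).replace(dict(mapping))
        repaired = MicrodataTable(df, dict(table.roles))
        new_partition = stratify(repaired, partition.columns)
        ok, violators = check_k_anonymity(new_partition, k)
        if not ok:
            raise SmallStratumError(
                f"merge map still leaves {k}-anonymity violations: {violators}"
            )
        return repaired, new_partition, np.empty(0, dtype=int)
    raise ValueError(f"unknown policy {policy!r}")


# ---------------------------------------------------------------------------
# step 3: nearest neighbours
# ---------------------------------------------------------------------------

def knn_neighbour_sets(points: np.ndarray, k: int) -> list[np.ndarray]:
    """Neighbour set of every row: itself plus its k-1 nearest rows.

    Distances are Euclidean on the (standardised) coordinates. Ties —
    including exact duplicate points — are broken by ascending row index,
    which makes the search fully deterministic. Returns one sorted index
    array of length k per row.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if n < k:
        raise ValueError(f"stratum of size {n} is smaller than k={k}")
    if k == 1:
        return [np.array([i]) for i in range(n)]
    d = cdist(points, points, metric="sqeuclidean")
    sets: list[np.ndarray] = []
    for i in range(n):
        order = np.argsort(d[i], kind="stable")  # stable: ties in index order
        others = order[order != i][: k - 1]
        sets.append(np.sort(np.append(others, i)))
    return sets


# ---------------------------------------------------------------------------
# step 4: centroid replacement
# ---------------------------------------------------------------------------

def centroid_replace(points: np.ndarray, neighbour_sets: list[np.ndarray]) -> np.ndarray:
    """Replace each row by the per-dimension mean of its neighbour set."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(neighbour_sets) != points.shape[0]:
        raise ValueError("one neighbour set per row is required")
    return np.vstack([points[s].mean(axis=0) for s in neighbour_sets])


# ---------------------------------------------------------------------------
# step 5: re-scaling and re-centring
# ---------------------------------------------------------------------------

def rescale_recentre(
    masked: pd.DataFrame, params: StandardisationParams
) -> pd.DataFrame:
    """Restore the original scale: sd exactly, mean approximately.

    Each masked column (centroids on the z-score scale) is multiplied by the
    ratio of the original standard deviation to the masked standard
    deviation, then shifted by the original mean. The factor is computed on
    the whole dataset, never per stratum. Because averaging shrinks spread,
    the factor usually exceeds the original sd, and extreme centroids can
    land outside the convex hull of the original data — a deliberate extra
    layer of obfuscation.
    """
    sd_masked = masked.std(ddof=1)
    # sd of a numerically constant column is FP dust, not signal
    scale = masked.abs().max().clip(lower=1.0)
    flat = sd_masked[sd_masked <= 1e-12 * scale]
    if len(flat):
        raise ValueError(
            f"masked column(s) {list(flat.index)} are constant (all centroids "
            "coincide); k is too large for the stratum structure — use a smaller k"
        )
    return masked * (params.s / sd_masked) + params.mu


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def anonymise(table: MicrodataTable, config: AnonymisationConfig) -> AnonymisationResult:
    """Run the full five-step deterministic anonymisation.

    The k-anonymity check runs after preprocessing (imputation or
    complete-case filtering), since dropping rows changes stratum sizes. If
    repair suppresses rows, standardisation is computed on the surviving
    rows so that the exact sd-preservation guarantee holds for the released
    table.
    """
    table.require_continuous()
    prepared = impute(table, config)
    prepared.require_complete()

    partition = stratify(prepared, config.stratify_on)
    prepared, partition, suppressed = enforce_k_anonymity(
        prepared, partition, config.k, config.small_stratum_policy, config.merge_map
    )
    logger.info("k=%d; %d rows in %d strata (min size %d)",
                config.k, prepared.n, partition.n_strata, partition.min_size())

    standardised, params = zscore_standardise(prepared)
    z = standardised.continuous.to_numpy()

    masked = np.empty_like(z)
    neighbour_sets: list[np.ndarray] = [np.empty(0, dtype=int)] * prepared.n
    for key, rows in partition.groups.items():
        local_sets = knn_neighbour_sets(z[rows], config.k)
        masked[rows] = centroid_replace(z[rows], local_sets)
        for local, global_row in enumerate(rows):
            neighbour_sets[global_row] = rows[local_sets[local]]

    masked_df = pd.DataFrame(masked, columns=prepared.continuous_columns)
    anonymised_cont = rescale_recentre(masked_df, params)
    anonymised = prepared.with_continuous(anonymised_cont)

    return AnonymisationResult(
        anonymised=anonymised,
        config=config,
        params=params,
        partition=partition,
        neighbour_sets=neighbour_sets,
        suppressed_rows=suppressed if suppressed.size else None,
    )
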