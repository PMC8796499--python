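"""Microdata tables with declared column roles.

A microdata table is a rectangular individual-level dataset in which every
column plays one of four roles:

``continuous``
    A numeric variable that the anonymiser is allowed to perturb.
``categorical``
    A label variable used for stratification; never perturbed.
``id``
    A direct identifier (pseudonym, record key). Carried through but excluded
    from every statistical computation, and dropped from anonymised exports
    by default.
``excluded``
    A column present in the source file but removed on load.

The container is a thin, validated wrapper around a :class:`pandas.DataFrame`
so every downstream module can rely on a single contract: column roles are
declared once, row order is stable, and missingness is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VALID_ROLES = ("continuous", "categorical", "id", "excluded")


class ColumnRoleError(ValueError):
    """A column-role declaration does not match the table."""


@dataclass
class MicrodataTable:
    """A rectangular microdata table plus its column-role declaration.

    Parameters
    ----------
    data:
        The table. Column order is preserved everywhere; the index is reset
        to a 0..n-1 positional index on construction so that row identity is
        positional and reproducible.
    roles:
        Mapping from column name to one of :data:`VALID_ROLES`. Every column
        of ``data`` must be covered; ``excluded`` columns are dropped.
    """

    data: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.roles) - set(self.data.columns)
        if unknown:
            raise ColumnRoleError(
                f"role declaration references absent column(s): {sorted(unknown)}"
            )
        missing_roles = [c for c in self.data.columns if c not in self.roles]
        if missing_roles:
            raise ColumnRoleError(f"no role declared for column(s): {missing_roles}")
        bad = {c: r for c, r in self.roles.items() if r not in VALID_ROLES}
        if bad:
            raise ColumnRoleError(f"invalid role(s): {bad}; valid roles are {VALID_ROLES}")
        keep = [c for c in self.data.columns if self.roles[c] != "excluded"]
        self.data = self.data[keep].reset_index(drop=True)
        self.roles = {c: self.roles[c] for c in keep}
        for c in self.continuous_columns:
            self.data[c] = pd.to_numeric(self.data[c], errors="raise").astype(float)
        if len(self.data) < 1:
            raise ValueError("a microdata table must have at least one row")

    # -- role views ---------------------------------------------------------

    def _cols(self, role: str) -> list[str]:
        return [c for c in self.data.columns if self.roles[c] == role]

    @property
    def continuous_columns(self) -> list[str]:
        return self._cols("continuous")

    @property
    def categorical_columns(self) -> list[str]:
        return self._cols("categorical")

    @property
    def id_columns(self) -> list[str]:
        return self._cols("id")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def continuous(self) -> pd.DataFrame:
        """The continuous block as a float frame (copy-on-write view)."""
        return self.data[self.continuous_columns]

    @property
    def categorical(self) -> pd.DataFrame:
        return self.data[self.categorical_columns]

    # -- invariants ---------------------------------------------------------

    def require_continuous(self) -> None:
        if not self.continuous_columns:
            raise ValueError(
                "the anonymisation method requires at least one continuous column"
            )

    def has_missing(self) -> bool:
        return bool(self.data[self.continuous_columns + self.categorical_columns]
                    .isna().any().any())

    def require_complete(self) -> None:
        cols = self.continuous_columns + self.categorical_columns
        bad = self.data[cols].isna().sum()
        bad = bad[bad > 0]
        if len(bad):
            raise ValueError(
                f"missing cells remain after preprocessing in: {dict(bad)}"
            )

    # -- convenience --------------------------------------------------------

    def copy(self) -> "MicrodataTable":
        return MicrodataTable(self.data.copy(), dict(self.roles))

    def with_continuous(self, values: pd.DataFrame) -> "MicrodataTable":
        """Return a copy whose continuous block is replaced by ``values``."""
        if list(values.columns) != self.continuous_columns or len(values) != self.n:
            raise ValueError("replacement continuous block has wrong shape or columns")
        out = self.data.copy()
        for c in values.columns:
            out[c] = np.asarray(values[c], dtype=float)
        return MicrodataTable(out, dict(self.roles))


def load_table(
    path: str | Path,
    roles: Mapping[str, str],
    *,
    sep: str | None = None,
    na_values: Iterable[str] | None = None,
) -> MicrodataTable:
    """Read a CSV/TSV file with a header row into a :class:`MicrodataTable`.

    The delimiter is inferred from the file extension (``.tsv`` → tab)
    unless ``sep`` is given. Missing cells (empty fields, NA/NaN markers)
    are recorded as NaN and handled later by the imputation step.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, na_values=na_values, keep_default_na=True)
    return MicrodataTable(df, dict(roles))


def save_table(
    table: MicrodataTable,
    path: str | Path,
    *,
    include_ids: bool = False,
) -> None:
    """Write a table as RFC-4180 CSV (UTF-8, header row).

    Floats are serialised with ``repr`` (shortest round-trip representation),
    so a write/read cycle preserves values bit-for-bit and the determinism
    guarantee of the anonymiser survives file I/O. Identifier columns are
    omitted unless ``include_ids`` is set: they are direct identifiers and
    have no place in a released file.
    """
    cols = [c for c in table.data.columns
            if include_ids or table.roles[c] != "id"]
    table.data[cols].to_csv(path, index=False)
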