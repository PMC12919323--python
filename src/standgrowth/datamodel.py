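"""Inventory data model, CSV I/O and reproducible random partitions.

The universal container is :class:`InventoryTable`, a thin wrapper around a
pandas DataFrame with canonical columns ``species, dbh_cm, height_m, age_yr``
plus any number of per-plot environmental covariate columns (elevation,
precipitation, temperature indices, ...).  Rows with missing or non-positive
DBH, height or age are dropped at read time and counted in an audit rather
than raising: survey tables routinely contain incomplete plots.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyDataError, SchemaError

#: canonical column names for the three core measurements
CORE_COLUMNS = ("species", "dbh_cm", "height_m", "age_yr")

#: default mapping canonical name -> file column name (identity)
DEFAULT_SCHEMA = {c: c for c in CORE_COLUMNS}


@dataclass
class InventoryTable:
    """Plot-level inventory records for one or more species.

    Parameters
    ----------
    df : pandas.DataFrame
        Must contain the four core columns; any further numeric columns are
        treated as per-plot covariates unless listed in ``extra_columns``.
    covariates : list of str, optional
        Names of covariate columns.  Defaults to every non-core column.
    """

    df: pd.DataFrame
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self):
        missing = [c for c in CORE_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing core columns: {missing}")
        if not self.covariates:
            self.covariates = [c for c in self.df.columns if c not in CORE_COLUMNS]
        self.df = self.df.reset_index(drop=True)

    def __len__(self):
        return len(self.df)

    @property
    def species(self) -> list[str]:
        return list(pd.unique(self.df["species"]))

    def subset(self, species: str) -> "InventoryTable":
        """Rows for one species, matched case-insensitively."""
        mask = self.df["species"].str.lower() == species.lower()
        return InventoryTable(self.df[mask].copy(), list(self.covariates))

    def column(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy(dtype=float)


@dataclass(frozen=True)
class SplitSpec:
    """Specification of a seeded random partition.

    fractions must be positive and sum to 1 (e.g. ``(0.7, 0.3)`` for a
    modelling/validation split or ``(0.70, 0.15, 0.15)`` for
    train/validation/test).  The same seed and input always produce the
    identical partition.
    """

    fractions: tuple[float, ...] = (0.7, 0.3)
    seed: int = 0
    stratify_by_species: bool = False

    def __post_init__(self):
        if any(f <= 0 for f in self.fractions):
            raise ValueError("every fraction must be > 0")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def read_inventory(path, schema=None, covariates=None):
    """Read a plot-inventory CSV.

    Parameters
    ----------
    path : str or file-like
    schema : dict, optional
        Mapping canonical name -> column name in the file, for the four core
        columns.  Unmapped canonical names default to themselves.
    covariates : list of str, optional
        Covariate columns to retain (file names).  Default: every remaining
        numeric column.

    Returns
    -------
    (InventoryTable, dict)
        The table plus an audit dict with the number of rows dropped for
        missing or non-positive core values.
    """
    raw = pd.read_csv(path)
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    for canonical, actual in colmap.items():
        if actual not in raw.columns:
            raise SchemaError(f"required column not found: {actual!r}")
    df = raw.rename(columns={v: k for k, v in colmap.items()})
    if covariates is None:
        covariates = [
            c for c in df.columns
            if c not in CORE_COLUMNS and pd.api.types.is_numeric_dtype(df[c])
        ]
    df = df[list(CORE_COLUMNS) + list(covariates)].copy()
    for c in ("dbh_cm", "height_m", "age_yr"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    n_before = len(df)
    keep = (
        df["dbh_cm"].gt(0) & df["height_m"].gt(0) & df["age_yr"].gt(0)
    ).fillna(False)
    df = df[keep].reset_index(drop=True)
    audit = {"n_read": n_before, "n_kept": len(df), "n_dropped": n_before - len(df)}
    if len(df) == 0:
        raise EmptyDataError("no valid records after filtering")
    return InventoryTable(df, list(covariates)), audit


def write_inventory(table: InventoryTable, path) -> None:
    """Write the table back to CSV (header row, UTF-8, '.' decimal)."""
    table.df.to_csv(path, index=False)


def write_audit(audit: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(audit, fh, indent=2)


def _largest_remainder_sizes(n: int, fractions) -> list[int]:
    """Integer partition sizes that sum exactly to n.

    Each size starts at floor(f*n); leftover units go to the largest
    fractional remainders (ties to the earlier fraction).
    """
    exact = [f * n for f in fractions]
    sizes = [int(np.floor(e)) for e in exact]
    remainders = [e - s for e, s in zip(exact, sizes)]
    for _ in range(n - sum(sizes)):
        i = int(np.argmax(remainders))
        sizes[i] += 1
        remainders[i] = -1.0
    return sizes


def split_table(table: InventoryTable, spec: SplitSpec) -> list[InventoryTable]:
    """Randomly partition a table into disjoint sub-tables.

    Partition sizes follow largest-remainder rounding so they always sum to
    ``len(table)``; with ``stratify_by_species`` the rounding is applied
    within each species and the per-species parts concatenated.
    """
    if len(table) == 0:
        raise EmptyDataError("cannot split an empty table")
    rng = np.random.default_rng(spec.seed)
    parts_idx: list[list[int]] = [[] for _ in spec.fractions]
    if spec.stratify_by_species:
        groups = [
            table.df.index[table.df["species"] == s].to_numpy()
            for s in sorted(table.df["species"].unique())
        ]
    else:
        groups = [table.df.index.to_numpy()]
    for idx in groups:
        perm = rng.permutation(idx)
        sizes = _largest_remainder_sizes(len(perm), spec.fractions)
        start = 0
        for k, size in enumerate(sizes):
            parts_idx[k].extend(perm[start:start + size].tolist())
            start += size
    out = []
    for k, ids in enumerate(parts_idx):
        if not ids:
            warnings.warn(
                f"partition {k} (fraction {spec.fractions[k]}) is empty for "
                f"n={len(table)}", UserWarning, stacklevel=2,
            )
        sub = table.df.loc[sorted(ids)].reset_index(drop=True)
        out.append(InventoryTable(sub, list(table.covariates)))
    return out
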