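"""Data model, validation and tabular I/O for core-break root-count datasets.

The core-break method extracts a soil core from a field plot, breaks it at
regular depth increments, and counts the roots exposed on each pair of break
faces.  A dataset is a long table with one record per
(genotype, block, core, depth) cell holding a non-negative integer root count.
Depth is stored as the 1-based segment index ``t``; the physical depth of
segment ``t`` is ``t * depth_increment_cm``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "COLUMNS",
    "DesignConfig",
    "CoreBreakDataset",
    "CompletenessReport",
    "SchemaError",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "completeness_report",
]

#: Canonical column order of the on-disk CSV dialect.
COLUMNS = ("genotype", "block", "core", "depth", "count")


class SchemaError(ValueError):
    """A table is missing required columns or has an unusable layout."""


class ValidationError(ValueError):
    """A table violates a dataset invariant (bounds, sign, duplicates)."""


@dataclass(frozen=True)
class DesignConfig:
    """Field-trial design: how many genotypes, blocks, cores and depths.

    Defaults match a 20-genotype trial with 4 replicate blocks, 4 soil cores
    per plot, and 18 depth segments of 10 cm (so the grid reaches 180 cm).
    """

    n_genotypes: int = 20
    n_blocks: int = 4
    n_cores: int = 4
    n_depths: int = 18
    depth_increment_cm: float = 10.0

    def __post_init__(self) -> None:
        for name in ("n_genotypes", "n_blocks", "n_cores", "n_depths"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValidationError(f"{name} must be an integer >= 1, got {v!r}")
        if self.depth_increment_cm <= 0:
            raise ValidationError("depth_increment_cm must be > 0")

    @property
    def n_records(self) -> int:
        """Number of records in a complete dataset."""
        return self.n_genotypes * self.n_blocks * self.n_cores * self.n_depths

    @property
    def depth_indices(self) -> np.ndarray:
        """The 1-based depth indices ``t = 1..n_depths``."""
        return np.arange(1, self.n_depths + 1)

    @property
    def depth_cm(self) -> np.ndarray:
        """Physical depth (cm) of each segment midline, ``t * increment``."""
        return self.depth_indices * self.depth_increment_cm

    @classmethod
    def from_mapping(cls, mapping: dict) -> "DesignConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise SchemaError(f"unknown design keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_file(cls, path) -> "DesignConfig":
        """Load from a plain key/value (YAML-compatible) config file."""
        with open(path) as fh:
            mapping = yaml.safe_load(fh) or {}
        if not isinstance(mapping, dict):
            raise SchemaError(f"design config {path} is not a key/value mapping")
        return cls.from_mapping(mapping)

    def replace(self, **kwargs) -> "DesignConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _validate_table(df: pd.DataFrame, design: DesignConfig | None) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = df.loc[:, list(COLUMNS)].copy()

    for col in COLUMNS:
        vals = df[col]
        if col == "count":
            as_float = pd.to_numeric(vals, errors="coerce")
            bad = as_float.isna() | (as_float != np.floor(as_float)) | (as_float < 0)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"count must be a non-negative integer; offending row {row}: "
                    f"{df.iloc[row].to_dict()}"
                )
            df[col] = as_float.astype(np.int64)
        else:
            as_float = pd.to_numeric(vals, errors="coerce")
            bad = as_float.isna() | (as_float != np.floor(as_float)) | (as_float < 1)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"{col} must be a 1-based integer index; offending row {row}: "
                    f"{df.iloc[row].to_dict()}"
                )
            df[col] = as_float.astype(np.int64)

    if design is not None:
        bounds = {
            "genotype": design.n_genotypes,
            "block": design.n_blocks,
            "core": design.n_cores,
            "depth": design.n_depths,
        }
        for col, upper in bounds.items():
            over = df[col] > upper
            if over.any():
                row = int(np.flatnonzero(over.to_numpy())[0])
                raise ValidationError(
                    f"{col} index exceeds design bound {upper}; offending row "
                    f"{row}: {df.iloc[row].to_dict()}"
                )

    dup = df.duplicated(subset=["genotype", "block", "core", "depth"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"duplicate (genotype, block, core, depth) cell at row {row}: "
            f"{df.iloc[row].to_dict()}"
        )

    return df.sort_values(list(COLUMNS[:4]), kind="mergesort").reset_index(drop=True)


@dataclass(frozen=True)
class CoreBreakDataset:
    """A validated long table of core-break counts, sorted by (i, j, k, t)."""

    table: pd.DataFrame = field(repr=False)
    design: DesignConfig | None = None

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, design: DesignConfig | None = None
    ) -> "CoreBreakDataset":
        return cls(table=_validate_table(df, design), design=design)

    @classmethod
    def from_records(cls, records, design: DesignConfig | None = None) -> "CoreBreakDataset":
        """Build from an iterable of (genotype, block, core, depth, count) tuples."""
        df = pd.DataFrame(list(records), columns=list(COLUMNS))
        return cls.from_dataframe(df, design)

    def __len__(self) -> int:
        return len(self.table)

    def to_dataframe(self, depth_cm: bool = False) -> pd.DataFrame:
        """Copy of the long table; optionally append a derived depth_cm column."""
        df = self.table.copy()
        if depth_cm:
            inc = self.design.depth_increment_cm if self.design is not None else 10.0
            df["depth_cm"] = df["depth"] * inc
        return df

    @property
    def counts(self) -> np.ndarray:
        return self.table["count"].to_numpy()

    def record_set(self) -> set:
        return set(map(tuple, self.table.itertuples(index=False)))


def read_dataset(path, design: DesignConfig | None = None) -> CoreBreakDataset:
    """Read a comma-separated core-break table and validate it.

    The file must carry a header with columns
    ``genotype,block,core,depth,count`` (extra columns are ignored).
    """
    df = pd.read_csv(path)
    return CoreBreakDataset.from_dataframe(df, design)


def write_dataset(data: CoreBreakDataset, path) -> None:
    """Write the dataset as CSV with stable column order and row sort."""
    data.table.to_csv(path, index=False, columns=list(COLUMNS))


@dataclass(frozen=True)
class CompletenessReport:
    """Record-count bookkeeping against a target design."""

    per_genotype: pd.Series
    per_depth: pd.Series
    missing_cells: list
    expected_per_genotype: int
    expected_per_depth: int

    @property
    def is_complete(self) -> bool:
        return not self.missing_cells

    def __str__(self) -> str:  # human-readable report
        buf = io.StringIO()
        buf.write("records per genotype (expected "
                  f"{self.expected_per_genotype}):\n")
        buf.write(self.per_genotype.to_string())
        buf.write("\nrecords per depth (expected "
                  f"{self.expected_per_depth}):\n")
        buf.write(self.per_depth.to_string())
        if self.missing_cells:
            buf.write(f"\nmissing cells ({len(self.missing_cells)}):\n")
            for cell in self.missing_cells[:50]:
                buf.write(f"  genotype={cell[0]} block={cell[1]} "
                          f"core={cell[2]} depth={cell[3]}\n")
            if len(self.missing_cells) > 50:
                buf.write(f"  ... and {len(self.missing_cells) - 50} more\n")
        else:
            buf.write("\ndataset is complete\n")
        return buf.getvalue()


def completeness_report(
    data: CoreBreakDataset, design: DesignConfig
) -> CompletenessReport:
    """Per-genotype and per-depth record counts plus the list of missing cells.

    For a complete design every genotype carries ``n_blocks * n_cores *
    n_depths`` records and every depth index ``n_blocks * n_cores *
    n_genotypes`` records.
    """
    df = data.table
    per_genotype = (
        df.groupby("genotype").size()
        .reindex(range(1, design.n_genotypes + 1), fill_value=0)
        .rename("n_records")
    )
    per_depth = (
        df.groupby("depth").size()
        .reindex(range(1, design.n_depths + 1), fill_value=0)
        .rename("n_records")
    )
    present = data.record_set()
    present_cells = {rec[:4] for rec in present}
    missing = [
        (i, j, k, t)
        for i in range(1, design.n_genotypes + 1)
        for j in range(1, design.n_blocks + 1)
        for k in range(1, design.n_cores + 1)
        for t in range(1, design.n_depths + 1)
        if (i, j, k, t) not in present_cells
    ]
    return CompletenessReport(
        per_genotype=per_genotype,
        per_depth=per_depth,
        missing_cells=missing,
        expected_per_genotype=design.n_blocks * design.n_cores * design.n_depths,
        expected_per_depth=design.n_blocks * design.n_cores * design.n_genotypes,
    )
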