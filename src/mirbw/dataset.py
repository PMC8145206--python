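"""Core containers: wavenumber grid, spectral datasets, delimited-text I/O.

A dataset is one table with a row per milking-test record. Meta columns hold
identifiers and covariates (herd, cow, parity, days in milk, milk yield,
bodyweight); the remaining columns are spectral absorbance values named
``wn_<wavenumber>`` on a shared grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: meta (non-spectral) columns, in canonical order
META_COLUMNS = [
    "record_id",
    "herd_id",
    "cow_id",
    "parity",
    "parity_class",
    "dim",
    "my",
    "bw",
]

#: covariate feature identifiers usable alongside spectral columns
COVARIATE_FEATURES = ["parity_class", "dim", "my"]

# canonical mid-infrared window shared by common milk spectrometers
CANONICAL_START = 925.66
CANONICAL_END = 3995.78
CANONICAL_N_POINTS = 797


def spectral_name(wavenumber: float) -> str:
    """Column name for a spectral point (wavenumber printed to 2 decimals)."""
    return f"wn_{wavenumber:.2f}"


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform grid of wavenumbers (cm^-1), strictly increasing."""

    start: float
    end: float
    n_points: int
    values: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.n_points < 2:
            raise ValueError("grid needs at least 2 points")
        if not self.end > self.start:
            raise ValueError("grid end must exceed start")
        if self.values is None:
            object.__setattr__(
                self, "values", np.linspace(self.start, self.end, self.n_points)
            )
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.n_points,):
            raise ValueError("values length mismatch")
        steps = np.diff(vals)
        if np.any(steps <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.ptp(steps) > 1e-6:
            raise ValueError("grid spacing must be uniform within 1e-6 cm^-1")

    @property
    def step(self) -> float:
        return (self.end - self.start) / (self.n_points - 1)

    def column_names(self) -> list[str]:
        return [spectral_name(v) for v in self.values]

    def __len__(self) -> int:
        return self.n_points

    def __eq__(self, other) -> bool:  # value semantics
        return (
            isinstance(other, WavenumberGrid)
            and self.n_points == other.n_points
            and abs(self.start - other.start) < 1e-9
            and abs(self.end - other.end) < 1e-9
        )


def make_canonical_grid() -> WavenumberGrid:
    """The 797-point grid from 925.66 to 3995.78 cm^-1 shared across
    Foss, PerkinElmer and Bentley instruments."""
    return WavenumberGrid(CANONICAL_START, CANONICAL_END, CANONICAL_N_POINTS)


def parity_class(parity: int) -> int:
    """Pool lactation number into classes 1, 2, 3, 4 (4 = fourth or later).

    Holsteins approach mature weight around the fourth lactation, so parities
    of four and above share one class.
    """
    parity = int(parity)
    if parity < 1:
        raise ValueError(f"parity must be >= 1, got {parity}")
    return min(parity, 4)


@dataclass
class Dataset:
    """Spectral records plus covariates, all rows sharing one grid.

    ``grid`` is None after region subsetting (the retained points are no
    longer uniformly spaced); spectral identity then lives in column names.
    ``stage_tag`` tracks provenance: raw -> derived -> cleaned -> scaled.
    """

    df: pd.DataFrame
    grid: WavenumberGrid | None
    stage_tag: str = "raw"

    def __post_init__(self):
        missing = [c for c in META_COLUMNS if c not in self.df.columns and c != "bw"]
        if missing:
            raise ValueError(f"missing meta columns: {missing}")
        if "bw" not in self.df.columns:
            self.df = self.df.assign(bw=np.nan)
        if self.df["record_id"].duplicated().any():
            raise ValueError("record_id values must be unique")
        if self.grid is not None:
            expected = self.grid.column_names()
            if self.spectral_columns != expected:
                raise ValueError("spectral columns do not match the grid")

    @property
    def spectral_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("wn_")]

    @property
    def feature_columns(self) -> list[str]:
        """All candidate predictors: spectral points plus parity class,
        days in milk and milk yield."""
        return self.spectral_columns + COVARIATE_FEATURES

    @property
    def n_records(self) -> int:
        return len(self.df)

    def spectra(self) -> np.ndarray:
        return self.df[self.spectral_columns].to_numpy(dtype=float)

    def feature_matrix(self, feature_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = list(feature_ids) if feature_ids is not None else self.feature_columns
        unknown = [f for f in ids if f not in self.df.columns]
        if unknown:
            raise KeyError(f"unknown features: {unknown[:5]}")
        return self.df[ids].to_numpy(dtype=float)

    def bw(self) -> np.ndarray:
        y = self.df["bw"].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError("bodyweight missing for some records")
        return y

    def subset_records(self, mask_or_ids) -> "Dataset":
        if isinstance(mask_or_ids, (pd.Series, np.ndarray)) and np.asarray(
            mask_or_ids
        ).dtype == bool:
            sub = self.df.loc[np.asarray(mask_or_ids)]
        else:
            sub = self.df[self.df["record_id"].isin(list(mask_or_ids))]
        return Dataset(sub.reset_index(drop=True).copy(), self.grid, self.stage_tag)

    def copy(self) -> "Dataset":
        return Dataset(self.df.copy(), self.grid, self.stage_tag)

    def with_stage(self, tag: str) -> "Dataset":
        return Dataset(self.df, self.grid, tag)


def write_csv(dataset: Dataset, path) -> None:
    """Write the canonical delimited format (full float precision)."""
    cols = [c for c in META_COLUMNS if c in dataset.df.columns]
    cols += dataset.spectral_columns
    out = dataset.df[cols]
    out.to_csv(path, index=False, float_format="%.17g")


def read_csv(path, stage_tag: str = "raw") -> Dataset:
    """Read the canonical format; the grid is inferred from wn_ headers.

    Header wavenumbers are printed to 2 decimals, so the grid is rebuilt as a
    uniform grid spanning the first and last header values and each header is
    checked against it to 0.01 cm^-1; a mismatch is a hard error.
    """
    df = pd.read_csv(path)
    wn_cols = [c for c in df.columns if c.startswith("wn_")]
    if not wn_cols:
        raise ValueError("no spectral wn_ columns found")
    header_vals = np.array([float(c[3:]) for c in wn_cols])
    grid = None
    if len(wn_cols) >= 2:
        candidate = np.linspace(header_vals[0], header_vals[-1], len(wn_cols))
        if np.max(np.abs(candidate - header_vals)) <= 0.011:
            grid = WavenumberGrid(header_vals[0], header_vals[-1], len(wn_cols))
            # re-name columns onto the reconstructed grid for exact matching
            df = df.rename(columns=dict(zip(wn_cols, grid.column_names())))
        else:
            raise ValueError("wn_ headers are not a uniform grid")
    if "parity_class" not in df.columns:
        df["parity_class"] = df["parity"].map(parity_class)
    return Dataset(df, grid, stage_tag)
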