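"""Spectral preprocessing: gap first derivative, region subsetting, scaling.

The derivative flattens baseline drift; region subsetting restricts to the
windows known to carry milk-composition information; centering/scaling puts
every predictor on the same footing before PLS modeling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import COVARIATE_FEATURES, Dataset, WavenumberGrid

#: expert preselection windows (cm^-1): the milk-composition-relevant regions
HSO_INTERVALS = [(950.0, 1600.0), (1750.0, 1800.0), (2600.0, 3000.0)]


def first_derivative(dataset: Dataset, gap: int = 5) -> Dataset:
    """Gap-difference first derivative: d_i = x_{i+gap} - x_i.

    The output keeps the first ``n - gap`` wavenumbers (left-anchored) and is
    tagged ``derived``. Covariates and bodyweight pass through unchanged.
    """
    if dataset.grid is None:
        raise ValueError("derivative requires a uniform grid")
    n = dataset.grid.n_points
    if gap < 1 or gap >= n:
        raise ValueError(f"gap must be in [1, {n - 1}]")
    spectra = dataset.spectra()
    deriv = spectra[:, gap:] - spectra[:, :-gap]
    new_grid = WavenumberGrid(
        dataset.grid.start,
        float(dataset.grid.values[n - gap - 1]),
        n - gap,
    )
    meta = dataset.df.drop(columns=dataset.spectral_columns)
    out = pd.concat(
        [
            meta.reset_index(drop=True),
            pd.DataFrame(deriv, columns=new_grid.column_names()),
        ],
        axis=1,
    )
    return Dataset(out, new_grid, "derived")


def select_regions(
    dataset: Dataset, intervals: Sequence[tuple[float, float]]
) -> Dataset:
    """Keep grid points whose wavenumber lies in the closed union of intervals.

    Column names (original wavenumbers) are retained so feature identity
    survives subsetting; the result no longer carries a uniform grid.
    """
    for lo, hi in intervals:
        if not lo < hi:
            raise ValueError(f"invalid interval ({lo}, {hi})")
    cols = dataset.spectral_columns
    wavenumbers = np.array([float(c[3:]) for c in cols])
    keep = np.zeros(len(cols), dtype=bool)
    for lo, hi in intervals:
        keep |= (wavenumbers >= lo) & (wavenumbers <= hi)
    if not keep.any():
        raise ValueError("empty selection: no grid point falls in the intervals")
    kept_cols = [c for c, k in zip(cols, keep) if k]
    meta = dataset.df.drop(columns=cols)
    out = pd.concat([meta, dataset.df[kept_cols]], axis=1)
    return Dataset(out, None, dataset.stage_tag)


@dataclass(frozen=True)
class ScaleTransform:
    """Frozen centering/scaling fitted on training data only."""

    feature_ids: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self):
        if not (len(self.feature_ids) == len(self.means) == len(self.sds)):
            raise ValueError("length mismatch")
        if np.any(self.sds <= 0):
            raise ValueError("standard deviations must be strictly positive")

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.means) / self.sds


def fit_scale(dataset: Dataset, feature_ids: Sequence[str] | None = None) -> ScaleTransform:
    """Per-feature mean and sample standard deviation (n-1 denominator)."""
    ids = list(feature_ids) if feature_ids is not None else dataset.feature_columns
    if dataset.n_records < 2:
        raise ValueError("need at least 2 records to fit a scale")
    X = dataset.feature_matrix(ids)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(sds == 0)
    if dead.size:
        raise ValueError(f"zero-variance feature(s): {[ids[i] for i in dead[:5]]}")
    return ScaleTransform(tuple(ids), means, sds)


def apply_scale(transform: ScaleTransform, dataset: Dataset) -> Dataset:
    """Return a copy with the transform's features standardized in place.

    Covariate features are overwritten in the copy; the ``scaled`` stage tag
    marks that those columns are no longer in physical units.
    """
    missing = [f for f in transform.feature_ids if f not in dataset.df.columns]
    if missing:
        raise KeyError(f"features absent from dataset: {missing[:5]}")
    out = dataset.df.copy()
    ids = list(transform.feature_ids)
    out[ids] = transform.transform(dataset.feature_matrix(ids))
    return Dataset(out, dataset.grid, "scaled")
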