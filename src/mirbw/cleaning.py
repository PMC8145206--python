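"""Record cleaning: parity-specific BW ranges, GH spectral distance filter,
and iterative PLS-residual outlier removal.

The three stages run in a fixed order (BW range -> GH -> residual); each
record is removed at most once and the composite report keeps the removal
ids per stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset import Dataset
from .pls import fit_pls, predict
from .preprocess import apply_scale, fit_scale
from .simulate import DEFAULT_BW_INTERVALS

log = logging.getLogger(__name__)

#: parity-class (1..4+) bodyweight intervals in kg, treated as closed ranges
ParityBwIntervals = dict


@dataclass
class CleaningReport:
    n_input: int
    removed_bw_range: list[str] = field(default_factory=list)
    removed_gh: list[str] = field(default_factory=list)
    removed_residual: list[list[str]] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return len(self.removed_residual)

    @property
    def n_removed(self) -> int:
        return (
            len(self.removed_bw_range)
            + len(self.removed_gh)
            + sum(len(it) for it in self.removed_residual)
        )

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_removed

    @property
    def fraction_removed(self) -> float:
        return (self.n_input - self.n_output) / self.n_input

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_output": self.n_output,
                "n_iterations": self.n_iterations,
                "fraction_removed": self.fraction_removed,
                "removed_bw_range": self.removed_bw_range,
                "removed_gh": self.removed_gh,
                "removed_residual": self.removed_residual,
            }
        )


def removal_fraction(n_input: int, n_output: int) -> float:
    """Share of records deleted by cleaning, e.g. 1915 -> 1849 gives 0.0345."""
    if n_output > n_input or n_input <= 0:
        raise ValueError("need 0 < n_output <= n_input")
    return (n_input - n_output) / n_input


def bw_range_filter(
    dataset: Dataset, intervals: ParityBwIntervals = DEFAULT_BW_INTERVALS
) -> tuple[Dataset, list[str]]:
    """Keep records whose BW lies in the closed interval for their parity
    class; return the removed record ids."""
    df = dataset.df
    if df["bw"].isna().any():
        raise ValueError("bodyweight missing for some records")
    lo = df["parity_class"].map(lambda c: intervals[int(c)][0])
    hi = df["parity_class"].map(lambda c: intervals[int(c)][1])
    keep = (df["bw"] >= lo) & (df["bw"] <= hi)
    removed = df.loc[~keep, "record_id"].tolist()
    log.info("bw_range_filter removed %d/%d records: %s", len(removed), len(df), removed)
    return dataset.subset_records(keep.to_numpy()), removed


def gh_scores(spectra: np.ndarray, var_explained: float = 0.99) -> np.ndarray:
    """Global H distance: squared standardized PCA-score distance averaged
    over the components explaining ``var_explained`` of the variance.

    GH_i = (1/k) * sum_a t_ia^2 / lambda_a  with lambda_a the score variance.
    """
    X = np.asarray(spectra, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 records for the GH filter")
    Xc = X - X.mean(axis=0)
    # covariance-scaled PCA via SVD of the centered matrix
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    ev = s**2 / (n - 1)
    total = ev.sum()
    if total <= 0:
        raise ValueError("degenerate variance: all spectra identical")
    cum = np.cumsum(ev) / total
    k = int(np.searchsorted(cum, var_explained) + 1)
    k = min(k, np.count_nonzero(ev > 1e-12 * ev[0]))
    if k == 0:
        raise ValueError("degenerate variance: no retained component")
    scores = Xc @ Vt[:k].T  # (n, k)
    return (scores**2 / ev[:k]).mean(axis=1)


def gh_filter(
    dataset: Dataset, var_explained: float = 0.99, threshold: float = 3.0
) -> tuple[Dataset, list[str]]:
    """Drop records with GH distance above ``threshold`` (default 3)."""
    gh = gh_scores(dataset.spectra(), var_explained)
    keep = gh <= threshold
    removed = dataset.df.loc[~keep, "record_id"].tolist()
    log.info("gh_filter removed %d/%d records: %s", len(removed), len(dataset.df), removed)
    return dataset.subset_records(keep), removed


def iterative_residual_clean(
    dataset: Dataset,
    n_components: int = 10,
    sd_threshold: float = 3.0,
    report: CleaningReport | None = None,
) -> tuple[Dataset, CleaningReport]:
    """Repeatedly fit PLS(BW ~ all predictors) and drop records whose
    residual deviates from the mean residual by more than ``sd_threshold``
    standard deviations; stop when an iteration removes nothing."""
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    rep = report or CleaningReport(n_input=dataset.n_records)
    current = dataset
    while True:
        n = current.n_records
        A = min(n_components, len(current.feature_columns), n - 2)
        if n <= A + 1 or A < 1:
            raise ValueError("dataset shrank below the minimum fit size")
        scale = fit_scale(current)
        scaled = apply_scale(scale, current)
        X = scaled.feature_matrix()
        y = current.bw()
        model = fit_pls(X, y, A, feature_ids=current.feature_columns)
        resid = y - predict(model, X)
        dev = np.abs(resid - resid.mean())
        cut = sd_threshold * resid.std(ddof=1)
        keep = dev <= cut
        removed = current.df.loc[~keep, "record_id"].tolist()
        rep.removed_residual.append(removed)
        log.info(
            "residual_clean iteration %d removed %d/%d records",
            rep.n_iterations,
            len(removed),
            n,
        )
        if not removed:
            break
        current = current.subset_records(keep)
    return current.with_stage("cleaned"), rep


def clean_dataset(
    dataset: Dataset,
    intervals: ParityBwIntervals = DEFAULT_BW_INTERVALS,
    var_explained: float = 0.99,
    gh_threshold: float = 3.0,
    n_components: int = 10,
    sd_threshold: float = 3.0,
) -> tuple[Dataset, CleaningReport]:
    """The full three-stage cleaning: BW range -> GH -> residual analysis."""
    report = CleaningReport(n_input=dataset.n_records)
    ds, report.removed_bw_range = bw_range_filter(dataset, intervals)
    ds, report.removed_gh = gh_filter(ds, var_explained, gh_threshold)
    ds, report = iterative_residual_clean(ds, n_components, sd_threshold, report)
    return ds, report
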