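"""Validation designs: BW-stratified folds, herd-disjoint repeated
partitions, PLS-factor selection, finalization and external validation.

Stratified 10-fold cross-validation balances bodyweight across folds but
lets herds straddle the split, so a separate herd-independent design (no
herd on both sides, validation share of records between 10 and 30%,
repeated many times) measures transferability to unseen herds.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import Dataset
from .pls import PlsModel, fit_pls, predict, predict_path, r2, rmse
from .preprocess import ScaleTransform, apply_scale, fit_scale

log = logging.getLogger(__name__)


@dataclass
class Strata:
    """Quartile-based bodyweight strata: (min,Q1], (Q1,median], (median,Q3],
    (Q3,max]; the minimum itself goes to the first stratum."""

    boundaries: np.ndarray  # (5,): min, Q1, median, Q3, max
    labels: np.ndarray  # per-record stratum in {0,1,2,3}


def make_strata(bw: np.ndarray) -> Strata:
    bw = np.asarray(bw, dtype=float)
    if np.unique(bw).size < 4:
        raise ValueError("need at least 4 distinct BW values to stratify")
    bounds = np.quantile(bw, [0.0, 0.25, 0.5, 0.75, 1.0])  # linear interpolation
    labels = np.digitize(bw, bounds[1:4], right=True)
    return Strata(boundaries=bounds, labels=labels)


def stratified_kfold(strata: Strata, k: int = 10, seed: int = 0) -> np.ndarray:
    """Fold labels 0..k-1: records shuffled within each stratum and dealt
    round-robin, so per-stratum fold counts differ by at most one."""
    rng = np.random.default_rng(seed)
    n = strata.labels.size
    folds = np.empty(n, dtype=int)
    for s in np.unique(strata.labels):
        idx = np.flatnonzero(strata.labels == s)
        if idx.size < k:
            warnings.warn(f"stratum {s} has {idx.size} < {k} records", stacklevel=2)
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


@dataclass
class PartitionScheme:
    """Herd-disjoint repeated train/validation splits."""

    repeats: list[tuple[frozenset, frozenset]]  # (train_herds, validation_herds)
    fraction_range: tuple[float, float]
    seed: int

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)


def herd_partitions(
    herd_sizes: dict,
    fraction_range: tuple[float, float] = (0.10, 0.30),
    n_repeats: int = 101,
    seed: int = 0,
) -> PartitionScheme:
    """Sample ``n_repeats`` herd subsets (validation side) whose record share
    lies in the closed fraction range; without replacement when enough
    feasible subsets exist, with replacement (and a warning) otherwise."""
    herds = sorted(herd_sizes)
    total = sum(herd_sizes.values())
    lo, hi = fraction_range
    feasible = []
    for r in range(1, len(herds)):
        for combo in itertools.combinations(herds, r):
            frac = sum(herd_sizes[h] for h in combo) / total
            if lo <= frac <= hi:
                feasible.append(frozenset(combo))
    if not feasible:
        raise ValueError("no herd subset satisfies the validation fraction range")
    rng = np.random.default_rng(seed)
    if len(feasible) >= n_repeats:
        picks = rng.choice(len(feasible), size=n_repeats, replace=False)
    else:
        warnings.warn(
            f"only {len(feasible)} feasible subsets for {n_repeats} repeats; "
            "sampling with replacement",
            stacklevel=2,
        )
        picks = rng.choice(len(feasible), size=n_repeats, replace=True)
    all_herds = frozenset(herds)
    repeats = [(all_herds - feasible[i], feasible[i]) for i in picks]
    return PartitionScheme(repeats=repeats, fraction_range=fraction_range, seed=seed)


@dataclass
class EvaluationSummary:
    family_tag: str
    feature_ids: list[str]
    n_components: int
    rmse_iv_mean: float
    rmse_iv_sd: float
    rmse_scv_mean: float = np.nan
    rmse_scv_sd: float = np.nan
    r2_scv: float = np.nan
    rmse_v: float = np.nan
    tolerance: int | None = None

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


def cv_rmse_path(
    X: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    max_components: int,
) -> np.ndarray:
    """Cross-validated RMSE for every component count: (A_max, k) array of
    per-fold RMSE along the PLS component path. Scaling is refit on each
    training side."""
    ks = np.unique(folds)
    A_max = max_components
    out = np.full((A_max, ks.size), np.nan)
    for j, f in enumerate(ks):
        tr = folds != f
        te = ~tr
        Xtr, ytr = X[tr], y[tr]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        A = min(A_max, Xtr.shape[1], Xtr.shape[0] - 1)
        model = fit_pls((Xtr - mu) / sd, ytr, A)
        preds = predict_path(model, (X[te] - mu) / sd)  # (A_fit, n_te)
        err = preds - y[te][None, :]
        out[: model.n_components, j] = np.sqrt((err**2).mean(axis=1))
    return out


def evaluate_scv(
    dataset: Dataset,
    feature_ids: list[str],
    strata: Strata,
    n_components: int,
    k: int = 10,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Stratified k-fold CV at a fixed component count: (rmse mean, rmse sd
    over folds, pooled R^2)."""
    X = dataset.feature_matrix(feature_ids)
    y = dataset.bw()
    folds = stratified_kfold(strata, k=k, seed=seed)
    per_fold = []
    pooled = np.empty_like(y)
    for f in np.unique(folds):
        tr = folds != f
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        A = min(n_components, X.shape[1], tr.sum() - 1)
        model = fit_pls((X[tr] - mu) / sd, y[tr], A)
        yh = predict(model, (X[~tr] - mu) / sd)
        pooled[~tr] = yh
        per_fold.append(rmse(y[~tr], yh))
    per_fold = np.array(per_fold)
    return float(per_fold.mean()), float(per_fold.std(ddof=1)), r2(y, pooled)


def evaluate_iv(
    dataset: Dataset,
    feature_ids: list[str],
    scheme: PartitionScheme,
    max_components: int = 10,
    family_tag: str = "",
) -> EvaluationSummary:
    """Herd-independent repeated validation; the optimal number of PLS
    factors minimizes the mean validation RMSE across repeats (ties to the
    smaller count)."""
    X = dataset.feature_matrix(feature_ids)
    y = dataset.bw()
    herd = dataset.df["herd_id"].to_numpy()
    A_max = max_components
    per_repeat = np.full((A_max, scheme.n_repeats), np.nan)
    for rix, (train_h, valid_h) in enumerate(scheme.repeats):
        tr = np.isin(herd, list(train_h))
        te = ~tr
        if tr.sum() < 3 or te.sum() < 1:
            warnings.warn(f"repeat {rix} too small; skipped", stacklevel=2)
            continue
        Xtr = X[tr]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        A = min(A_max, Xtr.shape[1], Xtr.shape[0] - 1)
        if A < 1:
            warnings.warn(f"repeat {rix} smaller than the model; skipped", stacklevel=2)
            continue
        model = fit_pls((Xtr - mu) / sd, y[tr], A)
        preds = predict_path(model, (X[te] - mu) / sd)
        err = preds - y[te][None, :]
        per_repeat[: model.n_components, rix] = np.sqrt((err**2).mean(axis=1))
    mean_by_A = np.nanmean(per_repeat, axis=1)
    if np.all(np.isnan(mean_by_A)):
        raise ValueError("no usable repeat in the partition scheme")
    best_A = int(np.nanargmin(mean_by_A)) + 1
    row = per_repeat[best_A - 1]
    row = row[~np.isnan(row)]
    return EvaluationSummary(
        family_tag=family_tag,
        feature_ids=list(feature_ids),
        n_components=best_A,
        rmse_iv_mean=float(row.mean()),
        rmse_iv_sd=float(row.std(ddof=1)) if row.size > 1 else 0.0,
    )


def pick_best_per_family(summaries: list[EvaluationSummary]) -> list[EvaluationSummary]:
    """One finalist per family: smallest mean herd-independent RMSE, ties
    broken by its sd, then the stratified-CV mean, then fewer features."""
    if not summaries:
        raise ValueError("no summaries supplied")
    best: dict[str, EvaluationSummary] = {}
    for s in summaries:
        key = (
            s.rmse_iv_mean,
            s.rmse_iv_sd,
            s.rmse_scv_mean if np.isfinite(s.rmse_scv_mean) else np.inf,
            s.n_features,
        )
        cur = best.get(s.family_tag)
        if cur is None or key < (
            cur.rmse_iv_mean,
            cur.rmse_iv_sd,
            cur.rmse_scv_mean if np.isfinite(cur.rmse_scv_mean) else np.inf,
            cur.n_features,
        ):
            best[s.family_tag] = s
    return [best[t] for t in sorted(best)]


def fit_final_model(
    dataset: Dataset, feature_ids: list[str], n_components: int
) -> PlsModel:
    """Refit on every training record at the chosen component count, with
    the frozen training scale stored inside the model."""
    scale = fit_scale(dataset, feature_ids)
    X = scale.transform(dataset.feature_matrix(feature_ids))
    return fit_pls(
        X, dataset.bw(), n_components, feature_ids=list(feature_ids), scale=scale
    )


def finalize_and_external_validate(
    selected: list[EvaluationSummary],
    training: Dataset,
    external: Dataset,
) -> tuple[list[EvaluationSummary], list[PlsModel], np.ndarray]:
    """Refit each finalist on the full training set and score it on an
    untouched external dataset; also report the pairwise Pearson correlation
    of the external predictions."""
    models, preds = [], []
    out = []
    y_ext = external.bw()
    for s in selected:
        missing = [f for f in s.feature_ids if f not in external.df.columns]
        if missing:
            raise KeyError(f"features absent from external data: {missing[:5]}")
        model = fit_final_model(training, s.feature_ids, s.n_components)
        yh = predict(model, external.feature_matrix(s.feature_ids))
        models.append(model)
        preds.append(yh)
        out.append(
            EvaluationSummary(
                family_tag=s.family_tag,
                feature_ids=s.feature_ids,
                n_components=model.n_components,
                rmse_iv_mean=s.rmse_iv_mean,
                rmse_iv_sd=s.rmse_iv_sd,
                rmse_scv_mean=s.rmse_scv_mean,
                rmse_scv_sd=s.rmse_scv_sd,
                r2_scv=s.r2_scv,
                rmse_v=rmse(y_ext, yh),
                tolerance=s.tolerance,
            )
        )
    P = np.asarray(preds)
    if len(preds) >= 2:
        corr = np.corrcoef(P)
    else:
        corr = np.ones((len(preds), len(preds)))
    return out, models, corr
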