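"""Feature selection: univariate spline screen (SBF), recursive feature
elimination with VIP/BETA re-ranking, and tolerance-based model retention.

SBF fits, per predictor, a univariate smooth model BW = b0 + s(X) + e using a
cubic B-spline basis with interior knots at quantiles of X, and tests the
spline terms against the intercept-only model with a classical F-test; a
predictor is kept when p < alpha. The screen is univariate and deliberately
tolerant: it only discards predictors with no detectable functional relation
to bodyweight, linear or not.

RFE then walks a decreasing subset-size schedule. At each size it keeps the
top-ranked features, refits a PLS model (component count chosen by stratified
cross-validation, capped at 10), records the CV RMSE, and re-ranks the
surviving features with VIP or BETA scores before the next cut.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline

from .dataset import Dataset
from .pls import beta_scores, fit_pls, vip_scores
from .validation import Strata, cv_rmse_path, stratified_kfold

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# filter selection (SBF)
# ---------------------------------------------------------------------------

@dataclass
class SbfResult:
    retained: list[str]
    p_values: dict[str, float]
    alpha: float


def _spline_basis(x: np.ndarray, n_interior: int = 3, degree: int = 3) -> np.ndarray | None:
    """Cubic B-spline design matrix with interior knots at quantiles of x;
    None when x is (nearly) constant."""
    lo, hi = float(x.min()), float(x.max())
    if hi - lo <= 0:
        return None
    interior = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
    knots = np.concatenate(
        [np.full(degree + 1, lo), np.clip(interior, lo, hi), np.full(degree + 1, hi)]
    )
    try:
        B = BSpline.design_matrix(x, knots, degree, extrapolate=True).toarray()
    except ValueError:
        return None
    return B


def smooth_f_test(x: np.ndarray, y: np.ndarray) -> float:
    """p-value of the F-test of the univariate spline model against the
    intercept-only model; NaN when the predictor is degenerate."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = y.size
    B = _spline_basis(x)
    if B is None:
        return float("nan")
    design = np.column_stack([np.ones(n), B])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    rss1 = float(np.sum((y - fitted) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    df_model = rank - 1
    df_resid = n - rank
    if df_model < 1 or df_resid < 1 or rss1 <= 0:
        return float("nan")
    f = ((rss0 - rss1) / df_model) / (rss1 / df_resid)
    return float(stats.f.sf(f, df_model, df_resid))


def sbf_filter(
    dataset: Dataset,
    feature_ids: list[str] | None = None,
    alpha: float = 0.05,
) -> SbfResult:
    """Univariate smooth screen of every candidate predictor against BW."""
    ids = list(feature_ids) if feature_ids is not None else dataset.feature_columns
    y = dataset.bw()
    if y.size < 30:
        raise ValueError("SBF needs at least ~30 records for a stable spline fit")
    X = dataset.feature_matrix(ids)
    p_values: dict[str, float] = {}
    retained: list[str] = []
    for j, fid in enumerate(ids):
        p = smooth_f_test(X[:, j], y)
        p_values[fid] = p
        if np.isnan(p):
            warnings.warn(f"constant predictor {fid!r} excluded from SBF", stacklevel=2)
            continue
        if p < alpha:
            retained.append(fid)
    log.info("sbf_filter retained %d/%d predictors", len(retained), len(ids))
    return SbfResult(retained=retained, p_values=p_values, alpha=alpha)


def sbf_reduction(n_before: int, n_after: int) -> float:
    """Fractional reduction of the predictor count, e.g. 280 -> 159 gives
    0.4321."""
    if not 0 <= n_after <= n_before or n_before == 0:
        raise ValueError("need 0 <= n_after <= n_before, n_before > 0")
    return (n_before - n_after) / n_before


# ---------------------------------------------------------------------------
# wrapper selection (RFE)
# ---------------------------------------------------------------------------

def rfe_schedule(n_features: int) -> list[int]:
    """Decreasing subset sizes: step 5 while the size exceeds 255, step 2
    while in 201..255, step 1 at or below 200; stops before going under 2.
    The starting size is included."""
    if n_features < 2:
        raise ValueError("need at least 2 features")
    sizes = [n_features]
    cur = n_features
    while True:
        if cur > 255:
            nxt = cur - 5
        elif cur > 200:
            nxt = cur - 2
        else:
            nxt = cur - 1
        if nxt < 2:
            break
        sizes.append(nxt)
        cur = nxt
    return sizes


@dataclass
class RfeStep:
    subset_size: int
    feature_ids: list[str]
    n_components: int
    rmse_scv_mean: float
    rmse_scv_sd: float


@dataclass
class RfeTrace:
    family_tag: str
    steps: list[RfeStep] = field(default_factory=list)

    def sizes(self) -> list[int]:
        return [s.subset_size for s in self.steps]

    def best_step(self) -> RfeStep:
        return min(self.steps, key=lambda s: (s.rmse_scv_mean, s.subset_size))


def _rank_features(X, y, feature_ids, folds, max_components, ranking_method):
    """Pick the CV-optimal component count, fit on everything, and return
    (ranking, best_A, per-fold RMSE at best_A)."""
    A_cap = min(max_components, X.shape[1], X.shape[0] - 1)
    path = cv_rmse_path(X, y, folds, A_cap)  # (A_cap, k)
    mean_by_A = np.nanmean(path, axis=1)
    best_A = int(np.nanargmin(mean_by_A)) + 1
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    model = fit_pls((X - mu) / sd, y, best_A, feature_ids=feature_ids)
    scorer = vip_scores if ranking_method == "vip" else beta_scores
    ranking = scorer(model)
    fold_rmse = path[best_A - 1]
    return ranking, best_A, fold_rmse[~np.isnan(fold_rmse)]


def run_rfe(
    dataset: Dataset,
    starting_features: list[str],
    ranking_method: str = "vip",
    strata: Strata | None = None,
    k: int = 10,
    max_components: int = 10,
    seed: int = 0,
    family_tag: str | None = None,
) -> RfeTrace:
    """Backward elimination along ``rfe_schedule``; features kept at each
    step are the top of the previous step's ranking, and the subset is
    re-ranked after refitting."""
    if ranking_method not in ("vip", "beta"):
        raise ValueError("ranking_method must be 'vip' or 'beta'")
    missing = [f for f in starting_features if f not in dataset.df.columns]
    if missing:
        raise KeyError(f"starting features not in dataset: {missing[:5]}")
    y = dataset.bw()
    if strata is None:
        from .validation import make_strata

        strata = make_strata(y)
    folds = stratified_kfold(strata, k=k, seed=seed)
    tag = family_tag or f"RFE_{ranking_method.upper()}"
    trace = RfeTrace(family_tag=tag)

    current = list(starting_features)
    X_all = dataset.feature_matrix(current)
    col_of = {f: i for i, f in enumerate(current)}
    ranking, _, _ = _rank_features(
        X_all, y, current, folds, max_components, ranking_method
    )
    order = ranking.feature_ids
    for size in rfe_schedule(len(current)):
        feats = order[:size]
        X = X_all[:, [col_of[f] for f in feats]]
        ranking, best_A, fold_rmse = _rank_features(
            X, y, feats, folds, max_components, ranking_method
        )
        trace.steps.append(
            RfeStep(
                subset_size=size,
                feature_ids=list(feats),
                n_components=best_A,
                rmse_scv_mean=float(fold_rmse.mean()),
                rmse_scv_sd=float(fold_rmse.std(ddof=1)) if fold_rmse.size > 1 else 0.0,
            )
        )
        order = ranking.feature_ids
    return trace


# ---------------------------------------------------------------------------
# tolerance-based retention
# ---------------------------------------------------------------------------

@dataclass
class SelectedModel:
    family_tag: str
    tolerance: int  # percent
    feature_ids: list[str]
    rmse_scv: float
    n_components: int


def tolerance_select(
    trace: RfeTrace, tolerances: list[int] | range = range(0, 13)
) -> list[SelectedModel]:
    """For each tolerance t, keep the smallest subset whose CV RMSE does not
    exceed (1 + t/100) times the best CV RMSE in the trace (ties to the
    lower RMSE). The default grid 0..12 yields 13 retained models; the same
    subset may recur at several tolerances."""
    tolerances = list(tolerances)
    if not tolerances:
        raise ValueError("empty tolerance list")
    if not trace.steps:
        raise ValueError("empty trace")
    min_rmse = min(s.rmse_scv_mean for s in trace.steps)
    out = []
    for t in tolerances:
        threshold = min_rmse * (1 + t / 100.0)
        eligible = [s for s in trace.steps if s.rmse_scv_mean <= threshold]
        pick = min(eligible, key=lambda s: (s.subset_size, s.rmse_scv_mean))
        out.append(
            SelectedModel(
                family_tag=trace.family_tag,
                tolerance=int(t),
                feature_ids=list(pick.feature_ids),
                rmse_scv=pick.rmse_scv_mean,
                n_components=pick.n_components,
            )
        )
    return out
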