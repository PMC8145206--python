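"""Pipeline orchestration and application summaries.

``run_pipeline`` chains the full analysis: derivative, region subsetting,
three-stage cleaning, the SBF screen, six RFE families (two starting
spectral subsets x optional filter x two rankings), tolerance retention,
herd-independent repeated validation, finalist selection and, when an
external dataset is supplied, external validation.

The summary helpers reproduce the two application-level views: averaged
predicted bodyweight by days in milk within parity class, and the pairwise
correlation of different finalists' predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cleaning import CleaningReport, clean_dataset
from .config import PipelineConfig
from .dataset import COVARIATE_FEATURES, Dataset
from .pls import PlsModel, predict
from .preprocess import first_derivative, select_regions
from .selection import (
    RfeTrace,
    SbfResult,
    SelectedModel,
    run_rfe,
    sbf_filter,
    tolerance_select,
)
from .validation import (
    EvaluationSummary,
    PartitionScheme,
    evaluate_iv,
    evaluate_scv,
    finalize_and_external_validate,
    herd_partitions,
    make_strata,
    pick_best_per_family,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    cleaned: Dataset
    cleaning_report: CleaningReport | None
    sbf: dict[str, SbfResult]
    traces: dict[str, RfeTrace]
    selected: list[SelectedModel]
    scheme: PartitionScheme
    summaries: list[EvaluationSummary]
    finalists: list[EvaluationSummary]
    final_models: list[PlsModel] = field(default_factory=list)
    prediction_corr: np.ndarray | None = None

    def summary_table(self) -> pd.DataFrame:
        rows = [
            {
                "family": s.family_tag,
                "n_features": s.n_features,
                "rmse_iv_mean": s.rmse_iv_mean,
                "rmse_iv_sd": s.rmse_iv_sd,
                "rmse_scv_mean": s.rmse_scv_mean,
                "rmse_scv_sd": s.rmse_scv_sd,
                "ncomp": s.n_components,
                "r2_scv": s.r2_scv,
                "rmse_v": s.rmse_v,
            }
            for s in self.finalists
        ]
        return pd.DataFrame(rows)


def _prepare(dataset: Dataset, cfg: PipelineConfig) -> tuple[Dataset, CleaningReport | None]:
    ds = dataset
    if cfg.apply_derivative and ds.stage_tag == "raw":
        ds = first_derivative(ds, gap=cfg.derivative_gap)
    report = None
    if cfg.apply_cleaning:
        ds, report = clean_dataset(
            ds,
            var_explained=cfg.gh_var_explained,
            gh_threshold=cfg.gh_threshold,
            n_components=cfg.max_components,
            sd_threshold=cfg.residual_sd_threshold,
        )
    return ds, report


def build_families(dataset: Dataset, cfg: PipelineConfig) -> dict[str, list[str]]:
    """Starting feature sets: ALL (every spectral point plus covariates) and
    HSO (the expert wavenumber windows plus covariates), each optionally
    screened by SBF."""
    all_features = dataset.feature_columns
    hso_ds = select_regions(dataset, cfg.hso_intervals)
    hso_features = hso_ds.spectral_columns + COVARIATE_FEATURES
    families: dict[str, list[str]] = {"ALL": all_features, "HSO": hso_features}
    return families


def run_pipeline(
    dataset: Dataset,
    cfg: PipelineConfig | None = None,
    external: Dataset | None = None,
) -> PipelineResult:
    cfg = cfg or PipelineConfig()
    ds, report = _prepare(dataset, cfg)
    ext = None
    if external is not None:
        ext, _ = _prepare(external, PipelineConfig(
            apply_derivative=cfg.apply_derivative,
            derivative_gap=cfg.derivative_gap,
            apply_cleaning=False,
        ))

    families = build_families(ds, cfg)
    strata = make_strata(ds.bw())

    sbf_results: dict[str, SbfResult] = {}
    for tag in ("ALL", "HSO"):
        sbf_results[tag] = sbf_filter(ds, families[tag], alpha=cfg.sbf_alpha)
        families[f"{tag}_SBF"] = sbf_results[tag].retained
        log.info("%s_SBF: %d features", tag, len(sbf_results[tag].retained))

    rfe_plan = [
        ("ALL_SBF_VIP", "ALL_SBF", "vip"),
        ("ALL_SBF_BETA", "ALL_SBF", "beta"),
        ("HSO_VIP", "HSO", "vip"),
        ("HSO_BETA", "HSO", "beta"),
        ("HSO_SBF_VIP", "HSO_SBF", "vip"),
        ("HSO_SBF_BETA", "HSO_SBF", "beta"),
    ]
    traces: dict[str, RfeTrace] = {}
    selected: list[SelectedModel] = []
    for tag, start, method in rfe_plan:
        trace = run_rfe(
            ds,
            families[start],
            ranking_method=method,
            strata=strata,
            k=cfg.k_folds,
            max_components=cfg.max_components,
            seed=cfg.seed,
            family_tag=tag,
        )
        traces[tag] = trace
        selected.extend(tolerance_select(trace, list(cfg.tolerances)))
        log.info("%s: %d scheduled subsets", tag, len(trace.steps))

    herd_sizes = ds.df["herd_id"].value_counts().to_dict()
    scheme = herd_partitions(
        herd_sizes,
        fraction_range=cfg.fraction_range,
        n_repeats=cfg.n_repeats,
        seed=cfg.seed,
    )

    summaries: list[EvaluationSummary] = []
    for m in selected:
        s = evaluate_iv(
            ds, m.feature_ids, scheme, max_components=cfg.max_components,
            family_tag=m.family_tag,
        )
        scv_mean, scv_sd, scv_r2 = evaluate_scv(
            ds, m.feature_ids, strata, s.n_components, k=cfg.k_folds, seed=cfg.seed
        )
        s.rmse_scv_mean, s.rmse_scv_sd, s.r2_scv = scv_mean, scv_sd, scv_r2
        s.tolerance = m.tolerance
        summaries.append(s)

    finalists = pick_best_per_family(summaries)
    if ext is not None:
        finalists, final_models, corr = finalize_and_external_validate(
            finalists, ds, ext
        )
    else:
        from .validation import fit_final_model

        final_models = [
            fit_final_model(ds, s.feature_ids, s.n_components) for s in finalists
        ]
        corr = prediction_correlation(final_models, ds) if len(final_models) >= 2 else None
    return PipelineResult(
        cleaned=ds,
        cleaning_report=report,
        sbf=sbf_results,
        traces=traces,
        selected=selected,
        scheme=scheme,
        summaries=summaries,
        finalists=finalists,
        final_models=final_models,
        prediction_corr=corr,
    )


# ---------------------------------------------------------------------------
# application summaries
# ---------------------------------------------------------------------------

@dataclass
class LactationCurve:
    parity_class: int
    bin_width: int
    dim_bin_start: np.ndarray
    mean_bw: np.ndarray
    n_per_bin: np.ndarray


def lactation_curve(
    predictions: pd.DataFrame, bin_width: int = 5
) -> list[LactationCurve]:
    """Mean predicted bodyweight per DIM bin within each parity class.

    ``predictions`` needs columns dim, parity_class and pred_bw. Only bins
    with at least one record are reported.
    """
    required = {"dim", "parity_class", "pred_bw"}
    if predictions.empty or not required <= set(predictions.columns):
        raise ValueError(f"predictions must be non-empty with columns {sorted(required)}")
    out = []
    df = predictions.copy()
    df["bin"] = (df["dim"] // bin_width).astype(int) * bin_width
    for pc, grp in df.groupby("parity_class"):
        agg = grp.groupby("bin")["pred_bw"].agg(["mean", "size"]).reset_index()
        out.append(
            LactationCurve(
                parity_class=int(pc),
                bin_width=bin_width,
                dim_bin_start=agg["bin"].to_numpy(),
                mean_bw=agg["mean"].to_numpy(),
                n_per_bin=agg["size"].to_numpy(),
            )
        )
    return out


def prediction_correlation(models: list[PlsModel], dataset: Dataset) -> np.ndarray:
    """Pairwise Pearson correlation of model predictions on one dataset."""
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    preds = []
    for m in models:
        yh = predict(m, dataset.feature_matrix(m.feature_ids))
        if np.std(yh) == 0:
            raise ValueError("constant predictions: correlation undefined")
        preds.append(yh)
    return np.corrcoef(np.asarray(preds))
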