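"""Strata, stratified folds, herd-disjoint partitions, and validation."""

import dataclasses
import warnings

import numpy as np
import pytest

from mirbw import (
    EvaluationSummary,
    GeneratorConfig,
    PlsModel,
    evaluate_iv,
    finalize_and_external_validate,
    fit_final_model,
    generate,
    herd_partitions,
    make_strata,
    pick_best_per_family,
    predict,
    rmse,
    stratified_kfold,
)

# cleaned per-herd record counts of a 9-herd, 1849-record training set
HERD_SIZES = dict(
    zip(
        [f"h{i:02d}" for i in range(1, 10)],
        [31, 39, 146, 377, 153, 174, 630, 174, 125],
    )
)


class TestStrata:
    def test_quartile_boundaries_linear_interpolation(self):
        s = make_strata(np.arange(1.0, 101.0))
        np.testing.assert_allclose(s.boundaries, [1.0, 25.75, 50.5, 75.25, 100.0])

    def test_four_distinct_values_one_per_stratum(self):
        s = make_strata(np.array([500.0, 550.0, 600.0, 650.0]))
        assert sorted(s.labels) == [0, 1, 2, 3]

    def test_constant_bw_rejected(self):
        with pytest.raises(ValueError):
            make_strata(np.full(10, 600.0))


class TestStratifiedKfold:
    def test_exact_division_one_per_stratum_per_fold(self):
        bw = np.concatenate([np.full(10, v) + np.arange(10) * 0.1 for v in (500, 550, 600, 650)])
        s = make_strata(bw)
        folds = stratified_kfold(s, k=10, seed=0)
        for st_label in range(4):
            counts = np.bincount(folds[s.labels == st_label], minlength=10)
            assert np.all(counts == 1)

    def test_per_stratum_balance_within_one(self, synthetic):
        ds, _ = synthetic
        s = make_strata(ds.bw())
        folds = stratified_kfold(s, k=10, seed=3)
        for st_label in np.unique(s.labels):
            counts = np.bincount(folds[s.labels == st_label], minlength=10)
            assert counts.max() - counts.min() <= 1

    def test_seed_reproducibility(self, synthetic):
        ds, _ = synthetic
        s = make_strata(ds.bw())
        np.testing.assert_array_equal(
            stratified_kfold(s, k=10, seed=5), stratified_kfold(s, k=10, seed=5)
        )


class TestHerdPartitions:
    def test_fraction_arithmetic_on_printed_herd_sizes(self):
        total = sum(HERD_SIZES.values())
        assert total == 1849
        assert 0.10 <= HERD_SIZES["h04"] / total <= 0.30  # ~0.204: feasible alone
        assert HERD_SIZES["h07"] / total > 0.30  # ~0.341: infeasible alone

    def test_disjoint_and_within_fraction_for_all_repeats(self):
        scheme = herd_partitions(HERD_SIZES, n_repeats=101, seed=0)
        total = sum(HERD_SIZES.values())
        assert scheme.n_repeats == 101
        for train_h, valid_h in scheme.repeats:
            assert train_h & valid_h == frozenset()
            assert train_h | valid_h == frozenset(HERD_SIZES)
            frac = sum(HERD_SIZES[h] for h in valid_h) / total
            assert 0.10 <= frac <= 0.30
            assert valid_h != frozenset({"h07"})

    def test_two_equal_herds_infeasible(self):
        with pytest.raises(ValueError):
            herd_partitions({"a": 50, "b": 50})

    def test_with_replacement_warning_when_few_subsets(self):
        sizes = {"a": 50, "b": 30, "c": 20}
        with pytest.warns(UserWarning, match="replacement"):
            scheme = herd_partitions(sizes, fraction_range=(0.10, 0.30), n_repeats=50)
        assert scheme.n_repeats == 50


@pytest.fixture(scope="module")
def scheme(synthetic):
    ds, _ = synthetic
    sizes = ds.df["herd_id"].value_counts().to_dict()
    return herd_partitions(sizes, n_repeats=20, seed=0)


class TestEvaluateIv:
    def test_max_components_one_forces_single_factor(self, synthetic, scheme):
        ds, _ = synthetic
        s = evaluate_iv(ds, ds.feature_columns[:20], scheme, max_components=1)
        assert s.n_components == 1

    def test_reproducible_at_fixed_scheme(self, synthetic, scheme):
        ds, _ = synthetic
        a = evaluate_iv(ds, ds.feature_columns[:20], scheme, max_components=4)
        b = evaluate_iv(ds, ds.feature_columns[:20], scheme, max_components=4)
        assert a.rmse_iv_mean == b.rmse_iv_mean and a.rmse_iv_sd == b.rmse_iv_sd

    def test_large_herd_effects_penalize_herd_disjoint_validation(self, small_grid):
        from mirbw.validation import evaluate_scv, make_strata

        cfg = GeneratorConfig(
            grid=small_grid,
            n_herds=6,
            cows_per_herd=(10, 14),
            records_per_cow=(3, 5),
            herd_sd=60.0,
            seed=21,
        )
        ds, _ = generate(cfg)
        sizes = ds.df["herd_id"].value_counts().to_dict()
        scheme = herd_partitions(sizes, n_repeats=15, seed=0)
        feats = ds.feature_columns
        s = evaluate_iv(ds, feats, scheme, max_components=5)
        scv_mean, _, _ = evaluate_scv(
            ds, feats, make_strata(ds.bw()), s.n_components
        )
        assert s.rmse_iv_mean > scv_mean


class TestFinalists:
    def _summary(self, tag, mean, sd, scv=np.nan, nfeat=5):
        return EvaluationSummary(
            family_tag=tag,
            feature_ids=[f"f{i}" for i in range(nfeat)],
            n_components=2,
            rmse_iv_mean=mean,
            rmse_iv_sd=sd,
            rmse_scv_mean=scv,
        )

    def test_single_candidate_per_family(self):
        s = self._summary("A", 50.0, 2.0)
        assert pick_best_per_family([s]) == [s]

    def test_sd_breaks_mean_ties(self):
        a = self._summary("A", 50.0, 3.0)
        b = self._summary("A", 50.0, 2.0)
        assert pick_best_per_family([a, b])[0] is b

    def test_six_families_in_six_out(self):
        summaries = [
            self._summary(t, 50.0 + i, 2.0)
            for i, t in enumerate("ABCDEF")
            for _ in range(3)
        ]
        assert len(pick_best_per_family(summaries)) == 6


class TestExternalValidation:
    def test_external_copy_of_training_reproduces_training_rmse(self, synthetic):
        ds, _ = synthetic
        feats = ds.feature_columns[:25]
        s = EvaluationSummary(
            family_tag="X", feature_ids=feats, n_components=3,
            rmse_iv_mean=0.0, rmse_iv_sd=0.0,
        )
        out, models, corr = finalize_and_external_validate([s], ds, ds)
        model = models[0]
        train_rmse = rmse(ds.bw(), predict(model, ds.feature_matrix(feats)))
        assert out[0].rmse_v == pytest.approx(train_rmse, abs=1e-12)

    def test_serialized_model_gives_identical_rmse(self, synthetic):
        ds, _ = synthetic
        feats = ds.feature_columns[:25]
        model = fit_final_model(ds, feats, 3)
        reloaded = PlsModel.from_json(model.to_json())
        a = rmse(ds.bw(), predict(model, ds.feature_matrix(feats)))
        b = rmse(ds.bw(), predict(reloaded, ds.feature_matrix(feats)))
        assert a == pytest.approx(b, abs=1e-12)

    def test_permuted_external_columns_align_by_feature_id(self, synthetic):
        ds, _ = synthetic
        feats = ds.feature_columns[:25]
        model = fit_final_model(ds, feats, 3)
        shuffled = ds.copy()
        cols = list(shuffled.df.columns)
        shuffled.df = shuffled.df[cols[:8] + cols[:7:-1]]  # reverse feature block
        a = predict(model, ds.feature_matrix(feats))
        b = predict(model, shuffled.feature_matrix(feats))
        np.testing.assert_array_equal(a, b)

    def test_missing_external_feature_rejected(self, synthetic):
        ds, _ = synthetic
        feats = ds.feature_columns[:5]
        s = EvaluationSummary(
            family_tag="X", feature_ids=feats, n_components=2,
            rmse_iv_mean=0.0, rmse_iv_sd=0.0,
        )
        broken = ds.copy()
        broken.df = broken.df.drop(columns=feats[:1])
        with pytest.raises(KeyError):
            finalize_and_external_validate([s], ds, broken)
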