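import numpy as np
import pandas as pd
import pytest

import birdreg as br
from birdreg.model import (
    aggregate_predictions,
    correlation_matrix,
    pearson_rows,
    screen_predictors_batch,
    zscore_rows,
)


class TestKmeans:
    def test_duplicate_rows_cocluster(self):
        m = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        labels, means = br.cluster_rows_kmeans(m, 2, seed=0)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_k_equals_rows_gives_singletons(self, rng):
        m = rng.normal(size=(6, 4))
        labels, means = br.cluster_rows_kmeans(m, 6, seed=0)
        assert sorted(labels.tolist()) == list(range(6))
        np.testing.assert_allclose(np.sort(means, axis=0), np.sort(m, axis=0))

    def test_k_above_rows_errors(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            br.cluster_rows_kmeans(rng.normal(size=(3, 2)), 4, seed=0)

    def test_planted_partition_recovered(self, rng):
        centers = np.array([[0.0] * 6, [10.0] * 6, [-10.0] * 6])
        truth = rng.integers(0, 3, size=20)
        m = centers[truth] + rng.normal(0, 0.1, size=(20, 6))
        labels, _ = br.cluster_rows_kmeans(m, 3, seed=1)
        # partition matches generating labels up to relabeling
        for g in range(3):
            assert len(set(labels[truth == g])) == 1
        assert len(set(labels)) == 3

    def test_cluster_means_are_member_means(self, rng):
        m = rng.normal(size=(25, 5))
        labels, means = br.cluster_rows_kmeans(m, 4, seed=2)
        for j in range(means.shape[0]):
            np.testing.assert_allclose(means[j], m[labels == j].mean(axis=0))

    def test_deterministic_given_seed(self, rng):
        m = rng.normal(size=(30, 5))
        a = br.cluster_rows_kmeans(m, 5, seed=7)
        b = br.cluster_rows_kmeans(m, 5, seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestScreening:
    def brute_force(self, y, means, n):
        """Exhaustive |Pearson r| ranking with lower-id tie break."""
        rs = []
        for k in range(means.shape[0]):
            x = means[k]
            if x.std() == 0 or np.std(y) == 0:
                rs.append(0.0)
            else:
                rs.append(abs(np.corrcoef(y, x)[0, 1]))
        order = sorted(range(len(rs)), key=lambda k: (-rs[k], k))
        return order[:n]

    def test_exact_match_ranked_first(self, rng):
        means = rng.normal(size=(10, 8))
        sel = br.screen_predictors(means[5].copy(), means, 3)
        assert sel[0] == 5

    def test_negated_row_ranked_first(self, rng):
        means = rng.normal(size=(10, 8))
        sel = br.screen_predictors(-means[4], means, 3)
        assert sel[0] == 4

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            means = rng.normal(size=(12, 6))
            y = rng.normal(size=6)
            got = br.screen_predictors(y, means, 4)
            assert got.tolist() == self.brute_force(y, means, 4)

    def test_tie_broken_by_lower_id(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        means = np.vstack([y, y * 2 + 1, -y])  # all |r| = 1
        sel = br.screen_predictors(y, means, 2)
        assert sel.tolist() == [0, 1]

    def test_zero_variance_cluster_scores_zero(self, rng):
        y = rng.normal(size=6)
        means = np.vstack([np.full(6, 3.0), y])
        sel = br.screen_predictors(y, means, 2)
        assert sel.tolist() == [1, 0]

    def test_batch_agrees_with_single(self, rng):
        means = rng.normal(size=(15, 7))
        ys = rng.normal(size=(9, 7))
        batch = screen_predictors_batch(ys, means, 5)
        for i in range(9):
            np.testing.assert_array_equal(
                batch[i], br.screen_predictors(ys[i], means, 5)
            )


class TestOls:
    def test_exact_linear_combination(self, rng):
        X = rng.normal(size=(2, 10))
        y = 2 * X[0] - X[1]
        b0, b = br.fit_linear_model(y, X)
        assert abs(b0) < 1e-10
        np.testing.assert_allclose(b, [2.0, -1.0], atol=1e-10)
        resid = y - (b0 + b @ X)
        assert np.abs(resid).max() < 1e-10

    def test_zero_predictors_intercept_only(self, rng):
        y = rng.normal(size=8)
        b0, b = br.fit_linear_model(y, np.zeros((3, 8)))
        assert b0 == pytest.approx(y.mean())

    def test_empty_design_returns_mean(self, rng):
        y = rng.normal(size=5)
        b0, b = br.fit_linear_model(y, np.zeros((0, 5)))
        assert b0 == pytest.approx(y.mean())
        assert b.size == 0

    def test_normal_equations_oracle(self, rng):
        for _ in range(100):
            X = rng.normal(size=(4, 12))
            y = rng.normal(size=12)
            b0, b = br.fit_linear_model(y, X)
            D = np.column_stack([np.ones(12), X.T])
            want = np.linalg.solve(D.T @ D, D.T @ y)
            np.testing.assert_allclose(np.r_[b0, b], want, atol=1e-8)

    def test_residual_orthogonal_to_predictors(self, rng):
        X = rng.normal(size=(3, 20))
        y = rng.normal(size=20)
        b0, b = br.fit_linear_model(y, X)
        resid = y - (b0 + b @ X)
        for row in X:
            u = row / np.linalg.norm(row)
            assert abs(resid @ u) < 1e-8

    def test_rank_deficient_minimum_norm(self):
        x = np.arange(6.0)
        X = np.vstack([x, x])  # duplicated predictor
        y = 3 * x
        b0, b = br.fit_linear_model(y, X)
        pred = b0 + b @ X
        np.testing.assert_allclose(pred, y, atol=1e-8)


class TestCorrelationHelpers:
    def test_pearson_rows_zero_variance_is_zero(self):
        a = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        b = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        np.testing.assert_allclose(pearson_rows(a, b), [0.0, 1.0])

    def test_correlation_matrix_matches_corrcoef(self, rng):
        a = rng.normal(size=(4, 9))
        b = rng.normal(size=(5, 9))
        got = correlation_matrix(a, b)
        want = np.corrcoef(a, b)[:4, 4:]
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_zscore_rows_population_convention(self):
        z = zscore_rows(np.array([[1.0, 3.0]]))
        np.testing.assert_allclose(z, [[-1.0, 1.0]])


class TestAggregation:
    def test_weighted_average_arithmetic(self):
        out = aggregate_predictions(
            np.array([2.0]), {10: np.array([4.0])}, {10: np.array([0.5])}
        )
        assert out[0] == pytest.approx(8.0 / 3.0)

    def test_zero_weights_reduce_to_locus_level(self, rng):
        locus = rng.normal(size=20)
        out = aggregate_predictions(
            locus, {5: rng.normal(size=20)}, {5: np.zeros(20)}
        )
        np.testing.assert_array_equal(out, locus)

    def test_equal_predictions_conserved(self, rng):
        p = rng.normal(size=10)
        out = aggregate_predictions(
            p, {2: p.copy(), 3: p.copy()}, {2: np.ones(10), 3: np.ones(10)}
        )
        np.testing.assert_allclose(out, p)

    def test_negative_weights_clamped(self, rng):
        locus = rng.normal(size=5)
        other = rng.normal(size=5)
        out = aggregate_predictions(locus, {2: other}, {2: -np.ones(5)})
        np.testing.assert_array_equal(out, locus)

    def test_unclamped_weights_kept_when_disabled(self):
        out = aggregate_predictions(
            np.array([2.0]), {2: np.array([4.0])}, {2: np.array([-0.5])},
            clamp_weights=False,
        )
        assert out[0] == pytest.approx((2.0 - 0.5 * 4.0) / 0.5)

    def test_convexity_after_clamping(self, rng):
        locus = rng.normal(size=50)
        preds = {h: rng.normal(size=50) for h in (2, 3)}
        weights = {h: rng.uniform(-1, 1, size=50) for h in (2, 3)}
        out = aggregate_predictions(locus, preds, weights)
        stack = np.vstack([locus, preds[2], preds[3]])
        assert (out >= stack.min(axis=0) - 1e-12).all()
        assert (out <= stack.max(axis=0) + 1e-12).all()


class TestBirdEstimator:
    def test_training_fit_is_exact_on_noiseless_data(
        self, noiseless_truth, noiseless_model
    ):
        pred = noiseless_model.predict(noiseless_truth.expr_train)
        np.testing.assert_allclose(
            pred.to_numpy(), noiseless_truth.dh_train.to_numpy(), atol=1e-8
        )

    def test_out_of_sample_recovery_noiseless(self, noiseless_truth, noiseless_model):
        pred = noiseless_model.predict(noiseless_truth.expr_test)
        r_c = br.cross_cell_correlation(pred, noiseless_truth.dh_test)
        assert np.nanmean(r_c) > 0.98

    def test_xbar_zero_gives_intercepts(self, small_model):
        xbar = np.zeros(small_model.cluster_means_.shape[0])
        np.testing.assert_array_equal(
            small_model.predict_locus_level(xbar), small_model.locus_intercepts_
        )

    def test_profile_at_training_means_maps_to_zero_xbar(self, small_model):
        model = br.BIRD(**{**small_model.get_params(), "map_to_training_quantiles": False})
        for attr in (
            "gene_ids_", "locus_ids_", "reference_quantiles_", "gene_standardizer_",
            "locus_standardizer_", "gene_labels_", "cluster_means_",
            "locus_selected_", "locus_intercepts_", "locus_coefs_",
            "pathway_layers_", "n_training_cell_types_",
        ):
            setattr(model, attr, getattr(small_model, attr))
        xbar = model.prepare_sample(
            pd.Series(model.gene_standardizer_.means, index=model.gene_ids_)
        )
        np.testing.assert_allclose(xbar, 0.0, atol=1e-12)

    def test_gene_permutation_invariance(self, small_truth, small_model):
        sample = small_truth.expr_test.iloc[0]
        shuffled = sample.sample(frac=1.0, random_state=1)
        np.testing.assert_allclose(
            small_model.prepare_sample(sample),
            small_model.prepare_sample(shuffled),
            atol=1e-12,
        )

    def test_identical_samples_identical_predictions(self, small_truth, small_model):
        x = small_truth.expr_test.iloc[[0, 0]]
        pred = small_model.predict(x)
        np.testing.assert_array_equal(pred.iloc[0].to_numpy(), pred.iloc[1].to_numpy())

    def test_missing_genes_warn_and_impute(self, small_truth, small_model):
        sample = small_truth.expr_test.iloc[0]
        partial = sample.iloc[: int(len(sample) * 0.7)]
        with pytest.warns(UserWarning, match="missing"):
            xbar = small_model.prepare_sample(partial)
        assert np.isfinite(xbar).all()

    def test_too_few_genes_error(self, small_truth, small_model):
        sample = small_truth.expr_test.iloc[0]
        with pytest.raises(ValueError, match="model genes"):
            small_model.prepare_sample(sample.iloc[:10])

    def test_constant_locus_predicts_training_mean(self, small_truth):
        dh = small_truth.dh_train.copy()
        dh.iloc[:, 0] = 4.2  # constant locus across training cell types
        model = br.BIRD(
            n_gene_clusters=10, n_predictors=3, pathway_sizes=(), random_state=0
        ).fit(small_truth.expr_train, dh)
        pred = model.predict(small_truth.expr_test)
        np.testing.assert_allclose(pred.iloc[:, 0], 4.2, atol=1e-12)

    def test_empty_pathway_sizes_is_pure_locus_model(self, small_truth):
        model = br.BIRD(
            n_gene_clusters=10, n_predictors=3, pathway_sizes=(), random_state=0
        ).fit(small_truth.expr_train, small_truth.dh_train)
        assert model.pathway_layers_ == {}
        xbar = model.prepare_sample(small_truth.expr_test.iloc[0])
        agg = model.predict_standardized(small_truth.expr_test.iloc[[0]])[0]
        np.testing.assert_allclose(agg, model.predict_locus_level(xbar), atol=1e-15)

    def test_singleton_pathway_layer_equals_locus_model(self, small_truth):
        L = small_truth.config.n_loci
        model = br.BIRD(
            n_gene_clusters=10, n_predictors=3, pathway_sizes=(L,), random_state=0
        ).fit(small_truth.expr_train, small_truth.dh_train)
        layer = model.pathway_layers_[L]
        np.testing.assert_array_equal(layer.weights, 1.0)
        xbar = model.prepare_sample(small_truth.expr_test.iloc[0])
        np.testing.assert_array_equal(
            model.predict_pathway_level(xbar, L), model.predict_locus_level(xbar)
        )

    def test_pathway_size_clipped_with_warning(self, small_truth):
        with pytest.warns(UserWarning, match="clipped"):
            model = br.BIRD(
                n_gene_clusters=10,
                n_predictors=3,
                pathway_sizes=(10_000,),
                random_state=0,
            ).fit(small_truth.expr_train, small_truth.dh_train)
        assert list(model.pathway_layers_) == [small_truth.config.n_loci]

    def test_loci_in_same_pathway_share_prediction(self, small_truth, small_model):
        xbar = small_model.prepare_sample(small_truth.expr_test.iloc[0])
        h = next(iter(small_model.pathway_layers_))
        pred = small_model.predict_pathway_level(xbar, h)
        labels = small_model.pathway_layers_[h].labels
        for c in np.unique(labels):
            assert np.unique(pred[labels == c]).size == 1

    def test_unknown_pathway_size_errors(self, small_model):
        with pytest.raises(KeyError, match="pathway layer"):
            small_model._layer(999)

    def test_column_mismatch_errors(self, small_truth):
        with pytest.raises(ValueError, match="cell types"):
            br.BIRD(n_gene_clusters=5, n_predictors=2).fit(
                small_truth.expr_train.iloc[:-1], small_truth.dh_train
            )

    def test_same_seed_bit_identical(self, small_truth):
        kw = dict(
            n_gene_clusters=12, n_predictors=4, pathway_sizes=(10,), random_state=5
        )
        a = br.BIRD(**kw).fit(small_truth.expr_train, small_truth.dh_train)
        b = br.BIRD(**kw).fit(small_truth.expr_train, small_truth.dh_train)
        np.testing.assert_array_equal(a.locus_coefs_, b.locus_coefs_)
        np.testing.assert_array_equal(a.gene_labels_, b.gene_labels_)
        np.testing.assert_array_equal(
            a.pathway_layers_[10].weights, b.pathway_layers_[10].weights
        )

    def test_save_load_round_trip(self, tmp_path, small_truth, small_model):
        small_model.save(tmp_path / "model")
        loaded = br.BIRD.load(tmp_path / "model")
        a = small_model.predict(small_truth.expr_test)
        b = loaded.predict(small_truth.expr_test)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_weights_are_profile_cluster_correlations(self, small_truth, small_model):
        h = next(iter(small_model.pathway_layers_))
        layer = small_model.pathway_layers_[h]
        dh_std = small_model.locus_standardizer_.transform(
            small_truth.dh_train.T
        ).to_numpy()
        cluster_mean_rows = np.stack(
            [dh_std[layer.labels == c].mean(axis=0) for c in range(layer.n_clusters)]
        )
        want = pearson_rows(dh_std, cluster_mean_rows[layer.labels])
        np.testing.assert_allclose(layer.weights, want, atol=1e-12)
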