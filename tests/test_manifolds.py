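"""Weighted arrays, affinity propagation, embeddings, predictive manifolds."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import pm25panel as pp
from pm25panel.manifolds import _standardize


def frame(arr):
    return pd.DataFrame(np.asarray(arr, dtype=float))


class TestWeightColumns:
    def test_elementwise_product_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(10, 23)), columns=list(pp.FEATURES))
        w = rng.dirichlet(np.ones(23))
        out = pp.weight_columns(X, w)
        for i in range(10):
            for j in range(23):
                assert out.values.iloc[i, j] == pytest.approx(
                    X.iloc[i, j] * w[j], abs=1e-14
                )
        assert out.weighting_tag == "posterior"

    def test_one_hot_weight_zeroes_other_columns(self):
        X = pd.DataFrame(np.ones((5, 23)), columns=list(pp.FEATURES))
        w = np.zeros(23)
        w[2] = 1.0
        out = pp.weight_columns(X, w)
        assert out.values.iloc[:, 2].eq(1.0).all()
        assert out.values.drop(columns=[pp.FEATURES[2]]).eq(0.0).all().all()

    def test_uniform_weights_are_a_global_rescale(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(8, 23)), columns=list(pp.FEATURES))
        out = pp.weight_columns(X, np.full(23, 1 / 23))
        np.testing.assert_allclose(
            out.values.to_numpy(), X.to_numpy() / 23, atol=1e-14
        )

    def test_negative_weights_rejected(self):
        X = pd.DataFrame(np.ones((4, 23)), columns=list(pp.FEATURES))
        with pytest.raises(ValueError):
            pp.weight_columns(X, -np.ones(23) / 23)


class TestAffinityPropagation:
    def test_three_separated_blobs_give_three_clusters(self):
        rng = np.random.default_rng(2)
        blobs = np.vstack([
            rng.normal(0, 0.3, size=(15, 4)),
            rng.normal(8, 0.3, size=(15, 4)),
            rng.normal(-8, 0.3, size=(15, 4)),
        ])
        # higher damping: symmetric geometry makes plain AP oscillate
        sol = pp.cluster_affinity(frame(blobs), damping=0.75)
        assert sol.n_clusters == 3
        for lab in range(3):
            members = sol.members(lab)
            exemplar = sol.exemplars[lab]
            assert exemplar in members  # exemplar inside its own blob
            assert len(set(members // 15)) == 1

    def test_duplicated_rows_share_a_label(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 3))
        X[5] = X[2]
        sol = pp.cluster_affinity(frame(X), damping=0.9)
        assert sol.labels[5] == sol.labels[2]

    def test_repeated_runs_identical(self):
        rng = np.random.default_rng(4)
        X = frame(rng.normal(size=(20, 5)))
        a = pp.cluster_affinity(X)
        b = pp.cluster_affinity(X)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_country_level_cluster_counts_in_range(self, pipeline_result):
        for tag in ("prior", "posterior"):
            sol = pipeline_result.country_clusters[tag]
            assert 2 <= sol.n_clusters <= 27
            # every cluster's exemplar carries that cluster's label
            for lab, ex in enumerate(sol.exemplars):
                assert sol.labels[ex] == lab


class TestEmbeddings:
    def test_pca_recovers_rank_one_direction(self):
        rng = np.random.default_rng(5)
        t = rng.normal(size=40)
        direction = rng.normal(size=23)
        X = frame(np.outer(t, direction))
        emb = pp.embed(X, "pca", k=1)
        assert abs(np.corrcoef(emb.coordinates[:, 0], t)[0, 1]) > 0.9999

    @pytest.mark.parametrize("method", ["isomap", "lle"])
    def test_noiseless_curve_ordering_preserved(self, method):
        # 1-D curve embedded in 23 dimensions
        t = np.linspace(0, 3, 60)
        X = frame(np.column_stack(
            [np.sin(t + j / 5.0) for j in range(23)]
        ))
        emb = pp.embed(X, method, k=1, n_neighbors=8)
        rho = spearmanr(emb.coordinates[:, 0], t).statistic
        assert abs(rho) > 0.95

    def test_mds_three_dimensional_shape_and_stress_nesting(self):
        rng = np.random.default_rng(6)
        X = frame(rng.normal(size=(30, 8)))
        e3 = pp.embed(X, "mds", k=3, seed=1)
        e1 = pp.embed(X, "mds", k=1, seed=1)
        assert e3.coordinates.shape == (30, 3)
        assert e3.meta["stress"] <= e1.meta["stress"]

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="pca"):
            pp.embed(frame(np.zeros((5, 4))), "umap", k=1)


class TestPredictiveManifolds:
    def test_all_predictions_standardized_and_aligned(self, pipeline_result):
        for tag in ("prior", "posterior"):
            for name, pred in pipeline_result.manifold_predictions[tag].items():
                assert abs(pred.z.mean()) < 1e-9, name
                assert abs(pred.z.std() - 1) < 1e-9, name
                y = pipeline_result.split.full_scaled_y
                assert np.corrcoef(pred.z, y)[0, 1] >= 0, name

    def test_dominant_direction_equal_to_target_gives_high_r2(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=120)
        # y spans the dominant-variance direction of the array
        X = frame(
            np.outer(y, np.full(23, 3.0)) + rng.normal(size=(120, 23)) * 0.3
        )
        pred = pp.predictive_manifold(X, "pca", y)
        assert pred.accuracy.r2 > 0.9

    def test_zero_variance_embedding_rejected(self):
        with pytest.raises(ValueError):
            _standardize(np.full(7, 2.0))


class TestMdsEcliptic:
    def test_planar_target_recovered(self):
        # points in a 2-D plane; y is a linear function of the plane coords
        rng = np.random.default_rng(8)
        plane = rng.normal(size=(60, 2))
        basis, _ = np.linalg.qr(rng.normal(size=(6, 2)))
        X = frame(plane @ basis.T)
        # target on the z-scale, matching the pipeline's scaled ground truth
        y = _standardize(2.0 * plane[:, 0] - plane[:, 1])
        pred = pp.mds_ecliptic(X, y, seed=1)
        assert pred.accuracy.r2 > 0.95

    def test_not_below_one_dimensional_mds(self, pipeline_result):
        for tag in ("prior", "posterior"):
            preds = pipeline_result.manifold_predictions[tag]
            assert (
                preds["mds_ecliptic"].accuracy.r2
                >= preds["mds"].accuracy.r2 - 1e-9
            )

    def test_output_is_standardized_vector(self, pipeline_result):
        pred = pipeline_result.manifold_predictions["posterior"]["mds_ecliptic"]
        assert pred.z.shape == (297,)
        assert abs(pred.z.mean()) < 1e-9


class TestUnsupervisedBlend:
    def test_perfect_input_gives_r2_one(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=50)
        perfect = pp.ManifoldPrediction(
            "oracle", _standardize(y), pp.accuracy_block(y, _standardize(y))
        )
        noise = pp.ManifoldPrediction(
            "noise", _standardize(rng.normal(size=50)),
            pp.accuracy_block(y, _standardize(rng.normal(size=50))),
        )
        blend = pp.unsupervised_ols_blend([perfect, noise], y)
        # fitted values are standardized, so compare correlation-squared
        assert np.corrcoef(blend.z, y)[0, 1] ** 2 > 1 - 1e-9

    def test_blend_at_least_best_single(self, pipeline_result):
        for tag in ("prior", "posterior"):
            preds = pipeline_result.manifold_predictions[tag]
            blend_r2 = preds["unsupervised_ols"].accuracy.r2
            singles = [
                p.accuracy.r2 for m, p in preds.items()
                if m != "unsupervised_ols"
            ]
            assert blend_r2 >= max(singles) - 1e-9

    def test_coefficients_match_normal_equations_oracle(self, default_split):
        rng = np.random.default_rng(10)
        y = default_split.full_scaled_y
        vecs = [
            pp.ManifoldPrediction(
                f"m{i}", _standardize(y + rng.normal(0, s, len(y))),
                pp.accuracy_block(y, _standardize(y)),
            )
            for i, s in enumerate((0.5, 1.0, 2.0))
        ]
        blend = pp.unsupervised_ols_blend(vecs, y)
        A = np.column_stack([np.ones(len(y)), *(v.z for v in vecs)])
        coef = np.linalg.solve(A.T @ A, A.T @ y)
        oracle = _standardize(A @ coef)
        np.testing.assert_allclose(blend.z, oracle, atol=1e-10)

    def test_single_vector_rejected(self, default_split):
        y = default_split.full_scaled_y
        one = pp.ManifoldPrediction(
            "m", _standardize(y), pp.accuracy_block(y, _standardize(y))
        )
        with pytest.raises(ValueError):
            pp.unsupervised_ols_blend([one], y)
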