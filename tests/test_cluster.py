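"""Gaussian-mixture fitting, BIC model selection and frozen-model assignment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

import strainpheno as sp
from strainpheno.cluster import GmmModel, assignments_to_frame, posterior_matrix
from strainpheno.io import FEATURE_COLUMNS


def _frame(X):
    df = pd.DataFrame(X, columns=FEATURE_COLUMNS[: X.shape[1]])
    if X.shape[1] < 6:
        for c in FEATURE_COLUMNS[X.shape[1]:]:
            df[c] = 0.0  # pad constant columns
    df.insert(0, "subject_id", [f"s{i}" for i in range(len(df))])
    return df


def _blobs(n_per=120, d=6, sep=8.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n_per, d))
    b = rng.normal(0, 1, (n_per, d)) + sep / np.sqrt(d)
    X = np.vstack([a, b])
    labels = np.repeat([0, 1], n_per)
    return _frame(X), labels


def _toy_model(means, weights=None, covs=None):
    means = np.asarray(means, dtype=float)
    k, d = means.shape
    weights = np.full(k, 1 / k) if weights is None else np.asarray(weights)
    covs = np.stack([np.eye(d)] * k) if covs is None else np.asarray(covs)
    return GmmModel(
        k=k, weights=weights, means=means, covariances=covs,
        scale_center=np.zeros(d), scale_scale=np.ones(d),
        log_likelihood=0.0, bic=0.0,
        feature_names=list(FEATURE_COLUMNS[:d]),
    )


class TestFitGmm:
    def test_k1_matches_sample_moments(self):
        rng = np.random.default_rng(1)
        X = rng.normal(2.0, 3.0, (200, 6))
        model = sp.fit_gmm(_frame(X), k=1, seed=0)
        np.testing.assert_allclose(model.means_original()[0], X.mean(axis=0),
                                   atol=1e-8)
        cov_orig = (
            model.covariances[0]
            * np.outer(model.scale_scale, model.scale_scale)
        )
        np.testing.assert_allclose(cov_orig, np.cov(X.T, ddof=0), atol=1e-5)

    def test_two_blobs_recovered(self):
        feats, labels = _blobs(seed=2)
        model = sp.fit_gmm(feats, k=2, seed=0)
        hard = np.array([a.label for a in sp.assign(model, feats)])
        assert adjusted_rand_score(labels, hard) == 1.0
        means = model.means_original()
        X = feats[FEATURE_COLUMNS].to_numpy()
        for m in means:
            grp = X[np.argmin(((means - m) ** 2).sum(1)) == labels + 0]
            # component mean within 3 standard errors of its blob's mean
            closest = min(
                (np.linalg.norm(m - X[labels == g].mean(0)), g) for g in (0, 1)
            )[1]
            blob = X[labels == closest]
            se = blob.std(axis=0, ddof=1) / np.sqrt(len(blob))
            assert np.all(np.abs(m - blob.mean(0)) < 3 * se + 1e-6)

    def test_duplicating_rows_doubles_loglik(self):
        feats, _ = _blobs(n_per=80, seed=3)
        doubled = pd.concat([feats, feats], ignore_index=True)
        m1 = sp.fit_gmm(feats, k=2, seed=0)
        m2 = sp.fit_gmm(doubled, k=2, seed=0)
        assert m2.log_likelihood == pytest.approx(2 * m1.log_likelihood, rel=1e-4)
        order = np.argsort(m1.means_original()[:, 0])
        order2 = np.argsort(m2.means_original()[:, 0])
        np.testing.assert_allclose(
            m1.means_original()[order], m2.means_original()[order2], atol=1e-3
        )

    def test_matches_sklearn_mixture(self):
        """Independent cross-check: same data, sklearn EM finds the same optimum."""
        feats, labels = _blobs(seed=4)
        model = sp.fit_gmm(feats, k=2, seed=0)
        X = (feats[FEATURE_COLUMNS].to_numpy() - model.scale_center) / model.scale_scale
        ref = GaussianMixture(
            n_components=2, covariance_type="full", n_init=5, random_state=0,
            reg_covar=1e-6, tol=1e-6, max_iter=500,
        ).fit(X)
        per_sample = model.log_likelihood / len(X)
        assert per_sample == pytest.approx(ref.score(X), rel=1e-5)
        hard = np.array([a.label for a in sp.assign(model, feats)])
        assert adjusted_rand_score(ref.predict(X), hard) == 1.0

    def test_bic_matches_closed_form(self):
        feats, _ = _blobs(n_per=100, seed=5)
        model = sp.fit_gmm(feats, k=2, seed=0)
        n, d, k = 200, 6, 2
        p = (k - 1) + k * d + k * d * (d + 1) // 2
        assert model.n_parameters == p
        assert model.bic == pytest.approx(
            -2 * model.log_likelihood + p * np.log(n), abs=1e-9
        )

    def test_too_few_subjects_error(self):
        feats, _ = _blobs(n_per=10, seed=0)
        with pytest.raises(ValueError, match="subjects"):
            sp.fit_gmm(feats.iloc[:20], k=3, seed=0)

    def test_missing_values_error(self):
        feats, _ = _blobs(seed=0)
        feats.loc[3, "slope_sys"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            sp.fit_gmm(feats, k=2, seed=0)


class TestSelectK:
    def test_single_cloud_selects_one(self):
        rng = np.random.default_rng(7)
        feats = _frame(rng.normal(0, 1, (300, 6)))
        k, curve, _ = sp.select_k(feats, k_range=range(1, 5), seed=0)
        assert k == 1

    def test_two_blobs_select_two(self):
        feats, _ = _blobs(seed=8)
        k, curve, _ = sp.select_k(feats, k_range=range(1, 6), seed=0)
        assert k == 2

    def test_elbow_fraction_zero_is_argmin(self):
        feats, _ = _blobs(seed=9)
        k, curve, _ = sp.select_k(
            feats, k_range=range(1, 6), seed=0, elbow_fraction=0.0
        )
        assert k == curve.loc[curve.bic.idxmin(), "k"]

    def test_bic_curve_consistent_with_models(self):
        feats, _ = _blobs(n_per=60, seed=10)
        _, curve, models = sp.select_k(feats, k_range=range(1, 4), seed=0)
        for _, row in curve.iterrows():
            m = models[int(row.k)]
            assert row.bic == pytest.approx(
                -2 * m.log_likelihood + m.n_parameters * np.log(m.n_train)
            )


class TestAssign:
    def test_point_at_component_mean_confident(self):
        model = _toy_model([[0, 0, 0], [10, 10, 10]])
        post = posterior_matrix(model, np.array([[0.0, 0.0, 0.0]]))
        assert post[0, 0] > 0.99

    def test_equidistant_point_splits_evenly(self):
        model = _toy_model([[-1, 0, 0], [1, 0, 0]])
        post = posterior_matrix(model, np.array([[0.0, 5.0, -3.0]]))
        np.testing.assert_allclose(post[0], [0.5, 0.5], atol=1e-12)

    def test_posteriors_sum_to_one(self, fitted, featurized):
        model, assignments, _ = fitted
        for a in assignments:
            assert a.posteriors.sum() == pytest.approx(1.0, abs=1e-9)
            assert a.label == int(np.argmax(a.posteriors)) + 1

    def test_training_set_reassignment_is_self_consistent(self, fitted, featurized):
        model, assignments, labels = fitted
        _, feats, _ = featurized
        again = sp.assign(model, feats)
        confident = [
            (a, b) for a, b in zip(assignments, again) if a.posteriors.max() > 0.6
        ]
        assert all(a.label == b.label for a, b in confident)

    def test_feature_count_mismatch_error(self, fitted):
        model, _, _ = fitted
        with pytest.raises(ValueError, match="mismatch"):
            sp.assign(model, np.zeros((3, 4)))


class TestCanonicalRelabel:
    def test_canonical_model_is_fixed_point(self, fitted):
        model, assignments, _ = fitted
        again, asg2 = sp.relabel_canonical(model, assignments)
        np.testing.assert_array_equal(again.means, model.means)
        assert [a.label for a in asg2] == [a.label for a in assignments]

    def test_component_permutation_invariance(self, fitted, featurized):
        model, _, _ = fitted
        _, feats, _ = featurized
        perm = np.array([2, 0, 3, 1])
        shuffled = GmmModel(
            k=model.k, weights=model.weights[perm], means=model.means[perm],
            covariances=model.covariances[perm],
            scale_center=model.scale_center, scale_scale=model.scale_scale,
            log_likelihood=model.log_likelihood, bic=model.bic,
            feature_names=model.feature_names,
        )
        canon_a, _ = sp.relabel_canonical(model)
        canon_b, _ = sp.relabel_canonical(shuffled)
        np.testing.assert_allclose(canon_a.means, canon_b.means)
        np.testing.assert_allclose(canon_a.weights, canon_b.weights)

    def test_order_is_by_early_diastolic_release(self, fitted):
        model, _, _ = fitted
        slope_ed = model.means_original()[:, model.feature_names.index("slope_ed")]
        assert np.all(np.diff(slope_ed) >= 0)  # fastest release first

    def test_two_seeds_agree_up_to_boundaries(self, featurized):
        _, feats, _ = featurized
        out = []
        for seed in (0, 99):
            m = sp.fit_gmm(feats, k=4, seed=seed)
            m, asg = sp.relabel_canonical(m, sp.assign(m, feats))
            out.append(asg)
        pairs = [
            (a, b) for a, b in zip(*out)
            if min(a.posteriors.max(), b.posteriors.max()) > 0.8
        ]
        agree = np.mean([a.label == b.label for a, b in pairs])
        assert agree > 0.99


class TestSerialization:
    def test_model_round_trip_is_exact(self, fitted, tmp_path):
        model, _, _ = fitted
        path = sp.save_model(model, tmp_path / "m.json")
        back = sp.load_model(path)
        np.testing.assert_array_equal(back.means, model.means)
        np.testing.assert_array_equal(back.covariances, model.covariances)
        np.testing.assert_array_equal(back.scale_center, model.scale_center)
        assert back.bic == model.bic and back.k == model.k

    def test_assignment_frame_shape(self, fitted):
        _, assignments, _ = fitted
        df = assignments_to_frame(assignments)
        assert list(df.columns) == ["subject_id", "label", "p1", "p2", "p3", "p4"]
        np.testing.assert_allclose(df[["p1", "p2", "p3", "p4"]].sum(1), 1.0)
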