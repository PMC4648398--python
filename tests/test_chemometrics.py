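"""PCA/KPCA ordination and LDA/KDA classification with LOOCV."""

import warnings

import numpy as np
import pytest

import chemoprint as cp
from chemoprint.chemometrics import Standardizer, median_pairwise_distance
from chemoprint.errors import DataError


def blobs(rng, n_classes=3, per_class=5, dim=8, spread=0.3, gap=5.0):
    X = np.vstack([
        rng.normal(gap * i, spread, size=(per_class, dim))
        for i in range(n_classes)
    ])
    y = [f"class_{i}" for i in range(n_classes) for _ in range(per_class)]
    return X, y


class TestPca:
    def test_perfectly_correlated_variables(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        X = np.c_[a, 3 * a + 1]
        r = cp.pca(X, mode="correlation")
        np.testing.assert_allclose(r.variance_explained, [1.0, 0.0],
                                   atol=1e-12)

    def test_uncorrelated_variables_share_variance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4000, 5))
        r = cp.pca(X, mode="correlation")
        assert np.all(np.abs(r.variance_explained - 0.2) < 0.03)

    def test_eigenvalues_match_explicit_correlation_eigensolve(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 6)) @ rng.normal(size=(6, 6))
        r = cp.pca(X, mode="correlation")
        # oracle: explicitly form the correlation matrix and eigensolve it
        corr = np.corrcoef(X, rowvar=False)
        expect = np.sort(np.linalg.eigvalsh(corr))[::-1]
        np.testing.assert_allclose(r.eigenvalues, expect[: len(r.eigenvalues)],
                                   atol=1e-10)

    def test_covariance_mode_matches_explicit_eigensolve(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 4)) * [1, 10, 100, 1000]
        r = cp.pca(X, mode="covariance")
        cov = np.cov(X, rowvar=False)
        expect = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(r.eigenvalues, expect[: len(r.eigenvalues)],
                                   atol=1e-8 * expect[0])

    def test_variance_explained_sums_to_one(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 7))
        for mode in ("correlation", "covariance"):
            r = cp.pca(X, mode=mode)
            assert abs(r.variance_explained.sum() - 1.0) < 1e-10

    def test_correlation_mode_scale_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(18, 5))
        scales = np.array([0.01, 1.0, 30.0, 7.0, 1000.0])
        shifts = np.array([-5.0, 0.0, 2.0, 100.0, 0.3])
        a = cp.pca(X, mode="correlation")
        b = cp.pca(X * scales + shifts, mode="correlation")
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-8)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(25, 6))
        r = cp.pca(X, mode="correlation")
        gram = r.loadings.T @ r.loadings
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-10)

    def test_zero_variance_column_rejected_by_name(self):
        X = np.c_[np.arange(10.0), np.full(10, 3.0)]
        with pytest.raises(DataError, match=r"\[1\]"):
            cp.pca(X, mode="correlation")


class TestKpca:
    def test_linear_kernel_on_standardized_equals_correlation_pca(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(14, 5)) * [1, 5, 2, 9, 3]
        p = cp.pca(X, mode="correlation", k=4)
        z = Standardizer.fit(X)(X)
        kp = cp.kpca(z, cp.KernelSpec("linear"), k=4)
        # the Gram matrix of standardized data has eigenvalues (n-1)*lambda
        # and scores identical to correlation-PCA scores, up to column sign
        for j in range(4):
            a = p.scores[:, j]
            b = kp.scores[:, j]
            assert (np.allclose(a, b, atol=1e-8)
                    or np.allclose(a, -b, atol=1e-8))

    def test_rbf_infinite_bandwidth_limit(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 4))
        r = cp.kpca(X, cp.KernelSpec("rbf", bandwidth=1e8))
        assert r.eigenvalues[0] < 1e-6  # all-ones kernel centers to ~zero
        assert np.all(r.eigenvalues[1:] < 1e-6)

    def test_duplicate_samples_get_identical_scores(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(6, 3))
        X = np.vstack([X, X[0]])
        r = cp.kpca(X, cp.KernelSpec("rbf", bandwidth=2.0))
        np.testing.assert_allclose(r.scores[0], r.scores[-1], atol=1e-6)


class TestDiscriminant:
    def test_identical_point_classes_separate(self):
        X = np.vstack([np.tile([0.0, 0.0], (3, 1)),
                       np.tile([5.0, 5.0], (3, 1))])
        X += np.random.default_rng(0).normal(0, 1e-3, X.shape)
        y = ["a"] * 3 + ["b"] * 3
        model = cp.train_discriminant(X, y, method="lda")
        dist = np.linalg.norm(model.class_centroids[0]
                              - model.class_centroids[1])
        assert dist > 0
        label, _ = model.predict(X[0])
        assert label == "a"

    def test_kda_linear_matches_lda_assignments(self):
        """KDA with a linear kernel reproduces LDA class assignments on
        separable data (50 random datasets)."""
        rng = np.random.default_rng(10)
        for trial in range(50):
            X, y = blobs(rng, n_classes=rng.integers(2, 5),
                         per_class=int(rng.integers(3, 7)),
                         dim=int(rng.integers(2, 10)),
                         spread=0.5, gap=4.0)
            lda = cp.train_discriminant(X, y, method="lda")
            kda = cp.train_discriminant(X, y, method="kda",
                                        kernel=cp.KernelSpec("linear"))
            for row in X:
                assert lda.predict(row)[0] == kda.predict(row)[0]

    def test_collinear_classes_rank_bound(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=5)
        X = np.vstack([i * 3.0 * base + rng.normal(0, 1e-4, (4, 5))
                       for i in range(3)])
        y = [f"c{i}" for i in range(3) for _ in range(4)]
        model = cp.train_discriminant(X, y, method="lda")
        assert model.class_centroids.shape[1] <= 2
        assert model.eigenvalues[1] < 1e-3 * model.eigenvalues[0]

    def test_singleton_class_rejected(self):
        X = np.arange(10.0).reshape(5, 2)
        y = ["a", "a", "b", "b", "c"]
        with pytest.raises(DataError, match="c"):
            cp.train_discriminant(X, y, method="lda")

    def test_predict_training_sample(self):
        rng = np.random.default_rng(12)
        X, y = blobs(rng)
        model = cp.train_discriminant(X, y, method="kda")
        assert model.predict(X[0])[0] == y[0]

    def test_tie_breaks_to_smallest_label(self):
        # perfectly symmetric two-class layout: the midpoint is equidistant
        X = np.array([[0.0, 0], [0, 1], [4, 0], [4, 1]])
        y = ["zebra", "zebra", "ant", "ant"]
        model = cp.train_discriminant(X, y, method="lda")
        mid = X.mean(axis=0)
        label, dist = model.predict(mid)
        assert abs(dist["ant"] - dist["zebra"]) < 1e-9
        assert label == "ant"

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(13)
        X, y = blobs(rng)
        model = cp.train_discriminant(X, y, method="lda")
        with pytest.raises(DataError, match="variables"):
            model.predict(np.zeros(3))

    def test_held_out_high_separation_all_correct(self, study_profiles,
                                                  study_noise):
        """One study at the canonical seed, split into 5 training and 3
        blind replicates per species: every blind sample is recovered."""
        coll, labels = cp.simulate_dataset(study_profiles, 8, study_noise,
                                           seed=42)
        targets = cp.profile_target_masses(study_profiles)
        X = cp.extract_features(coll, targets, 0.01).values
        labels = np.array(labels)
        train = np.array([i for i in range(len(X)) if i % 8 < 5])
        blind = np.array([i for i in range(len(X)) if i % 8 >= 5])
        model = cp.train_discriminant(X[train], list(labels[train]),
                                      method="kda")
        preds = [model.predict(row)[0] for row in X[blind]]
        assert preds == list(labels[blind])


class TestLoocv:
    def test_identical_within_class_distinct_between(self):
        X = np.vstack([np.tile([i * 10.0, 0.0], (4, 1)) for i in range(3)])
        X += np.random.default_rng(1).normal(0, 1e-6, X.shape)
        y = [f"c{i}" for i in range(3) for _ in range(4)]
        res = cp.loocv(X, y, method="lda")
        assert res.percent_correct == 100.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(14)
        k = 4
        X = rng.normal(size=(k * 12, 6))
        y = [f"c{i}" for i in range(k) for _ in range(12)]
        rates = []
        for _ in range(5):
            perm = rng.permutation(len(y))
            res = cp.loocv(X[perm], [y[i] for i in perm], method="lda")
            rates.append(res.percent_correct)
        assert abs(np.mean(rates) - 100.0 / k) < 12.0

    def test_confusion_row_sums_and_percent(self, study_dataset):
        coll, labels = study_dataset
        targets = cp.profile_target_masses
        table = cp.extract_features(
            coll, cp.profile_target_masses(
                cp.make_species_profiles(5, 25, 0.5, 1.0, seed=42,
                                         abundance_cv=0.1)), 0.01)
        res = cp.loocv(table.values, labels, method="kda")
        counts = {c: labels.count(c) for c in res.classes}
        for i, c in enumerate(res.classes):
            assert res.confusion[i].sum() == counts[c]
        assert res.percent_correct == pytest.approx(
            100.0 * np.trace(res.confusion) / res.confusion.sum()
        )

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(15)
        X, y = blobs(rng, spread=1.5, gap=3.0)
        a = cp.loocv(X, y, method="lda").percent_correct
        perm = rng.permutation(len(y))
        b = cp.loocv(X[perm], [y[i] for i in perm], method="lda").percent_correct
        assert a == b

    def test_size_two_class_fold_warns_and_completes(self):
        rng = np.random.default_rng(16)
        X = np.vstack([rng.normal(0, 0.3, (2, 4)),
                       rng.normal(5, 0.3, (5, 4)),
                       rng.normal(10, 0.3, (5, 4))])
        y = ["tiny"] * 2 + ["mid"] * 5 + ["big"] * 5
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = cp.loocv(X, y, method="lda")
        assert any("single sample" in str(w.message) for w in caught)
        assert len(res.predicted) == 12

    def test_synonym_merge_raises_accuracy(self):
        """Two labels from one generator confuse LOOCV; merging them
        restores near-perfect accuracy."""
        import dataclasses

        profiles = cp.make_species_profiles(2, 25, 0.5, 1.0, seed=42,
                                            abundance_cv=0.1)
        syn_a = dataclasses.replace(profiles[0], name="syn_A")
        syn_b = dataclasses.replace(profiles[0], name="syn_B")
        noise = cp.NoiseModel(5.0, 0.02, 5.0, 2.0)
        coll, labels = cp.simulate_dataset([syn_a, syn_b, profiles[1]], 8,
                                           noise, seed=42)
        targets = cp.profile_target_masses([syn_a, profiles[1]])
        X = cp.extract_features(coll, targets, 0.01).values
        split = cp.loocv(X, labels, method="kda")
        pair = [i for i, l in enumerate(labels) if l.startswith("syn")]
        pair_rate = 100.0 * np.mean(
            [split.predicted[i] == split.truth[i] for i in pair]
        )
        assert pair_rate < 75.0  # near-chance within the synonym pair
        merged = ["syn_A" if l == "syn_B" else l for l in labels]
        joined = cp.loocv(X, merged, method="kda")
        assert joined.percent_correct > split.percent_correct
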