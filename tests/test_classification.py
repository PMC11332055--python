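"""Grouped folds, SVD compression, dimension selection, and the
cross-validated multinomial protocol."""

import numpy as np
import pytest

from qcla.classification import (
    DIMENSION_LADDER,
    FeatureMatrix,
    SVDCompressor,
    _fit_multinomial,
    _predict_codes,
    assert_no_leakage,
    cross_validated_categorize,
    ladder_for,
    make_group_folds,
    regress_scale_scores,
    select_dimensions,
)
from qcla.records import EMOTIONS, ValidationError


class TestLadder:
    def test_full_ladder_for_768(self):
        assert ladder_for(768) == DIMENSION_LADDER

    def test_low_dimensional_truncation(self):
        assert ladder_for(4) == (1, 2, 3, 4)
        assert ladder_for(26)[-1] == 26
        assert ladder_for(772)[-2:] == (768, 772)

    def test_strictly_increasing(self):
        for d in (4, 26, 768, 772):
            lad = ladder_for(d)
            assert all(a < b for a, b in zip(lad, lad[1:]))


class TestGroupFolds:
    def test_singleton_narratives_one_per_fold(self):
        ids = [f"n{i}" for i in range(10)]
        plan = make_group_folds(ids, k=10, rng=0)
        sizes = [len(plan.test_indices(f)) for f in range(10)]
        assert sizes == [1] * 10

    def test_repeated_narrative_shares_fold(self):
        ids = ["a", "b", "c", "a", "d", "e", "f", "g", "h", "i", "j", "a"]
        plan = make_group_folds(ids, k=10, rng=1)
        folds_of_a = {plan.fold_of_record[i] for i, n in enumerate(ids) if n == "a"}
        assert len(folds_of_a) == 1

    def test_deterministic_given_seed(self):
        ids = [f"n{i % 17}" for i in range(50)]
        a = make_group_folds(ids, k=10, rng=5)
        b = make_group_folds(ids, k=10, rng=5)
        assert np.array_equal(a.fold_of_record, b.fold_of_record)

    def test_too_few_narratives_rejected(self):
        with pytest.raises(ValidationError):
            make_group_folds(["a", "b", "c"], k=10, rng=0)

    def test_every_record_assigned_once(self):
        ids = [f"n{i % 23}" for i in range(60)]
        plan = make_group_folds(ids, k=10, rng=2)
        seen = np.concatenate([plan.test_indices(f) for f in range(10)])
        assert sorted(seen.tolist()) == list(range(60))


class TestSVD:
    def test_rank_one_energy_in_first_component(self, rng):
        u = rng.standard_normal((12, 1))
        v = rng.standard_normal((1, 6))
        svd = SVDCompressor().fit(u @ v)
        s = svd.singular_values_
        assert s[0] ** 2 / np.sum(s**2) == pytest.approx(1.0)

    def test_orthonormal_rows_equal_singular_values(self):
        svd = SVDCompressor().fit(np.eye(5))
        assert np.allclose(svd.singular_values_, 1.0)

    def test_full_rank_reconstruction(self, rng):
        X = rng.standard_normal((20, 8))
        svd = SVDCompressor().fit(X)
        Z = svd.transform(X, 8)
        recon = Z @ svd.components_[:8]
        assert np.max(np.abs(recon - X)) < 1e-8

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValidationError):
            SVDCompressor().fit(np.zeros((5, 3)))

    def test_transform_bounds(self, rng):
        svd = SVDCompressor().fit(rng.standard_normal((6, 4)))
        with pytest.raises(ValidationError):
            svd.transform(np.zeros((2, 4)), 5)


class TestSelectDimensions:
    def test_separable_in_first_dimension(self, rng):
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = np.zeros((n, 5))
        X[:, 0] = np.where(y == 0, -5.0, 5.0) + 0.1 * rng.standard_normal(n)
        X[:, 1:] = rng.standard_normal((n, 4))
        groups = [f"g{i}" for i in range(n)]
        m = select_dimensions(X, y, groups, ladder=(1, 2, 3, 5), rng=0)
        assert m == 1

    def test_reproducible(self, rng):
        X = rng.standard_normal((40, 6))
        y = rng.integers(0, 2, size=40)
        groups = [f"g{i}" for i in range(40)]
        args = dict(ladder=(1, 2, 3, 5, 6), inner_k=4)
        assert select_dimensions(X, y, groups, rng=3, **args) == select_dimensions(
            X, y, groups, rng=3, **args
        )


def _toy_features(rng, n=60, d=6, spread=1.2):
    """Four overlapping Gaussian classes (not linearly separable)."""
    y = np.array([i % 4 for i in range(n)])
    centers = rng.standard_normal((4, d)) * spread
    X = centers[y] + rng.standard_normal((n, d))
    labels = np.array([EMOTIONS[c] for c in y])
    ids = np.array([f"n{i}" for i in range(n)])
    return FeatureMatrix(X=X, narrative_ids=ids, labels=labels, feature_set="words")


class TestCrossValidatedCategorize:
    def test_coverage_and_bounds(self, rng):
        fm = _toy_features(rng)
        res = cross_validated_categorize(fm, k=5, rng=0, inner_k=3)
        assert len(res.predicted) == fm.n
        assert 0.0 <= res.percent_correct <= 100.0
        assert len(res.selected_dims) == 5
        assert all(m in ladder_for(fm.d) for m in res.selected_dims)

    def test_deterministic_given_seed(self, rng):
        fm = _toy_features(rng)
        a = cross_validated_categorize(fm, k=5, rng=9, inner_k=3)
        b = cross_validated_categorize(fm, k=5, rng=9, inner_k=3)
        assert np.array_equal(a.predicted, b.predicted)
        assert a.selected_dims == b.selected_dims

    def test_missing_class_in_training_split_errors(self, rng):
        # one class confined to a single narrative: when its fold is held
        # out, training lacks the class entirely
        X = rng.standard_normal((20, 3))
        labels = np.array(["harmony"] * 18 + ["anxiety"] * 2)
        ids = np.array([f"n{i}" for i in range(18)] + ["nx", "nx"])
        fm = FeatureMatrix(X=X, narrative_ids=ids, labels=labels, feature_set="words")
        with pytest.raises(ValidationError, match="lacks class"):
            cross_validated_categorize(fm, k=10, rng=0, inner_k=3)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((12, 3))
        fm = FeatureMatrix(
            X=X,
            narrative_ids=np.array([f"n{i}" for i in range(12)]),
            labels=np.array(["harmony"] * 12),
            feature_set="words",
        )
        with pytest.raises(ValidationError):
            cross_validated_categorize(fm, k=4, rng=0)


class TestMultinomialOracle:
    def test_matches_brute_force_likelihood_fit(self, rng):
        """The fitted multinomial model must agree with a direct numerical
        maximization of the identical ridge-penalized likelihood."""
        from scipy.optimize import minimize
        from scipy.special import logsumexp

        n, d, ridge = 30, 3, 1e-6
        y = np.array([i % 4 for i in range(n)])
        centers = rng.standard_normal((4, d))
        Z = centers[y] + 1.5 * rng.standard_normal((n, d))

        model = _fit_multinomial(Z, y, ridge)
        pred_impl = _predict_codes(model, Z)

        Y = np.eye(4)[y]

        def negloglik(theta):
            W = theta[: 4 * d].reshape(4, d)
            b = theta[4 * d :]
            scores = Z @ W.T + b
            ll = np.sum(scores * Y) - np.sum(logsumexp(scores, axis=1))
            return -ll + 0.5 * ridge * np.sum(W**2)

        theta0 = np.zeros(4 * d + 4)
        opt = minimize(negloglik, theta0, method="L-BFGS-B",
                       options={"maxiter": 20000, "ftol": 1e-14})
        W = opt.x[: 4 * 3].reshape(4, 3)
        b = opt.x[4 * 3 :]
        pred_oracle = np.argmax(Z @ W.T + b, axis=1)
        assert np.array_equal(pred_impl, pred_oracle)


class TestRegression:
    def test_noiseless_linear_target_recovered(self, rng):
        n, d = 120, 10
        X = rng.standard_normal((n, d))
        svd = SVDCompressor().fit(X)
        Z = svd.transform(X, 3)
        target = Z @ np.array([2.0, -1.0, 0.5])
        fm = FeatureMatrix(
            X=X,
            narrative_ids=np.array([f"n{i}" for i in range(n)]),
            labels=np.array([EMOTIONS[i % 4] for i in range(n)]),
            feature_set="words",
        )
        out = regress_scale_scores(fm, target, k=5, rng=0, inner_k=3)
        r = np.corrcoef(out["predictions"][:, 0], target)[0, 1]
        assert r > 0.99

    def test_independent_target_near_zero_correlation(self, rng):
        n, d = 400, 4
        X = rng.standard_normal((n, d))
        target = rng.standard_normal(n)
        fm = FeatureMatrix(
            X=X,
            narrative_ids=np.array([f"n{i}" for i in range(n)]),
            labels=np.array([EMOTIONS[i % 4] for i in range(n)]),
            feature_set="scales",
        )
        out = regress_scale_scores(fm, target, k=10, rng=1, inner_k=3)
        r = np.corrcoef(out["predictions"][:, 0], target)[0, 1]
        assert abs(r) < 0.15

    def test_constant_target_warns(self, rng):
        fm = _toy_features(rng, n=40)
        with pytest.warns(UserWarning, match="constant"):
            regress_scale_scores(fm, np.ones(40), k=4, rng=0, inner_k=3)


class TestLeakage:
    def test_no_narrative_spans_train_and_test(self, rng):
        ids = np.array([f"n{i % 37}" for i in range(100)])
        for seed in range(20):
            plan = make_group_folds(ids, k=10, rng=seed)
            assert_no_leakage(plan, ids)
            for f in range(10):
                te = set(ids[plan.test_indices(f)])
                tr = set(ids[plan.train_indices(f)])
                assert not te & tr
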