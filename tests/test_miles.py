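"""MILES: concept pool, embedding, 1-norm SVM (with grid oracle), tuning."""

import numpy as np
import pytest

from ppgmiles.miles import (ConceptPool, build_concept_pool, embed_bag,
                            embed_bags, fit_sparse_linear, min_sq_distances,
                            score_recording, sparse_linear_objective,
                            tune_hyperparams, MILESModel)
from ppgmiles.morphometry import RecordingBag

rng = np.random.default_rng(12345)


def make_bag(n, shift, label, sid, rid=None):
    X = rng.normal(0, 1, (n, 42)) + shift
    return RecordingBag(X, sid, rid or f"{sid}_r0", label)


def toy_cohort(n_h=6, n_o=4, shift=1.5, beats=10):
    bags = ([make_bag(beats, 0.0, "healthy", f"H{i}") for i in range(n_h)]
            + [make_bag(beats, shift, "oHCM", f"O{i}") for i in range(n_o)])
    return bags, [b.subject_id for b in bags], [b.label for b in bags]


class TestConceptPool:
    def test_all_instances_kept_under_cap(self):
        bags, _, _ = toy_cohort(2, 1)
        pool = build_concept_pool(bags, pool_cap=1000)
        assert pool.size == 30

    def test_stratified_subsample_proportions(self):
        bags, _, _ = toy_cohort(10, 10, beats=30)
        pool = build_concept_pool(bags, pool_cap=200, seed=3)
        assert pool.size == 200
        _, counts = np.unique(pool.concept_labels, return_counts=True)
        assert abs(counts[0] - counts[1]) <= 2  # ~100 per class

    def test_seeded_determinism(self):
        bags, _, _ = toy_cohort(5, 5, beats=40)
        p1 = build_concept_pool(bags, pool_cap=100, seed=9)
        p2 = build_concept_pool(bags, pool_cap=100, seed=9)
        assert np.array_equal(p1.concepts, p2.concepts)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            build_concept_pool([], pool_cap=10)


class TestEmbedding:
    def test_bag_containing_concept_has_unit_coordinate(self):
        bags, _, _ = toy_cohort(3, 2)
        pool = build_concept_pool(bags, pool_cap=1000)
        e = embed_bag(bags[0], pool, sigma=1.0)
        assert e.max() == pytest.approx(1.0)
        assert ((e > 0) & (e <= 1)).all()

    def test_hand_computed_distance_example(self):
        # instances at standardised distances 1 and 2 from the concept,
        # sigma = 1: coordinate = max(e^-1, e^-4) = e^-1
        concept = np.zeros((1, 42))
        pool = ConceptPool(concepts=concept, mean=np.zeros(42),
                           sd=np.ones(42), concept_labels=np.array(["x"]))
        X = np.zeros((2, 42))
        X[0, 0], X[1, 0] = 1.0, 2.0
        bag = RecordingBag(X, "s", "r", "healthy")
        assert embed_bag(bag, pool, 1.0)[0] == pytest.approx(np.exp(-1), rel=1e-6)

    def test_large_sigma_limit_is_one(self):
        bags, _, _ = toy_cohort(3, 2)
        pool = build_concept_pool(bags, pool_cap=1000)
        e = embed_bag(bags[4], pool, sigma=1e6)
        assert np.allclose(e, 1.0, atol=1e-6)

    def test_monotone_in_sigma(self):
        bags, _, _ = toy_cohort(3, 2)
        pool = build_concept_pool(bags, pool_cap=1000)
        M = min_sq_distances(bags, pool)
        e1, e2, e3 = (embed_bags(M, s) for s in (1.0, 2.0, 5.0))
        assert (e2 >= e1).all() and (e3 >= e2).all()

    def test_bag_permutation_invariance(self):
        bags, _, _ = toy_cohort(3, 2)
        pool = build_concept_pool(bags, pool_cap=1000)
        bag = bags[1]
        perm = RecordingBag(bag.features[::-1].copy(), bag.subject_id,
                            bag.recording_id, bag.label)
        assert np.allclose(embed_bag(bag, pool, 2.0), embed_bag(perm, pool, 2.0))

    def test_invalid_sigma(self):
        bags, _, _ = toy_cohort(2, 2)
        pool = build_concept_pool(bags, pool_cap=100)
        with pytest.raises(ValueError):
            embed_bag(bags[0], pool, 0.0)


class TestSparseLinearFit:
    def test_separable_1d(self):
        E = np.array([[1.0], [1.0], [0.0], [0.0]])
        y = np.array(["oHCM", "oHCM", "healthy", "healthy"])
        w, b, _ = fit_sparse_linear(E, y, 0.1)
        assert np.all(np.sign(E @ w + b) == [1, 1, -1, -1])

    def test_objective_matches_grid_oracle(self):
        # 4 bags, 2 concept coordinates: exhaustive grid over weights in
        # [-5, 5] at step 0.01 with the optimal intercept at hinge kinks
        g = np.random.default_rng(7)
        E = g.random((4, 2))
        y = np.array([1.0, 1.0, -1.0, -1.0])
        lam = 0.1
        w, b, obj = fit_sparse_linear(E, y, lam)
        ws = np.arange(-5.0, 5.0001, 0.01)
        W1, W2 = np.meshgrid(ws, ws, indexing="ij")
        W = np.stack([W1.ravel(), W2.ravel()], axis=1)
        scores = W @ E.T                       # (G, 4)
        best = np.full(len(W), np.inf)
        for k in range(4):                     # optimal b lies at a kink
            bb = y[k] - scores[:, k]
            margins = y[None, :] * (scores + bb[:, None])
            o = np.mean(np.maximum(0.0, 1.0 - margins), axis=1) \
                + lam * np.abs(W).sum(axis=1)
            best = np.minimum(best, o)
        assert obj == pytest.approx(best.min(), abs=1e-2)
        assert obj <= best.min() + 1e-9        # LP at least as good as grid

    def test_huge_lambda_zeroes_weights(self):
        E = np.random.default_rng(1).random((8, 5))
        y = np.array([1, 1, 1, 1, -1, -1, -1, -1])
        w, b, _ = fit_sparse_linear(E, y, 1e3)
        assert np.all(w == 0.0)

    def test_single_class_rejected(self):
        E = np.ones((3, 2))
        with pytest.raises(ValueError):
            fit_sparse_linear(E, np.array([1, 1, 1]), 0.1)

    def test_deterministic_objective(self):
        g = np.random.default_rng(3)
        E = g.random((30, 50))
        y = np.where(g.random(30) > 0.6, 1.0, -1.0)
        r1 = fit_sparse_linear(E, y, 0.05)
        r2 = fit_sparse_linear(E, y, 0.05)
        assert r1[2] == r2[2]
        assert np.array_equal(r1[0], r2[0])

    def test_reported_objective_consistent(self):
        g = np.random.default_rng(4)
        E = g.random((20, 10))
        y = np.where(g.random(20) > 0.5, 1.0, -1.0)
        lam = 0.2
        w, b, obj = fit_sparse_linear(E, y, lam)
        assert obj == pytest.approx(sparse_linear_objective(E, y, w, b, lam),
                                    abs=1e-8)


class TestScoring:
    def test_zero_model_scores_zero(self):
        bags, _, _ = toy_cohort(2, 2)
        pool = build_concept_pool(bags, pool_cap=100)
        model = MILESModel(pool=pool, sigma=2.0, lam=0.1,
                           weights=np.zeros(pool.size), intercept=0.0)
        assert score_recording(bags[0], model) == 0.0

    def test_separable_toy_scores_by_class(self):
        bags, subs, labels = toy_cohort(5, 4, shift=2.0, beats=15)
        pool = build_concept_pool(bags, pool_cap=1000)
        M = min_sq_distances(bags, pool)
        E = embed_bags(M, 8.0)
        w, b, _ = fit_sparse_linear(E, np.asarray(labels), 0.01)
        model = MILESModel(pool=pool, sigma=8.0, lam=0.01, weights=w, intercept=b)
        scores = [score_recording(bag, model) for bag in bags]
        assert all(s < 0 for s in scores[:5])
        assert all(s > 0 for s in scores[5:])

    def test_duplicated_beats_leave_score_unchanged(self):
        bags, subs, labels = toy_cohort(3, 3)
        pool = build_concept_pool(bags, pool_cap=1000)
        model = MILESModel(pool=pool, sigma=4.0, lam=0.1,
                           weights=np.ones(pool.size), intercept=0.5)
        bag = bags[0]
        dup = RecordingBag(np.vstack([bag.features, bag.features]),
                           bag.subject_id, bag.recording_id, bag.label)
        assert score_recording(dup, model) == pytest.approx(
            score_recording(bag, model), rel=1e-12)

    def test_model_json_roundtrip(self):
        bags, _, labels = toy_cohort(3, 3)
        pool = build_concept_pool(bags, pool_cap=200)
        M = min_sq_distances(bags, pool)
        w, b, obj = fit_sparse_linear(embed_bags(M, 4.0), np.asarray(labels), 0.1)
        model = MILESModel(pool=pool, sigma=4.0, lam=0.1, weights=w,
                           intercept=b, objective=obj)
        back = MILESModel.from_json(model.to_json())
        assert score_recording(bags[2], back) == pytest.approx(
            score_recording(bags[2], model), rel=1e-12)


class TestTuning:
    def test_one_point_grid_returned(self):
        bags, subs, labels = toy_cohort(4, 3)
        sig, lam = tune_hyperparams(bags, subs, labels, sigma_grid=[4.0],
                                    lambda_grid=[0.1], n_splits=5, seed=0)
        assert (sig, lam) == (4.0, 0.1)

    def test_good_point_beats_degenerate_lambda(self):
        bags, subs, labels = toy_cohort(6, 5, shift=2.0, beats=12)
        sig, lam = tune_hyperparams(bags, subs, labels, sigma_grid=[8.0],
                                    lambda_grid=[0.01, 1e6], n_splits=8, seed=2)
        assert lam == 0.01

    def test_seeded_determinism(self):
        bags, subs, labels = toy_cohort(5, 4)
        a = tune_hyperparams(bags, subs, labels, n_splits=6, seed=11)
        b = tune_hyperparams(bags, subs, labels, n_splits=6, seed=11)
        assert a == b

    def test_empty_grid_rejected(self):
        bags, subs, labels = toy_cohort(4, 3)
        with pytest.raises(ValueError):
            tune_hyperparams(bags, subs, labels, sigma_grid=[], n_splits=3)

    def test_too_few_subjects_rejected(self):
        bags, subs, labels = toy_cohort(2, 1)
        with pytest.raises(ValueError):
            tune_hyperparams(bags, subs, labels, n_splits=3)
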