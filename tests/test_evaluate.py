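"""Evaluation harness: folds, ROC/AUC oracles, bootstrap CI, Youden."""

import numpy as np
import pytest

from ppgmiles.evaluate import (auc_ci_bootstrap, logo_folds, roc_curve_auc,
                               run_logo_cv, youden_threshold)
from ppgmiles.morphometry import RecordingBag

rng = np.random.default_rng(2024)


def brute_force_auc(pos, neg):
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def toy_bags(n_h=7, n_o=5, shift=1.5, beats=12, recs=(1, 2)):
    bags = []
    for i in range(n_h):
        for r in range(int(rng.integers(recs[0], recs[1] + 1))):
            bags.append(RecordingBag(rng.normal(0, 1, (beats, 42)),
                                     f"H{i}", f"H{i}_r{r}", "healthy"))
    for i in range(n_o):
        for r in range(int(rng.integers(recs[0], recs[1] + 1))):
            bags.append(RecordingBag(rng.normal(0, 1, (beats, 42)) + shift,
                                     f"O{i}", f"O{i}_r{r}", "oHCM"))
    return bags


class TestFolds:
    def test_one_fold_per_subject(self):
        subs = [f"S{i}" for i in range(83) for _ in range(2)]
        folds = logo_folds(subs)
        assert len(folds) == 83

    def test_partition_and_exclusion(self):
        subs = ["A", "A", "A", "B", "C", "C"]
        folds = logo_folds(subs)
        held = [h for _, h in folds]
        assert sorted(held) == ["A", "B", "C"]
        for train, h in folds:
            assert h not in train
            assert set(train) | {h} == {"A", "B", "C"}

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            logo_folds(["A", "B"])


class TestROC:
    def test_textbook_pairs(self):
        scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
        labels = ["oHCM"] * 3 + ["healthy"] * 3
        _, auc = roc_curve_auc(scores, labels)
        assert auc == pytest.approx(8 / 9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_pair_counting(self, seed):
        g = np.random.default_rng(seed)
        pos = np.round(g.normal(1, 1, 12), 1)   # rounding forces ties
        neg = np.round(g.normal(0, 1, 15), 1)
        scores = np.concatenate([pos, neg])
        labels = ["oHCM"] * 12 + ["healthy"] * 15
        _, auc = roc_curve_auc(scores, labels)
        assert auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    def test_perfect_separation(self):
        _, auc = roc_curve_auc([3, 2, 1, -1, -2], ["oHCM"] * 3 + ["healthy"] * 2)
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, auc = roc_curve_auc([1, 1, 1, 1], ["oHCM", "oHCM", "healthy", "healthy"])
        assert auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve_auc([1, 2], ["oHCM", "oHCM"])

    def test_invariant_under_monotone_transform(self):
        g = np.random.default_rng(8)
        s = g.normal(0, 1, 30)
        labels = ["oHCM" if v else "healthy" for v in g.random(30) > 0.5]
        _, a1 = roc_curve_auc(s, labels)
        _, a2 = roc_curve_auc(np.exp(3 * s), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestBootstrapCI:
    def test_perfect_separation_ci_is_unit(self):
        lo, hi = auc_ci_bootstrap([3, 2, 1, -1, -2, -3],
                                  ["oHCM"] * 3 + ["healthy"] * 3,
                                  n_boot=300, seed=4)
        assert (lo, hi) == (1.0, 1.0)

    def test_matches_independent_reimplementation(self):
        scores = [0.9, 0.8, 0.6, 0.7, 0.3, 0.2]
        labels = ["oHCM"] * 3 + ["healthy"] * 3
        lo, hi = auc_ci_bootstrap(scores, labels, n_boot=500, seed=31)
        # independent coding of the documented resampling scheme
        s = np.asarray(scores)
        pos, neg = s[:3], s[3:]
        r = np.random.default_rng(31)
        aucs = []
        for _ in range(500):
            p = pos[r.integers(0, 3, 3)]
            q = neg[r.integers(0, 3, 3)]
            aucs.append(brute_force_auc(p, q))
        elo, ehi = np.percentile(aucs, [2.5, 97.5])
        assert lo == pytest.approx(elo, abs=1e-12)
        assert hi == pytest.approx(ehi, abs=1e-12)

    def test_ci_brackets_point_estimate(self):
        g = np.random.default_rng(5)
        scores = np.concatenate([g.normal(1, 1, 10), g.normal(0, 1, 14)])
        labels = ["oHCM"] * 10 + ["healthy"] * 14
        _, auc = roc_curve_auc(scores, labels)
        lo, hi = auc_ci_bootstrap(scores, labels, n_boot=1000, seed=6)
        assert lo <= auc <= hi


class TestYouden:
    def test_tie_break_prefers_specificity(self):
        thr, sens, spec, conf = youden_threshold(
            [0.9, 0.8, 0.6, 0.7, 0.3, 0.2], ["oHCM"] * 3 + ["healthy"] * 3)
        assert sens == pytest.approx(2 / 3)
        assert spec == 1.0
        assert conf == (2, 1, 3, 0)

    def test_separable(self):
        thr, sens, spec, conf = youden_threshold(
            [2, 3, -1, -2], ["oHCM", "oHCM", "healthy", "healthy"])
        assert sens == 1.0 and spec == 1.0

    def test_degenerate_low_threshold_has_zero_specificity(self):
        scores = [1.0, 1.0, 1.0, 1.0]
        labels = ["oHCM", "oHCM", "healthy", "healthy"]
        thr, sens, spec, conf = youden_threshold(scores, labels)
        # all scores tied: either everything positive or everything negative
        assert sens + spec == 1.0

    def test_brute_force_over_cut_midpoints(self):
        g = np.random.default_rng(9)
        scores = np.round(g.normal(0, 1, 20), 2)
        labels = ["oHCM" if v else "healthy" for v in g.random(20) > 0.4]
        thr, sens, spec, _ = youden_threshold(scores, labels)
        s = np.asarray(scores)
        y = np.array([l == "oHCM" for l in labels])
        d = np.unique(s)
        cuts = np.concatenate([[d[0] - 1], (d[:-1] + d[1:]) / 2, [d[-1] + 1]])
        best = max((np.mean(s[y] >= c) + np.mean(s[~y] < c)) for c in cuts)
        assert sens + spec == pytest.approx(best, abs=1e-12)


class TestLogoCV:
    def test_no_leakage_and_every_recording_scored_once(self):
        bags = toy_bags()
        res = run_logo_cv(bags, pool_cap=300, n_inner_splits=5, n_boot=100, seed=1)
        assert len(res.recording_scores) == len(bags)
        assert res.recording_scores["recording_id"].is_unique
        subs = {b.subject_id for b in bags}
        assert set(res.subject_scores["subject_id"]) == subs

    def test_separable_cohort_high_auc(self):
        bags = toy_bags(shift=2.5)
        res = run_logo_cv(bags, pool_cap=300, n_inner_splits=5, n_boot=100, seed=2)
        assert res.c_statistic >= 0.95
        assert 0.0 <= res.ci_low <= res.c_statistic <= res.ci_high <= 1.0

    def test_null_cohort_near_chance(self):
        bags = toy_bags(shift=0.0)
        res = run_logo_cv(bags, pool_cap=200, n_inner_splits=4, n_boot=100, seed=3)
        assert 0.0 <= res.c_statistic <= 1.0
        tp, fn, tn, fp = res.confusion
        assert tp + fn == 5 and tn + fp == 7

    def test_single_class_rejected(self):
        bags = toy_bags(n_o=0)
        with pytest.raises(ValueError):
            run_logo_cv(bags, n_inner_splits=3)
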