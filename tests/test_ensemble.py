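"""Mean sensitivity, per-class metrics, and exhaustive ensemble subset search."""

import numpy as np
import pytest

from dermpipe import (
    PredictionTensor,
    SyntheticPredictionSpec,
    ensemble_average,
    exhaustive_subset_search,
    gen_prediction_tensor,
    mean_sensitivity,
    per_class_report,
    pool_best_last,
)


def recall_mean_oracle(y_true, y_pred_labels, n_classes):
    """Independent per-class-recall mean (plain loops)."""
    recalls = []
    for c in range(n_classes):
        tp = fn = 0
        for t, p in zip(y_true, y_pred_labels):
            if t == c:
                if p == c:
                    tp += 1
                else:
                    fn += 1
        if tp + fn:
            recalls.append(tp / (tp + fn))
    return sum(recalls) / len(recalls)


def auc_pair_oracle(y_bin, scores):
    """Rank-statistic AUC by O(n^2) pair counting."""
    pos = [s for s, y in zip(scores, y_bin) if y]
    neg = [s for s, y in zip(scores, y_bin) if not y]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMeanSensitivity:
    def test_all_correct_is_one(self):
        y = np.array([0, 1, 2, 2, 1])
        assert mean_sensitivity(y, y) == 1.0

    def test_hand_computed_two_class_case(self):
        y_true = np.array([0, 0, 1, 1])
        y_pred = np.array([0, 0, 1, 0])  # recalls 1.0 and 0.5
        assert mean_sensitivity(y_true, y_pred) == pytest.approx(0.75)

    def test_matches_recall_mean_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(20, 200))
            y = rng.integers(0, 9, size=n)
            probs = rng.dirichlet(np.ones(9), size=n)
            s = mean_sensitivity(y, probs, n_classes=9)
            oracle = recall_mean_oracle(y, probs.argmax(axis=1), 9)
            assert abs(s - oracle) < 1e-12

    def test_permutation_invariance(self, rng):
        y = rng.integers(0, 5, size=100)
        pred = rng.integers(0, 5, size=100)
        perm = rng.permutation(5)
        assert mean_sensitivity(perm[y], perm[pred]) == pytest.approx(
            mean_sensitivity(y, pred), abs=1e-15)

    def test_absent_class_excluded_with_warning(self):
        y = np.array([0, 0, 1])
        pred = np.array([0, 0, 1])
        with pytest.warns(UserWarning, match="absent"):
            s = mean_sensitivity(y, pred, n_classes=3)
        assert s == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mean_sensitivity(np.array([]), np.array([]))


class TestPerClassReport:
    def test_perfectly_separable_scores(self):
        y = np.array([0] * 10 + [1] * 10)
        probs = np.zeros((20, 2))
        probs[:10, 0] = 0.9
        probs[:10, 1] = 0.1
        probs[10:, 1] = 0.9
        probs[10:, 0] = 0.1
        rep = per_class_report(y, probs)
        assert rep.auc == [1.0, 1.0]
        assert rep.auc_above_80_sens == [pytest.approx(1.0), pytest.approx(1.0)]
        assert rep.sensitivity == [1.0, 1.0]

    def test_chance_scores_have_half_auc(self, rng):
        n = 4000
        y = rng.integers(0, 3, size=n)
        probs = rng.dirichlet(np.ones(3), size=n)
        rep = per_class_report(y, probs)
        for a in rep.auc:
            assert abs(a - 0.5) < 0.03

    def test_auc_matches_pair_counting_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(10, 40))
            y = rng.integers(0, 3, size=n)
            while len(set(y)) < 2:
                y = rng.integers(0, 3, size=n)
            probs = rng.dirichlet(np.ones(3), size=n)
            rep = per_class_report(y, probs)
            for c in range(3):
                pos = (y == c).astype(int)
                if 0 < pos.sum() < n:
                    assert rep.auc[c] == pytest.approx(
                        auc_pair_oracle(pos, probs[:, c]), abs=1e-12)

    def test_single_class_truth_reports_missing_auc(self):
        y = np.zeros(5, dtype=int)
        probs = np.tile([0.6, 0.4], (5, 1))
        rep = per_class_report(y, probs)
        assert rep.auc == [None, None]


def small_tensor(rng, n_configs=3, n_folds=2, n=30):
    tensor, _ = gen_prediction_tensor(
        SyntheticPredictionSpec(n_configs=n_configs, n_folds=n_folds,
                                n_images_per_fold=n, skill=0.4,
                                seed=int(rng.integers(2**31))))
    return tensor


class TestEnsembleAverage:
    def test_singleton_is_identity(self, rng):
        t = small_tensor(rng)
        avg = ensemble_average(t, [1])
        for j in range(t.n_folds):
            assert np.array_equal(avg[j], t.probs[1][j])

    def test_duplicate_configs_average_to_either(self, rng):
        t = small_tensor(rng, n_configs=1)
        twin = PredictionTensor(probs=[t.probs[0], [p.copy() for p in t.probs[0]]],
                                labels=t.labels)
        avg = ensemble_average(twin, [0, 1])
        for j in range(twin.n_folds):
            assert np.allclose(avg[j], t.probs[0][j])

    def test_matches_nested_mean_oracle(self, rng):
        t = small_tensor(rng, n_configs=4)
        subset = [0, 2, 3]
        avg = ensemble_average(t, subset)
        for j in range(t.n_folds):
            expected = sum(t.probs[i][j] for i in subset) / len(subset)
            assert np.allclose(avg[j], expected, atol=1e-12)
            assert np.allclose(avg[j].sum(axis=1), 1.0, atol=1e-9)

    def test_empty_subset_rejected(self, rng):
        with pytest.raises(ValueError):
            ensemble_average(small_tensor(rng), [])


class TestSubsetSearch:
    def test_single_config_selected(self, rng):
        sel = exhaustive_subset_search(small_tensor(rng, n_configs=1))
        assert sel.subset == (0,)
        assert len(sel.search_log) == 1

    def test_all_subsets_enumerated(self, rng):
        sel = exhaustive_subset_search(small_tensor(rng, n_configs=4))
        assert len(sel.search_log) == 2**4 - 1

    def test_optimal_beats_average_and_singletons(self, rng):
        t = small_tensor(rng, n_configs=4, n=60)
        sel = exhaustive_subset_search(t)
        labels = t.pooled_labels()
        s_full = mean_sensitivity(labels, np.concatenate(ensemble_average(t, range(4))))
        assert sel.mean_sensitivity >= s_full
        for i in range(4):
            s_i = mean_sensitivity(labels, np.concatenate(ensemble_average(t, [i])))
            assert sel.mean_sensitivity >= s_i

    def test_strong_configuration_always_selected(self):
        tensor, _ = gen_prediction_tensor(
            SyntheticPredictionSpec(n_configs=4, n_folds=3, n_images_per_fold=60,
                                    skill=[0.9, 0.0, 0.0, 0.0], seed=11))
        sel = exhaustive_subset_search(tensor)
        assert 0 in sel.subset

    def test_deterministic(self, rng):
        t = small_tensor(rng, n_configs=4)
        assert exhaustive_subset_search(t).subset == exhaustive_subset_search(t).subset

    def test_cap_enforced(self, rng):
        t = small_tensor(rng, n_configs=3)
        with pytest.raises(ValueError, match="max_configs"):
            exhaustive_subset_search(t, max_configs=2)


class TestPoolBestLast:
    def test_identical_tensors_reproduce_selection_prediction(self, rng):
        t = small_tensor(rng, n_configs=3)
        sel = exhaustive_subset_search(t)
        final = pool_best_last(sel, t, t)
        for j in range(t.n_folds):
            assert np.allclose(final[j], sel.predictions[j], atol=1e-12)
            assert np.allclose(final[j].sum(axis=1), 1.0, atol=1e-9)

    def test_matches_bruteforce_mean_over_all_models(self, rng):
        best = small_tensor(rng, n_configs=3)
        last = PredictionTensor(
            probs=[[np.roll(p, 1, axis=1) for p in cfg] for cfg in best.probs],
            labels=best.labels)
        sel = exhaustive_subset_search(best)
        final = pool_best_last(sel, best, last)
        m = best.n_folds
        for j in range(m):
            arrays = [best.probs[i][j] for i in sel.subset] + \
                     [last.probs[i][j] for i in sel.subset]
            assert np.allclose(final[j], np.mean(arrays, axis=0), atol=1e-12)

    def test_misaligned_tensors_rejected(self, rng):
        best = small_tensor(rng, n_configs=2)
        bad_labels = [l + 1 for l in best.labels]
        last = PredictionTensor(probs=[[p.copy() for p in c] for c in best.probs],
                                labels=[l % 9 for l in bad_labels])
        sel = exhaustive_subset_search(best)
        with pytest.raises(ValueError, match="misaligned"):
            pool_best_last(sel, best, last)
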