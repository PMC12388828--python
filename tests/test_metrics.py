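"""Evaluation metrics, concordance, ROC, combination search and PCA."""

from itertools import combinations as iter_combinations

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from rnaensemble.metrics import (
    combination_search,
    confusion,
    evaluate,
    inf_score,
    jaccard_distance,
    pairwise_concordance,
    pca_error_embedding,
    precision_recall_f1,
    roc_points,
)
from rnaensemble.structure_io import ContactMap

from conftest import random_contact_map


def brute_counts(pred: ContactMap, truth: ContactMap):
    """Oracle: explicit loop over every unordered cell."""
    tp = fp = tn = fn = 0
    for i in range(pred.n):
        for j in range(i + 1, pred.n):
            p, t = (i, j) in pred.pairs, (i, j) in truth.pairs
            tp += p and t
            fp += p and not t
            fn += t and not p
            tn += not p and not t
    return tp, fp, tn, fn


class TestConfusion:
    def test_hand_example(self):
        truth = ContactMap(12, frozenset({(1, 10), (2, 9)}))
        pred = ContactMap(12, frozenset({(1, 10), (3, 8)}))
        assert confusion(pred, truth) == (1, 1, 63, 1)

    def test_perfect_and_empty(self, rng):
        cm = random_contact_map(rng, 20)
        assert confusion(cm, cm)[1] == confusion(cm, cm)[3] == 0
        empty = ContactMap(20)
        tp, fp, tn, fn = confusion(empty, cm)
        assert (tp, fp, fn) == (0, 0, len(cm.pairs))

    def test_counts_match_cell_enumeration_and_sum(self, rng):
        for _ in range(100):
            n = int(rng.integers(8, 40))
            pred, truth = random_contact_map(rng, n), random_contact_map(rng, n)
            counts = confusion(pred, truth)
            assert counts == brute_counts(pred, truth)
            assert sum(counts) == n * (n - 1) // 2


class TestScores:
    def test_precision_recall_f1_values(self):
        assert precision_recall_f1((1, 1, 63, 1)) == (0.5, 0.5, 0.5)
        assert precision_recall_f1((5, 0, 10, 0)) == (1.0, 1.0, 1.0)
        assert precision_recall_f1((0, 0, 10, 0)) == (0.0, 0.0, 0.0)

    def test_inf_hand_example(self):
        assert inf_score((3, 1, 20, 1)) == pytest.approx(59 / 84, abs=1e-9)

    def test_inf_zero_factor_convention(self):
        assert inf_score((0, 0, 5, 5)) == 0.0

    def test_inf_equals_mcc(self, rng):
        """INF coincides with an independently computed MCC."""
        for _ in range(300):
            tp, fp, tn, fn = (int(x) for x in rng.integers(0, 30, size=4))
            labels = [1] * (tp + fn) + [0] * (fp + tn)
            preds = [1] * tp + [0] * fn + [1] * fp + [0] * tn
            if len(set(labels)) < 2 or len(set(preds)) < 2:
                continue
            assert inf_score((tp, fp, tn, fn)) == pytest.approx(
                matthews_corrcoef(labels, preds), abs=1e-12
            )

    def test_evaluate_bundles_counts_and_scores(self, rng):
        pred, truth = random_contact_map(rng, 30), random_contact_map(rng, 30)
        r = evaluate(pred, truth)
        assert (r.TP, r.FP, r.TN, r.FN) == confusion(pred, truth)
        assert r.f1 == precision_recall_f1(confusion(pred, truth))[2]


class TestJaccard:
    def test_examples(self):
        A = ContactMap(12, frozenset({(1, 5), (2, 8)}))
        B = ContactMap(12, frozenset({(1, 5), (3, 9)}))
        assert jaccard_distance(A, B) == pytest.approx(2 / 3)
        assert jaccard_distance(A, A) == 0.0
        C = ContactMap(12, frozenset({(0, 11)}))
        assert jaccard_distance(A, C) == 1.0
        assert jaccard_distance(ContactMap(5), ContactMap(5)) == 0.0

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 30))
            A, B, C = (random_contact_map(rng, n) for _ in range(3))
            dab, dba = jaccard_distance(A, B), jaccard_distance(B, A)
            assert dab == dba
            assert jaccard_distance(A, A) == 0.0
            assert dab <= jaccard_distance(A, C) + jaccard_distance(C, B) + 1e-12


class TestPairwiseConcordance:
    def test_matches_direct_loop(self, rng):
        preds = {
            name: [random_contact_map(rng, 20) for _ in range(30)]
            for name in ("a", "b", "c")
        }
        D = pairwise_concordance(preds)
        assert np.allclose(D.values, D.values.T, atol=1e-15)
        assert np.all(np.diag(D.values) == 0)
        direct = np.mean(
            [jaccard_distance(x, y) for x, y in zip(preds["a"], preds["b"])]
        )
        assert D.loc["a", "b"] == pytest.approx(direct)


class TestRoc:
    def test_perfect_scores_area_one(self, rng):
        truth = random_contact_map(rng, 20)
        _, _, auc = roc_points([truth.matrix()], [truth])
        assert auc == pytest.approx(1.0)

    def test_constant_scores_area_half(self, rng):
        truth = random_contact_map(rng, 20)
        _, _, auc = roc_points([np.full((20, 20), 0.5)], [truth])
        assert auc == pytest.approx(0.5)

    def test_matches_sklearn_on_random_scores(self, rng):
        truth = random_contact_map(rng, 30)
        Y = rng.random((30, 30))
        _, _, auc = roc_points([Y], [truth])
        iu = np.triu_indices(30, 1)
        ref = roc_auc_score(truth.matrix()[iu], (0.5 * (Y + Y.T))[iu])
        assert auc == pytest.approx(ref, abs=1e-12)


class TestCombinationSearch:
    def test_subset_enumeration_and_nested_maxima(self, small_benchmark):
        from rnaensemble.trainer import TrainConfig

        records, stacks = small_benchmark
        sub = [s.subset([0, 1, 2]) for s in stacks]
        report = combination_search(
            records, sub, cfg=TrainConfig(epochs=2, seed=0)
        )
        assert len(report.per_subset) == 7
        best = report.per_size["best_median_f1"].tolist()
        assert best == sorted(best)

    def test_refuses_exponential_blowup(self, small_benchmark):
        records, stacks = small_benchmark
        wide = [
            type(s)(tuple(f"l{k}" for k in range(11)), np.repeat(s.A[:1], 11, axis=0))
            for s in stacks[:4]
        ]
        with pytest.raises(ValueError, match="force"):
            combination_search(records[:4], wide)


class TestPcaEmbedding:
    def test_identical_algorithms_identical_coords(self, rng):
        truths = [random_contact_map(rng, 15) for _ in range(10)]
        same = [random_contact_map(rng, 15) for _ in range(10)]
        coords = pca_error_embedding({"a": same, "b": same, "c": truths}, truths)
        assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-9)

    def test_truth_algorithm_has_zero_features(self, rng):
        truths = [random_contact_map(rng, 15) for _ in range(5)]
        other = [random_contact_map(rng, 15) for _ in range(5)]
        coords = pca_error_embedding({"truth": truths, "other": other}, truths)
        # with two algorithms PC1 separates them; the truth row is the
        # zero-error feature vector, so the two rows are symmetric about 0
        assert np.allclose(coords.values.sum(axis=0), 0.0, atol=1e-9)

    def test_pca_distances_track_jaccard_distances(self, small_benchmark):
        """Error-map PCA and Jaccard concordance rank learner pairs alike."""
        from scipy.stats import spearmanr

        records, stacks = small_benchmark
        names = stacks[0].learner_names
        preds = {
            name: [s.slice_map(v) for s in stacks] for v, name in enumerate(names)
        }
        truths = [r.structure for r in records]
        D = pairwise_concordance(preds)
        coords = pca_error_embedding(preds, truths)
        jac, euc = [], []
        for a, b in iter_combinations(names, 2):
            jac.append(D.loc[a, b])
            euc.append(np.linalg.norm(coords.loc[a] - coords.loc[b]))
        rho, _ = spearmanr(jac, euc)
        assert rho > 0
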