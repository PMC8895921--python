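"""Ranking metrics vs brute-force oracles, thresholding, pair labeling,
permutation test."""

import numpy as np
import pandas as pd
import pytest

from ddisig import (
    TripletDataset,
    auc,
    aupr,
    label_pairs_by_count,
    mean_side_effects_per_pair,
    optimal_threshold,
    per_side_effect_report,
    permutation_test,
)


def _auc_oracle(scores, labels):
    """Mann-Whitney pairwise comparisons; lower distance ranks first."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p < n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _aupr_oracle(scores, labels):
    """Step-wise precision-recall integration over distinct thresholds."""
    order = np.argsort(scores, kind="stable")
    s, y = scores[order], labels[order]
    n_pos = y.sum()
    ap, tp, fp, prev_recall = 0.0, 0, 0, 0.0
    k = 0
    while k < len(s):
        # advance over a tie block of equal scores
        j = k
        while j < len(s) and s[j] == s[k]:
            tp += y[j]
            fp += 1 - y[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        k = j
    return ap


class TestAUC:
    def test_perfect_separation(self):
        s = np.array([0.1, 0.2, 0.9, 1.5])
        y = np.array([1, 1, 0, 0])
        assert auc(s, y) == 1.0

    def test_interleaved_hand_case(self):
        # positives at distances {1,3}, negative at {2}: one win, one loss
        assert auc(np.array([1.0, 3.0, 2.0]), np.array([1, 1, 0])) == 0.5

    def test_label_inversion_complements(self):
        rng = np.random.default_rng(0)
        s = rng.random(30)
        y = (rng.random(30) < 0.4).astype(int)
        assert auc(s, y) == pytest.approx(1 - auc(s, 1 - y))

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc(np.array([1.0, 2.0]), np.array([1, 1]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = rng.integers(0, 12, n).astype(float)  # heavy ties
        labels = (rng.random(n) < 0.4).astype(int)
        if len(np.unique(labels)) < 2:
            labels[:2] = [0, 1]
        assert auc(scores, labels) == pytest.approx(_auc_oracle(scores, labels))


class TestAUPR:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_step_integration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(10, 200))
        scores = np.round(rng.random(n), 2)
        labels = (rng.random(n) < 0.3).astype(int)
        if len(np.unique(labels)) < 2:
            labels[:2] = [0, 1]
        assert aupr(scores, labels) == pytest.approx(_aupr_oracle(scores, labels))

    def test_perfect_ranking_gives_unit_area(self):
        assert aupr(np.array([0.1, 0.2, 5.0, 9.0]), np.array([1, 1, 0, 0])) == 1.0


class TestOptimalThreshold:
    def test_separable_data_gets_perfect_sensitivity_specificity(self):
        thr, sens, spec = optimal_threshold(
            np.array([0.5, 0.7, 2.0, 3.0]), np.array([1, 1, 0, 0])
        )
        assert (sens, spec) == (1.0, 1.0)
        assert 0.7 < thr < 2.0

    def test_matches_exhaustive_scan(self):
        scores = np.array([1.0, 3.0, 2.0, 4.0])
        labels = np.array([1, 1, 0, 0])
        thr, sens, spec = optimal_threshold(scores, labels)
        uniq = np.unique(scores)
        best_j = max(
            np.mean(scores[labels == 1] <= t) + np.mean(scores[labels == 0] > t) - 1
            for t in (uniq[:-1] + uniq[1:]) / 2
        )
        assert sens + spec - 1 == pytest.approx(best_j)

    def test_identical_scores_degenerate(self):
        thr, sens, spec = optimal_threshold(np.ones(6), np.array([1, 0, 1, 0, 1, 0]))
        assert thr == 1.0
        assert sens + spec - 1 == pytest.approx(0.0)


class TestPerSideEffectReport:
    def _dataset(self):
        rows = []
        # SE "good": separable; SE "coin": exactly interleaved
        for k in range(4):
            rows.append((f"a{k}", f"b{k}", "good", 1))
            rows.append((f"c{k}", f"d{k}", "good", 0))
            rows.append((f"a{k}", f"e{k}", "coin", 1))
            rows.append((f"c{k}", f"f{k}", "coin", 0))
        ds = TripletDataset(pd.DataFrame(rows, columns=["drug_i", "drug_j", "side_effect", "label"]))
        f = ds.frame
        scores = np.zeros(len(f))
        good = f["side_effect"] == "good"
        scores[good.to_numpy()] = np.where(f.loc[good, "label"] == 1, 0.1, 0.9)
        coin = ~good.to_numpy()
        scores[coin] = np.tile([0.4, 0.4], 4)  # uninformative: AUC 0.5
        return ds, scores

    def test_macro_average_of_mixed_side_effects(self):
        ds, scores = self._dataset()
        rows, macro = per_side_effect_report(scores, ds)
        assert {r.side_effect for r in rows} == {"good", "coin"}
        assert macro["auc"] == pytest.approx(0.75)
        assert macro["n_side_effects"] == 2

    def test_single_class_side_effect_excluded_with_warning(self):
        ds, scores = self._dataset()
        extra = pd.concat([ds.frame, pd.DataFrame(
            [("x1", "x2", "lonely", 1)], columns=ds.frame.columns)], ignore_index=True)
        ds2 = TripletDataset(extra)
        with pytest.warns(UserWarning, match="lonely"):
            rows, macro = per_side_effect_report(
                np.concatenate([scores, [0.2]]), ds2
            )
        assert macro["n_side_effects"] == 2

    def test_macro_invariant_to_side_effect_naming_order(self):
        ds, scores = self._dataset()
        renamed = ds.frame.replace({"good": "zzz"})
        _, macro_a = per_side_effect_report(scores, ds)
        _, macro_b = per_side_effect_report(scores, TripletDataset(renamed))
        assert macro_a["auc"] == pytest.approx(macro_b["auc"])


class TestPairLabeling:
    def _predictions(self, n_se):
        return pd.DataFrame({
            "drug_i": ["a"] * n_se, "drug_j": ["b"] * n_se,
            "side_effect": [f"se{k}" for k in range(n_se)],
        })

    def test_strict_cutoff_boundary(self):
        assert label_pairs_by_count(self._predictions(70), cutoff=65).labels.iloc[0] == 1
        assert label_pairs_by_count(self._predictions(65), cutoff=65).labels.iloc[0] == 0
        assert label_pairs_by_count(self._predictions(1), cutoff=65).labels.iloc[0] == 0

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError):
            label_pairs_by_count(self._predictions(1), cutoff=-1)

    def test_raising_cutoff_never_adds_positives(self):
        rng = np.random.default_rng(0)
        rows = []
        for p in range(20):
            for k in range(int(rng.integers(1, 100))):
                rows.append((f"x{p}", f"y{p}", f"se{k}"))
        preds = pd.DataFrame(rows, columns=["drug_i", "drug_j", "side_effect"])
        prev = None
        for cutoff in (0, 10, 40, 80):
            pos = set(label_pairs_by_count(preds, cutoff).labels.pipe(
                lambda s: s[s == 1].index))
            if prev is not None:
                assert pos <= prev
            prev = pos

    def test_pair_order_ignored(self):
        preds = pd.DataFrame({
            "drug_i": ["a", "b"], "drug_j": ["b", "a"], "side_effect": ["s1", "s2"],
        })
        counts = label_pairs_by_count(preds, cutoff=1).counts
        assert len(counts) == 1
        assert counts.iloc[0] == 2


class TestMeanSideEffectsPerPair:
    def test_thirty_positives_over_ten_pairs(self):
        rows = [(f"a{p}", f"b{p}", f"se{k}", 1) for p in range(10) for k in range(3)]
        ds = TripletDataset(pd.DataFrame(rows, columns=["drug_i", "drug_j", "side_effect", "label"]))
        assert mean_side_effects_per_pair(ds) == 3.0

    def test_single_triplet(self):
        ds = TripletDataset(pd.DataFrame(
            [("a", "b", "r", 1)], columns=["drug_i", "drug_j", "side_effect", "label"]))
        assert mean_side_effects_per_pair(ds) == 1.0

    def test_empty_positives_raise(self):
        ds = TripletDataset(pd.DataFrame(
            [("a", "b", "r", 0)], columns=["drug_i", "drug_j", "side_effect", "label"]))
        with pytest.raises(ValueError):
            mean_side_effects_per_pair(ds)


class TestPermutationTest:
    def test_observation_above_all_nulls_reports_floor_p(self):
        pool = list(range(200))
        hits = set(range(10))
        p, null = permutation_test(
            observed_hits=10, candidate_pool=pool,
            hit_predicate=lambda x: x in hits, sample_size=10,
            n_perm=2000, seed=0,
        )
        assert null.max() < 10
        assert p == pytest.approx(1 / 2000)

    def test_worst_case_observation_gives_p_one(self):
        pool = list(range(50))
        p, _ = permutation_test(0, pool, lambda x: x < 25, sample_size=30,
                                n_perm=500, seed=1)
        assert p == 1.0

    def test_null_distribution_reproducible(self):
        pool = list(range(60))
        _, a = permutation_test(3, pool, lambda x: x % 3 == 0, 10, n_perm=300, seed=5)
        _, b = permutation_test(3, pool, lambda x: x % 3 == 0, 10, n_perm=300, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_oversized_sample_rejected(self):
        with pytest.raises(ValueError):
            permutation_test(0, [1, 2], lambda x: True, sample_size=5)
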