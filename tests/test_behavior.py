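import numpy as np
import pandas as pd
import pytest

from sounddissim import behavior as B
from sounddissim.dissimilarity import DissimMatrix, RatingTable
from sounddissim.raters import RaterModel, counterbalance_lists, simulate_ratings
from conftest import make_synthetic_features


def _conf(trials, items, submap=None):
    df = pd.DataFrame(trials, columns=["participant", "stimulus", "response"])
    return B.ConfusionTable(df, items, submap or {})


ITEMS = ["a1", "a2", "b1", "b2"]
SUBMAP = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}


class TestAccuracy:
    def test_diagonal_only_counts(self):
        trials = [("p1", i, i) for i in ITEMS for _ in range(3)]
        acc = B.item_accuracy(_conf(trials, ITEMS))
        assert (acc.accuracy == 1.0).all()

    def test_partial_accuracy(self):
        trials = ([("p1", "a1", "a1")] * 7 + [("p1", "a1", "a2")] * 3
                  + [("p1", i, i) for i in ITEMS[1:]])
        acc = B.item_accuracy(_conf(trials, ITEMS))
        assert acc.query("item == 'a1'").accuracy.iloc[0] == pytest.approx(0.7)

    def test_missing_presentations_rejected(self):
        trials = [("p1", "a1", "a1")]
        with pytest.raises(B.BehaviorError, match="no presentations"):
            B.item_accuracy(_conf(trials, ITEMS))


class TestRecoding:
    def test_within_subcategory_confusions_become_correct(self):
        trials = [("p1", "a1", "a2")] * 5 + [("p1", i, i) for i in ITEMS[1:]]
        conf = _conf(trials, ITEMS, SUBMAP)
        recoded = B.recode_subcategory(conf)
        assert recoded.query("item == 'a1'").accuracy.iloc[0] == 1.0

    def test_recoded_never_below_raw(self):
        rng = np.random.default_rng(0)
        trials = [(f"p{p}", s, rng.choice(ITEMS))
                  for p in range(3) for s in ITEMS for _ in range(5)]
        conf = _conf(trials, ITEMS, SUBMAP)
        raw = B.item_accuracy(conf).set_index(["participant", "item"])
        rec = B.recode_subcategory(conf).set_index(["participant", "item"])
        assert (rec.accuracy >= raw.accuracy - 1e-12).all()

    def test_unmapped_item_rejected(self):
        trials = [("p1", i, i) for i in ITEMS]
        with pytest.raises(B.BehaviorError, match="subcategory map"):
            B.recode_subcategory(_conf(trials, ITEMS, {"a1": "A"}))


class TestChanceTests:
    def _acc_frame(self, values_by_item, n_participants=10):
        rows = [(f"p{p}", item, v[p]) for item, v in values_by_item.items()
                for p in range(n_participants)]
        return pd.DataFrame(rows, columns=["participant", "item", "accuracy"])

    def test_perfect_accuracy_minimal_p(self):
        df = self._acc_frame({"x": [1.0] * 10, "y": [1.0] * 10})
        out = B.accuracy_vs_chance(df, 1 / 36)
        # minimal attainable one-sided exact p for n=10: 1/2^10
        assert np.allclose(out.p, 1 / 2**10)

    def test_symmetric_around_chance_p_near_half(self):
        rng = np.random.default_rng(1)
        vals = 0.5 + rng.permutation(np.r_[np.linspace(-0.3, 0.3, 40)])
        df = self._acc_frame({"x": list(vals)}, n_participants=40)
        out = B.accuracy_vs_chance(df, 0.5)
        assert 0.2 < out.p.iloc[0] < 0.8

    def test_single_participant_rejected(self):
        df = self._acc_frame({"x": [1.0]}, n_participants=1)
        with pytest.raises(B.BehaviorError):
            B.accuracy_vs_chance(df, 1 / 36)

    def test_all_at_chance_flagged(self):
        df = self._acc_frame({"x": [0.5] * 10, "y": [1.0] * 10})
        out = B.accuracy_vs_chance(df, 0.5)
        assert out.query("item == 'x'").flag.iloc[0] != ""
        assert np.isnan(out.query("item == 'x'").p.iloc[0])


class TestConfusionDissim:
    def _rating_matrix(self, values, items):
        return DissimMatrix(items, values, "behavioral_rating",
                            value_range=(1.0, 9.0))

    def test_confusions_decreasing_in_distance_give_negative_tau(self):
        rng = np.random.default_rng(2)
        n = 8
        items = [f"i{k}" for k in range(n)]
        R = rng.uniform(1, 9, (n, n))
        R = 0.5 * (R + R.T)
        trials = []
        for s in range(n):
            for _ in range(50):
                w = np.exp(-0.8 * R[s])
                trials.append(("p1", items[s],
                               items[rng.choice(n, p=w / w.sum())]))
        conf = _conf(trials, items)
        tau = B.confusion_dissim_correlation(conf, self._rating_matrix(R, items))
        assert tau < -0.3

    def test_self_correlation_equals_one(self):
        n = 6
        items = [f"i{k}" for k in range(n)]
        rng = np.random.default_rng(3)
        C = rng.integers(1, 10, (n, n)).astype(float)
        C = 0.5 * (C + C.T)
        conf = B.ConfusionTable(
            pd.DataFrame([("p1", items[i], items[j], C[i, j])
                          for i in range(n) for j in range(n)],
                         columns=["participant", "stimulus", "response",
                                  "count"]), items)
        # rating matrix equal to the confusion rates: tau = 1 over the
        # off-diagonal cells (restricted mode leaves both untransformed)
        rates = C / C.sum(axis=1, keepdims=True)
        rates = 0.5 * (rates + rates.T)
        ratings = self._rating_matrix(rates, items)
        ratings.value_range = (rates.min(), rates.max())
        tau = B.confusion_dissim_correlation(conf, ratings, mode="restricted")
        assert tau == pytest.approx(1.0)

    def test_restricted_mode_rejects_diagonal_only(self):
        items = ["x", "y"]
        trials = [("p1", i, i) for i in items for _ in range(3)]
        conf = _conf(trials, items)
        ratings = self._rating_matrix(np.array([[1.0, 5.0], [5.0, 1.0]]), items)
        with pytest.raises(B.BehaviorError, match="no off-diagonal"):
            B.confusion_dissim_correlation(conf, ratings, mode="restricted")

    def test_item_permutation_invariance(self):
        rng = np.random.default_rng(4)
        n = 6
        items = [f"i{k}" for k in range(n)]
        trials = [("p1", items[s], items[rng.integers(n)])
                  for s in range(n) for _ in range(30)]
        R = rng.uniform(1, 9, (n, n))
        tau1 = B.confusion_dissim_correlation(
            _conf(trials, items), self._rating_matrix(R, items))
        perm = rng.permutation(n)
        items_p = [items[k] for k in perm]
        conf_p = _conf(trials, items_p)
        tau2 = B.confusion_dissim_correlation(
            conf_p, self._rating_matrix(R[np.ix_(perm, perm)], items_p))
        assert tau1 == pytest.approx(tau2)


class TestReliability:
    def test_spearman_brown_formula(self):
        assert B.spearman_brown(0.5) == pytest.approx(2 / 3)
        assert B.spearman_brown(0.0) == 0.0
        assert B.spearman_brown(1.0) == 1.0

    def test_noise_free_raters_fully_reliable(self):
        feats = make_synthetic_features(n_items=8, seed=0)
        model = RaterModel(response_noise_sd=0.0, participant_criterion_sd=0.0)
        table = simulate_ratings(feats, model, 8, seed=0)
        assert B.split_half_reliability(table, n_splits=10, seed=1) == 1.0

    def test_noisy_raters_less_reliable_than_noise_free(self):
        feats = make_synthetic_features(n_items=8, seed=0)
        noisy = RaterModel(response_noise_sd=3.0, participant_criterion_sd=1.0)
        table = simulate_ratings(feats, noisy, 8, seed=0)
        r = B.split_half_reliability(table, n_splits=20, seed=1)
        assert r < 1.0

    def test_too_few_participants_rejected(self):
        feats = make_synthetic_features(n_items=6, seed=0)
        table = simulate_ratings(feats, RaterModel(), 2, seed=0)
        with pytest.raises(B.BehaviorError):
            B.split_half_reliability(table)
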