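"""Training-set assembly, margin classifier, ranking, selection, metrics."""

import numpy as np
import pytest

from lmcenm import classifier as clf
from lmcenm.contacts import BREAKING, MAINTAINED, TransitionMap


def toy_tmap(n, breaking, maintained):
    labels = np.zeros((n, n), dtype=int)
    for i, j in breaking:
        labels[i, j] = labels[j, i] = BREAKING
    for i, j in maintained:
        labels[i, j] = labels[j, i] = MAINTAINED
    return TransitionMap(cutoff=10.0, strain_threshold=0.09, labels=labels,
                         strain=np.full((n, n), np.nan),
                         matched=np.arange(n))


def toy_protein(pid, n_break, n_maint, n_features=6, seed=0, n=200):
    """Linearly separable toy: feature 0 carries the label."""
    rng = np.random.default_rng(seed)
    breaking = [(k, k + 4) for k in range(n_break)]
    maintained = [(k, k + 5) for k in range(n_maint)]
    tmap = toy_tmap(n, breaking, maintained)
    pairs = breaking + maintained
    vals = rng.normal(size=(len(pairs), n_features))
    vals[: n_break, 0] = rng.normal(3.0, 0.3, n_break)
    vals[n_break:, 0] = rng.normal(-3.0, 0.3, n_maint)
    avail = np.ones_like(vals, dtype=bool)
    return (pid, pairs, vals, avail, tmap)


class TestBuildTrainingSet:
    def test_undersampling_ratio(self):
        entry = toy_protein("p1", 10, 60)
        tset = clf.build_training_set([entry], ratio=3.0, seed=0)
        assert (tset.labels == 1).sum() == 10
        assert (tset.labels == 0).sum() == 30

    def test_cap_at_availability(self):
        entry = toy_protein("p1", 10, 20)
        tset = clf.build_training_set([entry], ratio=3.0, seed=0)
        assert (tset.labels == 1).sum() == 10
        assert (tset.labels == 0).sum() == 20

    def test_seed_changes_negatives_not_positives(self):
        entry = toy_protein("p1", 10, 60)
        a = clf.build_training_set([entry], seed=1)
        b = clf.build_training_set([entry], seed=2)
        pos_a = {p for p, y in zip(a.pairs, a.labels) if y == 1}
        pos_b = {p for p, y in zip(b.pairs, b.labels) if y == 1}
        assert pos_a == pos_b
        neg_a = {p for p, y in zip(a.pairs, a.labels) if y == 0}
        neg_b = {p for p, y in zip(b.pairs, b.labels) if y == 0}
        assert neg_a != neg_b

    def test_protein_without_positives_skipped(self):
        entry = toy_protein("p1", 0, 40)
        with pytest.raises(ValueError, match="empty training set"):
            clf.build_training_set([entry])

    def test_per_protein_subseed_stability(self):
        assert clf.protein_seed(7, "prot") == clf.protein_seed(7, "prot")
        assert clf.protein_seed(7, "prot") != clf.protein_seed(8, "prot")


class TestTrain:
    def test_separable_toy_perfect_training_accuracy(self):
        entry = toy_protein("p1", 10, 30)
        tset = clf.build_training_set([entry], seed=0)
        model = clf.train(tset, cost=100.0, gamma="scale")
        scores = model.predict_proba(tset.values, tset.available)
        pred = (scores > 0.5).astype(int)
        assert (pred == tset.labels).mean() == 1.0

    def test_shuffled_labels_give_chance_auroc(self):
        rng = np.random.default_rng(3)
        entry = toy_protein("p1", 40, 40, seed=3)
        tset = clf.build_training_set([entry], ratio=1.0, seed=3)
        shuffled = rng.permutation(tset.labels)
        tset.labels = shuffled
        model = clf.train(tset, cost=1.0, gamma="scale")
        # evaluate on a freshly generated batch from the same null generator
        from sklearn.metrics import roc_auc_score

        test = toy_protein("p2", 40, 40, seed=4)
        x = test[2]
        y = rng.permutation(np.array([1] * 40 + [0] * 40))
        auroc = roc_auc_score(y, model.predict_proba(x, test[3]))
        assert auroc == pytest.approx(0.5, abs=0.15)

    def test_single_class_rejected(self):
        entry = toy_protein("p1", 10, 30)
        tset = clf.build_training_set([entry], seed=0)
        tset.labels[:] = 1
        with pytest.raises(ValueError, match="degenerate labels"):
            clf.train(tset)

    def test_model_round_trip(self, tmp_path):
        entry = toy_protein("p1", 10, 30)
        tset = clf.build_training_set([entry], seed=0)
        model = clf.train(tset, gamma="scale")
        path = tmp_path / "model.pkl"
        model.save(path)
        back = clf.BreakingContactModel.load(path)
        np.testing.assert_array_equal(
            back.predict_proba(tset.values, tset.available),
            model.predict_proba(tset.values, tset.available),
        )


class TestRanking:
    def test_empty_ranking(self):
        entry = toy_protein("p1", 10, 30)
        model = clf.train(clf.build_training_set([entry], seed=0), gamma="scale")
        ranked = clf.rank_contacts(model, [], np.zeros((0, 6)),
                                   np.zeros((0, 6), bool))
        assert len(ranked) == 0

    def test_scores_sorted_and_bounded(self):
        entry = toy_protein("p1", 10, 30)
        tset = clf.build_training_set([entry], seed=0)
        model = clf.train(tset, gamma="scale")
        _, pairs, vals, avail, _ = entry
        ranked = clf.rank_contacts(model, pairs, vals, avail)
        assert np.all(np.diff(ranked.scores) <= 1e-12)
        assert np.all((ranked.scores >= 0) & (ranked.scores <= 1))

    def test_matches_score_then_sort_oracle(self):
        entry = toy_protein("p1", 10, 30)
        tset = clf.build_training_set([entry], seed=0)
        model = clf.train(tset, gamma="scale")
        _, pairs, vals, avail, _ = entry
        ranked = clf.rank_contacts(model, pairs, vals, avail)
        scores = model.predict_proba(vals, avail)
        oracle = sorted(range(len(pairs)),
                        key=lambda r: (-scores[r], pairs[r]))
        assert ranked.pairs == [pairs[r] for r in oracle]


class TestSelectRemovals:
    def make_ranked(self, scores):
        pairs = [(k, k + 10) for k in range(len(scores))]
        return clf.RankedContacts(pairs=pairs, scores=np.asarray(scores, float))

    def test_relative_sixteen_percent_of_250(self):
        ranked = self.make_ranked(np.linspace(1, 0, 250))
        assert len(clf.select_removals(ranked, "relative", 0.16)) == 40

    def test_constant_clamped(self):
        ranked = self.make_ranked(np.linspace(1, 0, 50))
        assert len(clf.select_removals(ranked, "constant", 60)) == 50

    def test_score_cutoff_strict(self):
        ranked = self.make_ranked([0.9, 0.5, 0.41, 0.39])
        sel = clf.select_removals(ranked, "score", 0.4)
        assert len(sel) == 3

    def test_boundary_not_inclusive(self):
        ranked = self.make_ranked([0.9, 0.4])
        assert len(clf.select_removals(ranked, "score", 0.4)) == 1

    def test_selection_is_ranking_prefix(self):
        ranked = self.make_ranked(np.linspace(1, 0, 30))
        sel = clf.select_removals(ranked, "relative", 0.5)
        assert sel == ranked.pairs[: len(sel)]

    def test_unknown_strategy(self):
        with pytest.raises(ValueError, match="unknown selection"):
            clf.select_removals(self.make_ranked([0.5]), "bogus", 1)


class TestClassifierMetrics:
    def test_perfect_prediction(self):
        tmap = toy_tmap(30, [(0, 5), (1, 8)], [(2, 9)])
        m = clf.classifier_metrics([(0, 5), (1, 8)], tmap)
        assert m["precision"] == 1.0 and m["coverage"] == 1.0

    def test_disjoint_prediction(self):
        tmap = toy_tmap(30, [(0, 5)], [(2, 9), (3, 10)])
        m = clf.classifier_metrics([(2, 9), (3, 10)], tmap)
        assert m["precision"] == 0.0 and m["coverage"] == 0.0

    def test_auroc_matches_pair_counting(self):
        """2 positives ranked 1st and 3rd of 4 → AUROC = 3/4 concordant pairs."""
        tmap = toy_tmap(30, [(0, 5), (2, 9)], [(1, 8), (3, 10)])
        ranked = clf.RankedContacts(
            pairs=[(0, 5), (1, 8), (2, 9), (3, 10)],
            scores=np.array([0.9, 0.7, 0.5, 0.3]),
        )
        m = clf.classifier_metrics([(0, 5)], tmap, ranked)
        observed = {(0, 5), (2, 9)}
        concordant = 0
        for p in observed:
            for q in [(1, 8), (3, 10)]:
                sp = ranked.scores[ranked.pairs.index(p)]
                sq = ranked.scores[ranked.pairs.index(q)]
                concordant += sp > sq
        assert m["auroc"] == pytest.approx(concordant / 4) == pytest.approx(0.75)


class TestLinearFeatureWeights:
    def test_signal_feature_dominates(self):
        entry = toy_protein("p1", 20, 60, seed=1)
        tset = clf.build_training_set([entry], seed=1)
        df = clf.linear_feature_weights(tset)
        top = df.iloc[df["weight"].abs().argmax()]
        from lmcenm.features import FEATURE_NAMES

        assert top["feature"] == FEATURE_NAMES[0]

    def test_duplicated_column_deterministic(self):
        entry = toy_protein("p1", 20, 60, seed=1)
        tset = clf.build_training_set([entry], seed=1)
        tset.values[:, 1] = tset.values[:, 0]
        a = clf.linear_feature_weights(tset)
        b = clf.linear_feature_weights(tset)
        assert list(a["feature"]) == list(b["feature"])

    def test_two_point_analytic_direction(self):
        """Two separable points: the margin direction is the difference vector."""
        tset = clf.TrainingSet(
            values=np.array([[1.0, 0.0], [-1.0, 0.0]] * 10),
            available=np.ones((20, 2), bool),
            labels=np.array([1, 0] * 10),
            protein_ids=["p"] * 20,
            pairs=[(k, k + 10) for k in range(20)],
        )
        df = clf.linear_feature_weights(tset, cost=10.0)
        w = df.set_index("feature")["weight"]
        from lmcenm.features import FEATURE_NAMES

        assert abs(w[FEATURE_NAMES[0]]) > 10 * abs(w[FEATURE_NAMES[1]])


class TestTuneLOOCV:
    def test_grid_of_one(self):
        entries = [toy_protein(f"p{k}", 8, 24, seed=k, n=40) for k in range(3)]
        out = clf.tune_loocv(entries, grid=[(10.0, 1e-3)])
        assert out == (10.0, 1e-3)

    def test_dominant_grid_point_wins(self):
        entries = [toy_protein(f"p{k}", 8, 24, seed=k, n=40) for k in range(3)]
        # gamma="?": use two points where one is absurdly poor (tiny cost)
        out = clf.tune_loocv(entries, grid=[(1e-6, 1e-9), (10.0, 1e-2)])
        assert out == (10.0, 1e-2)
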