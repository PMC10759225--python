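"""Training loop, early stopping, and evaluation metrics."""

import numpy as np
import pytest

import tcrbind as tb
from tcrbind.training import EarlyStopping


class TestEarlyStopping:
    def test_decreasing_then_flat_stops_after_patience(self):
        # monitored values: initial 1.0, three improving epochs, ten flat ones
        stopper = EarlyStopping(patience=10)
        values = [1.0, 0.9, 0.8, 0.7] + [0.7] * 10
        stops = [stopper.update(v) for v in values]
        assert stops.index(True) == 13          # stops at epoch 13
        assert stopper.best_index == 3          # best = epoch 3

    def test_immediate_worsening_with_patience_one(self):
        stopper = EarlyStopping(patience=1)
        assert stopper.update(0.5) is False     # initial weights
        assert stopper.update(0.6) is True      # first epoch worsens -> stop
        assert stopper.best_index == 0          # best = initial

    def test_patience_must_be_positive(self):
        with pytest.raises(ValueError):
            EarlyStopping(patience=0)


class TestTrain:
    def test_single_class_data_rejected(self):
        ds = tb.InteractionDataset(
            [tb.InteractionRecord("CAV", "CAS", "GIL", 1)] * 4)
        with pytest.raises(ValueError, match="both labels"):
            tb.train(ds, tb.TrainConfig(max_epochs=1))

    def test_loss_decreases_on_learnable_motif_data(self, trained_tiny):
        _, _, _, _ = trained_tiny
        # history recorded by the shared fixture's training run
        # (re-derive cheaply: final monitored BCE below the initial one)
        # The fixture model is trained; verify it beats chance on training data.
        model, rule, train_ds, _ = trained_tiny
        scores = tb.predict(model, train_ds)
        assert tb.roc_auc(scores, train_ds.labels) > 0.8


class TestPredict:
    def test_duplicates_and_order(self, trained_tiny):
        model, _, train_ds, _ = trained_tiny
        ds = tb.InteractionDataset([train_ds.records[0], train_ds.records[1],
                                    train_ds.records[0]])
        scores = tb.predict(model, ds)
        assert scores[0] == scores[2]

    def test_empty_dataset(self, trained_tiny):
        model, _, _, _ = trained_tiny
        assert tb.predict(model, tb.InteractionDataset([])).size == 0

    def test_batch_size_independence(self, trained_tiny):
        model, _, train_ds, _ = trained_tiny
        ds = tb.InteractionDataset(train_ds.records[:40])
        a = tb.predict(model, ds, batch_size=1)
        b = tb.predict(model, ds, batch_size=32)
        assert np.max(np.abs(a - b)) <= 1e-6


class TestRocAuc:
    def test_perfect_separation(self):
        assert tb.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_inverted_scores(self):
        assert tb.roc_auc([0.2, 0.8], [1, 0]) == 0.0

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(5, 50))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # O(n^2) oracle: P(score_pos > score_neg) + 0.5 P(tie)
            pos, neg = scores[labels == 1], scores[labels == 0]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            oracle = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert tb.roc_auc(scores, labels) == pytest.approx(oracle)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            tb.roc_auc([0.5, 0.6], [1, 1])


class TestAveragePrecision:
    def test_top_scored_positive(self):
        assert tb.average_precision([0.9, 0.1], [1, 0]) == 1.0

    def test_hand_stepped_pr_curve(self):
        # positives at ranks 1 and 3: AP = 1*(1/2) + (2/3)*(1/2) = 0.8333
        assert tb.average_precision([0.9, 0.8, 0.7], [1, 0, 1]) == \
            pytest.approx(1 / 2 + (2 / 3) / 2, abs=1e-4)

    def test_all_positives(self):
        assert tb.average_precision([0.2, 0.9], [1, 1]) == 1.0


class TestConfusion:
    def test_printed_recall(self):
        # 24 true positives, 16 false negatives -> recall 0.600
        scores = np.r_[np.ones(24), np.zeros(16)]
        labels = np.ones(40, int)
        c = tb.confusion_at(scores, labels, 0.5)
        assert c["recall"] == pytest.approx(0.600, abs=1e-9)

    def test_printed_precision_at_scale(self):
        # 24 TP against 959,512 FP -> precision 2.501e-5 (4 s.f.)
        tp, fp = 24, 959_512
        scores = np.r_[np.ones(tp + fp), np.zeros(16)]
        labels = np.r_[np.ones(tp, int), np.zeros(fp, int), np.ones(16, int)]
        c = tb.confusion_at(scores, labels, 0.5)
        assert c["precision"] == pytest.approx(2.501e-5, rel=5e-4)

    def test_zero_threshold_recall_one(self):
        c = tb.confusion_at([0.1, 0.0, 0.9], [1, 1, 0], 0.0)
        assert c["recall"] == 1.0

    def test_counts_sum_and_recall_monotone(self):
        rng = np.random.default_rng(1)
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        prev = 1.1
        for t in np.linspace(0, 1, 7):
            c = tb.confusion_at(scores, labels, t)
            assert c["tp"] + c["fp"] + c["fn"] + c["tn"] == 60
            assert c["recall"] <= prev + 1e-12
            prev = c["recall"]


class TestBestF1:
    def test_exhaustive_scan_example(self):
        assert tb.best_f1_threshold([0.9, 0.8, 0.1], [1, 0, 0]) == 0.9

    def test_perfect_separation_picks_lowest_positive_score(self):
        assert tb.best_f1_threshold([0.9, 0.7, 0.2, 0.1], [1, 1, 0, 0]) == 0.7

    def test_constant_scores(self):
        assert tb.best_f1_threshold([0.4, 0.4, 0.4], [1, 0, 1]) == 0.4

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[0] = 1
        best = tb.best_f1_threshold(scores, labels)
        f1 = tb.confusion_at(scores, labels, best)["f1"]
        for t in np.unique(scores):
            assert tb.confusion_at(scores, labels, t)["f1"] <= f1 + 1e-12


class TestFoldEnrichment:
    def test_printed_arithmetic(self):
        # from the raw confusion counts: 24/(24+959,512) over 40/2,120,140
        fold = tb.fold_enrichment(24 / (24 + 959_512), 40 / 2_120_140)
        assert fold == pytest.approx(1.326, abs=1e-3)

    def test_random_selection_is_one(self):
        assert tb.fold_enrichment(0.2, 0.2) == 1.0

    def test_zero_precision(self):
        assert tb.fold_enrichment(0.0, 0.3) == 0.0


class TestPerPeptide:
    def test_single_peptide_matches_global(self):
        ds = tb.InteractionDataset([
            tb.InteractionRecord("A", "B", "GIL", 1),
            tb.InteractionRecord("C", "D", "GIL", 0),
        ])
        scores = [0.9, 0.2]
        table = tb.per_peptide_report(scores, ds, top_k=8)
        assert len(table) == 1
        assert table.aps[0] == tb.average_precision(scores, [1, 0])

    def test_two_peptide_hand_aps(self):
        ds = tb.InteractionDataset(
            [tb.InteractionRecord("A", "B", "GIL", 1),
             tb.InteractionRecord("C", "D", "GIL", 0),
             tb.InteractionRecord("E", "F", "GIL", 1),
             tb.InteractionRecord("G", "H", "NLV", 1),
             tb.InteractionRecord("I", "K", "NLV", 0)])
        scores = [0.9, 0.8, 0.7, 0.3, 0.6]
        table = tb.per_peptide_report(scores, ds, top_k=2).set_index("peptide")
        assert table.loc["GIL", "aps"] == pytest.approx(1 / 2 + (2 / 3) / 2)
        # NLV: positive scored below the negative -> AP = 1/2
        assert table.loc["NLV", "aps"] == pytest.approx(0.5)
        assert table.loc["GIL", "positive_rate"] == pytest.approx(2 / 3)

    def test_top_k_larger_than_peptide_count(self):
        ds = tb.InteractionDataset([tb.InteractionRecord("A", "B", "GIL", 1)])
        assert len(tb.per_peptide_report([0.5], ds, top_k=10)) == 1


def test_evaluate_report_round_trip(tmp_path):
    scores = [0.9, 0.8, 0.3, 0.1]
    labels = [1, 0, 1, 0]
    rep = tb.evaluate(scores, labels)
    assert 0 <= rep.roc_auc <= 1 and rep.tp + rep.fn == 2
    rep.to_json(tmp_path / "r.json")
    import json
    loaded = json.loads((tmp_path / "r.json").read_text())
    assert loaded["roc_auc"] == rep.roc_auc
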