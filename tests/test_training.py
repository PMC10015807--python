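import numpy as np
import pytest
from sklearn.metrics import precision_score, recall_score

from mufrf.training import (MetricsReport, MuFRF, TrainConfig, compute_metrics,
                            sample_negative_pairs, split_pairs, train_mufrf)


class TestSplitPairs:
    def make_pairs(self, n, n_classes=2, seed=0):
        rng = np.random.default_rng(seed)
        return [(f"a{i}", f"b{i}", int(rng.integers(n_classes))) for i in range(n)]

    def test_eighty_twenty(self):
        train, test = split_pairs(self.make_pairs(10), 0.2, seed=0)
        assert len(train) == 8 and len(test) == 2
        assert sorted(train + test) == sorted(self.make_pairs(10))

    def test_seed_determinism(self):
        pairs = self.make_pairs(30)
        assert split_pairs(pairs, 0.2, seed=4) == split_pairs(pairs, 0.2, seed=4)

    def test_stratification_preserves_proportions(self):
        pairs = self.make_pairs(100, n_classes=5, seed=1)
        train, test = split_pairs(pairs, 0.2, seed=0, stratify=True)
        for c in range(5):
            total = sum(1 for p in pairs if p[2] == c)
            in_test = sum(1 for p in test if p[2] == c)
            assert abs(in_test - 0.2 * total) <= 1

    def test_rare_class_falls_back_unstratified(self, caplog):
        pairs = self.make_pairs(10, n_classes=2) + [("x", "y", 7)]
        train, test = split_pairs(pairs, 0.2, seed=0, stratify=True)
        assert len(train) + len(test) == 11

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            split_pairs([("a", "b", 1)], 0.2, seed=0)


class TestSampleNegativePairs:
    POS = [("d0", "d1", 1), ("d1", "d2", 1)]
    VOCAB = [f"d{i}" for i in range(8)]

    def test_ratio_one_matches_count(self):
        negs = sample_negative_pairs(self.POS, self.VOCAB, 1.0, seed=0)
        assert len(negs) == 2
        assert all(label == 0 for _, _, label in negs)

    def test_no_collision_with_positives_either_order(self):
        negs = sample_negative_pairs(self.POS, self.VOCAB, 5.0, seed=1)
        pos = {frozenset((a, b)) for a, b, _ in self.POS}
        assert all(frozenset((a, b)) not in pos for a, b, _ in negs)
        assert len({frozenset((a, b)) for a, b, _ in negs}) == len(negs)

    def test_seed_determinism(self):
        assert (sample_negative_pairs(self.POS, self.VOCAB, 2.0, seed=3)
                == sample_negative_pairs(self.POS, self.VOCAB, 2.0, seed=3))

    def test_exhausted_space_rejected(self):
        with pytest.raises(ValueError, match="cannot sample"):
            sample_negative_pairs(self.POS, ["d0", "d1", "d2"], 10.0, seed=0)


class TestComputeMetrics:
    def test_perfect_predictions(self):
        rep = compute_metrics([0, 1, 2, 1], [0, 1, 2, 1], 3)
        assert rep.acc == rep.precision == rep.recall == rep.f1 == 1.0

    def test_hand_confusion_oracle(self):
        # truth (1,1,0,0), pred (1,0,0,0): macro P = 5/6, macro R = 3/4,
        # F1 = 2PR/(P+R) ≈ 0.78947
        rep = compute_metrics([1, 1, 0, 0], [1, 0, 0, 0], 2)
        assert rep.recall == pytest.approx(0.75, abs=1e-12)
        assert rep.precision == pytest.approx(5 / 6, abs=1e-12)
        assert rep.f1 == pytest.approx(2 * (5 / 6) * 0.75 / (5 / 6 + 0.75), abs=1e-10)
        assert rep.tp[1] == 1 and rep.fn[1] == 1 and rep.fp[1] == 0 and rep.tn[1] == 2

    def test_all_one_class_on_balanced_truth(self):
        rep = compute_metrics([0, 0, 1, 1], [1, 1, 1, 1], 2)
        assert rep.recall == pytest.approx(0.5)

    def test_binary_printed_acc_equals_plain_accuracy(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 2, 50)
        y_pred = rng.integers(0, 2, 50)
        rep = compute_metrics(y_true, y_pred, 2)
        assert rep.acc == pytest.approx(rep.plain_accuracy, abs=1e-12)

    def test_matches_sklearn_on_random_configurations(self):
        # independent oracle: sklearn macro precision/recall on 200 random
        # label configurations
        rng = np.random.default_rng(123)
        for _ in range(200):
            n_c = int(rng.integers(2, 6))
            n = int(rng.integers(5, 40))
            y_true = rng.integers(0, n_c, n)
            y_pred = rng.integers(0, n_c, n)
            rep = compute_metrics(y_true, y_pred, n_c)
            p = precision_score(y_true, y_pred, labels=range(n_c),
                                average="macro", zero_division=0)
            r = recall_score(y_true, y_pred, labels=range(n_c),
                             average="macro", zero_division=0)
            assert rep.precision == pytest.approx(p, abs=1e-12)
            assert rep.recall == pytest.approx(r, abs=1e-12)
            expected_f1 = 0.0 if p + r == 0 else 2 * p * r / (p + r)
            assert rep.f1 == pytest.approx(expected_f1, abs=1e-12)

    def test_counts_sum_to_samples(self):
        rep = compute_metrics([0, 1, 2], [2, 1, 0], 3)
        totals = rep.tp + rep.tn + rep.fp + rep.fn
        assert np.all(totals == 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            compute_metrics([0, 1], [0], 2)

    def test_undefined_ratio_reported_as_zero(self):
        rep = compute_metrics([0, 0], [0, 0], 2)  # class 1 never seen
        assert rep.precision == pytest.approx(0.5)  # (1 + 0)/2

    def test_report_serializable(self):
        d = compute_metrics([0, 1], [0, 1], 2).to_dict()
        assert set(d) >= {"acc", "precision", "recall", "f1", "tp"}


class TestEndToEnd:
    """Structural end-to-end checks at tiny scale (fast settings)."""

    FAST = dict(epochs=3, kg_epochs=10, kg_negatives=8, hidden_dense=64,
                gin_hidden_dim=8, gin_layers=2)

    def _fit(self, world, task="binary", **kw):
        kwargs = {**self.FAST, **kw}
        pairs = [(a, b) for a, b, _ in world.pairs]
        labels = [c for _, _, c in world.pairs]
        return MuFRF(task=task, random_state=0, **kwargs).fit(
            pairs, labels, smiles=world.smiles_table, kg_triples=world.triples)

    def test_binary_pipeline_runs_and_predicts(self, tiny_world):
        model = self._fit(tiny_world)
        proba = model.predict_proba([(a, b) for a, b, _ in tiny_world.pairs[:5]])
        assert proba.shape == (5, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        preds = model.predict([(a, b) for a, b, _ in tiny_world.pairs[:5]])
        assert set(preds) <= {0, 1}

    def test_loss_moving_average_decreases(self, tiny_world):
        model = self._fit(tiny_world, epochs=8)
        assert model.loss_history_[-1] <= model.loss_history_[0]

    def test_prediction_is_order_averaged(self, tiny_world):
        model = self._fit(tiny_world)
        a, b, _ = tiny_world.pairs[0]
        assert np.allclose(model.predict_proba([(a, b)]),
                           model.predict_proba([(b, a)]))

    @pytest.mark.parametrize("ablate", [("kg",), ("structure",), ("c0",), ("c1",),
                                        ("add",), ("product",), ("attn",)])
    def test_ablation_variants_run_end_to_end(self, tiny_world, ablate):
        model = self._fit(tiny_world, ablate=ablate, epochs=2)
        preds = model.predict([(a, b) for a, b, _ in tiny_world.pairs[:4]])
        assert len(preds) == 4

    def test_unresolvable_drugs_dropped_with_warning(self, tiny_world, caplog):
        pairs = [(a, b) for a, b, _ in tiny_world.pairs] + [("ghost", "D000")]
        labels = [c for _, _, c in tiny_world.pairs] + [1]
        model = MuFRF(task="binary", random_state=0, **self.FAST).fit(
            pairs, labels, smiles=tiny_world.smiles_table,
            kg_triples=tiny_world.triples)
        assert "ghost" not in model.drug_index_

    def test_empty_training_set_rejected(self, tiny_world):
        with pytest.raises(ValueError, match="empty"):
            MuFRF(task="binary").fit([], [], smiles=tiny_world.smiles_table,
                                     kg_triples=tiny_world.triples)

    def test_checkpoint_roundtrip(self, tiny_world, tmp_path):
        model = self._fit(tiny_world)
        model.save(tmp_path / "ckpt")
        loaded = MuFRF.load(tmp_path / "ckpt")
        pairs = [(a, b) for a, b, _ in tiny_world.pairs[:6]]
        assert np.allclose(model.predict_proba(pairs), loaded.predict_proba(pairs))

    def test_train_mufrf_writes_report(self, tiny_world, tmp_path):
        config = TrainConfig(task="binary", epochs=3, seed=0,
                             kg={"epochs": 10, "negatives_per_positive": 8},
                             gin={"hidden_dim": 8, "n_layers": 2},
                             hidden_dense=64)
        model, report = train_mufrf(tiny_world.smiles_table, tiny_world.triples,
                                    tiny_world.pairs, config,
                                    out_dir=tmp_path / "run")
        assert isinstance(report, MetricsReport)
        assert (tmp_path / "run" / "metrics.json").exists()
        assert 0.0 <= report.plain_accuracy <= 1.0

    def test_positive_only_binary_input_triggers_negative_sampling(self, tiny_world):
        positives = [(a, b, 1) for a, b, c in tiny_world.pairs if c == 1]
        config = TrainConfig(task="binary", epochs=2, seed=0,
                             kg={"epochs": 5, "negatives_per_positive": 4},
                             gin={"hidden_dim": 8, "n_layers": 2}, hidden_dense=32)
        _, report = train_mufrf(tiny_world.smiles_table, tiny_world.triples,
                                positives, config)
        # test split contains both classes only if negatives were sampled
        assert (report.tp + report.fn)[0] > 0 and (report.tp + report.fn)[1] > 0

    def test_five_fold_cross_validation_pools_counts(self, tiny_world):
        config = TrainConfig(task="binary", epochs=2, seed=0, folds=3,
                             kg={"epochs": 5, "negatives_per_positive": 4},
                             gin={"hidden_dim": 8, "n_layers": 2}, hidden_dense=32)
        _, report = train_mufrf(tiny_world.smiles_table, tiny_world.triples,
                                tiny_world.pairs, config)
        # pooled over folds, every pair is tested exactly once, and each
        # sample is the positive of exactly one class
        assert (report.tp + report.fn).sum() == len(tiny_world.pairs)

    def test_sklearn_get_params_roundtrip(self):
        m = MuFRF(task="multiclass", n_classes=4)
        m2 = MuFRF(**m.get_params())
        assert m2.task == "multiclass" and m2.n_classes == 4
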