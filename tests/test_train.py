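"""Splitting, negative sampling, schedule, metrics, and short training runs."""

import numpy as np
import pytest

from ddisub.model import DDIModel, ModelConfig
from ddisub.molgraph import DDITuple, DrugRecord
from ddisub.train import (TrainConfig, _metrics, evaluate, lr_at_epoch,
                          negative_sampling, per_type_metrics, split_dataset,
                          train)
from ddisub import synthetic


def toy_tuples(n, n_relations=3, seed=0):
    rng = np.random.default_rng(seed)
    return [DDITuple(f"d{i}", f"d{(i + 1) % n}", int(rng.integers(n_relations)))
            for i in range(n)]


class TestSplit:
    def test_sixty_twenty_twenty_on_100(self):
        tr, va, te = split_dataset(toy_tuples(100), (0.6, 0.2, 0.2), seed=1)
        assert (len(tr), len(va), len(te)) == (60, 20, 20)

    def test_floor_allocation_remainder_to_train(self):
        tr, va, te = split_dataset(toy_tuples(5), (0.6, 0.2, 0.2), seed=1)
        assert (len(tr), len(va), len(te)) == (3, 1, 1)

    def test_partition_is_exact_and_deterministic(self):
        tuples = toy_tuples(37)
        a = split_dataset(tuples, seed=9)
        b = split_dataset(tuples, seed=9)
        assert a == b
        merged = a[0] + a[1] + a[2]
        assert sorted(map(repr, merged)) == sorted(map(repr, tuples))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(toy_tuples(10), (0.5, 0.2, 0.2), seed=0)

    def test_too_few_tuples_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(toy_tuples(4), seed=0)


class TestNegativeSampling:
    def setup_method(self):
        self.drugs = [DrugRecord(f"d{i}", "C" * (i + 1)) for i in range(8)]
        self.pos = [DDITuple(f"d{i}", f"d{i + 1}", 0) for i in range(6)]

    def test_one_to_one_ratio(self):
        out = negative_sampling(self.pos, self.drugs, seed=0)
        assert len(out) == 2 * len(self.pos)
        assert sum(t.label for t in out) == len(self.pos)

    def test_no_negative_collides_with_positives(self):
        out = negative_sampling(self.pos, self.drugs, seed=1)
        keys = {(t.drug_x, t.drug_y, t.relation) for t in self.pos}
        for t in out:
            if t.label == 0:
                assert (t.drug_x, t.drug_y, t.relation) not in keys
                assert t.drug_x != t.drug_y

    def test_corruption_changes_exactly_one_side(self):
        out = negative_sampling(self.pos, self.drugs, seed=2)
        negs = [t for t in out if t.label == 0]
        for pos, neg in zip(self.pos, negs):
            assert (neg.drug_x == pos.drug_x) != (neg.drug_y == pos.drug_y)
            assert neg.relation == pos.relation

    def test_deterministic_given_seed(self):
        a = negative_sampling(self.pos, self.drugs, seed=3)
        b = negative_sampling(self.pos, self.drugs, seed=3)
        assert a == b

    def test_extra_rejection_respected(self):
        closure = {(f"d{i}", f"d{j}", 0) for i in range(8) for j in range(4)}
        out = negative_sampling(self.pos, self.drugs, seed=4,
                                extra_rejection=closure)
        for t in out:
            if t.label == 0:
                assert (t.drug_x, t.drug_y, t.relation) not in closure

    def test_non_positive_input_rejected(self):
        with pytest.raises(ValueError):
            negative_sampling([DDITuple("d0", "d1", 0, label=0)], self.drugs)


class TestSchedule:
    def test_exponential_decay_closed_form(self):
        assert lr_at_epoch(1e-4, 0) == pytest.approx(1e-4)
        assert lr_at_epoch(1e-4, 2) == pytest.approx(1e-4 * 0.96**2, rel=1e-12)
        assert lr_at_epoch(1e-4, 2) == pytest.approx(9.216e-5, rel=1e-9)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(fractions=(0.5, 0.3, 0.3))
        with pytest.raises(ValueError):
            TrainConfig(T=0)


class TestMetrics:
    def test_perfect_separation_gives_all_ones(self):
        m = _metrics(np.array([1, 1, 0, 0]), np.array([0.9, 0.8, 0.1, 0.2]))
        assert (m.acc, m.auc, m.f1, m.precision, m.recall, m.aupr) == (1, 1, 1, 1, 1, 1)

    def test_inverted_scores_give_zero_acc_and_auc(self):
        m = _metrics(np.array([1, 1, 0, 0]), np.array([0.1, 0.2, 0.9, 0.8]))
        assert m.acc == 0.0 and m.auc == 0.0

    def test_hand_worked_confusion_matrix(self):
        # preds at 0.5: [1, 0, 1, 0] vs labels [1, 1, 0, 0] -> TP=1 FP=1 FN=1 TN=1
        labels = np.array([1, 1, 0, 0])
        probs = np.array([0.7, 0.3, 0.6, 0.4])
        m = _metrics(labels, probs)
        assert m.acc == pytest.approx(0.5)
        assert m.precision == pytest.approx(0.5)
        assert m.recall == pytest.approx(0.5)
        assert m.f1 == pytest.approx(0.5)
        assert m.auc == pytest.approx(0.5)  # hand ROC over the 4 rankings

    def test_random_scorer_auc_near_half(self):
        rng = np.random.default_rng(11)
        labels = np.array([1, 0] * 500)
        m = _metrics(labels, rng.random(1000))
        assert 0.4 <= m.auc <= 0.6

    def test_single_class_type_reports_missing_auc(self):
        drugs = synthetic.generate_drugs(4, seed=2)
        tuples = [DDITuple(drugs[0].id, drugs[1].id, 0, 1),
                  DDITuple(drugs[1].id, drugs[0].id, 0, 1),
                  DDITuple(drugs[2].id, drugs[3].id, 1, 1),
                  DDITuple(drugs[3].id, drugs[2].id, 1, 0)]
        model = DDIModel(ModelConfig(hidden=8, T=1, L=1, n_relations=2))
        per = per_type_metrics(model, drugs, tuples)
        assert per[0].auc is None  # only positives for type 0
        assert per[1].auc is not None


class TestTrainLoop:
    def test_zero_epochs_returns_initialized_model(self):
        drugs = synthetic.generate_drugs(5, seed=1)
        tuples = synthetic.random_tuples(drugs, 6, seed=1)
        labeled = negative_sampling(tuples, drugs, seed=1)
        cfg = TrainConfig(T=1, L=1, hidden=8, epochs=0, seed=1)
        result = train(cfg, drugs, labeled)
        assert result.history == []
        ref = DDIModel(ModelConfig(hidden=8, T=1, L=1, n_relations=2, seed=1))
        for a, b in zip(result.model.state_arrays(), ref.state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_training_is_reproducible(self):
        drugs = synthetic.generate_drugs(5, seed=2)
        labeled = negative_sampling(synthetic.random_tuples(drugs, 6, seed=2),
                                    drugs, seed=2)
        cfg = TrainConfig(T=1, L=1, hidden=8, epochs=3, lr=1e-3, seed=2)
        a = train(cfg, drugs, labeled)
        b = train(cfg, drugs, labeled)
        assert [r["train_loss"] for r in a.history] == \
               [r["train_loss"] for r in b.history]

    def test_loss_decreases_on_average(self):
        drugs = synthetic.generate_drugs(6, seed=3)
        labeled = negative_sampling(synthetic.random_tuples(drugs, 10, seed=3),
                                    drugs, seed=3)
        cfg = TrainConfig(T=1, L=2, hidden=16, epochs=30, lr=3e-3,
                          lr_decay=1.0, weight_decay=0.0, seed=3)
        res = train(cfg, drugs, labeled)
        first = np.mean([r["train_loss"] for r in res.history[:10]])
        last = np.mean([r["train_loss"] for r in res.history[-10:]])
        assert last < first

    def test_checkpoint_round_trip(self, tmp_path):
        drugs = synthetic.generate_drugs(5, seed=4)
        labeled = negative_sampling(synthetic.random_tuples(drugs, 6, seed=4),
                                    drugs, seed=4)
        cfg = TrainConfig(T=1, L=1, hidden=8, epochs=2, lr=1e-3, seed=4)
        res = train(cfg, drugs, labeled)
        res.model.save(tmp_path / "ck.npz")
        loaded = DDIModel.load(tmp_path / "ck.npz")
        a = evaluate(res.model, drugs, labeled).to_dict()
        b = evaluate(loaded, drugs, labeled).to_dict()
        assert a == b
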