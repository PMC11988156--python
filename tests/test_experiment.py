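"""Cross-validation harness: folds, metrics, training loop, aggregation."""

import numpy as np
import pytest

from budmil import (
    EmbeddingMatrix,
    TrainConfig,
    aggregate_and_report,
    auc_score,
    bags_as_store,
    evaluate,
    make_folds,
    precision_recall,
    render_table,
    run_cross_validation,
    train_fold,
)
from budmil.experiment import FoldSplit, _gather


def brute_force_auc(scores, labels):
    """All-pairs comparison with ties counting one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def tiny_store(rng, n_pos=12, n_neg=12, delta=3.0, K=4, D=3):
    bags = []
    for i in range(n_pos):
        H = rng.normal(size=(K, D))
        H[0, 0] += delta
        bags.append(EmbeddingMatrix(f"p{i:02d}", H, "sim", label=1))
    for i in range(n_neg):
        bags.append(EmbeddingMatrix(f"n{i:02d}", rng.normal(size=(K, D)), "sim", label=0))
    return bags_as_store(bags)


class TestMakeFolds:
    def test_29_slides_10_10_9(self):
        ids = [f"wsi{i:02d}" for i in range(29)]
        folds = make_folds(ids, 6, (10, 10, 9), seed=7)
        assert len(folds) == 6
        for f in folds:
            assert (len(f.train), len(f.val), len(f.test)) == (10, 10, 9)
            union = set(f.train) | set(f.val) | set(f.test)
            assert union == set(ids)  # disjointness enforced by FoldSplit

    def test_three_ids_each_fold_a_permutation(self):
        folds = make_folds(["a", "b", "c"], 4, (1, 1, 1), seed=0)
        for f in folds:
            assert set(f.train) | set(f.val) | set(f.test) == {"a", "b", "c"}

    def test_inconsistent_sizes_error(self):
        with pytest.raises(ValueError, match="sum"):
            make_folds([str(i) for i in range(29)], 6, (10, 10, 10), seed=0)

    def test_reproducible_from_seed(self):
        ids = [str(i) for i in range(12)]
        a = make_folds(ids, 3, (6, 3, 3), seed=42)
        b = make_folds(ids, 3, (6, 3, 3), seed=42)
        assert a == b
        c = make_folds(ids, 3, (6, 3, 3), seed=43)
        assert a != c

    def test_leakage_guard_rejects_overlap(self):
        with pytest.raises(ValueError, match="leak"):
            FoldSplit(1, ("a", "b"), ("b",), ("c",))

    def test_stratified_draw_keeps_both_classes_everywhere(self):
        # 8 positive + 4 negative bags as units: an unstratified 6/3/3 cut
        # frequently lands a single-class partition; stratified never does
        ids = [f"p{i}" for i in range(8)] + [f"n{i}" for i in range(4)]
        labels = {u: int(u.startswith("p")) for u in ids}
        for seed in range(10):
            for f in make_folds(ids, 4, (6, 3, 3), seed=seed, stratify=labels):
                for part in (f.train, f.val, f.test):
                    assert {labels[u] for u in part} == {0, 1}
                assert (len(f.train), len(f.val), len(f.test)) == (6, 3, 3)


class TestMetrics:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        labels = np.array([1, 1, 0, 0])
        assert auc_score(scores, labels) == 1.0
        assert precision_recall(scores, labels, 0.5) == (1.0, 1.0)

    def test_reversal(self):
        assert auc_score(np.array([0.4, 0.6]), np.array([1, 0])) == 0.0

    def test_mixed_case_hand_counted(self):
        scores = np.array([0.9, 0.4, 0.35, 0.5, 0.3])
        labels = np.array([1, 1, 1, 0, 0])
        assert auc_score(scores, labels) == pytest.approx(4 / 6, abs=1e-12)
        # at 0.5: TP {0.9}, FP {0.5}, FN {0.4, 0.35}
        precision, recall = precision_recall(scores, labels, 0.5)
        assert precision == pytest.approx(0.5)
        assert recall == pytest.approx(1 / 3)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="single-class"):
            auc_score(np.array([0.5, 0.6]), np.array([1, 1]))

    def test_rank_auc_equals_brute_force_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 51))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # quantized scores force ties
            scores = rng.integers(0, 5, size=n) / 4.0
            assert auc_score(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_against_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(10):
            scores = rng.normal(size=30)
            labels = rng.integers(0, 2, size=30)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auc_score(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )


class TestTrainFold:
    def fold_for(self, store):
        ids = sorted(store)
        pos = [i for i in ids if i.startswith("p")]
        neg = [i for i in ids if i.startswith("n")]
        return FoldSplit(1, tuple(pos[:8] + neg[:8]), tuple(pos[8:10] + neg[8:10]),
                         tuple(pos[10:] + neg[10:]))

    def test_separable_bags_reach_high_val_auc(self, rng):
        store = tiny_store(rng, delta=4.0)
        fold = self.fold_for(store)
        cfg = TrainConfig(seed=5, attention_width=16)
        params, hist = train_fold(fold, store, cfg)
        assert hist.best_val_auc >= 0.95
        assert len(hist.epoch_loss) == cfg.epochs

    def test_zero_learning_rate_is_a_null_update(self, rng):
        store = tiny_store(rng)
        fold = self.fold_for(store)
        cfg = TrainConfig(seed=5, lr=0.0, epochs=5, attention_width=8)
        params, hist = train_fold(fold, store, cfg)
        assert len(set(hist.epoch_val_auc)) == 1  # AUC frozen at its initial value
        assert hist.best_epoch == 0

    def test_same_seed_bit_identical_history(self, rng):
        store = tiny_store(rng)
        fold = self.fold_for(store)
        cfg = TrainConfig(seed=9, epochs=5, attention_width=8)
        p1, h1 = train_fold(fold, store, cfg)
        p2, h2 = train_fold(fold, store, cfg)
        assert h1.epoch_loss == h2.epoch_loss
        assert h1.epoch_val_auc == h2.epoch_val_auc
        assert (p1.V == p2.V).all() and p1.b == p2.b

    def test_single_class_train_set_errors(self, rng):
        store = tiny_store(rng)
        pos = tuple(i for i in sorted(store) if i.startswith("p"))
        fold = FoldSplit(1, pos[:8], ("p08", "n00"), ("p09", "n01"))
        with pytest.raises(ValueError, match="both classes"):
            train_fold(fold, store, TrainConfig(seed=1, epochs=1))

    def test_best_checkpoint_reproduces_recorded_val_auc(self, rng):
        store = tiny_store(rng)
        fold = self.fold_for(store)
        params, hist = train_fold(fold, store, TrainConfig(seed=2, epochs=8, attention_width=8))
        val_bags = _gather(store, fold.val)
        auc, _, _ = evaluate(params, val_bags)
        assert auc == hist.best_val_auc


class TestAggregation:
    def test_mean_of_two(self):
        rep = aggregate_and_report([
            {"fold_id": 1, "auc": 0.9, "precision": 1.0, "recall": 1.0},
            {"fold_id": 2, "auc": 1.0, "precision": 1.0, "recall": 1.0},
        ])
        assert rep.mean["auc"] == pytest.approx(0.95)

    def test_single_fold_zero_spread(self):
        rep = aggregate_and_report(
            [{"fold_id": 1, "auc": 0.8, "precision": 0.7, "recall": 0.9}]
        )
        assert rep.mean["auc"] == 0.8
        assert rep.sd["auc"] == 0.0 and rep.se["auc"] == 0.0

    def test_sample_sd_closed_form(self):
        rep = aggregate_and_report([
            {"fold_id": i + 1, "auc": v, "precision": v, "recall": v}
            for i, v in enumerate([0.8, 0.9, 1.0])
        ])
        assert rep.mean["auc"] == pytest.approx(0.9)
        assert rep.sd["auc"] == pytest.approx(0.1)  # sqrt(((0.1)^2 + 0 + (0.1)^2)/2)
        assert rep.se["auc"] == pytest.approx(0.1 / np.sqrt(3))

    def test_render_table_layout(self):
        rep = aggregate_and_report(
            [{"fold_id": 1, "auc": 0.9, "precision": 0.8, "recall": 0.7}],
            holdout={"auc": 0.85, "precision": 0.75, "recall": 0.65},
        )
        table = render_table(rep)
        assert "Average over folds" in table
        assert "Hold-out test set" in table
        assert "0.900" in table and "0.850" in table


class TestRunCrossValidation:
    def test_full_protocol_shapes(self, rng):
        store = tiny_store(rng, delta=4.0)
        cfg = TrainConfig(seed=3, epochs=5, attention_width=8)
        report, histories, checkpoints = run_cross_validation(store, 3, (16, 4, 4), cfg)
        assert len(report.per_fold) == 3
        assert set(checkpoints) == {1, 2, 3}
        assert report.best_fold_id in checkpoints
        for m in ("auc", "precision", "recall"):
            assert 0.0 <= report.mean[m] <= 1.0

    def test_holdout_uses_best_fold(self, rng):
        store = tiny_store(rng, delta=4.0)
        holdout = [
            EmbeddingMatrix("h0", rng.normal(size=(4, 3)) + [3, 0, 0], "sim", label=1),
            EmbeddingMatrix("h1", rng.normal(size=(4, 3)), "sim", label=0),
        ]
        cfg = TrainConfig(seed=3, epochs=5, attention_width=8)
        report, _, _ = run_cross_validation(store, 2, (16, 4, 4), cfg, holdout_bags=holdout)
        assert report.holdout is not None
        assert set(report.holdout) == {"auc", "precision", "recall"}


def test_roc_curve_figure_written(tmp_path, rng):
    from budmil.experiment import roc_curve_figure

    scores = rng.uniform(size=20)
    labels = (scores + rng.normal(0, 0.2, 20) > 0.5).astype(int)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    out = tmp_path / "roc.png"
    roc_curve_figure(scores, labels, out)
    assert out.stat().st_size > 0
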