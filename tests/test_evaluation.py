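"""Metrics, confusion matrices, cross-validation plumbing, ablation grid."""

import numpy as np
import pytest

from tcngru import (ConfigError, ModelConfig, SynthConfig, TrainConfig,
                    ablation_grid, build_model, confusion_matrix, crossval_run,
                    evaluate, generate, get_preset)
from tcngru.evaluation import report_from_predictions


def brute_force_macro_metrics(y_true, y_pred, k):
    """Definition-level macro precision / recall / F1 for cross-checking."""
    ps, rs, fs = [], [], []
    for c in range(k):
        tp = np.sum((y_true == c) & (y_pred == c))
        fp = np.sum((y_true != c) & (y_pred == c))
        fn = np.sum((y_true == c) & (y_pred != c))
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        ps.append(p); rs.append(r); fs.append(f)
    return np.mean(ps), np.mean(rs), np.mean(fs)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 2, 1])
        rep = report_from_predictions(y, y, ("a", "b", "c"))
        assert rep.accuracy == 1.0 and rep.f1 == 1.0
        assert np.array_equal(np.diag(rep.confusion), [1, 2, 2])

    def test_two_class_hand_example(self):
        # y=[0,0,1,1], yhat=[0,1,1,1]: per-class F1 are 2/3 and 4/5
        rep = report_from_predictions([0, 0, 1, 1], [0, 1, 1, 1], ("a", "b"))
        assert rep.accuracy == 0.75
        assert rep.precision == pytest.approx(5 / 6)
        assert rep.recall == pytest.approx(0.75)
        assert rep.f1 == pytest.approx(11 / 15)  # mean(2/3, 4/5)

    def test_matches_brute_force_on_random_toys(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 7))
            n = int(rng.integers(10, 60))
            y_true = rng.integers(0, k, n)
            y_pred = rng.integers(0, k, n)
            rep = report_from_predictions(y_true, y_pred,
                                          tuple(f"c{i}" for i in range(k)))
            p, r, f = brute_force_macro_metrics(y_true, y_pred, k)
            assert rep.precision == pytest.approx(p)
            assert rep.recall == pytest.approx(r)
            assert rep.f1 == pytest.approx(f)
            # accuracy is exactly the confusion trace over its total
            assert rep.accuracy == np.trace(rep.confusion) / rep.confusion.sum()
            assert np.array_equal(rep.confusion.sum(axis=1),
                                  np.bincount(y_true, minlength=k))

    def test_confusion_matrix_contract(self):
        cm = confusion_matrix([0, 0, 1], [1, 1, 0], 2)
        assert cm[0, 1] == 2 and cm[1, 0] == 1 and np.trace(cm) == 0
        with pytest.raises(ValueError):
            confusion_matrix([0, 3], [0, 1], 2)

    def test_row_normalised_rows_sum_to_one(self, rng):
        y_true = rng.integers(0, 3, 30)
        y_pred = rng.integers(0, 3, 30)
        rep = report_from_predictions(y_true, y_pred, ("a", "b", "c"))
        rows = rep.confusion_normalised.sum(axis=1)
        present = rep.confusion.sum(axis=1) > 0
        assert np.allclose(rows[present], 1.0)


class TestEvaluate:
    def test_empty_test_set_rejected(self, tiny_cfg, small_synth):
        _, ds = small_synth
        model = build_model(tiny_cfg, seed=0)
        with pytest.raises(ValueError):
            evaluate(model, ds.select([]))

    def test_chance_level_for_random_model(self, rng):
        cfg = ModelConfig(input_length=32, input_channels=2, num_classes=6,
                          filters=4, gru_units=8, pool_size=2)
        synth = SynthConfig(num_subjects=5, windows_per_subject_per_class=20,
                            window_length=32, channels=2, seed=0)
        ds = generate(synth)
        model = build_model(cfg, seed=0)  # untrained
        rep = evaluate(model, ds)
        assert abs(rep.accuracy - 1 / 6) < 0.15


class TestAblationGrid:
    def test_gru_units_parameter_column(self):
        grid = ablation_grid(get_preset("uci_har"), "gru_units",
                             (32, 64, 128, 256))
        assert list(grid["num_parameters"]) == [33446, 64870, 183014, 640486]

    def test_kernel_size_parameter_column(self):
        grid = ablation_grid(get_preset("uci_har"), "kernel_size", (2, 3, 4, 5))
        assert list(grid["num_parameters"]) == [183014, 190470, 197926, 205382]

    def test_pooling_column_constant(self):
        grid = ablation_grid(get_preset("uci_har"), "pooling",
                             ("none", "avg", "max"))
        assert grid["num_parameters"].nunique() == 1

    def test_unknown_axis_rejected(self):
        with pytest.raises(ConfigError):
            ablation_grid(get_preset("uci_har"), "activation", ("relu",))

    def test_evaluate_fn_rows(self, small_synth):
        calls = []

        def fake_eval(cfg):
            calls.append(cfg)
            return report_from_predictions([0, 1], [0, 1], ("a", "b"))

        grid = ablation_grid(get_preset("uci_har"), "gru_layers", (1, 2),
                             evaluate_fn=fake_eval)
        assert len(calls) == 2
        assert np.allclose(grid["accuracy_percent"], 100.0)


def test_crossval_runs_one_model_per_fold(small_synth):
    cfg = ModelConfig(input_length=64, input_channels=3, num_classes=6,
                      filters=6, pool_size=4, gru_units=12)
    _, ds = small_synth
    result = crossval_run(cfg, ds, k=2, seed=0,
                          train_cfg=TrainConfig(epochs=2, seed=0),
                          val_fraction=0.12)
    assert len(result.reports) == 2
    total = sum(r.confusion.sum() for r in result.reports)
    assert total == len(ds)  # folds cover every window exactly once
    assert 0.0 <= result.mean_accuracy <= 1.0
    assert result.summary()
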