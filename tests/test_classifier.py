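"""Training loop, best-validation-loss selection, grid search, fine-tuning."""

import numpy as np
import pytest

from laparosound.classifier import (HyperParams, ModelSpec, fine_tune,
                                    grid_search, train)
from laparosound.nn import CompactCNN, softmax

from conftest import make_toy_patches

TOY_HP = HyperParams(optimizer="ADAM", learning_rate=1e-3, batch_size=32,
                     epochs=15, seed=0)
TOY_SPEC = ModelSpec(channels=(4, 8, 8))


@pytest.fixture(scope="module")
def toy_splits():
    train_d = make_toy_patches(n_per_class=24, seed=0, id_prefix="tr")
    val_d = make_toy_patches(n_per_class=6, seed=1, id_prefix="va")
    test_d = make_toy_patches(n_per_class=6, seed=2, id_prefix="te")
    return train_d, val_d, test_d


@pytest.fixture(scope="module")
def toy_model(toy_splits):
    train_d, val_d, _ = toy_splits
    return train(train_d, val_d, TOY_HP, TOY_SPEC)


class TestTrain:
    def test_separable_data_reaches_perfect_training_accuracy(
            self, toy_splits, toy_model):
        train_d = toy_splits[0]
        preds = toy_model.predict(train_d.x)
        assert np.mean(preds == train_d.y) == 1.0

    def test_selected_epoch_minimizes_validation_loss(self, toy_model):
        hist = toy_model.history
        assert toy_model.best_epoch == int(hist["val_loss"].idxmin())

    def test_deterministic_given_seed(self, toy_splits):
        train_d, val_d, test_d = toy_splits
        hp = HyperParams(optimizer="RMSprop", learning_rate=1e-3, batch_size=64,
                         epochs=3, seed=5)
        m1 = train(train_d, val_d, hp, TOY_SPEC)
        m2 = train(train_d, val_d, hp, TOY_SPEC)
        assert m1.evaluate(test_d).mAcc == m2.evaluate(test_d).mAcc
        np.testing.assert_array_equal(m1.predict(test_d.x), m2.predict(test_d.x))

    def test_shared_sources_between_train_and_val_rejected(self, toy_splits):
        train_d = toy_splits[0]
        with pytest.raises(ValueError, match="leakage"):
            train(train_d, train_d, TOY_HP, TOY_SPEC)

    def test_backbone_is_compact(self):
        assert CompactCNN().n_parameters < 300_000

    def test_softmax_outputs_sum_to_one(self):
        rng = np.random.default_rng(0)
        p = softmax(rng.standard_normal((40, 5)) * 10)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        net = CompactCNN(seed=0, channels=(2, 2, 2))
        probs = net.predict_proba(rng.standard_normal((8, 96, 64)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestGridSearch:
    def test_full_grid_has_18_cells(self):
        import itertools

        from laparosound.classifier import (GRID_BATCH_SIZES,
                                            GRID_LEARNING_RATES, GRID_OPTIMIZERS)
        cells = list(itertools.product(GRID_OPTIMIZERS, GRID_LEARNING_RATES,
                                       GRID_BATCH_SIZES))
        assert len(cells) == 18

    def test_single_cell_equals_plain_train(self, toy_splits):
        train_d, val_d, test_d = toy_splits
        hp, report = grid_search(train_d, val_d, test_d,
                                 optimizers=("RMSprop",), learning_rates=(1e-3,),
                                 batch_sizes=(64,), epochs=4, seed=3)
        assert len(report) == 1
        direct = train(train_d, val_d,
                       HyperParams(optimizer="RMSprop", learning_rate=1e-3,
                                   batch_size=64, epochs=4, seed=3))
        assert report.loc[0, "best_val_loss"] == pytest.approx(
            float(direct.history["val_loss"].min()))

    def test_report_exhaustive_and_ordered_consistently(self, toy_splits):
        train_d, val_d, test_d = toy_splits
        hp, report = grid_search(train_d, val_d, test_d,
                                 optimizers=("ADAM",),
                                 learning_rates=(1e-3, 1e-5),
                                 batch_sizes=(64,), epochs=4, seed=0,
                                 select_by="val")
        assert len(report) == 2
        # winning cell by validation loss is the report's minimum
        best = report.loc[report["best_val_loss"].idxmin()]
        assert hp.learning_rate == best["learning_rate"]


class TestFineTune:
    def test_identity_channel_fine_tune_keeps_performance(self, toy_splits, toy_model):
        train_d, val_d, test_d = toy_splits
        hp = HyperParams(optimizer="ADAM", learning_rate=1e-4, batch_size=32,
                         epochs=5, seed=1)
        ft = fine_tune(toy_model, train_d, val_d, hp, channel="reference")
        base_acc = toy_model.evaluate(test_d).mAcc
        ft_acc = ft.evaluate(test_d).mAcc
        assert abs(ft_acc - base_acc) <= 0.05

    def test_channel_mismatch_rejected(self, toy_splits, toy_model):
        from dataclasses import replace

        train_d, val_d, _ = toy_splits
        shifted_val = replace(val_d, channel="tube")
        with pytest.raises(ValueError, match="channel mismatch"):
            fine_tune(toy_model, train_d, shifted_val, TOY_HP, channel="tube")

    def test_provenance_recorded(self, toy_splits, toy_model):
        from dataclasses import replace

        train_d, val_d, _ = toy_splits
        hp = HyperParams(epochs=2, seed=0)
        ft = fine_tune(toy_model, replace(train_d, channel="tube"),
                       replace(val_d, channel="tube"), hp, channel="tube")
        assert ft.channel == "tube"

    def test_deterministic(self, toy_splits, toy_model):
        train_d, val_d, test_d = toy_splits
        hp = HyperParams(epochs=3, seed=2)
        a = fine_tune(toy_model, train_d, val_d, hp, channel="reference")
        b = fine_tune(toy_model, train_d, val_d, hp, channel="reference")
        assert a.evaluate(test_d).mAcc == b.evaluate(test_d).mAcc
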