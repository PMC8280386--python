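"""Tests for network construction, training and inference contracts."""

import numpy as np
import pytest

from lungseg import nn, traindata
from lungseg.models import (
    ClassifierSpec,
    TrainConfig,
    UnetSpec,
    binary_body_view,
    build_classifier,
    build_unet,
    load_model,
    predict_class,
    predict_mask,
    save_model,
    train_classifier,
    train_unet,
)
from lungseg.phantom import PhantomParams, make_thorax_slice


@pytest.fixture(scope="module")
def tiny_slices():
    recs = [make_thorax_slice(PhantomParams(image_size=64, seed=s))
            for s in range(24)]
    recs += [make_thorax_slice(PhantomParams(image_size=64, seed=100 + s,
                                             lung_present=False))
             for s in range(24)]
    return recs


@pytest.fixture(scope="module")
def tiny_classifier(tiny_slices):
    data = traindata.build_cnn1_set(tiny_slices)
    cfg = TrainConfig.desk_scale(seed=1, max_iterations=60, learning_rate=0.05)
    return train_classifier(ClassifierSpec(input_size=64), data, cfg)


class TestArchitecture:
    def test_classifier_filter_counts_and_kernels(self):
        model = build_classifier(ClassifierSpec(), np.random.default_rng(0))
        convs = [l for l in model.net.layers if isinstance(l, nn.Conv2D)]
        assert [c.w.shape[0] for c in convs] == [8, 16, 32]
        assert all(c.w.shape[2:] == (3, 3) for c in convs)
        # conv -> relu -> batchnorm -> pool per stage
        kinds = [type(l).__name__ for l in model.net.layers[:4]]
        assert kinds == ["Conv2D", "ReLU", "BatchNorm2D", "MaxPool2D"]

    def test_unet_has_64_filter_convs_and_x4_bottleneck(self):
        model = build_unet(UnetSpec(), np.random.default_rng(0))
        convs = [l for l in model.net.layers
                 if isinstance(l, (nn.Conv2D, nn.ConvTranspose2D))]
        assert all(64 in c.w.shape[:2] for c in convs[:-1])
        pools = [l for l in model.net.layers if isinstance(l, nn.MaxPool2D)]
        deconvs = [l for l in model.net.layers
                   if isinstance(l, nn.ConvTranspose2D)]
        assert len(pools) == 2 and len(deconvs) == 2  # x4 down, x4 up

    def test_unet_output_aligned_to_input_frame(self):
        model = build_unet(UnetSpec(n_classes=3), np.random.default_rng(0))
        x = np.zeros((1, 1, 64, 64), dtype=np.float32)
        y = model.forward(x)
        assert y.shape == (1, 3, 64, 64)


class TestTrainConfig:
    def test_full_scale_defaults(self):
        cfg = TrainConfig()
        assert (cfg.learning_rate, cfg.max_epochs,
                cfg.validation_frequency, cfg.minibatch_size) == (0.001, 100, 30, 32)


class TestClassifierTraining:
    def test_separable_phantom_task_learned(self, tiny_slices, tiny_classifier):
        held_out = [make_thorax_slice(PhantomParams(image_size=64, seed=500 + s,
                                                    lung_present=bool(s % 2)))
                    for s in range(12)]
        data = traindata.build_cnn1_set(held_out)
        correct = 0
        for img, label in zip(data.images, data.labels):
            pred, conf = predict_class(tiny_classifier, img)
            assert 0.5 <= conf <= 1.0
            correct += (pred == "lung") == bool(label)
        assert correct / len(data.images) >= 0.9

    def test_empty_or_single_class_data_rejected(self, tiny_slices):
        with pytest.raises(ValueError):
            train_classifier(ClassifierSpec(),
                             traindata.ClassifierSet([], []), TrainConfig())
        lung_only = traindata.ClassifierSet(
            [np.ones((64, 64), np.uint8)] * 4, [1, 1, 1, 1])
        with pytest.raises(ValueError):
            train_classifier(ClassifierSpec(), lung_only, TrainConfig())

    def test_prediction_deterministic_and_resizes_with_warning(self, tiny_classifier):
        img = np.zeros((128, 128))
        img[30:90, 30:90] = 1.0
        with pytest.warns(UserWarning):
            a = predict_class(tiny_classifier, img)
        with pytest.warns(UserWarning):
            b = predict_class(tiny_classifier, img)
        assert a == b


class TestUnetTraining:
    def test_label_arity_must_match_spec(self, tiny_slices):
        data = traindata.build_unet1_set(tiny_slices, config_id=5)
        with pytest.raises(ValueError):
            train_unet(UnetSpec(n_classes=2), data, TrainConfig())

    def test_identity_task_converges_quickly(self, tiny_slices):
        data = traindata.build_unet1_set(tiny_slices[:12], config_id=1)
        cfg = TrainConfig.desk_scale(seed=0, max_iterations=40, learning_rate=0.1)
        model = train_unet(UnetSpec(input_size=64), data, cfg)
        accs = [(predict_mask(model, inp) == lab).mean()
                for inp, lab in zip(data.inputs, data.labels)]
        assert np.mean(accs) >= 0.97
        assert model.log["input_domain"] == "binary"

    def test_prediction_matches_input_resolution_and_is_deterministic(
            self, tiny_slices):
        data = traindata.build_unet1_set(tiny_slices[:8], config_id=2)
        cfg = TrainConfig.desk_scale(seed=2, max_iterations=10)
        model = train_unet(UnetSpec(input_size=64), data, cfg)
        img = make_thorax_slice(PhantomParams(seed=900)).image  # 128 x 128
        a = predict_mask(model, img)
        b = predict_mask(model, img)
        assert a.shape == img.shape
        np.testing.assert_array_equal(a, b)
        assert set(np.unique(a)) <= {0, 1}

    def test_training_reproducible_to_identical_loss_curves(self, tiny_slices):
        data = traindata.build_unet1_set(tiny_slices[:8], config_id=1)
        cfg = TrainConfig.desk_scale(seed=5, max_iterations=12)
        a = train_unet(UnetSpec(input_size=64), data, cfg)
        b = train_unet(UnetSpec(input_size=64), data, cfg)
        assert a.log["train_loss"] == b.log["train_loss"]


class TestBinaryBodyView:
    def test_brightest_class_is_foreground(self):
        labels = np.zeros((10, 10), dtype=np.uint8)
        labels[:, 5:] = 1
        img = np.where(labels == 1, 0.9, 0.1)
        np.testing.assert_array_equal(binary_body_view(labels, img), labels)
        np.testing.assert_array_equal(binary_body_view(1 - labels, img), labels)

    def test_three_class_case_picks_top_class_only(self):
        labels = np.repeat(np.array([0, 1, 2], dtype=np.uint8), 4)[None, :].repeat(4, 0)
        img = labels / 2.0
        view = binary_body_view(labels, img)
        np.testing.assert_array_equal(view, (labels == 2).astype(np.uint8))


class TestCheckpointRoundTrip:
    def test_save_load_preserves_predictions(self, tiny_classifier, tmp_path):
        img = np.zeros((64, 64))
        img[16:48, 16:48] = 1.0
        before = predict_class(tiny_classifier, img)
        save_model(tiny_classifier, tmp_path / "cnn1")
        loaded = load_model(tmp_path / "cnn1")
        assert predict_class(loaded, img) == before
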