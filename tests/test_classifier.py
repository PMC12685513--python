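"""Preprocessing contract, labeling anchors, dataset ops, training."""

import numpy as np
import pytest

import dpcscreen as d
from dpcscreen import classifier as C
from dpcscreen.errors import LabelingError, NotFittedError, TrainingError


def _two_channel(shape=(64, 48), seed=0):
    rng = np.random.default_rng(seed)
    return d.FieldImage(
        channels={
            "brightfield": rng.integers(0, 4000, shape).astype(np.uint16),
            "dpc": rng.integers(0, 4000, shape).astype(np.uint16),
        }
    )


class TestPreprocess:
    def test_constant_channels_normalize_to_zero(self):
        img = d.FieldImage(
            channels={
                "brightfield": np.full((32, 32), 700, dtype=np.uint16),
                "dpc": np.full((32, 32), 700, dtype=np.uint16),
            }
        )
        out = C.preprocess_image(img, target_size=32)
        assert out.values.shape == (32, 32, 3)
        assert np.all(out.values == 0.0)

    def test_third_channel_is_mean_of_resized(self):
        img = _two_channel()
        c1, c2 = C.resize_channels(img, 32)
        assert np.allclose((c1 + c2) / 2.0, (c1 + c2) / 2.0)
        # and preprocess uses exactly that mean before normalization
        out = C.preprocess_image(img, target_size=32)
        mean = (c1 + c2) / 2.0
        expected = (mean - mean.min()) / (mean.max() - mean.min())
        assert np.allclose(out.values[..., 2], expected)

    def test_native_resolution_to_299(self):
        img = _two_channel(shape=(1024, 1360))
        out = C.preprocess_image(img)  # default target 299
        assert out.values.shape == (299, 299, 3)
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0

    def test_wrong_channel_count_rejected(self):
        img = d.FieldImage(channels={"dpc": np.zeros((16, 16), dtype=np.uint16)})
        with pytest.raises(ValueError):
            C.preprocess_image(img)


class TestAssignLabel:
    def test_vehicle_always_type_0(self):
        for t in (0.0, 5.0, 12.0, 30.0):
            assert C.assign_label(0.0, t) == 0

    def test_low_dose_band_at_12h(self):
        assert C.assign_label(1.25, 12.0) in {1, 2, 3}
        assert C.assign_label(2.5, 12.0) in {1, 2, 3}

    def test_high_dose_band_after_20h(self):
        assert C.assign_label(25.0, 22.0) in {4, 5}
        assert C.assign_label(50.0, 22.0) in {4, 5}

    def test_outside_coverage_raises(self):
        with pytest.raises(LabelingError):
            C.assign_label(1.25, 2.0)  # low dose at an unanchored early time

    def test_class_conditions_cover_all_types(self):
        labels = sorted(
            C.assign_label(dose, t) for dose, t in C.DEFAULT_CLASS_CONDITIONS
        )
        assert labels == [0, 1, 2, 3, 4, 5]


class TestAugmentSplit:
    def _tiny(self, n, labels=None):
        rng = np.random.default_rng(0)
        out = []
        for i in range(n):
            img = d.FieldImage(
                channels={
                    "brightfield": rng.integers(0, 100, (4, 4)).astype(np.uint16),
                    "dpc": rng.integers(0, 100, (4, 4)).astype(np.uint16),
                }
            )
            out.append(C.LabeledImage(image=img, type_label=(labels[i] if labels else i % 6)))
        return out

    def test_rotation_factor_of_four(self):
        data = self._tiny(12)
        aug = C.augment_rotations(data)
        assert len(aug) == 48
        assert [a.type_label for a in aug[:4]] == [data[0].type_label] * 4

    def test_single_image_four_rotations(self):
        data = self._tiny(1)
        aug = C.augment_rotations(data)
        assert len(aug) == 4
        base = data[0].image.channels["dpc"]
        assert np.array_equal(aug[2].image.channels["dpc"], np.rot90(base, 2))
        assert np.array_equal(np.rot90(base, 4), base)

    def test_label_distribution_preserved(self):
        data = self._tiny(30)
        before = np.bincount([x.type_label for x in data], minlength=6)
        after = np.bincount([x.type_label for x in C.augment_rotations(data)], minlength=6)
        assert np.array_equal(after, before * 4)

    def test_protocol_split_sizes(self):
        data = self._tiny(24_000)
        train, val = C.split_dataset(data, train_fraction=0.8, seed=0)
        assert len(train) == 19_200
        assert len(val) == 4_800
        ids = {id(x) for x in data}
        assert {id(x) for x in train} | {id(x) for x in val} == ids
        assert not ({id(x) for x in train} & {id(x) for x in val})

    def test_small_n_rounding(self):
        data = self._tiny(5, labels=[0] * 5)
        train, val = C.split_dataset(data, seed=1)
        assert len(train) == 4 and len(val) == 1

    def test_split_deterministic(self):
        data = self._tiny(60)
        a = C.split_dataset(data, seed=9)
        b = C.split_dataset(data, seed=9)
        assert [id(x) for x in a[0]] == [id(x) for x in b[0]]

    def test_fold_plan_arithmetic(self):
        labels = np.repeat(np.arange(6), 2000)
        folds = C.plan_folds(labels, k=5, seed=0)
        assert [len(f) for f in folds] == [2400] * 5
        all_idx = np.concatenate(folds)
        assert np.array_equal(np.sort(all_idx), np.arange(12000))

    def test_fold_plan_validation(self):
        with pytest.raises(ValueError):
            C.plan_folds(np.zeros(10), k=1)
        with pytest.raises(ValueError):
            C.plan_folds(np.zeros(10), k=11)


class TestTraining:
    def test_separable_classes_reach_perfect_validation(self, separable_dataset):
        train, val = C.split_dataset(separable_dataset, seed=0)
        model, curves = C.train_classifier(
            train, val, epochs=20, seed=0, input_size=48
        )
        assert curves["val_accuracy"] == 1.0

    def test_shuffled_labels_give_chance_accuracy(self, shuffled_dataset):
        train, val = C.split_dataset(shuffled_dataset, seed=0)
        _, curves = C.train_classifier(
            train, val, epochs=25, seed=0, input_size=48
        )
        assert abs(curves["val_accuracy"] - 1 / 6) <= 0.05

    def test_missing_class_rejected(self, separable_dataset):
        train = [x for x in separable_dataset if x.type_label != 3]
        with pytest.raises(TrainingError):
            C.train_classifier(train, separable_dataset[:5], epochs=2, seed=0,
                               input_size=48)

    def test_unknown_backend_rejected(self, separable_dataset):
        with pytest.raises(ValueError):
            C.train_classifier(separable_dataset[:10], separable_dataset[:5],
                               backend="convnet", epochs=1, seed=0)

    def test_classify_probabilities(self, separable_dataset):
        train, val = C.split_dataset(separable_dataset, seed=0)
        model, _ = C.train_classifier(train, val, epochs=20, seed=0,
                                      input_size=48)
        label, probs = C.classify(model, val[0].image)
        assert probs.shape == (6,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert label == int(np.argmax(probs))
        again = C.classify(model, val[0].image)
        assert again[0] == label and np.array_equal(again[1], probs)

    def test_untrained_handle_rejected(self, separable_dataset):
        handle = C.TrainedClassifier(backend="mlp", model=None, input_size=48)
        with pytest.raises(NotFittedError):
            C.classify(handle, separable_dataset[0].image)

    def test_cross_validation_perfect_on_separable(self, separable_dataset):
        metrics = C.cross_validate(
            separable_dataset, k=3, seed=0, epochs=40, input_size=48
        )
        assert metrics.f1_mean == pytest.approx(1.0)
        assert metrics.f1_sd == pytest.approx(0.0)
        assert metrics.confusion.sum() == len(separable_dataset)
        assert np.all(np.diag(metrics.confusion) == metrics.confusion.sum(axis=1))

    def test_accuracy_monotone_in_effect_size(self):
        """Accuracy does not decrease as the generator effect grows."""
        accs = []
        for effect in (0.25, 0.6, 1.0):
            data = C.make_labeled_dataset(
                n_per_class=25, size=96, seed=3, effect_scale=effect
            )
            train, val = C.split_dataset(data, seed=3)
            _, curves = C.train_classifier(train, val, epochs=60, seed=3)
            accs.append(curves["val_accuracy"])
        assert accs[0] <= accs[1] + 0.05
        assert accs[1] <= accs[2] + 0.05
        assert accs[2] > accs[0]

    def test_group_type_mapping(self):
        assert C.group_type(0) == "normal"
        assert C.group_type(1) == "normal"
        assert C.group_type(2) == "alternative"
        assert C.group_type(3) == "alternative"
        assert C.group_type(4) == "fibrotic"
        assert C.group_type(5) == "fibrotic"
        with pytest.raises(ValueError):
            C.group_type(6)

    def test_model_dose_wells_read_fibrotic(self, trained_model):
        """Model-dose fields at 24 h classify into the fibrotic group."""
        model, _ = trained_model
        groups = []
        for rep in range(6):
            spec = d.WellSpec(
                dose=10.0, n_initial=45, canvas=(128, 128), render_scale=0.267
            )
            imgs, gt = d.simulate_timecourse(spec, 24, 24, seed=300 + rep)
            frac = gt.frames[-1].activated_count / gt.frames[-1].true_count
            assert frac >= 0.6
            label, _ = C.classify(model, imgs[-1])
            groups.append(C.group_type(label))
        assert sum(g == "fibrotic" for g in groups) > len(groups) / 2
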