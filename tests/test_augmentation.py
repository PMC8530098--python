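"""Augmentation operators, dataset expansion, class balancing."""

import hashlib

import numpy as np
import pytest

from parconvnet.augmentation import (
    AugmentationPolicy,
    augment_image,
    balance_classes,
    expand_dataset,
)
from parconvnet.synthetic import SyntheticTaskSpec, generate
from parconvnet.training import split_dataset


@pytest.fixture()
def img(rng):
    return (rng.random((40, 40, 3)) * 255).astype(np.uint8)


@pytest.fixture()
def small_split(tmp_path):
    spec = SyntheticTaskSpec(task="cells", n_per_class=6, image_hw=(24, 24),
                             separability=1.0, seed=77)
    return split_dataset(generate(spec, tmp_path / "d"), 0.67, seed=0)


class TestOperators:
    def test_zero_rotation_is_identity(self, img):
        out = augment_image(img, "rotate", {"angle": 0})
        assert np.array_equal(out, img)

    def test_right_angle_rotations_compose_to_identity(self, img):
        out = img
        for _ in range(4):
            out = augment_image(out, "rotate", {"angle": 90})
        assert np.array_equal(out, img)

    def test_flip_is_an_involution(self, img):
        once = augment_image(img, "flip", {"direction": "horizontal"})
        twice = augment_image(once, "flip", {"direction": "horizontal"})
        assert np.array_equal(twice, img)
        assert not np.array_equal(once, img)

    def test_brighten_shifts_mean_by_delta(self, rng):
        # mid-gray image: no clipping, so the mean moves by ~delta
        base = np.full((32, 32, 3), 120, dtype=np.uint8)
        out = augment_image(base, "brighten", {"delta": 0.1})
        shift = out.astype(float).mean() - base.astype(float).mean()
        assert shift == pytest.approx(0.1 * 255, abs=1.0)

    def test_unit_contrast_is_identity_up_to_rounding(self, img):
        out = augment_image(img, "contrast", {"factor": 1.0})
        assert np.abs(out.astype(int) - img.astype(int)).max() <= 1

    @pytest.mark.parametrize("op,params", [
        ("rotate", {"angle": 37.0}),
        ("zoom", {"factor": 1.1}),
        ("zoom", {"factor": 0.9}),
        ("crop", {"fraction": 0.8, "y0": 0.1, "x0": 0.05}),
        ("brighten", {"delta": -0.12}),
        ("contrast", {"factor": 1.2}),
    ])
    def test_geometry_and_dtype_preserved(self, img, op, params):
        out = augment_image(img, op, params)
        assert out.shape == img.shape and out.dtype == np.uint8

    def test_composition_of_two_operators_stays_valid(self, img):
        out = augment_image(img, "zoom", {"factor": 1.1})
        out = augment_image(out, "rotate", {"angle": 15})
        assert out.shape == img.shape and out.dtype == np.uint8

    def test_invalid_crop_fraction_rejected(self, img):
        with pytest.raises(ValueError, match="fraction"):
            augment_image(img, "crop", {"fraction": 1.2})

    def test_unknown_operator_rejected(self, img):
        with pytest.raises(ValueError, match="unknown operator"):
            augment_image(img, "sharpen", {})


class TestExpandDataset:
    def test_train_count_multiplied_labels_preserved(self, small_split):
        policy = AugmentationPolicy(seed=1)
        out = expand_dataset(small_split, policy, factor=3)
        assert len(out.train_records) == 3 * len(small_split.train_records)
        assert out.class_counts("train") == {
            c: 3 * n for c, n in small_split.class_counts("train").items()}

    def test_test_split_never_touched(self, small_split):
        out = expand_dataset(small_split, AugmentationPolicy(seed=1), factor=2)
        assert [r.path for r in out.test_records] == \
               [r.path for r in small_split.test_records]

    def test_factor_one_is_identity(self, small_split):
        assert expand_dataset(small_split, AugmentationPolicy(seed=1), 1) is small_split

    def test_same_seed_gives_byte_identical_images(self, small_split):
        def digest():
            out = expand_dataset(small_split, AugmentationPolicy(seed=9), 2)
            new = [r.path for r in out.train_records
                   if r.path not in {o.path for o in small_split.records}]
            h = hashlib.sha256()
            for p in sorted(new):
                h.update(open(p, "rb").read())
            return h.hexdigest()

        assert digest() == digest()

    def test_expanded_manifest_is_valid(self, small_split):
        out = expand_dataset(small_split, AugmentationPolicy(seed=1), 2)
        out.validate()  # unique paths, vocabulary intact
        assert out.classes == small_split.classes


class TestBalanceClasses:
    def make_imbalanced(self, tmp_path, counts):
        spec = SyntheticTaskSpec(task="cells", n_per_class=max(counts.values()),
                                 image_hw=(24, 24), separability=1.0, seed=13)
        m = generate(spec, tmp_path / "imb")
        keep, kept = [], {c: 0 for c in counts}
        for r in m.records:
            if kept[r.label] < counts[r.label]:
                keep.append(r)
                kept[r.label] += 1
        return m.with_records(keep)

    def test_minority_classes_filled_to_majority(self, tmp_path):
        m = self.make_imbalanced(tmp_path, {"circular": 8, "elongated": 5, "other": 3})
        out = balance_classes(m, AugmentationPolicy(seed=2))
        assert out.class_counts("train") == {"circular": 8, "elongated": 8, "other": 8}

    def test_only_minority_classes_gain_records(self, tmp_path):
        m = self.make_imbalanced(tmp_path, {"circular": 6, "elongated": 2, "other": 6})
        out = balance_classes(m, AugmentationPolicy(seed=2))
        originals = {r.path for r in m.records}
        added = [r for r in out.records if r.path not in originals]
        assert {r.label for r in added} == {"elongated"}
        assert len(added) == 4

    def test_already_balanced_is_a_fixed_point(self, tmp_path):
        m = self.make_imbalanced(tmp_path, {"circular": 4, "elongated": 4, "other": 4})
        out = balance_classes(m, AugmentationPolicy(seed=2))
        assert [r.path for r in out.records] == [r.path for r in m.records]

    def test_single_class_rejected(self, tmp_path):
        m = self.make_imbalanced(tmp_path, {"circular": 4, "elongated": 4, "other": 4})
        only = m.with_records([r for r in m.records if r.label == "circular"])
        # vocabulary still lists three classes, two of which now have no records
        with pytest.raises(ValueError, match="zero train records"):
            balance_classes(only, AugmentationPolicy(seed=2))


class TestPolicy:
    def test_empty_operator_set_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            AugmentationPolicy(operators=())

    def test_json_round_trip(self):
        policy = AugmentationPolicy(operators=("rotate", "zoom"), seed=9,
                                    zoom_range=(0.9, 1.1))
        assert AugmentationPolicy.from_json(policy.to_json()) == policy

    def test_sampled_params_fall_in_ranges(self):
        policy = AugmentationPolicy(seed=0)
        rng = np.random.default_rng(0)
        for _ in range(200):
            op, params = policy.sample(rng)
            assert op in policy.operators
            if op == "zoom":
                lo, hi = policy.zoom_range
                assert lo <= params["factor"] <= hi
            if op == "crop":
                assert 0 <= params["y0"] <= 1 - params["fraction"]
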