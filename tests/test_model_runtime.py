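"""Network instantiation, prediction, feature taps, head surgery, export."""

import numpy as np
import pytest

from parconvnet import _engine as eng
from parconvnet.archspec import lightweight_architecture, trace_shapes
from parconvnet.model_runtime import (
    export_first_layer_filters,
    extract_features,
    instantiate,
    load_checkpoint,
    predict_proba,
    replace_head,
    save_checkpoint,
)


class TestInstantiate:
    def test_seeded_weights_are_bitwise_reproducible(self):
        spec = lightweight_architecture((16, 16), 3, 2)
        a, b = instantiate(spec, 42), instantiate(spec, 42)
        for name, arr in a.named_parameters().items():
            assert np.array_equal(arr, b.named_parameters()[name]), name

    def test_different_seeds_differ(self):
        spec = lightweight_architecture((16, 16), 3, 2)
        a, b = instantiate(spec, 1), instantiate(spec, 2)
        assert not np.array_equal(a.stem[0][0].W, b.stem[0][0].W)

    def test_output_shape_is_batch_by_classes(self, tiny_net, rng):
        x = rng.random((4, 16, 16, 3), dtype=np.float32)
        assert tiny_net.forward(x).shape == (4, 2)

    @pytest.mark.parametrize("hw", [(80, 80), (224, 224), (500, 375), (96, 64)])
    def test_forward_activations_match_shape_trace(self, hw):
        """Brute-force shape oracle: run a real forward pass and compare every
        tapped tensor against the arithmetic trace."""
        spec = lightweight_architecture(hw, 3, 2)
        net = instantiate(spec, 0)
        x = np.random.default_rng(1).random((1, *hw, 3), dtype=np.float32)
        taps = {}
        net.forward(x, taps=taps)
        for name, h, w, c in trace_shapes(spec):
            got = taps[name]
            shape = got.shape[1:] if got.ndim == 4 else (1, 1, got.shape[1])
            assert tuple(shape) == (h, w, c), name


class TestPredictProba:
    def test_rows_are_distributions(self, tiny_net, rng):
        p = predict_proba(tiny_net, rng.random((5, 16, 16, 3), dtype=np.float32))
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_untrained_net_near_uniform_on_zero_image(self, tiny_net):
        p = predict_proba(tiny_net, np.zeros((1, 16, 16, 3), dtype=np.float32))
        np.testing.assert_allclose(p[0], 0.5, atol=0.2)

    def test_duplicated_image_gives_identical_rows(self, tiny_net, rng):
        img = rng.random((16, 16, 3), dtype=np.float32)
        p = predict_proba(tiny_net, np.stack([img, img, img]))
        assert np.array_equal(p[0], p[1]) and np.array_equal(p[1], p[2])

    def test_batch_permutation_equivariance(self, tiny_net, rng):
        x = rng.random((6, 16, 16, 3), dtype=np.float32)
        perm = np.array([3, 1, 5, 0, 2, 4])
        p = predict_proba(tiny_net, x)
        pp = predict_proba(tiny_net, x[perm])
        np.testing.assert_allclose(pp, p[perm], atol=1e-6)

    def test_dimension_mismatch_names_sizes(self, tiny_net, rng):
        with pytest.raises(ValueError, match="16x16"):
            tiny_net.forward(rng.random((1, 20, 20, 3), dtype=np.float32))


class TestExtractFeatures:
    def test_default_layer_yields_200_dims(self, cells_small):
        net = instantiate(lightweight_architecture((32, 32), 3, 3), 0)
        feats = extract_features(net, cells_small)
        assert feats.dim == 200
        assert feats.n_samples == len(cells_small)
        assert np.all(np.isfinite(feats.values))

    def test_gap_layer_width_equals_traced_channels(self, cells_small):
        spec = lightweight_architecture((32, 32), 3, 3)
        net = instantiate(spec, 0)
        feats = extract_features(net, cells_small, "G1")
        assert feats.dim == trace_shapes(spec)["G1"][2] == 288

    def test_empty_manifest_yields_zero_rows(self, cells_small):
        net = instantiate(lightweight_architecture((32, 32), 3, 3), 0)
        empty = cells_small.with_records([])
        assert extract_features(net, empty).n_samples == 0

    def test_unknown_layer_lists_registry(self, cells_small, tiny_net):
        with pytest.raises(KeyError, match="CN1"):
            extract_features(tiny_net, cells_small, "nope")

    def test_head_on_features_equals_end_to_end(self, cells_small):
        """Split-computation consistency: FC1 features pushed through the
        remaining head reproduce the end-to-end probabilities."""
        from parconvnet.model_runtime import load_images

        net = instantiate(lightweight_architecture((32, 32), 3, 3), 0)
        records = cells_small.records[:6]
        probs = predict_proba(net, load_images(records))
        feats = extract_features(net, cells_small.with_records(list(records)))
        head_logits = feats.values @ net.fc2.W + net.fc2.b
        head_probs = eng.softmax(head_logits)
        np.testing.assert_allclose(head_probs, probs, atol=1e-5)


class TestReplaceHead:
    def test_new_class_count_and_preserved_body(self, tiny_net, rng):
        new = replace_head(tiny_net, 3)
        x = rng.random((2, 16, 16, 3), dtype=np.float32)
        assert new.forward(x).shape == (2, 3)
        assert np.array_equal(new.stem[0][0].W, tiny_net.stem[0][0].W)
        assert new.fc2.W.shape == (200, 3)

    def test_same_class_count_reseeds_head_only(self, tiny_net):
        new = replace_head(tiny_net, 2)
        assert np.array_equal(new.blocks[1][3].gamma, tiny_net.blocks[1][3].gamma)
        assert not np.array_equal(new.fc1.W, tiny_net.fc1.W)

    def test_freeze_keeps_body_bit_identical_through_training(self, tiny_net, rng):
        frozen = replace_head(tiny_net, 2, freeze_body=True)
        before = {k: v.copy() for k, v in frozen.named_parameters().items()}
        x = rng.random((4, 16, 16, 3), dtype=np.float32)
        onehot = np.eye(2, dtype=np.float32)[[0, 1, 0, 1]]
        logits = frozen.forward(x, train=True)
        _, d = eng.cross_entropy_grad(eng.softmax(logits), onehot)
        frozen.backward(d)
        frozen.sgd_step(0.1, 0.9)
        for name, arr in frozen.named_parameters().items():
            if name.startswith(("F1", "F2")):
                continue
            if "running" in name:  # BN running stats update in train mode
                continue
            assert np.array_equal(arr, before[name]), name
        assert not np.array_equal(frozen.fc2.W, before["F2.W"])


class TestExportAndCheckpoints:
    def test_filter_grid_contains_32_tiles(self, tiny_net, tmp_path):
        from parconvnet.model_runtime import load_image

        path = export_first_layer_filters(tiny_net, tmp_path / "filters.png")
        grid = load_image(path)
        # 32 tiles of 3x3 on a 4x8 grid with 1-px borders
        assert grid.shape[:2] == (4 * 4 + 1, 8 * 4 + 1)

    def test_constant_filter_maps_to_mid_gray(self, tiny_net, tmp_path):
        from parconvnet.model_runtime import load_image

        tiny_net.stem[0][0].W[:, :, :, 0] = 0.37  # constant filter
        path = export_first_layer_filters(tiny_net, tmp_path / "filters.png")
        grid = load_image(path)
        assert np.all(grid[1:4, 1:4] == 128)

    def test_export_is_deterministic(self, tiny_net, tmp_path):
        p1 = export_first_layer_filters(tiny_net, tmp_path / "a.png")
        p2 = export_first_layer_filters(tiny_net, tmp_path / "b.png")
        assert p1.read_bytes() == p2.read_bytes()

    def test_checkpoint_round_trip_preserves_predictions(self, tiny_net, tmp_path, rng):
        x = rng.random((3, 16, 16, 3), dtype=np.float32)
        before = predict_proba(tiny_net, x)
        path = save_checkpoint(tiny_net, tmp_path / "net.ckpt")
        restored = load_checkpoint(path)
        np.testing.assert_array_equal(predict_proba(restored, x), before)
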