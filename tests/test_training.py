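"""Split arithmetic, the training loop, fine-tuning, and the TL chain."""

import numpy as np
import pytest

from parconvnet.archspec import lightweight_architecture
from parconvnet.manifest import DatasetManifest, ManifestRecord
from parconvnet.model_runtime import instantiate
from parconvnet.training import (
    TrainConfig,
    evaluate,
    finetune,
    same_domain_tl,
    split_dataset,
    train,
)

FAST = TrainConfig(learning_rate=0.01, batch_size=16, max_epochs=2, seed=3)


def path_manifest(counts, split=None):
    records = [
        ManifestRecord(f"mem/{label}/{i}.png", label,
                       split if split else "train")
        for label, n in counts.items() for i in range(n)
    ]
    return DatasetManifest(records=records)


class TestSplitDataset:
    def test_balanced_80_20(self):
        m = path_manifest({"a": 50, "b": 50})
        s = split_dataset(m, 0.8, seed=0)
        assert s.class_counts("train") == {"a": 40, "b": 40}
        assert s.class_counts("test") == {"a": 10, "b": 10}

    def test_55_45_on_4000_records(self):
        m = path_manifest({"a": 2000, "b": 2000})
        s = split_dataset(m, 0.55, seed=0)
        assert len(s.train_records) == 2200
        assert len(s.test_records) == 1800

    def test_every_record_assigned_exactly_once(self):
        m = path_manifest({"a": 33, "b": 17})
        s = split_dataset(m, 0.7, seed=5)
        assert len(s.train_records) + len(s.test_records) == 50

    def test_deterministic_under_seed(self):
        m = path_manifest({"a": 20, "b": 20})
        s1 = split_dataset(m, 0.6, seed=9)
        s2 = split_dataset(m, 0.6, seed=9)
        assert [r.split for r in s1.records] == [r.split for r in s2.records]

    def test_tiny_class_rejected(self):
        m = path_manifest({"a": 10, "b": 1})
        with pytest.raises(ValueError, match="at least 2"):
            split_dataset(m, 0.8, seed=0)

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(path_manifest({"a": 4, "b": 4}), 1.0, seed=0)


class TestTrainLoop:
    def test_zero_epochs_leaves_weights_bit_identical(self, cells_small):
        net = instantiate(lightweight_architecture((32, 32), 3, 3), 1)
        before = {k: v.copy() for k, v in net.named_parameters().items()}
        cfg = TrainConfig(max_epochs=0, seed=0)
        net2, report = train(net, cells_small, cfg)
        for k, v in net2.named_parameters().items():
            assert np.array_equal(v, before[k]), k
        assert report.epoch_losses == []
        assert report.test_metrics is not None

    def test_training_is_bitwise_reproducible(self, ulcer_small):
        def run():
            net = instantiate(lightweight_architecture((32, 32), 3, 2), 5)
            net, rep = train(net, ulcer_small, FAST)
            return net, rep

        n1, r1 = run()
        n2, r2 = run()
        assert r1.epoch_losses == r2.epoch_losses
        for k, v in n1.named_parameters().items():
            assert np.array_equal(v, n2.named_parameters()[k]), k

    def test_losses_recorded_and_finite(self, ulcer_small):
        net = instantiate(lightweight_architecture((32, 32), 3, 2), 5)
        _, rep = train(net, ulcer_small, FAST)
        assert len(rep.epoch_losses) == FAST.max_epochs
        assert all(np.isfinite(l) for l in rep.epoch_losses)

    def test_divergence_raises_descriptive_error(self, ulcer_small):
        net = instantiate(lightweight_architecture((32, 32), 3, 2), 5)
        net.fc2.W[:] = np.nan  # corrupted weights surface as non-finite loss
        with pytest.raises(FloatingPointError, match="diverged"):
            train(net, ulcer_small, FAST)

    def test_empty_train_split_rejected(self, ulcer_small):
        test_only = ulcer_small.with_records(list(ulcer_small.test_records))
        net = instantiate(lightweight_architecture((32, 32), 3, 2), 5)
        with pytest.raises(ValueError, match="no train records"):
            train(net, test_only, FAST)

    def test_geometry_mismatch_rejected(self, ulcer_small):
        net = instantiate(lightweight_architecture((64, 64), 3, 2), 5)
        with pytest.raises(ValueError, match="does not match"):
            train(net, ulcer_small, FAST)


class TestFinetune:
    def test_loss_descends_on_matched_distribution(self, ulcer_small):
        # full-batch updates keep batch-norm statistics stable on 18 images
        net = instantiate(lightweight_architecture((32, 32), 3, 2), 5)
        net, _ = train(net, ulcer_small,
                       TrainConfig(learning_rate=0.01, batch_size=18,
                                   max_epochs=4, seed=3))
        cfg = TrainConfig(learning_rate=0.001, batch_size=18, max_epochs=3, seed=4)
        _, rep = finetune(net, ulcer_small, cfg)
        assert rep.epoch_losses[-1] <= rep.epoch_losses[0]

    def test_head_replaced_when_vocabulary_changes(self, ulcer_small, cells_small):
        net = instantiate(lightweight_architecture((32, 32), 3, 2), 5)
        net, _ = train(net, ulcer_small, FAST)
        net3, rep = finetune(net, cells_small, FAST)
        assert net3.spec.n_classes == 3
        assert set(rep.test_metrics.per_class) == {"circular", "elongated", "other"}

    def test_freeze_body_touches_only_head(self, ulcer_small):
        net = instantiate(lightweight_architecture((32, 32), 3, 2), 5)
        before = {k: v.copy() for k, v in net.named_parameters().items()}
        net2, _ = finetune(net, ulcer_small, FAST, freeze_body=True)
        for k, v in net2.named_parameters().items():
            if k.startswith(("F1", "F2")) or "running" in k:
                continue
            assert np.array_equal(v, before[k]), k


class TestSameDomainTL:
    def test_empty_source_list_equals_plain_training(self, ulcer_small):
        net_tl, rep_tl = same_domain_tl([], ulcer_small, FAST)
        net_direct = instantiate(lightweight_architecture((32, 32), 3, 2), FAST.seed)
        net_direct, rep_direct = train(net_direct, ulcer_small, FAST)
        for k, v in net_tl.named_parameters().items():
            assert np.array_equal(v, net_direct.named_parameters()[k]), k
        assert rep_tl.test_metrics.as_dict() == rep_direct.test_metrics.as_dict()

    def test_zero_target_epochs_evaluates_source_model_unchanged(self, ulcer_small,
                                                                 tmp_path):
        from parconvnet.synthetic import SyntheticTaskSpec, generate

        src = generate(
            SyntheticTaskSpec(task="ulcer", n_per_class=8, image_hw=(32, 32),
                              separability=1.0, seed=55),
            tmp_path / "src",
        )
        frozen_cfg = TrainConfig(max_epochs=0, seed=3)
        net, rep = same_domain_tl([src], ulcer_small, frozen_cfg,
                                  source_config=FAST)
        # same vocabulary: the head is kept, stage B runs zero epochs
        direct = evaluate(net, ulcer_small)
        assert rep.test_metrics.as_dict() == direct.as_dict()
        assert "source" in rep.stages and "target" in rep.stages
        assert rep.stages["target"].epoch_losses == []

    def test_body_handoff_between_stages(self, ulcer_small, cells_small):
        """Body weights leaving stage A enter stage B bit-exactly (head swap
        only) when the vocabularies differ."""
        from parconvnet.training import merge_manifests  # noqa: F401

        cfg0 = TrainConfig(max_epochs=0, seed=3)
        # stage A trains on cells (3 classes) then head is swapped for ulcer
        net, rep = same_domain_tl([cells_small], ulcer_small, cfg0,
                                  source_config=FAST)
        ref = instantiate(lightweight_architecture((32, 32), 3, 3), FAST.seed)
        # replicate stage A: train on all pooled source records
        pooled = cells_small.with_records(
            [ManifestRecord(r.path, r.label, "train") for r in cells_small.records])
        ref, _ = train(ref, pooled, FAST)
        assert np.array_equal(net.stem[0][0].W, ref.stem[0][0].W)
        assert net.spec.n_classes == 2

    def test_geometry_mismatch_across_manifests_rejected(self, ulcer_small, tmp_path):
        from parconvnet.synthetic import SyntheticTaskSpec, generate

        big = generate(
            SyntheticTaskSpec(task="ulcer", n_per_class=2, image_hw=(48, 48),
                              separability=1.0, seed=5),
            tmp_path / "big",
        )
        with pytest.raises(ValueError, match="geometry"):
            same_domain_tl([big], ulcer_small, FAST)
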