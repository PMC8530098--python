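"""Training protocol: SGD with momentum, stratified splits, fine-tuning and
the four-step same-domain transfer-learning chain.

The default configuration is SGD with momentum 0.9, mini-batch 32, up to 100
epochs, initial learning rate 0.001, cross-entropy loss, shuffling every
epoch, no early stopping and no validation split.  Everything is seeded:
identical (data, config, seed) reproduces identical final weights.

The transfer chain mirrors the same-domain recipe: (A) train from scratch on
pooled source manifests with the source vocabulary; (B) replace the head for
the target vocabulary and fine-tune on the target train split; (C) evaluate
on the target test split.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import _engine as eng
from .manifest import DatasetManifest, ManifestRecord, TRAIN, TEST, merge_manifests
from .metrics import MetricsReport, multiclass_metrics
from .model_runtime import (
    NetworkInstance,
    instantiate,
    load_checkpoint,
    load_images,
    predict_proba,
    replace_head,
    save_checkpoint,
)

__all__ = [
    "TrainConfig",
    "TrainedModelReport",
    "split_dataset",
    "train",
    "finetune",
    "same_domain_tl",
    "evaluate",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings (defaults are the canonical protocol).

    ``lr_schedule="step"`` decays the rate by ``step_gamma`` every
    ``step_every`` epochs; the default is a constant rate.
    """

    learning_rate: float = 0.001
    momentum: float = 0.9
    batch_size: int = 32
    max_epochs: int = 100
    seed: int = 0
    lr_schedule: str = "constant"
    step_every: int = 30
    step_gamma: float = 0.1
    shuffle_each_epoch: bool = True

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if self.lr_schedule not in ("constant", "step"):
            raise ValueError("lr_schedule must be 'constant' or 'step'")

    def lr_at(self, epoch: int) -> float:
        if self.lr_schedule == "constant":
            return self.learning_rate
        return self.learning_rate * self.step_gamma ** (epoch // self.step_every)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TrainConfig":
        return cls(**json.loads(text))


@dataclass
class TrainedModelReport:
    """Per-epoch loss curve plus the final test metrics."""

    epoch_losses: list[float] = field(default_factory=list)
    test_metrics: MetricsReport | None = None
    config: TrainConfig | None = None
    wall_time_s: float = 0.0
    stages: dict[str, "TrainedModelReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "epoch_losses": self.epoch_losses,
            "test_metrics": self.test_metrics.as_dict() if self.test_metrics else None,
            "config": asdict(self.config) if self.config else None,
            "wall_time_s": round(self.wall_time_s, 2),
            "stages": {k: v.to_dict() for k, v in self.stages.items()},
        }


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(manifest: DatasetManifest, train_fraction: float,
                  seed: int) -> DatasetManifest:
    """Stratified train/test assignment.

    Each class is shuffled deterministically and the first
    ``floor(train_fraction * n_class)`` records go to train, the remainder
    to test, so e.g. 0.8 on 100 balanced two-class records yields exactly
    40/10 per class and 0.55 on 4,000 yields 2,200/1,800.
    """
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    by_class: dict[str, list[int]] = {c: [] for c in manifest.classes}
    for i, r in enumerate(manifest.records):
        by_class[r.label].append(i)
    for c, idxs in by_class.items():
        if 0 < len(idxs) < 2:
            raise ValueError(
                f"class {c!r} has {len(idxs)} record(s); stratified splitting "
                "needs at least 2 per class"
            )
    assignment = {}
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5B11]))
    for c in manifest.classes:  # fixed vocabulary order for determinism
        idxs = np.array(by_class[c], dtype=int)
        rng.shuffle(idxs)
        n_train = int(np.floor(train_fraction * len(idxs)))
        for j, i in enumerate(idxs):
            assignment[i] = TRAIN if j < n_train else TEST
    records = [
        ManifestRecord(r.path, r.label, assignment[i])
        for i, r in enumerate(manifest.records)
    ]
    return manifest.with_records(records)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _encode_labels(records: Sequence[ManifestRecord], classes: Sequence[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    unknown = [r.label for r in records if r.label not in index]
    if unknown:
        raise ValueError(f"labels outside the vocabulary {tuple(classes)}: {unknown[:3]}")
    return np.array([index[r.label] for r in records], dtype=int)


def evaluate(net: NetworkInstance, manifest: DatasetManifest,
             split: str = TEST) -> MetricsReport:
    """Predict the given split with the softmax head and score it."""
    records = manifest.subset(split)
    if not records:
        raise ValueError(f"manifest has no {split!r} records to evaluate")
    probs = predict_proba(net, load_images(records))
    classes = list(manifest.classes)
    y_pred = [classes[i] for i in probs.argmax(axis=1)]
    y_true = [r.label for r in records]
    return multiclass_metrics(y_true, y_pred, classes=classes)


def train(net: NetworkInstance, manifest: DatasetManifest,
          config: TrainConfig) -> tuple[NetworkInstance, TrainedModelReport]:
    """Mini-batch SGD with momentum on cross-entropy over the train split.

    Runs exactly ``config.max_epochs`` epochs (no early stopping), shuffling
    each epoch when configured, then evaluates the test split (if present)
    with the metrics module.  ``max_epochs=0`` returns the network untouched.
    Divergence (non-finite loss) raises rather than corrupting weights.
    """
    t0 = time.perf_counter()
    report = TrainedModelReport(config=config)
    if config.max_epochs == 0:
        if manifest.test_records:
            report.test_metrics = evaluate(net, manifest)
        report.wall_time_s = time.perf_counter() - t0
        return net, report

    train_records = manifest.train_records
    if not train_records:
        raise ValueError("manifest has no train records")
    if net.spec.n_classes != len(manifest.classes):
        raise ValueError(
            f"head has {net.spec.n_classes} classes but the manifest "
            f"vocabulary has {len(manifest.classes)}"
        )
    y = _encode_labels(train_records, manifest.classes)
    x = load_images(train_records).astype(eng.F32) / eng.F32(255.0)
    h, w = net.spec.input_hw
    if x.shape[1] != h or x.shape[2] != w:
        raise ValueError(
            f"image size {x.shape[1]}x{x.shape[2]} does not match the "
            f"network input {h}x{w}"
        )
    onehot = np.eye(net.spec.n_classes, dtype=eng.F32)[y]

    shuffle_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7A]))
    n = len(train_records)
    for epoch in range(config.max_epochs):
        order = np.arange(n)
        if config.shuffle_each_epoch:
            shuffle_rng.shuffle(order)
        lr = config.lr_at(epoch)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = net.forward(x[idx], train=True)
            probs = eng.softmax(logits)
            loss, dlogits = eng.cross_entropy_grad(probs, onehot[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss}"
                )
            net.backward(dlogits)
            net.sgd_step(lr, config.momentum)
            losses.append(loss)
        report.epoch_losses.append(float(np.mean(losses)))

    net.release_buffers()  # training-sized scratch can reach gigabytes
    if manifest.test_records:
        report.test_metrics = evaluate(net, manifest)
    report.wall_time_s = time.perf_counter() - t0
    return net, report


def finetune(net: NetworkInstance, manifest: DatasetManifest, config: TrainConfig,
             freeze_body: bool = False) -> tuple[NetworkInstance, TrainedModelReport]:
    """Continue training from the provided weights.

    If the head's class count does not match the manifest vocabulary the
    head is replaced first (seeded from ``config.seed``).  ``freeze_body``
    restricts updates to the fully connected head.
    """
    if net.spec.n_classes != len(manifest.classes):
        net = replace_head(net, len(manifest.classes), seed=config.seed)
    if freeze_body:
        net.set_body_trainable(False)
    try:
        return train(net, manifest, config)
    finally:
        net.set_body_trainable(True)


def same_domain_tl(
    source_manifests: list[DatasetManifest],
    target_manifest: DatasetManifest,
    config: TrainConfig,
    source_config: TrainConfig | None = None,
    freeze_body: bool = False,
) -> tuple[NetworkInstance, TrainedModelReport]:
    """Same-domain transfer chain: pretrain on sources, fine-tune on target.

    Stage A trains a fresh network on the pooled source manifests (all
    their records are used as training data, under the source vocabulary).
    Stage B carries the body over, replaces the head for the target
    vocabulary, and fine-tunes on the target train split.  Stage C
    evaluates on the target test split.  An empty source list degenerates
    to plain from-scratch training on the target.
    """
    source_config = source_config or config
    report = TrainedModelReport(config=config)

    geometry = target_manifest  # all manifests must share image geometry
    from .model_runtime import load_image

    def geom_of(manifest):
        return load_image(manifest.records[0].path).shape[:2] if manifest.records else None

    target_hw = geom_of(geometry)
    for m in source_manifests:
        hw = geom_of(m)
        if hw is not None and target_hw is not None and hw != target_hw:
            raise ValueError(
                f"source geometry {hw} does not match target geometry {target_hw}"
            )

    from .archspec import lightweight_architecture

    if not source_manifests:
        spec = lightweight_architecture(target_hw, 3, len(target_manifest.classes))
        net = instantiate(spec, config.seed)
        net, rep = train(net, target_manifest, config)
        report.stages["target"] = rep
        report.epoch_losses = rep.epoch_losses
        report.test_metrics = rep.test_metrics
        return net, report

    pooled = merge_manifests(source_manifests)
    # stage A trains on every pooled source record
    pooled = pooled.with_records(
        [ManifestRecord(r.path, r.label, TRAIN) for r in pooled.records])
    spec = lightweight_architecture(target_hw, 3, len(pooled.classes))
    net = instantiate(spec, source_config.seed)
    net, rep_a = train(net, pooled, source_config)
    report.stages["source"] = rep_a

    if tuple(pooled.classes) != tuple(target_manifest.classes):
        net = replace_head(net, len(target_manifest.classes), seed=config.seed)
    if freeze_body:
        net.set_body_trainable(False)
    try:
        net, rep_b = train(net, target_manifest, config)
    finally:
        net.set_body_trainable(True)
    report.stages["target"] = rep_b
    report.epoch_losses = rep_a.epoch_losses + rep_b.epoch_losses
    report.test_metrics = rep_b.test_metrics
    return net, report
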