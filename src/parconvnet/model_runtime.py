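"""Instantiate and run the lightweight network.

Builds a trainable numpy network from an :class:`~parconvnet.archspec.ArchitectureSpec`,
with every Table-style layer name (``C1`` ... ``C11``, ``CN1``, ``B1x``, ``G1``,
``F1``, ``F2``, ``O``) registered as a tappable activation.  Provides batched
softmax prediction, named-layer feature extraction for the SVM hybrid stage,
head replacement for transfer learning, first-layer filter export, and
checkpoint save/load.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import _engine as eng
from .archspec import ArchitectureSpec, ParallelBlockSpec, trace_shapes

__all__ = [
    "NetworkInstance",
    "FeatureMatrix",
    "instantiate",
    "predict_proba",
    "extract_features",
    "replace_head",
    "export_first_layer_filters",
    "save_checkpoint",
    "load_checkpoint",
    "load_image",
    "load_images",
]

DEFAULT_FEATURE_LAYER = "F1"
_PREDICT_CHUNK = 16


@dataclass
class FeatureMatrix:
    """n_samples x d activations tapped at one named layer."""

    values: np.ndarray
    layer_name: str
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


class NetworkInstance:
    """A runnable network: spec + weights + named activation registry.

    Built by :func:`instantiate`; the layer graph mirrors the spec exactly
    (sequential stem, parallel blocks with a residual fifth concat input,
    GAP head).  ``forward`` returns logits; pass ``taps`` to collect named
    activations on the way.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int):
        self.spec = spec
        self.init_seed = seed
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([seed, 0xD0]))

        def bn_relu(conv_name: str, c: int):
            i = conv_name[1:]
            return eng.BatchNorm(f"B{i}", c), eng.ReLU(f"R{i}")

        cin = spec.in_channels
        self.stem: list[tuple[eng.Conv2D, eng.BatchNorm, eng.ReLU]] = []
        for conv in spec.stem:
            c = eng.Conv2D(conv.name, conv.filter_hw, conv.stride, cin,
                           conv.out_channels, rng)
            bn, relu = bn_relu(conv.name, conv.out_channels)
            self.stem.append((c, bn, relu))
            cin = conv.out_channels

        self.blocks = []
        for bspec in spec.blocks:
            branches = []
            out_c = 0
            for conv in bspec.branches:
                c = eng.Conv2D(conv.name, conv.filter_hw, conv.stride, cin,
                               conv.out_channels, rng)
                bn, relu = bn_relu(conv.name, conv.out_channels)
                branches.append((c, bn, relu))
                out_c += conv.out_channels
            shortcut = None
            if bspec.shortcut is not None:
                sc = bspec.shortcut
                conv = eng.Conv2D(sc.name, sc.filter_hw, sc.stride, cin,
                                  sc.out_channels, rng)
                bn, relu = bn_relu(sc.name, sc.out_channels)
                shortcut = (conv, bn, relu)
                out_c += sc.out_channels
            else:
                out_c += cin
            post_bn = (eng.BatchNorm(f"B{bspec.name[-1]}x", out_c)
                       if bspec.post_concat_bn else None)
            self.blocks.append((bspec, branches, shortcut, post_bn))
            cin = out_c

        self.gap = eng.GlobalAvgPool("G1")
        self.fc1 = eng.Dense("F1", cin, spec.fc1_units, rng)
        self.fc1_relu = eng.ReLU("RF1")
        self.dropout = eng.Dropout("D1", spec.dropout_rate, self._dropout_rng)
        self.fc2 = eng.Dense("F2", spec.fc1_units, spec.n_classes, rng)
        self._body_dim = cin

    # -- structure ----------------------------------------------------------

    def _iter_layers(self, body_only: bool = False):
        for triple in self.stem:
            yield from triple
        for _, branches, shortcut, post_bn in self.blocks:
            for triple in branches:
                yield from triple
            if shortcut is not None:
                yield from shortcut
            if post_bn is not None:
                yield post_bn
        if not body_only:
            yield self.fc1
            yield self.fc2

    def head_layers(self):
        return [self.fc1, self.fc2]

    def body_layers(self):
        return list(self._iter_layers(body_only=True))

    def layer_names(self) -> list[str]:
        """All tappable activation names, in forward order."""
        names = ["Input"]
        for triple in self.stem:
            names += [l.name for l in triple]
        for bspec, branches, shortcut, post_bn in self.blocks:
            for triple in branches:
                names += [l.name for l in triple]
            if shortcut is not None:
                names += [l.name for l in shortcut]
            names.append(bspec.name)
            if post_bn is not None:
                names.append(post_bn.name)
        names += ["G1", "F1", "D1", "F2", "O"]
        return names

    def named_parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for layer in self._iter_layers():
            for k, v in layer.params().items():
                out[f"{layer.name}.{k}"] = v
            if isinstance(layer, eng.BatchNorm):
                out[f"{layer.name}.running_mean"] = layer.running_mean
                out[f"{layer.name}.running_var"] = layer.running_var
        return out

    def set_body_trainable(self, trainable: bool) -> None:
        for layer in self.body_layers():
            layer.trainable = trainable

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False,
                taps: dict[str, np.ndarray] | None = None) -> np.ndarray:
        """Run the network; ``x`` is NHWC float32 in [0, 1]; returns logits."""
        if x.ndim != 4:
            raise ValueError(f"expected NHWC batch, got shape {x.shape}")
        h, w = self.spec.input_hw
        if x.shape[1] != h or x.shape[2] != w or x.shape[3] != self.spec.in_channels:
            raise ValueError(
                f"input size mismatch: expected {h}x{w}x{self.spec.in_channels}, "
                f"received {x.shape[1]}x{x.shape[2]}x{x.shape[3]}"
            )

        def tap(name, val):
            if taps is not None:
                taps[name] = val

        tap("Input", x)
        out = x.astype(eng.F32, copy=False)
        for conv, bn, relu in self.stem:
            out = relu.forward(bn.forward(conv.forward(out, train), train), train)
            tap(conv.name, out)  # conv/bn/relu share the post-ReLU tensor
            tap(bn.name, out)
            tap(relu.name, out)

        for bspec, branches, shortcut, post_bn in self.blocks:
            block_in = out
            pieces = []
            for conv, bn, relu in branches:
                b = relu.forward(bn.forward(conv.forward(block_in, train), train), train)
                tap(conv.name, b)
                tap(bn.name, b)
                tap(relu.name, b)
                pieces.append(b)
            if shortcut is not None:
                conv, bn, relu = shortcut
                s = relu.forward(bn.forward(conv.forward(block_in, train), train), train)
                tap(conv.name, s)
                tap(bn.name, s)
                tap(relu.name, s)
                pieces.append(s)
            else:
                pieces.append(block_in)
            out = np.concatenate(pieces, axis=3)
            if train:
                self._concat_splits = getattr(self, "_concat_splits", {})
                self._concat_splits[bspec.name] = [p.shape[3] for p in pieces]
            tap(bspec.name, out)
            if post_bn is not None:
                out = post_bn.forward(out, train)
                tap(post_bn.name, out)

        out = self.gap.forward(out, train)
        tap("G1", out)
        out = self.fc1_relu.forward(self.fc1.forward(out, train), train)
        tap("F1", out)
        out = self.dropout.forward(out, train)
        tap("D1", out)
        logits = self.fc2.forward(out, train)
        tap("F2", logits)
        if taps is not None:
            taps["O"] = eng.softmax(logits)
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        """Backprop through the whole graph; fills every layer's gradients."""
        d = self.fc2.backward(dlogits)
        d = self.dropout.backward(d)
        d = self.fc1.backward(self.fc1_relu.backward(d))
        d = self.gap.backward(d)

        for bspec, branches, shortcut, post_bn in reversed(self.blocks):
            if post_bn is not None:
                d = post_bn.backward(d)
            splits = np.cumsum(self._concat_splits[bspec.name])[:-1]
            pieces = np.split(d, splits, axis=3)
            d_in = None

            def back_triple(triple, dpiece):
                conv, bn, relu = triple
                return conv.backward(bn.backward(relu.backward(dpiece)))

            for triple, dpiece in zip(branches, pieces[:4]):
                contrib = back_triple(triple, dpiece)
                d_in = contrib if d_in is None else d_in + contrib
            if shortcut is not None:
                d_in += back_triple(shortcut, pieces[4])
            else:
                d_in += pieces[4]  # pass-through residual
            d = d_in

        for conv, bn, relu in reversed(self.stem):
            d = conv.backward(bn.backward(relu.backward(d)))

    def sgd_step(self, lr: float, momentum: float) -> None:
        for layer in self._iter_layers():
            layer.sgd_step(lr, momentum)

    def release_buffers(self) -> None:
        """Free all layers' scratch buffers (weights are untouched)."""
        for triple in self.stem:
            for layer in triple:
                layer.release()
        for _, branches, shortcut, post_bn in self.blocks:
            for triple in branches:
                for layer in triple:
                    layer.release()
            if shortcut is not None:
                for layer in shortcut:
                    layer.release()
            if post_bn is not None:
                post_bn.release()
        for layer in (self.gap, self.fc1, self.fc1_relu, self.dropout, self.fc2):
            layer.release()


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def instantiate(spec: ArchitectureSpec, seed: int) -> NetworkInstance:
    """Build a network with He-initialized weights, deterministic in ``seed``."""
    return NetworkInstance(spec, seed)


def _as_batch(images: np.ndarray) -> np.ndarray:
    x = np.asarray(images)
    if x.ndim == 3:
        x = x[None]
    if x.dtype == np.uint8:
        x = x.astype(eng.F32) / eng.F32(255.0)
    return x.astype(eng.F32, copy=False)


def predict_proba(net: NetworkInstance, images: np.ndarray) -> np.ndarray:
    """Class probabilities for an NHWC batch (uint8 or float in [0, 1]).

    Evaluation mode: dropout inactive, batch-norm uses running statistics,
    so the output is a deterministic function of the weights.  Each row is
    a softmax distribution summing to 1.
    """
    x = _as_batch(images)
    out = []
    for i in range(0, x.shape[0], _PREDICT_CHUNK):
        logits = net.forward(x[i:i + _PREDICT_CHUNK], train=False)
        out.append(eng.softmax(logits))
    net.release_buffers()
    return np.concatenate(out, axis=0) if out else np.zeros((0, net.spec.n_classes))


def extract_features(net: NetworkInstance, manifest, layer_name: str = DEFAULT_FEATURE_LAYER,
                     split: str | None = None) -> FeatureMatrix:
    """Tap a named layer for every manifest record (row order = record order).

    The default tap is the 200-unit fully connected layer, the layer whose
    higher-level features feed the SVM hybrid stage.  Spatial activations are
    flattened per sample.  ``split`` restricts to one split tag.
    """
    known = net.layer_names()
    if layer_name not in known:
        raise KeyError(
            f"unknown layer {layer_name!r}; registered layers: {', '.join(known)}"
        )
    records = [r for r in manifest.records if split is None or r.split == split]
    if not records:
        return FeatureMatrix(np.zeros((0, 0), dtype=eng.F32), layer_name, [])
    rows, ids = [], []
    for i in range(0, len(records), _PREDICT_CHUNK):
        chunk = records[i:i + _PREDICT_CHUNK]
        x = _as_batch(np.stack([load_image(r.path) for r in chunk]))
        taps: dict[str, np.ndarray] = {}
        net.forward(x, train=False, taps=taps)
        act = taps[layer_name]
        # copy: tapped arrays alias engine scratch buffers reused by the next chunk
        rows.append(act.reshape(act.shape[0], -1).copy())
        ids += [r.path for r in chunk]
    net.release_buffers()
    return FeatureMatrix(np.concatenate(rows, axis=0), layer_name, ids)


def replace_head(net: NetworkInstance, n_classes: int, freeze_body: bool = False,
                 seed: int | None = None) -> NetworkInstance:
    """Return a network with the same body and a freshly initialized FC head.

    Body weights (convs, batch-norms, running statistics) are copied
    bit-exactly; FC1 and FC2 are re-initialized for ``n_classes`` outputs.
    With ``freeze_body`` the body is marked non-trainable, the standard
    frozen-feature-extractor variant of fine-tuning.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    from dataclasses import replace as dc_replace

    new_spec = dc_replace(net.spec, n_classes=n_classes)
    head_seed = seed if seed is not None else net.init_seed + 1
    new = NetworkInstance(new_spec, net.init_seed)
    # copy body parameters bit-exactly
    for old_l, new_l in zip(net.body_layers(), new.body_layers()):
        for k, v in old_l.params().items():
            new_l.params()[k][...] = v
        if isinstance(old_l, eng.BatchNorm):
            new_l.running_mean[...] = old_l.running_mean
            new_l.running_var[...] = old_l.running_var
    # fresh head
    rng = np.random.default_rng(np.random.SeedSequence([head_seed, 0xF0]))
    new.fc1 = eng.Dense("F1", new._body_dim, new_spec.fc1_units, rng)
    new.fc2 = eng.Dense("F2", new_spec.fc1_units, n_classes, rng)
    if freeze_body:
        new.set_body_trainable(False)
    return new


def export_first_layer_filters(net: NetworkInstance, path) -> Path:
    """Write the first convolution's filters as a tiled PNG grid.

    Each of the C1 filters becomes one RGB tile, min-max normalized to
    [0, 255] (a constant filter maps to mid-gray 128), laid out on a grid
    with a 1-pixel black border.
    """
    conv = net.stem[0][0]
    w = conv.W  # (k, k, cin, cout)
    k, _, cin, cout = w.shape
    ncols = 8 if cout % 8 == 0 else int(np.ceil(np.sqrt(cout)))
    nrows = int(np.ceil(cout / ncols))
    grid = np.zeros((nrows * (k + 1) + 1, ncols * (k + 1) + 1, 3), dtype=np.uint8)
    for idx in range(cout):
        f = w[:, :, :, idx]
        lo, hi = float(f.min()), float(f.max())
        if hi - lo < 1e-12:
            tile = np.full((k, k, cin), 128, dtype=np.uint8)
        else:
            tile = np.round((f - lo) / (hi - lo) * 255).astype(np.uint8)
        if cin == 1:
            tile = np.repeat(tile, 3, axis=2)
        r, c = divmod(idx, ncols)
        grid[r * (k + 1) + 1: r * (k + 1) + 1 + k,
             c * (k + 1) + 1: c * (k + 1) + 1 + k] = tile[:, :, :3]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, grid)
    return path


# ---------------------------------------------------------------------------
# checkpoints and image IO
# ---------------------------------------------------------------------------

def save_checkpoint(net: NetworkInstance, path) -> Path:
    """Single-archive checkpoint: spec JSON + every named weight array."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.BytesIO()
    np.savez(buf, **net.named_parameters())
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("spec.json", net.spec.to_json())
        zf.writestr("meta.json", json.dumps({"init_seed": net.init_seed}))
        zf.writestr("weights.npz", buf.getvalue())
    return path


def load_checkpoint(path) -> NetworkInstance:
    with zipfile.ZipFile(Path(path)) as zf:
        spec = ArchitectureSpec.from_json(zf.read("spec.json").decode())
        meta = json.loads(zf.read("meta.json").decode())
        arrays = np.load(io.BytesIO(zf.read("weights.npz")))
        net = NetworkInstance(spec, meta["init_seed"])
        params = net.named_parameters()
        for name in params:
            params[name][...] = arrays[name]
    return net


def load_image(path) -> np.ndarray:
    """Read an image file as HWC uint8, forcing 3 channels."""
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    if img.shape[2] == 4:
        img = img[:, :, :3]
    return img


def load_images(records) -> np.ndarray:
    """Stack the images of manifest records into one NHWC uint8 batch."""
    return np.stack([load_image(r.path) for r in records])
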