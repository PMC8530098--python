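"""Declarative architecture description and shape/parameter arithmetic.

The lightweight network is described as plain data (:class:`ArchitectureSpec`)
so its structure — a two-conv stem, two parallel-convolution blocks with a
residual fifth input, and a GAP head — can be checked layer by layer without
instantiating or training anything.  :func:`trace_shapes` performs the exact
"same"-padding convolution arithmetic and :func:`parameter_count` the trainable
weight count; both are pure functions of the spec.

Every convolution is implicitly followed by batch normalization and a ReLU.
Spatial arithmetic uses the TensorFlow-style SAME convention,
``out = ceil(in / stride)``, applied per axis so non-square inputs work.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

__all__ = [
    "ConvLayerSpec",
    "ParallelBlockSpec",
    "ArchitectureSpec",
    "ShapeTrace",
    "ArchitectureError",
    "lightweight_architecture",
    "trace_shapes",
    "parameter_count",
]

_ALLOWED_FILTERS = (1, 3, 5, 7)
_ALLOWED_STRIDES = (1, 2)

MIN_INPUT_SIDE = 16


class ArchitectureError(ValueError):
    """Raised for structurally invalid or infeasible architecture specs."""


@dataclass(frozen=True)
class ConvLayerSpec:
    """One convolution layer (conv -> batch-norm -> ReLU).

    Parameters
    ----------
    name : str
        Layer identifier (``C1`` ... ``C11`` in the canonical network).
    filter_hw : int
        Square filter side, one of 1/3/5/7.
    stride : int
        Spatial stride, 1 or 2.
    out_channels : int
        Number of output feature maps.
    padding : str
        Only ``"same"`` is supported: ``out = ceil(in / stride)``.
    """

    name: str
    filter_hw: int
    stride: int
    out_channels: int
    padding: str = "same"

    def __post_init__(self) -> None:
        if self.filter_hw not in _ALLOWED_FILTERS:
            raise ArchitectureError(
                f"{self.name}: filter size {self.filter_hw} not in {_ALLOWED_FILTERS}"
            )
        if self.stride not in _ALLOWED_STRIDES:
            raise ArchitectureError(
                f"{self.name}: stride {self.stride} not in {_ALLOWED_STRIDES}"
            )
        if self.out_channels <= 0:
            raise ArchitectureError(f"{self.name}: out_channels must be positive")
        if self.padding != "same":
            raise ArchitectureError(f"{self.name}: only 'same' padding is supported")


@dataclass(frozen=True)
class ParallelBlockSpec:
    """Four parallel convolutions plus a residual fifth input, concatenated.

    The residual is either a pass-through of the block input (``shortcut is
    None``) or a projection convolution applied to it.  The concatenation
    therefore always has exactly five inputs; ``post_concat_bn`` adds the
    batch-norm layer that follows it.
    """

    name: str
    branches: tuple[ConvLayerSpec, ...]
    shortcut: ConvLayerSpec | None = None
    post_concat_bn: bool = True

    def __post_init__(self) -> None:
        if len(self.branches) != 4:
            raise ArchitectureError(
                f"{self.name}: a parallel block needs exactly 4 branches, "
                f"got {len(self.branches)}"
            )
        strides = {b.stride for b in self.branches}
        if len(strides) != 1:
            raise ArchitectureError(
                f"{self.name}: branches must share one stride so their outputs "
                "have identical spatial dimensions"
            )
        if self.shortcut is not None and self.shortcut.stride != self.branches[0].stride:
            raise ArchitectureError(
                f"{self.name}: shortcut stride must match branch stride"
            )
        if self.shortcut is None and self.branches[0].stride != 1:
            raise ArchitectureError(
                f"{self.name}: a pass-through shortcut requires stride-1 branches"
            )

    @property
    def out_channels(self) -> int:
        c = sum(b.out_channels for b in self.branches)
        if self.shortcut is not None:
            return c + self.shortcut.out_channels
        return c  # pass-through contribution added at trace time

    @property
    def stride(self) -> int:
        return self.branches[0].stride


@dataclass(frozen=True)
class ArchitectureSpec:
    """Full description of the lightweight network.

    ``stem`` runs sequentially, each ``blocks`` entry is a parallel block fed
    by the previous stage, and the head is fixed to
    GAP -> FC(fc1_units) -> dropout -> FC(n_classes) -> softmax.
    """

    input_hw: tuple[int, int]
    in_channels: int
    stem: tuple[ConvLayerSpec, ...]
    blocks: tuple[ParallelBlockSpec, ...]
    n_classes: int
    fc1_units: int = 200
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        h, w = self.input_hw
        if h < MIN_INPUT_SIDE or w < MIN_INPUT_SIDE:
            raise ArchitectureError(
                f"input size {h}x{w} is too small; both sides must be >= {MIN_INPUT_SIDE}"
            )
        if self.in_channels <= 0:
            raise ArchitectureError("in_channels must be positive")
        if self.n_classes < 2:
            raise ArchitectureError("n_classes must be >= 2")
        if self.fc1_units <= 0:
            raise ArchitectureError("fc1_units must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ArchitectureError("dropout_rate must be in [0, 1)")

    # -- JSON round trip ----------------------------------------------------

    def to_json(self) -> str:
        def conv(c: ConvLayerSpec) -> dict:
            return {
                "name": c.name,
                "filter_hw": c.filter_hw,
                "stride": c.stride,
                "out_channels": c.out_channels,
                "padding": c.padding,
            }

        payload = {
            "input_hw": list(self.input_hw),
            "in_channels": self.in_channels,
            "stem": [conv(c) for c in self.stem],
            "blocks": [
                {
                    "name": b.name,
                    "branches": [conv(c) for c in b.branches],
                    "shortcut": conv(b.shortcut) if b.shortcut else None,
                    "post_concat_bn": b.post_concat_bn,
                }
                for b in self.blocks
            ],
            "n_classes": self.n_classes,
            "fc1_units": self.fc1_units,
            "dropout_rate": self.dropout_rate,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        d = json.loads(text)

        def conv(c: dict) -> ConvLayerSpec:
            return ConvLayerSpec(**c)

        return cls(
            input_hw=tuple(d["input_hw"]),
            in_channels=d["in_channels"],
            stem=tuple(conv(c) for c in d["stem"]),
            blocks=tuple(
                ParallelBlockSpec(
                    name=b["name"],
                    branches=tuple(conv(c) for c in b["branches"]),
                    shortcut=conv(b["shortcut"]) if b["shortcut"] else None,
                    post_concat_bn=b["post_concat_bn"],
                )
                for b in d["blocks"]
            ),
            n_classes=d["n_classes"],
            fc1_units=d["fc1_units"],
            dropout_rate=d["dropout_rate"],
        )


@dataclass
class ShapeTrace:
    """Ordered record of (layer name, height, width, channels)."""

    entries: list[tuple[str, int, int, int]] = field(default_factory=list)

    def __iter__(self) -> Iterator[tuple[str, int, int, int]]:
        return iter(self.entries)

    def __getitem__(self, name: str) -> tuple[int, int, int]:
        for entry, h, w, c in self.entries:
            if entry == name:
                return (h, w, c)
        raise KeyError(f"no layer named {name!r}; known: {self.names()}")

    def names(self) -> list[str]:
        return [e[0] for e in self.entries]

    def to_csv(self) -> str:
        lines = ["layer,height,width,channels"]
        lines += [f"{n},{h},{w},{c}" for n, h, w, c in self.entries]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# canonical architecture
# ---------------------------------------------------------------------------

def lightweight_architecture(
    input_hw: tuple[int, int] | int,
    in_channels: int = 3,
    n_classes: int = 2,
) -> ArchitectureSpec:
    """Build the canonical lightweight parallel-convolution network.

    Stem: C1 (3x3, s1, 32) then C2 (5x5, s2, 32), halving the input.
    Block 1: 1/3/5/7 branches at stride 1 with 32 channels each, plus the
    stem output passed through as the residual fifth input (concat -> 160
    channels for 32-channel branches), followed by batch-norm B1x.
    Block 2: the same four filter sizes at stride 2 with 64 channels each,
    plus a 3x3 stride-2 32-channel projection (C11) of the block-1 output as
    the residual, followed by B2x.  Head: GAP -> FC(200) -> dropout(0.5) ->
    FC(n_classes) -> softmax.

    Parameters
    ----------
    input_hw : (int, int) or int
        Input height and width in pixels (square if a single int).  Both
        sides must be at least 16.  Non-square inputs are supported; the GAP
        head makes the parameter count independent of input size.
    in_channels : int
        Input channels (3 for RGB patches).
    n_classes : int
        Output classes (>= 2).
    """
    if isinstance(input_hw, int):
        input_hw = (input_hw, input_hw)
    h, w = input_hw
    if h <= 0 or w <= 0:
        raise ArchitectureError(f"input size must be positive, got {h}x{w}")

    stem = (
        ConvLayerSpec("C1", 3, 1, 32),
        ConvLayerSpec("C2", 5, 2, 32),
    )
    block1 = ParallelBlockSpec(
        name="CN1",
        branches=(
            ConvLayerSpec("C3", 1, 1, 32),
            ConvLayerSpec("C4", 3, 1, 32),
            ConvLayerSpec("C5", 5, 1, 32),
            ConvLayerSpec("C6", 7, 1, 32),
        ),
        shortcut=None,  # pass-through of the C2 output
    )
    block2 = ParallelBlockSpec(
        name="CN2",
        branches=(
            ConvLayerSpec("C7", 1, 2, 64),
            ConvLayerSpec("C8", 3, 2, 64),
            ConvLayerSpec("C9", 5, 2, 64),
            ConvLayerSpec("C10", 7, 2, 64),
        ),
        shortcut=ConvLayerSpec("C11", 3, 2, 32),
    )
    return ArchitectureSpec(
        input_hw=(h, w),
        in_channels=in_channels,
        stem=stem,
        blocks=(block1, block2),
        n_classes=n_classes,
    )


# ---------------------------------------------------------------------------
# shape arithmetic
# ---------------------------------------------------------------------------

def _same_out(size: int, stride: int) -> int:
    return math.ceil(size / stride)


def trace_shapes(spec: ArchitectureSpec) -> ShapeTrace:
    """Trace (h, w, c) through every named layer of the spec.

    Pure conv arithmetic: "same" padding gives ``out = ceil(in / stride)``
    per axis; concatenation sums channel counts over its five inputs; GAP
    collapses to ``1 x 1 x C``.  Raises :class:`ArchitectureError` if a
    spatial dimension would reach zero before the GAP.
    """
    trace = ShapeTrace()
    h, w = spec.input_hw
    c = spec.in_channels
    trace.entries.append(("Input", h, w, c))

    def apply_conv(conv: ConvLayerSpec, h: int, w: int) -> tuple[int, int]:
        oh, ow = _same_out(h, conv.stride), _same_out(w, conv.stride)
        if oh < 1 or ow < 1:
            raise ArchitectureError(
                f"{conv.name}: spatial dimension collapsed to {oh}x{ow}"
            )
        return oh, ow

    for conv in spec.stem:
        h, w = apply_conv(conv, h, w)
        c = conv.out_channels
        trace.entries.append((conv.name, h, w, c))

    for block in spec.blocks:
        in_h, in_w, in_c = h, w, c
        out_c = 0
        for conv in block.branches:
            bh, bw = apply_conv(conv, in_h, in_w)
            trace.entries.append((conv.name, bh, bw, conv.out_channels))
            out_c += conv.out_channels
        if block.shortcut is not None:
            sh, sw = apply_conv(block.shortcut, in_h, in_w)
            trace.entries.append((block.shortcut.name, sh, sw, block.shortcut.out_channels))
            out_c += block.shortcut.out_channels
        else:
            out_c += in_c  # pass-through residual
        h, w = _same_out(in_h, block.stride), _same_out(in_w, block.stride)
        trace.entries.append((block.name, h, w, out_c))
        c = out_c
        if block.post_concat_bn:
            trace.entries.append((f"B{block.name[-1]}x", h, w, c))

    trace.entries.append(("G1", 1, 1, c))
    trace.entries.append(("F1", 1, 1, spec.fc1_units))
    trace.entries.append(("D1", 1, 1, spec.fc1_units))
    trace.entries.append(("F2", 1, 1, spec.n_classes))
    trace.entries.append(("O", 1, 1, spec.n_classes))
    return trace


# ---------------------------------------------------------------------------
# parameter arithmetic
# ---------------------------------------------------------------------------

def parameter_count(spec: ArchitectureSpec) -> int:
    """Total trainable weights: conv ``fh*fw*Cin*Cout + Cout``, BN ``2*C``
    (scale and shift; running statistics are not trainable), FC
    ``in*out + out``.  The fully convolutional body plus GAP makes the total
    independent of ``input_hw``.
    """
    total = 0

    def conv_params(conv: ConvLayerSpec, cin: int) -> int:
        w = conv.filter_hw * conv.filter_hw * cin * conv.out_channels + conv.out_channels
        bn = 2 * conv.out_channels
        return w + bn

    cin = spec.in_channels
    for conv in spec.stem:
        total += conv_params(conv, cin)
        cin = conv.out_channels

    for block in spec.blocks:
        out_c = 0
        for conv in block.branches:
            total += conv_params(conv, cin)
            out_c += conv.out_channels
        if block.shortcut is not None:
            total += conv_params(block.shortcut, cin)
            out_c += block.shortcut.out_channels
        else:
            out_c += cin
        cin = out_c
        if block.post_concat_bn:
            total += 2 * cin

    total += cin * spec.fc1_units + spec.fc1_units  # FC1
    total += spec.fc1_units * spec.n_classes + spec.n_classes  # FC2
    return total
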