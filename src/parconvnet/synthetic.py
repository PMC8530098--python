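"""Seeded synthetic image generators for the three patch-classification tasks.

Three generators emulate the statistical structure of the tasks the toolkit
targets, so every pipeline stage can be exercised without any download:

* ``cells`` — 80x80, 3 classes of single red-blood-cell morphology
  (``circular`` low-eccentricity discs, ``elongated`` high-eccentricity
  sickle-like cells, ``other`` irregular blobs);
* ``ulcer`` — 224x224, 2 classes of foot-skin patches (``normal`` smooth
  skin texture, ``abnormal`` skin with a dark-red irregular wound region);
* ``lesion`` — 500x375, 2 classes of skin-lesion patches (``benign``
  symmetric uniform blob, ``malignant`` asymmetric, irregular-bordered,
  multi-tone blob, the ABCD-rule cues).

The emulation target is class-conditional shape/texture/contrast structure,
not photorealism.  ``separability`` in (0, 1] scales how far the
class-conditional parameter distributions sit apart (1 = near-zero Bayes
error); ``noise_level`` adds pixel noise.  Generators are pure functions of
their spec: the same spec yields byte-identical PNGs and manifests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .manifest import DatasetManifest, ManifestRecord

__all__ = [
    "SyntheticTaskSpec",
    "generate_cells",
    "generate_ulcer_patches",
    "generate_lesions",
    "generate",
    "wound_mask_from_meta",
    "TASK_DEFAULTS",
]

TASK_DEFAULTS = {
    "cells": {"image_hw": (80, 80), "classes": ("circular", "elongated", "other")},
    "ulcer": {"image_hw": (224, 224), "classes": ("normal", "abnormal")},
    "lesion": {"image_hw": (500, 375), "classes": ("benign", "malignant")},
}

# guaranteed grayscale contrast of a wound region at separability 1
WOUND_BASE_CONTRAST = 0.25


@dataclass(frozen=True)
class SyntheticTaskSpec:
    """Parameters of one synthetic dataset.

    ``image_hw=None`` selects the task default (80x80 / 224x224 / 500x375).
    ``imbalance_ratio`` (lesion task) makes the malignant class
    ``round(ratio * n_per_class)`` strong while benign keeps ``n_per_class``.
    """

    task: str
    n_per_class: int = 50
    image_hw: tuple[int, int] | None = None
    separability: float = 0.9
    noise_level: float = 0.05
    seed: int = 0
    imbalance_ratio: float | None = None

    def __post_init__(self):
        if self.task not in TASK_DEFAULTS:
            raise ValueError(f"unknown task {self.task!r}; choose from {list(TASK_DEFAULTS)}")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not (0 < self.separability <= 1):
            raise ValueError("separability must be in (0, 1]")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")

    @property
    def hw(self) -> tuple[int, int]:
        return self.image_hw or TASK_DEFAULTS[self.task]["image_hw"]

    @property
    def classes(self) -> tuple[str, ...]:
        return TASK_DEFAULTS[self.task]["classes"]


# ---------------------------------------------------------------------------
# drawing primitives
# ---------------------------------------------------------------------------

def _grid(hw):
    h, w = hw
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    return yy, xx


def _blob_mask(hw, cy, cx, r0, ratio=1.0, angle=0.0, harmonics=(), edge=1.5):
    """Soft [0,1] mask of a star-shaped blob.

    The boundary radius is ``r0 * (1 + sum a_k cos(k*phi + p_k))`` measured
    in an elliptical metric with axis ratio ``ratio`` rotated by ``angle``.
    """
    yy, xx = _grid(hw)
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    u = u / ratio  # stretch major axis
    dist = np.sqrt(u * u + v * v)
    phi = np.arctan2(v, u)
    r = np.full(hw, r0, dtype=np.float32)
    for k, amp, phase in harmonics:
        r = r * (1 + amp * np.cos(k * phi + phase))
    return 1.0 / (1.0 + np.exp(np.clip((dist - r) / edge, -30, 30)))


def _smooth_field(hw, rng, scale=8, amp=0.05):
    """Low-frequency multiplicative shading field around 1.0."""
    h, w = hw
    coarse = rng.standard_normal((max(h // scale, 2), max(w // scale, 2)))
    field = ndimage.zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]), order=1)
    field = field[:h, :w]
    return 1.0 + amp * field / max(np.abs(field).max(), 1e-6)


def _finish(img, rng, noise_level):
    if noise_level > 0:
        img = img + rng.standard_normal(img.shape).astype(np.float32) * noise_level
    return (np.clip(img, 0, 1) * 255).round().astype(np.uint8)


def _record_rng(seed, class_idx, i):
    return np.random.default_rng(np.random.SeedSequence([int(seed), class_idx, i]))


# ---------------------------------------------------------------------------
# cells task
# ---------------------------------------------------------------------------

def _draw_cell(hw, label, sep, noise, rng):
    h, w = hw
    img = np.empty((h, w, 3), dtype=np.float32)
    base = np.array([0.93, 0.89, 0.87], dtype=np.float32)
    img[:] = base * _smooth_field(hw, rng, amp=0.03)[:, :, None]

    cy = h / 2 + rng.uniform(-h * 0.06, h * 0.06)
    cx = w / 2 + rng.uniform(-w * 0.06, w * 0.06)
    angle = rng.uniform(0, np.pi)
    r0 = min(h, w) * rng.uniform(0.16, 0.20)

    if label == "circular":
        ratio = 1.0 + rng.uniform(0, 0.10)
        harmonics = [(5, 0.02, rng.uniform(0, 2 * np.pi))]
        color = np.array([0.82, 0.42, 0.42], dtype=np.float32)
        params = {"axis_ratio": ratio, "border_amp": 0.02}
    elif label == "elongated":
        # eccentricity grows with separability; overlaps circular as sep -> 0
        ratio = 1.15 + sep * (2.2 + rng.uniform(0, 0.8))
        harmonics = [(2, 0.06 * sep, rng.uniform(0, 2 * np.pi))]
        r0 *= 0.8
        color = np.array([0.82, 0.42, 0.42], dtype=np.float32) - 0.10 * sep
        params = {"axis_ratio": ratio, "border_amp": 0.06 * sep}
    else:  # other: irregular blob
        ratio = 1.0 + rng.uniform(0, 0.25)
        amp = 0.10 + 0.18 * sep
        harmonics = [
            (3, amp * rng.uniform(0.6, 1.0), rng.uniform(0, 2 * np.pi)),
            (6, amp * rng.uniform(0.4, 0.8), rng.uniform(0, 2 * np.pi)),
        ]
        r0 *= 1.1
        color = np.array([0.72, 0.45, 0.55], dtype=np.float32)
        params = {"axis_ratio": ratio, "border_amp": amp}

    mask = _blob_mask(hw, cy, cx, r0, ratio, angle, harmonics, edge=1.2)
    # central pallor typical of a red cell seen in a smear
    pallor = _blob_mask(hw, cy, cx, r0 * 0.45, ratio, angle, (), edge=2.0)
    cell = color[None, None, :] * (1 - 0.25 * pallor[:, :, None])
    if label == "other":
        grain = rng.standard_normal((h, w, 1)).astype(np.float32) * 0.05 * sep
        cell = cell + grain
    img = img * (1 - mask[:, :, None]) + cell * mask[:, :, None]
    return _finish(img, rng, noise), params


def generate_cells(spec: SyntheticTaskSpec, out_dir) -> DatasetManifest:
    """Write the 3-class cell-morphology dataset; returns its manifest.

    At ``separability=1`` and ``noise_level=0`` a plain eccentricity
    threshold on the segmented cell separates circular from elongated
    perfectly; ``other`` is carried by border irregularity and hue.
    """
    if spec.task != "cells":
        raise ValueError(f"spec.task must be 'cells', got {spec.task!r}")
    return _run_generator(spec, out_dir, _draw_cell)


# ---------------------------------------------------------------------------
# ulcer task
# ---------------------------------------------------------------------------

def _draw_ulcer(hw, label, sep, noise, rng):
    h, w = hw
    tone = rng.uniform(0.65, 0.85)
    base = tone * np.array([1.0, 0.80, 0.68], dtype=np.float32)
    img = np.empty((h, w, 3), dtype=np.float32)
    img[:] = base
    img *= _smooth_field(hw, rng, scale=6, amp=0.06)[:, :, None]
    # fine skin texture
    img += rng.standard_normal((h, w, 1)).astype(np.float32) * 0.015

    params = {"tone": tone, "has_wound": 0, "cy": 0.0, "cx": 0.0, "r0": 0.0,
              "h1": 0.0, "h2": 0.0, "p1": 0.0, "p2": 0.0, "blend": 0.0}
    if label == "abnormal":
        cy = h / 2 + rng.uniform(-h * 0.15, h * 0.15)
        cx = w / 2 + rng.uniform(-w * 0.15, w * 0.15)
        r0 = min(h, w) * rng.uniform(0.14, 0.24)
        h1, p1 = 0.15 * rng.uniform(0.5, 1.0), rng.uniform(0, 2 * np.pi)
        h2, p2 = 0.10 * rng.uniform(0.5, 1.0), rng.uniform(0, 2 * np.pi)
        mask = _blob_mask(hw, cy, cx, r0, 1.0, 0.0,
                          [(3, h1, p1), (5, h2, p2)], edge=min(h, w) * 0.02)
        wound = np.array([0.38, 0.10, 0.09], dtype=np.float32)
        blend = 0.45 + 0.55 * sep
        img = img * (1 - blend * mask[:, :, None]) + wound * (blend * mask[:, :, None])
        params.update({"has_wound": 1, "cy": cy, "cx": cx, "r0": r0,
                       "h1": h1, "h2": h2, "p1": p1, "p2": p2, "blend": blend})
    return _finish(img, rng, noise), params


def wound_mask_from_meta(meta_row, hw) -> np.ndarray:
    """Rebuild the binary wound mask of an ``abnormal`` ulcer record."""
    if not meta_row["has_wound"]:
        return np.zeros(hw, dtype=bool)
    soft = _blob_mask(
        hw, meta_row["cy"], meta_row["cx"], meta_row["r0"], 1.0, 0.0,
        [(3, meta_row["h1"], meta_row["p1"]), (5, meta_row["h2"], meta_row["p2"])],
        edge=min(hw) * 0.02,
    )
    return soft > 0.5


def generate_ulcer_patches(spec: SyntheticTaskSpec, out_dir) -> DatasetManifest:
    """Write the 2-class foot-ulcer patch dataset; returns its manifest.

    ``normal`` is smooth skin texture; ``abnormal`` blends a dark-red
    irregular wound whose grayscale contrast against the surrounding skin
    scales with separability (>= ``WOUND_BASE_CONTRAST * separability``).
    """
    if spec.task != "ulcer":
        raise ValueError(f"spec.task must be 'ulcer', got {spec.task!r}")
    return _run_generator(spec, out_dir, _draw_ulcer)


# ---------------------------------------------------------------------------
# lesion task
# ---------------------------------------------------------------------------

def _draw_lesion(hw, label, sep, noise, rng):
    h, w = hw
    tone = rng.uniform(0.75, 0.9)
    base = tone * np.array([1.0, 0.84, 0.72], dtype=np.float32)
    img = np.empty((h, w, 3), dtype=np.float32)
    img[:] = base
    img *= _smooth_field(hw, rng, scale=6, amp=0.04)[:, :, None]

    cy = h / 2 + rng.uniform(-h * 0.08, h * 0.08)
    cx = w / 2 + rng.uniform(-w * 0.08, w * 0.08)
    angle = rng.uniform(0, np.pi)
    r0 = min(h, w) * rng.uniform(0.18, 0.24)
    brown = np.array([0.42, 0.27, 0.18], dtype=np.float32)

    if label == "benign":
        harmonics = [(4, 0.02, rng.uniform(0, 2 * np.pi))]
        asym, border = 0.0, 0.02
        mask = _blob_mask(hw, cy, cx, r0, 1.0 + rng.uniform(0, 0.1), angle,
                          harmonics, edge=min(h, w) * 0.03)
        lesion = np.broadcast_to(brown, (h, w, 3)).copy()
    else:  # malignant: asymmetric, irregular border, multi-tone
        asym = 0.22 * sep * rng.uniform(0.8, 1.2)
        border = (0.06 + 0.14 * sep) * rng.uniform(0.8, 1.2)
        harmonics = [
            (1, asym, rng.uniform(0, 2 * np.pi)),
            (8, border * 0.7, rng.uniform(0, 2 * np.pi)),
            (13, border * 0.5, rng.uniform(0, 2 * np.pi)),
        ]
        mask = _blob_mask(hw, cy, cx, r0 * 1.1, 1.0 + rng.uniform(0, 0.25), angle,
                          harmonics, edge=min(h, w) * 0.008)
        lesion = np.broadcast_to(brown, (h, w, 3)).copy()
        # colour variegation: a darker off-centre tone patch
        dark = _blob_mask(hw, cy + rng.uniform(-r0, r0) * 0.5,
                          cx + rng.uniform(-r0, r0) * 0.5, r0 * 0.5,
                          1.0, 0.0, (), edge=min(h, w) * 0.02)
        lesion = lesion * (1 - 0.5 * sep * dark[:, :, None]) \
            + np.array([0.15, 0.08, 0.10]) * (0.5 * sep * dark[:, :, None])
    img = img * (1 - mask[:, :, None]) + lesion * mask[:, :, None]
    return _finish(img, rng, noise), {"asymmetry": asym, "border_irregularity": border}


def generate_lesions(spec: SyntheticTaskSpec, out_dir) -> DatasetManifest:
    """Write the 2-class skin-lesion dataset; returns its manifest.

    Benign lesions are symmetric, smooth-bordered and uniformly coloured;
    malignant lesions add asymmetry, border irregularity and a second
    tone, with magnitudes scaling with separability (the ABCD cues).
    ``spec.imbalance_ratio`` shrinks the malignant class to exercise
    class balancing.
    """
    if spec.task != "lesion":
        raise ValueError(f"spec.task must be 'lesion', got {spec.task!r}")
    return _run_generator(spec, out_dir, _draw_lesion)


# ---------------------------------------------------------------------------
# shared driver
# ---------------------------------------------------------------------------

def _class_sizes(spec: SyntheticTaskSpec) -> dict[str, int]:
    sizes = {c: spec.n_per_class for c in spec.classes}
    if spec.imbalance_ratio is not None:
        if spec.task != "lesion":
            raise ValueError("imbalance_ratio is only defined for the lesion task")
        sizes["malignant"] = max(int(round(spec.imbalance_ratio * spec.n_per_class)), 1)
    return sizes


def _run_generator(spec: SyntheticTaskSpec, out_dir, draw) -> DatasetManifest:
    out_dir = Path(out_dir)
    records, meta_rows = [], []
    for class_idx, label in enumerate(spec.classes):
        class_dir = out_dir / label
        class_dir.mkdir(parents=True, exist_ok=True)
        for i in range(_class_sizes(spec)[label]):
            rng = _record_rng(spec.seed, class_idx, i)
            img, params = draw(spec.hw, label, spec.separability,
                               spec.noise_level, rng)
            path = class_dir / f"{label}_{i:04d}.png"
            iio.imwrite(path, img)
            records.append(ManifestRecord(str(path), label))
            meta_rows.append({"path": str(path), "label": label, **params})
    manifest = DatasetManifest(records=records, classes=spec.classes,
                               task=spec.task, meta=pd.DataFrame(meta_rows))
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest


_GENERATORS = {
    "cells": generate_cells,
    "ulcer": generate_ulcer_patches,
    "lesion": generate_lesions,
}


def generate(spec: SyntheticTaskSpec, out_dir) -> DatasetManifest:
    """Dispatch to the task's generator."""
    return _GENERATORS[spec.task](spec, out_dir)
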