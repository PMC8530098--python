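"""Label-preserving image augmentation, dataset expansion and class balancing.

The operator set covers rotation (fixed right angles plus small free angles),
horizontal/vertical flips, zoom, crop-and-resize, brightness and contrast.
Every operator maps a valid image to a valid image of the same geometry
(zoom/crop/rotate are resized or padded back), so augmented copies drop into
the original manifest unchanged except for their path.

Only train-split records are ever augmented; test records pass through
untouched, so no augmented pixel can leak into an evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import transform as sktransform

from .manifest import DatasetManifest, ManifestRecord, TRAIN
from .model_runtime import load_image

__all__ = [
    "AugmentationPolicy",
    "augment_image",
    "expand_dataset",
    "balance_classes",
    "OPERATORS",
]

OPERATORS = ("rotate", "flip", "zoom", "crop", "brighten", "contrast")


@dataclass(frozen=True)
class AugmentationPolicy:
    """Operator set and parameter ranges for random augmentation.

    Defaults: right-angle rotations {90, 180, 270} plus a uniform +/-15
    degree jitter, zoom 0.85-1.15, crop fraction 0.8 (then resized back),
    brightness +/-15% of full scale, contrast 0.8-1.2.
    """

    operators: tuple[str, ...] = OPERATORS
    rotation_angles: tuple[float, ...] = (90.0, 180.0, 270.0)
    rotation_jitter: float = 15.0
    zoom_range: tuple[float, float] = (0.85, 1.15)
    crop_fraction: float = 0.8
    brightness_delta: float = 0.15
    contrast_range: tuple[float, float] = (0.8, 1.2)
    seed: int = 0

    def __post_init__(self):
        if not self.operators:
            raise ValueError("policy needs at least one operator")
        unknown = set(self.operators) - set(OPERATORS)
        if unknown:
            raise ValueError(f"unknown operators {sorted(unknown)}; choose from {OPERATORS}")
        if not (0 < self.crop_fraction < 1):
            raise ValueError("crop_fraction must be in (0, 1)")
        if self.zoom_range[0] <= 0:
            raise ValueError("zoom factors must be positive")

    def to_json(self) -> str:
        import json
        from dataclasses import asdict

        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AugmentationPolicy":
        import json

        d = json.loads(text)
        for key in ("operators", "rotation_angles", "zoom_range", "contrast_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def sample(self, rng: np.random.Generator) -> tuple[str, dict]:
        """Draw one operator (uniformly) and parameters from its ranges."""
        op = self.operators[int(rng.integers(len(self.operators)))]
        if op == "rotate":
            if rng.random() < 0.5 and self.rotation_angles:
                angle = float(self.rotation_angles[int(rng.integers(len(self.rotation_angles)))])
            else:
                angle = float(rng.uniform(-self.rotation_jitter, self.rotation_jitter))
            return op, {"angle": angle}
        if op == "flip":
            return op, {"direction": "horizontal" if rng.random() < 0.5 else "vertical"}
        if op == "zoom":
            return op, {"factor": float(rng.uniform(*self.zoom_range))}
        if op == "crop":
            frac = self.crop_fraction
            return op, {
                "fraction": frac,
                "y0": float(rng.uniform(0, 1 - frac)),
                "x0": float(rng.uniform(0, 1 - frac)),
            }
        if op == "brighten":
            return op, {"delta": float(rng.uniform(-self.brightness_delta,
                                                   self.brightness_delta))}
        return op, {"factor": float(rng.uniform(*self.contrast_range))}


# ---------------------------------------------------------------------------
# single-image operators
# ---------------------------------------------------------------------------

def _to_float(img: np.ndarray) -> np.ndarray:
    return img.astype(np.float32) / 255.0


def _to_uint8(img: np.ndarray) -> np.ndarray:
    return (np.clip(img, 0, 1) * 255).round().astype(np.uint8)


def _resize(img: np.ndarray, hw: tuple[int, int]) -> np.ndarray:
    return sktransform.resize(img, hw, order=1, mode="edge",
                              anti_aliasing=False, preserve_range=True)


def augment_image(image: np.ndarray, operator: str, params: dict) -> np.ndarray:
    """Apply one operator; output keeps the input's geometry and dtype (uint8).

    Rotation by multiples of 90 degrees is exact (no interpolation); free
    angles rotate about the centre with edge fill.  Zoom and crop are resized
    back to the input dimensions; photometric operators clip to [0, 255].
    """
    if image.size == 0:
        raise ValueError("cannot augment an empty image")
    h, w = image.shape[:2]

    if operator == "rotate":
        angle = float(params["angle"]) % 360.0
        if angle == 0.0:
            return image.copy()
        if angle in (90.0, 180.0, 270.0) and h == w:
            return np.ascontiguousarray(np.rot90(image, k=int(angle // 90)))
        out = sktransform.rotate(_to_float(image), angle, resize=False,
                                 mode="edge", preserve_range=True)
        return _to_uint8(out)

    if operator == "flip":
        direction = params["direction"]
        if direction not in ("horizontal", "vertical"):
            raise ValueError(f"unknown flip direction {direction!r}")
        axis = 1 if direction == "horizontal" else 0
        return np.ascontiguousarray(np.flip(image, axis=axis))

    if operator == "zoom":
        factor = float(params["factor"])
        if factor <= 0:
            raise ValueError("zoom factor must be positive")
        if factor == 1.0:
            return image.copy()
        zh, zw = max(int(round(h * factor)), 1), max(int(round(w * factor)), 1)
        scaled = _resize(_to_float(image), (zh, zw))
        if factor >= 1.0:  # crop centre back to original size
            y0, x0 = (zh - h) // 2, (zw - w) // 2
            out = scaled[y0:y0 + h, x0:x0 + w]
        else:  # pad with edge values
            py, px = h - zh, w - zw
            out = np.pad(scaled, ((py // 2, py - py // 2),
                                  (px // 2, px - px // 2), (0, 0)), mode="edge")
        return _to_uint8(out)

    if operator == "crop":
        frac = float(params["fraction"])
        if not (0 < frac < 1):
            raise ValueError(f"crop fraction must be in (0, 1), got {frac}")
        ch, cw = max(int(round(h * frac)), 1), max(int(round(w * frac)), 1)
        y0 = int(round(float(params.get("y0", (1 - frac) / 2)) * h))
        x0 = int(round(float(params.get("x0", (1 - frac) / 2)) * w))
        y0, x0 = min(y0, h - ch), min(x0, w - cw)
        patch = _to_float(image[y0:y0 + ch, x0:x0 + cw])
        return _to_uint8(_resize(patch, (h, w)))

    if operator == "brighten":
        delta = float(params["delta"])
        return _to_uint8(_to_float(image) + delta)

    if operator == "contrast":
        factor = float(params["factor"])
        if factor < 0:
            raise ValueError("contrast factor must be >= 0")
        f = _to_float(image)
        mean = f.mean()
        return _to_uint8((f - mean) * factor + mean)

    raise ValueError(f"unknown operator {operator!r}; choose from {OPERATORS}")


# ---------------------------------------------------------------------------
# manifest-level operations
# ---------------------------------------------------------------------------

def _augment_record(record: ManifestRecord, policy: AugmentationPolicy,
                    rng: np.random.Generator, tag: str) -> ManifestRecord:
    img = load_image(record.path)
    op, params = policy.sample(rng)
    out = augment_image(img, op, params)
    src = Path(record.path)
    new_path = src.with_name(f"{src.stem}_{tag}.png")
    iio.imwrite(new_path, out)
    return ManifestRecord(str(new_path), record.label, record.split)


def expand_dataset(manifest: DatasetManifest, policy: AugmentationPolicy,
                   factor: int) -> DatasetManifest:
    """Expand the train split to ``factor`` times its size.

    Each original train record keeps its place and gains ``factor - 1``
    augmented copies, each produced by one operator drawn uniformly from the
    policy and written beside the original with a deterministic name.
    Test records are untouched.  ``factor=1`` returns the manifest unchanged.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return manifest
    records: list[ManifestRecord] = []
    train_idx = 0
    for record in manifest.records:
        records.append(record)
        if record.split != TRAIN:
            continue
        for j in range(factor - 1):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(policy.seed), train_idx, j]))
            records.append(_augment_record(record, policy, rng, f"aug{j}"))
        train_idx += 1
    return manifest.with_records(records)


def balance_classes(manifest: DatasetManifest, policy: AugmentationPolicy) -> DatasetManifest:
    """Augment minority classes until every class matches the majority count.

    Counts are taken over the train split only; augmented copies cycle over
    each minority class's originals.  An already balanced manifest is
    returned unchanged; a class with zero train records is an error.
    """
    counts = manifest.class_counts(TRAIN)
    if len(counts) < 2:
        raise ValueError("balancing needs at least two classes")
    zero = [c for c, n in counts.items() if n == 0]
    if zero:
        raise ValueError(f"classes with zero train records cannot be balanced: {zero}")
    target = max(counts.values())
    if all(n == target for n in counts.values()):
        return manifest

    records = list(manifest.records)
    for class_idx, label in enumerate(manifest.classes):
        deficit = target - counts[label]
        if deficit <= 0:
            continue
        originals = [r for r in manifest.train_records if r.label == label]
        for j in range(deficit):
            src = originals[j % len(originals)]
            rng = np.random.default_rng(
                np.random.SeedSequence([int(policy.seed), 0xBA1, class_idx, j]))
            records.append(_augment_record(src, policy, rng, f"bal{j}"))
    return manifest.with_records(records)
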