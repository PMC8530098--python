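"""Dataset manifests: the tabular index every pipeline stage consumes.

A :class:`DatasetManifest` is a list of (image path, class label, split)
records plus the class vocabulary.  CSV round-trip uses the three columns
``path,label,split``.  :func:`merge_manifests` and :func:`summarize`
implement the dataset bookkeeping arithmetic (e.g. pooling two patch sets
and checking the combined per-class totals).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

__all__ = [
    "ManifestRecord",
    "DatasetManifest",
    "DatasetSummary",
    "merge_manifests",
    "summarize",
]

TRAIN, TEST = "train", "test"
_SPLITS = (TRAIN, TEST)


@dataclass(frozen=True)
class ManifestRecord:
    path: str
    label: str
    split: str = TRAIN

    def __post_init__(self):
        if self.split not in _SPLITS:
            raise ValueError(f"split must be one of {_SPLITS}, got {self.split!r}")


@dataclass
class DatasetManifest:
    """Ordered image records with a class vocabulary.

    ``task`` is an optional tag naming the task the records belong to
    (e.g. ``"cells"``); merging manifests from different tasks that share
    label names is rejected rather than silently pooled.
    ``meta`` optionally carries per-record generator parameters (aligned
    with ``records``) for synthetic datasets.
    """

    records: list[ManifestRecord] = field(default_factory=list)
    classes: tuple[str, ...] = ()
    task: str | None = None
    meta: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.classes:
            self.classes = tuple(sorted({r.label for r in self.records}))
        self.validate()

    def validate(self) -> None:
        paths = [r.path for r in self.records]
        if len(paths) != len(set(paths)):
            dupes = [p for p, n in Counter(paths).items() if n > 1]
            raise ValueError(f"duplicate paths in manifest: {dupes[:3]} ...")
        vocab = set(self.classes)
        for r in self.records:
            if r.label not in vocab:
                raise ValueError(f"label {r.label!r} not in vocabulary {self.classes}")

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> list[ManifestRecord]:
        return [r for r in self.records if r.split == split]

    @property
    def train_records(self) -> list[ManifestRecord]:
        return self.subset(TRAIN)

    @property
    def test_records(self) -> list[ManifestRecord]:
        return self.subset(TEST)

    def class_counts(self, split: str | None = None) -> dict[str, int]:
        recs = self.records if split is None else self.subset(split)
        counts = Counter(r.label for r in recs)
        return {c: counts.get(c, 0) for c in self.classes}

    def with_records(self, records: list[ManifestRecord]) -> "DatasetManifest":
        return replace(self, records=records, meta=None)

    # -- CSV round trip -----------------------------------------------------

    def to_csv(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [(r.path, r.label, r.split) for r in self.records],
            columns=["path", "label", "split"],
        ).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path, task: str | None = None) -> "DatasetManifest":
        df = pd.read_csv(path, dtype=str)
        missing = {"path", "label", "split"} - set(df.columns)
        if missing:
            raise ValueError(f"manifest CSV missing columns: {sorted(missing)}")
        records = [
            ManifestRecord(row.path, row.label, row.split)
            for row in df.itertuples(index=False)
        ]
        return cls(records=records, task=task)


@dataclass(frozen=True)
class DatasetSummary:
    """Per-class / per-split counts with additive totals."""

    per_class: dict[str, int]
    per_split: dict[str, dict[str, int]]
    total: int
    tasks: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "per_class": dict(self.per_class),
            "per_split": {k: dict(v) for k, v in self.per_split.items()},
            "total": self.total,
            "tasks": list(self.tasks),
        }


def merge_manifests(manifests: list[DatasetManifest]) -> DatasetManifest:
    """Pool manifests; record counts and per-class counts are additive.

    The class vocabulary is the union.  Duplicate paths are an error, as is
    pooling manifests tagged with different tasks whose label names collide
    (same word, different meaning).
    """
    records: list[ManifestRecord] = []
    classes: list[str] = []
    tasks: dict[str, set[str]] = {}
    for m in manifests:
        records.extend(m.records)
        for c in m.classes:
            if c not in classes:
                classes.append(c)
            if m.task is not None:
                tasks.setdefault(c, set()).add(m.task)
    for label, owners in tasks.items():
        if len(owners) > 1:
            raise ValueError(
                f"label {label!r} is defined by different tasks {sorted(owners)}; "
                "refusing to merge semantically distinct vocabularies"
            )
    task_tags = sorted({m.task for m in manifests if m.task is not None})
    merged_task = task_tags[0] if len(task_tags) == 1 else None
    return DatasetManifest(records=records, classes=tuple(classes), task=merged_task)


def summarize(manifest: DatasetManifest) -> DatasetSummary:
    """Per-class and per-split counts; total equals the record count."""
    per_class = manifest.class_counts()
    per_split = {s: manifest.class_counts(s) for s in _SPLITS}
    return DatasetSummary(
        per_class=per_class,
        per_split=per_split,
        total=len(manifest),
        tasks=(manifest.task,) if manifest.task else (),
    )
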