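"""CNN-feature SVM hybrid: an SVM trained on deep features from the network.

Features tapped at a named layer (default: the 200-unit fully connected
layer) are standardized with train-split statistics and fed to a support
vector machine — a plain binary SVM for two classes, a one-vs-one
error-correcting-output-codes ensemble of k(k-1)/2 binary SVMs for more.
Evaluation extracts features for the test split only and scores predictions
with the metrics module, so no test image ever influences the fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.multiclass import OneVsOneClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .manifest import DatasetManifest, TEST, TRAIN
from .metrics import MetricsReport, multiclass_metrics
from .model_runtime import (
    DEFAULT_FEATURE_LAYER,
    FeatureMatrix,
    NetworkInstance,
    extract_features,
)

__all__ = ["SvmModel", "train_svm", "evaluate_hybrid", "train_and_evaluate_hybrid",
           "save_svm", "load_svm"]


@dataclass
class SvmModel:
    """A fitted SVM over deep features.

    ``mode`` is ``"binary"`` or ``"ecoc-multiclass"`` (one-vs-one ensemble);
    ``feature_dim`` and ``layer_name`` pin the feature space the model was
    fitted in so evaluation can reject mismatched taps.
    """

    mode: str
    kernel: str
    classes: tuple[str, ...]
    feature_dim: int
    layer_name: str
    scaler: StandardScaler
    clf: object

    @property
    def n_binary_learners(self) -> int:
        k = len(self.classes)
        return 1 if k == 2 else k * (k - 1) // 2

    def predict(self, features: np.ndarray) -> list[str]:
        if features.shape[1] != self.feature_dim:
            raise ValueError(
                f"feature dimension {features.shape[1]} does not match the "
                f"fitted dimension {self.feature_dim}"
            )
        return list(self.clf.predict(self.scaler.transform(features)))


def train_svm(features: FeatureMatrix, labels, kernel: str = "linear",
              C: float = 1.0, seed: int = 0) -> SvmModel:
    """Fit the SVM stage on extracted deep features.

    Features are standardized (zero mean, unit variance on the training
    rows).  Two label values give a single binary SVM; more give a
    one-vs-one ECOC ensemble.  Deterministic given the seed.
    """
    labels = list(labels)
    if features.n_samples != len(labels):
        raise ValueError(
            f"{features.n_samples} feature rows vs {len(labels)} labels"
        )
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError("SVM training needs at least two classes")
    if kernel not in ("linear", "rbf"):
        raise ValueError("kernel must be 'linear' or 'rbf'")

    scaler = StandardScaler().fit(features.values)
    x = scaler.transform(features.values)
    base = SVC(kernel=kernel, C=C, random_state=seed)
    if len(classes) == 2:
        clf, mode = base, "binary"
    else:
        clf, mode = OneVsOneClassifier(base), "ecoc-multiclass"
    clf.fit(x, labels)
    return SvmModel(
        mode=mode,
        kernel=kernel,
        classes=classes,
        feature_dim=features.dim,
        layer_name=features.layer_name,
        scaler=scaler,
        clf=clf,
    )


def evaluate_hybrid(net: NetworkInstance, svm: SvmModel,
                    manifest: DatasetManifest) -> MetricsReport:
    """Score the SVM on features extracted from the manifest's test split."""
    test = manifest.test_records
    if not test:
        raise ValueError("manifest has no test records to evaluate the hybrid on")
    feats = extract_features(net, manifest, svm.layer_name, split=TEST)
    if feats.dim != svm.feature_dim:
        raise ValueError(
            f"layer {svm.layer_name!r} yields {feats.dim}-dim features but the "
            f"SVM was fitted on {svm.feature_dim}"
        )
    y_pred = svm.predict(feats.values)
    y_true = [r.label for r in test]
    return multiclass_metrics(y_true, y_pred, classes=list(manifest.classes))


def save_svm(svm: SvmModel, path) -> None:
    """Persist a fitted SVM (pickle) next to its network checkpoint."""
    import pickle
    from pathlib import Path

    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "wb") as fh:
        pickle.dump(svm, fh)


def load_svm(path) -> SvmModel:
    """Load a fitted SVM saved by :func:`save_svm` (trusted files only)."""
    import pickle

    with open(path, "rb") as fh:
        svm = pickle.load(fh)
    if not isinstance(svm, SvmModel):
        raise TypeError(f"{path} does not contain an SvmModel")
    return svm


def train_and_evaluate_hybrid(net: NetworkInstance, manifest: DatasetManifest,
                              layer_name: str = DEFAULT_FEATURE_LAYER,
                              kernel: str = "linear", C: float = 1.0,
                              seed: int = 0) -> tuple[SvmModel, MetricsReport]:
    """Convenience: fit on the train split's features, score the test split."""
    train_feats = extract_features(net, manifest, layer_name, split=TRAIN)
    labels = [r.label for r in manifest.train_records]
    svm = train_svm(train_feats, labels, kernel=kernel, C=C, seed=seed)
    return svm, evaluate_hybrid(net, svm, manifest)
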