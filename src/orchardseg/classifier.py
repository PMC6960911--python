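"""Linear SVM over region feature vectors: training, scoring, persistence.

Features mix heterogeneous units (reflectances, radians, CIE units,
histogram mass), so each dimension is z-scored with statistics fitted on
the training set before the soft-margin linear SVM (C = 1 by default).
A region is kept as a tree iff its signed decision score is strictly
positive; background-scored regions are removed from the segmentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .features import FeatureVector

__all__ = ["SvmModel", "train_linear_svm", "classify_regions", "save_model", "load_model"]

_FORMAT_VERSION = 1


@dataclass
class SvmModel:
    """A trained linear SVM with its standardization parameters."""

    weights: np.ndarray  # (n_features,)
    bias: float
    scale_mean: np.ndarray
    scale_sd: np.ndarray  # 1.0 for zero-variance dims
    c: float = 1.0
    metadata: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"feature dim mismatch: model has {self.n_features}, got {x.shape[1]}"
            )
        z = (x - self.scale_mean) / self.scale_sd
        return z @ self.weights + self.bias


def _stack(features: list[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([f.values for f in features])
    labels = [f.label for f in features]
    if any(lab not in ("tree", "background") for lab in labels):
        raise ValueError("all training feature vectors must be labeled tree/background")
    y = np.array([1 if lab == "tree" else -1 for lab in labels])
    return x, y


def train_linear_svm(
    features: list[FeatureVector], c: float = 1.0, seed: int = 0
) -> SvmModel:
    """Fit a soft-margin linear SVM on labeled region features.

    Dimensions are z-scored (population sd; zero-variance dims pass
    through unscaled).  The libsvm solver is deterministic for binary
    problems, so refits with identical data reproduce identical weights;
    *seed* is recorded in the metadata and threaded to the solver.
    """
    if not features:
        raise ValueError("no training features")
    x, y = _stack(features)
    for k, f in enumerate(features):
        if not np.all(np.isfinite(f.values)):
            raise ValueError(f"NaN/inf features in training region index {k}")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (x - mean) / sd

    # tight solver tolerance so refits and label symmetry hold to ~1e-6
    svc = SVC(kernel="linear", C=c, tol=1e-8, random_state=seed)
    svc.fit(z, y)
    w = svc.coef_.ravel().astype(np.float64)
    b = float(svc.intercept_[0])
    # libsvm orients the decision function by class order; force tree=+1
    if svc.classes_[1] != 1:
        w, b = -w, -b
    return SvmModel(
        weights=w,
        bias=b,
        scale_mean=mean,
        scale_sd=sd,
        c=c,
        metadata={
            "n_train": int(len(features)),
            "n_features": int(x.shape[1]),
            "seed": int(seed),
            "n_support": [int(v) for v in svc.n_support_],
        },
    )


def classify_regions(
    model: SvmModel, features: list[FeatureVector]
) -> tuple[list[str], np.ndarray]:
    """Label each region tree/background with its signed decision score.

    A region is a tree iff its score is strictly positive (score 0 goes
    to background).
    """
    if not features:
        return [], np.zeros(0)
    x = np.stack([f.values for f in features])
    scores = model.decision_scores(x)
    labels = ["tree" if s > 0 else "background" for s in scores]
    return labels, scores


def save_model(model: SvmModel, path: str | Path) -> None:
    """Serialize the model to a versioned JSON file."""
    payload = {
        "format_version": _FORMAT_VERSION,
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "scale_mean": model.scale_mean.tolist(),
        "scale_sd": model.scale_sd.tolist(),
        "c": model.c,
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> SvmModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    return SvmModel(
        weights=np.array(payload["weights"], dtype=np.float64),
        bias=float(payload["bias"]),
        scale_mean=np.array(payload["scale_mean"], dtype=np.float64),
        scale_sd=np.array(payload["scale_sd"], dtype=np.float64),
        c=float(payload["c"]),
        metadata=dict(payload.get("metadata", {})),
    )
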