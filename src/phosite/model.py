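"""Per-residue, per-window RBF support vector classifiers.

One binary classifier is trained for each (residue, window) pair with
the fixed hyperparameters C = 1 and gamma = 1 / k, where k = 20 * W is
the feature dimension.  Features are the raw integer log-odds scores —
no rescaling by default — and the decision output is a hard label in
{+1, -1}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.svm import SVC

from phosite.dataset import Instance
from phosite.errors import ConfigError, DataError, ModelError
from phosite.profile_io import PHOSPHO_RESIDUES

_BUNDLE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Classifier configuration; gamma defaults to 1/k with k = 20 * W."""

    residue: str
    w: int
    c: float = 1.0
    gamma: float | None = None
    scale: bool = False

    def __post_init__(self):
        if self.residue not in PHOSPHO_RESIDUES:
            raise ConfigError(f"residue must be one of S, T, Y; got {self.residue!r}")
        if self.w < 1 or self.w % 2 == 0:
            raise ConfigError(f"window size must be a positive odd integer, got {self.w}")
        if self.c <= 0:
            raise ConfigError(f"C must be positive, got {self.c}")
        if self.gamma is not None and self.gamma <= 0:
            raise ConfigError(f"gamma must be positive, got {self.gamma}")

    @property
    def k(self) -> int:
        """Feature dimension: 20 scores per window position."""
        return 20 * self.w

    @property
    def effective_gamma(self) -> float:
        return self.gamma if self.gamma is not None else 1.0 / self.k


@dataclass
class ModelBundle:
    """A fitted classifier plus the metadata needed to apply it safely."""

    config: ModelConfig
    classifier: SVC
    n_positive: int
    n_negative: int
    seed: int
    scaler_mean: np.ndarray | None = None
    scaler_std: np.ndarray | None = None
    format_version: int = _BUNDLE_FORMAT_VERSION

    @property
    def metadata(self) -> dict:
        return {
            "format_version": self.format_version,
            "residue": self.config.residue,
            "window": self.config.w,
            "k": self.config.k,
            "C": self.config.c,
            "gamma": self.config.effective_gamma,
            "scaled": self.config.scale,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "seed": self.seed,
        }


def _feature_matrix(instances: Sequence[Instance], k: int) -> np.ndarray:
    if not instances:
        return np.empty((0, k))
    matrix = np.vstack([inst.features for inst in instances])
    if matrix.shape[1] != k:
        raise DataError(
            f"instance dimension {matrix.shape[1]} does not match configured k={k}"
        )
    return matrix


def train(instances: Sequence[Instance], config: ModelConfig, seed: int = 0) -> ModelBundle:
    """Fit an RBF SVM on labeled instances; both classes must be present."""
    targets = np.array([inst.target for inst in instances])
    classes = set(targets.tolist())
    if classes != {+1, -1}:
        raise DataError(
            f"training needs both classes; got targets {sorted(classes) or 'none'}"
        )
    features = _feature_matrix(instances, config.k)
    mean = std = None
    if config.scale:
        mean = features.mean(axis=0)
        std = features.std(axis=0)
        std[std == 0] = 1.0
        features = (features - mean) / std
    classifier = SVC(
        C=config.c,
        kernel="rbf",
        gamma=config.effective_gamma,
        random_state=seed,
    )
    classifier.fit(features, targets)
    return ModelBundle(
        config=config,
        classifier=classifier,
        n_positive=int((targets == 1).sum()),
        n_negative=int((targets == -1).sum()),
        seed=seed,
        scaler_mean=mean,
        scaler_std=std,
    )


def predict(bundle: ModelBundle, instances: Sequence[Instance]) -> np.ndarray:
    """Hard labels in {+1, -1}, one per instance, order-preserving."""
    if not instances:
        return np.empty(0, dtype=np.int64)
    features = _feature_matrix(instances, bundle.config.k)
    if bundle.scaler_mean is not None:
        features = (features - bundle.scaler_mean) / bundle.scaler_std
    return bundle.classifier.predict(features).astype(np.int64)


def bundle_filename(residue: str, w: int) -> str:
    return f"model_{residue}_w{w}.joblib"


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    """Persist a bundle with an embedded JSON metadata header."""
    payload = {
        "metadata_json": json.dumps(bundle.metadata, sort_keys=True),
        "classifier": bundle.classifier,
        "scaler_mean": bundle.scaler_mean,
        "scaler_std": bundle.scaler_std,
    }
    joblib.dump(payload, path)


def load_bundle(
    path: str | Path,
    residue: str | None = None,
    w: int | None = None,
) -> ModelBundle:
    """Load a bundle; refuse version mismatches and wrong (residue, W) requests."""
    path = Path(path)
    if not path.exists():
        raise ModelError(f"model bundle not found: {path}")
    try:
        payload = joblib.load(path)
        meta = json.loads(payload["metadata_json"])
    except (KeyError, ValueError, EOFError) as exc:
        raise ModelError(f"{path}: not a readable model bundle ({exc})") from exc
    if meta.get("format_version") != _BUNDLE_FORMAT_VERSION:
        raise ModelError(
            f"{path}: bundle format version {meta.get('format_version')} "
            f"!= supported {_BUNDLE_FORMAT_VERSION}"
        )
    if residue is not None and meta["residue"] != residue:
        raise ModelError(
            f"{path}: bundle is for residue {meta['residue']}, requested {residue}"
        )
    if w is not None and meta["window"] != w:
        raise ModelError(f"{path}: bundle is for W={meta['window']}, requested W={w}")
    config = ModelConfig(
        residue=meta["residue"],
        w=meta["window"],
        c=meta["C"],
        gamma=meta["gamma"],
        scale=meta["scaled"],
    )
    return ModelBundle(
        config=config,
        classifier=payload["classifier"],
        n_positive=meta["n_positive"],
        n_negative=meta["n_negative"],
        seed=meta["seed"],
        scaler_mean=payload.get("scaler_mean"),
        scaler_std=payload.get("scaler_std"),
        format_version=meta["format_version"],
    )
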