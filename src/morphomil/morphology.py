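"""The 13-class tissue-morphology classifier head and its feature extractor.

Colorectal tissue patches fall into 13 annotated morphology classes
(adenocarcinomas, adenomas, stroma, necrosis, ...).  A small MLP head
(input → 512 → 128 → 13, ReLU hidden activations, softmax output) is
trained with cross-entropy on patch embeddings from any fixed-dimension
backbone.  For downstream prognosis the head is truncated after the
512-unit layer: the post-rectifier hidden vector is the
"morphology-informed" patch feature, capturing within-class phenotypic
variability rather than just the argmax class.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Tuple

import h5py
import numpy as np

from ._nn import Adam, relu, softmax, xavier_uniform
from .errors import ShapeError, StratificationError
from .datamodel import FormatError

__all__ = [
    "MORPHOLOGY_CLASSES",
    "MorphHead",
    "MorphTrainConfig",
    "split_morph_dataset",
    "train_morph_head",
    "extract_morph_features",
    "save_morph_head",
    "load_morph_head",
]

MORPHOLOGY_CLASSES: Tuple[str, ...] = (
    "High-Grade Adenocarcinoma",
    "Low-Grade Adenocarcinoma",
    "High-Grade Adenoma",
    "Low-Grade Adenoma",
    "Fat",
    "Hyperplastic Polyp",
    "Inflammation",
    "Mucin",
    "Smooth Muscle",
    "Necrosis",
    "Sessile Serrated Lesion",
    "Stroma",
    "Vascular Structures",
)

N_CLASSES = len(MORPHOLOGY_CLASSES)
HIDDEN_1 = 512
HIDDEN_2 = 128


class MorphHead:
    """input -> 512 -> 128 -> 13 MLP; class codes follow MORPHOLOGY_CLASSES."""

    def __init__(self, input_dim: int, seed: int = 0,
                 n_classes: int = N_CLASSES) -> None:
        self.input_dim = input_dim
        self.n_classes = n_classes
        rng = np.random.Generator(np.random.PCG64(seed))
        self.params = {
            "W1": xavier_uniform(rng, input_dim, HIDDEN_1),
            "b1": np.zeros(HIDDEN_1),
            "W2": xavier_uniform(rng, HIDDEN_1, HIDDEN_2),
            "b2": np.zeros(HIDDEN_2),
            "W3": xavier_uniform(rng, HIDDEN_2, n_classes),
            "b3": np.zeros(n_classes),
        }

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.input_dim:
            raise ShapeError(
                f"embedding dim {X.shape[1]} does not match head input "
                f"{self.input_dim}"
            )
        return X

    def hidden(self, X: np.ndarray) -> np.ndarray:
        """Post-ReLU 512-d hidden representation (the truncation point)."""
        X = self._check_input(X)
        return relu(X @ self.params["W1"] + self.params["b1"])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        h1 = self.hidden(X)
        h2 = relu(h1 @ self.params["W2"] + self.params["b2"])
        return softmax(h2 @ self.params["W3"] + self.params["b3"], axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def copy_params(self):
        return {k: v.copy() for k, v in self.params.items()}


@dataclasses.dataclass(frozen=True)
class MorphTrainConfig:
    epochs: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0


def split_morph_dataset(features: np.ndarray, labels: np.ndarray,
                        fractions: Tuple[float, float, float] = (0.70, 0.15, 0.15),
                        seed: int = 0):
    """Per-class stratified train/val/test split.

    Each class contributes floor(f_train * n_c) samples to training; the
    remainder is divided between validation and test in proportion to
    their fractions, flooring toward validation.
    """
    features = np.asarray(features)
    labels = np.asarray(labels).astype(int)
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    f_tr, f_val, f_te = fractions
    rng = np.random.Generator(np.random.PCG64(seed))
    idx_tr, idx_val, idx_te = [], [], []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if len(members) < 3 and 0.0 < f_tr < 1.0:
            raise StratificationError(
                f"class {c} has only {len(members)} samples; cannot stratify"
            )
        members = members[rng.permutation(len(members))]
        n_tr = int(np.floor(f_tr * len(members)))
        rest = len(members) - n_tr
        n_val = int(np.floor(rest * (f_val / (f_val + f_te)))) if rest else 0
        idx_tr.append(members[:n_tr])
        idx_val.append(members[n_tr : n_tr + n_val])
        idx_te.append(members[n_tr + n_val :])
    idx_tr = np.concatenate(idx_tr)
    idx_val = np.concatenate(idx_val) if idx_val else np.array([], dtype=int)
    idx_te = np.concatenate(idx_te) if idx_te else np.array([], dtype=int)
    return (
        (features[idx_tr], labels[idx_tr]),
        (features[idx_val], labels[idx_val]),
        (features[idx_te], labels[idx_te]),
    )


def _forward_backward(head: MorphHead, X: np.ndarray, y: np.ndarray):
    P = head.params
    h1_pre = X @ P["W1"] + P["b1"]
    h1 = relu(h1_pre)
    h2_pre = h1 @ P["W2"] + P["b2"]
    h2 = relu(h2_pre)
    logits = h2 @ P["W3"] + P["b3"]
    probs = softmax(logits, axis=1)
    n = len(y)
    ce = -float(np.mean(np.log(probs[np.arange(n), y] + 1e-12)))
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits /= n
    grads = {
        "W3": h2.T @ dlogits,
        "b3": dlogits.sum(axis=0),
    }
    dh2 = (dlogits @ P["W3"].T) * (h2_pre > 0)
    grads["W2"] = h1.T @ dh2
    grads["b2"] = dh2.sum(axis=0)
    dh1 = (dh2 @ P["W2"].T) * (h1_pre > 0)
    grads["W1"] = X.T @ dh1
    grads["b1"] = dh1.sum(axis=0)
    return ce, grads


def train_morph_head(train, val, config: MorphTrainConfig = MorphTrainConfig()
                     ) -> MorphHead:
    """Train the head with cross-entropy; keep the best-validation-accuracy
    epoch's weights.  Deterministic under the config seed."""
    from .errors import DivergenceError

    X_tr, y_tr = np.asarray(train[0], dtype=np.float64), np.asarray(train[1]).astype(int)
    X_val, y_val = np.asarray(val[0], dtype=np.float64), np.asarray(val[1]).astype(int)
    head = MorphHead(X_tr.shape[1], seed=config.seed)
    opt = Adam(head.params, lr=config.learning_rate)
    rng = np.random.Generator(np.random.PCG64(config.seed))
    best = (-np.inf, -np.inf)  # (accuracy, -cross-entropy) lexicographic
    best_params = head.copy_params()
    X_sel, y_sel = (X_val, y_val) if len(X_val) else (X_tr, y_tr)
    for epoch in range(config.epochs):
        order = rng.permutation(len(X_tr))
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            ce, grads = _forward_backward(head, X_tr[batch], y_tr[batch])
            if not np.isfinite(ce):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            opt.step(head.params, grads)
        probs = head.predict_proba(X_sel)
        acc = float(np.mean(probs.argmax(axis=1) == y_sel))
        nll = -float(np.mean(np.log(probs[np.arange(len(y_sel)), y_sel] + 1e-12)))
        score = (acc, -nll)
        if score > best:
            best = score
            best_params = head.copy_params()
    head.params = best_params
    return head


def extract_morph_features(head: MorphHead, patch_embedding: np.ndarray
                           ) -> np.ndarray:
    """Deterministic 512-d morphology feature(s) for one or more embeddings."""
    emb = np.asarray(patch_embedding)
    single = emb.ndim == 1
    out = head.hidden(emb)
    return out[0] if single else out


def save_morph_head(head: MorphHead, path) -> None:
    """Serialize head weights (HDF5, same store as bags) + class-name JSON."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for k, v in head.params.items():
            f.create_dataset(k, data=v)
        f.attrs["input_dim"] = head.input_dim
        f.attrs["n_classes"] = head.n_classes
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"classes": list(MORPHOLOGY_CLASSES)}))


def load_morph_head(path) -> MorphHead:
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"not a readable head file: {path}") from exc
    with f:
        head = MorphHead(int(f.attrs["input_dim"]),
                         n_classes=int(f.attrs["n_classes"]))
        for k in head.params:
            if k not in f:
                raise FormatError(f"head file missing dataset '{k}'")
            head.params[k] = f[k][()]
    return head
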