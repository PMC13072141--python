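"""Bilinear-fusion gated-attention MIL model for slide-level survival.

Per patch, a generic embedding ``g`` and a morphology-informed embedding
``m`` are linearly projected into a common space (``Wg``, ``Wm``), combined
by outer product into a cross-feature interaction matrix ``f' = m_p g_pᵀ``,
and compressed by a learned map ``T`` (flatten → affine → rectifier) into
the fused patch feature ``f``.  A gated attention network scores each
fused patch,

    a_k = softmax_k( wᵀ ( tanh(Vᵀ f_k) ⊙ σ(Uᵀ f_k) ) ),

the slide embedding is the attention-weighted sum ``Z = Σ_k a_k f_k``, and
a logistic head maps ``Z`` to the probability of death within five years.
All stages are trained end-to-end (see :mod:`morphomil.training`); this
module owns the architecture, the forward pass, and its hand-derived
gradients.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Tuple

import numpy as np

from ._nn import Params, relu, sigmoid, softmax, xavier_uniform
from .datamodel import PatchBag
from .errors import ShapeError

__all__ = [
    "FusionConfig",
    "FusionModel",
    "AttentionOutput",
    "project_streams",
    "cross_interaction",
    "compress_interaction",
    "gated_attention",
    "aggregate",
    "predict_risk",
    "forward_bag",
    "export_attention",
    "save_model",
    "load_model",
]

#: parameters subject to L1 regularization (biases excluded)
WEIGHT_KEYS = ("Wg", "Wm", "Wt", "V", "U", "w_att", "w_out")


@dataclasses.dataclass(frozen=True)
class FusionConfig:
    """Architecture dimensions.

    ``p`` is the common projection width for both streams, so the
    interaction matrix has ``p**2`` entries; ``d_out`` is the fused patch
    dimension produced by ``T`` and must compress (``p**2 >= d_out``);
    ``l`` is the attention hidden width.
    """

    d_g: int
    d_m: int
    p: int = 64
    d_out: int = 256
    l: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("d_g", "d_m", "p", "d_out", "l"):
            if getattr(self, name) < 1:
                raise ShapeError(f"{name} must be >= 1")
        if self.p**2 < self.d_out:
            raise ShapeError(
                f"p**2 = {self.p**2} must be >= d_out = {self.d_out} "
                "(T is a compression)"
            )


@dataclasses.dataclass
class AttentionOutput:
    """Per-patch attention weights and the attended slide embedding."""

    weights: np.ndarray
    slide_embedding: np.ndarray


class FusionModel:
    """Parameter container with forward pass and manual backprop."""

    def __init__(self, config: FusionConfig) -> None:
        self.config = config
        rng = np.random.Generator(np.random.PCG64(config.seed))
        c = config
        self.params: Params = {
            "Wg": xavier_uniform(rng, c.d_g, c.p),
            "Wm": xavier_uniform(rng, c.d_m, c.p),
            "Wt": xavier_uniform(rng, c.p**2, c.d_out),
            "bt": np.zeros(c.d_out),
            "V": xavier_uniform(rng, c.d_out, c.l),
            "U": xavier_uniform(rng, c.d_out, c.l),
            # zero score vector -> near-uniform pooling at the start, so the
            # attention polarity is learned from data rather than inherited
            # from the random draw
            "w_att": np.zeros(c.l),
            "w_out": xavier_uniform(rng, c.d_out, 1, shape=(c.d_out,)),
            "b_out": np.zeros(1),
        }

    # -- forward ---------------------------------------------------------

    def forward(self, G: np.ndarray, M: np.ndarray, cache: bool = False):
        """Risk and attention for one bag; optionally keep intermediates."""
        P = self.params
        c = self.config
        G = np.asarray(G, dtype=np.float64)
        M = np.asarray(M, dtype=np.float64)
        if G.ndim != 2 or M.ndim != 2 or G.shape[0] != M.shape[0]:
            raise ShapeError("G and M must be 2-D with equal row counts")
        if G.shape[1] != c.d_g or M.shape[1] != c.d_m:
            raise ShapeError(
                f"feature dims ({G.shape[1]}, {M.shape[1]}) do not match "
                f"config ({c.d_g}, {c.d_m})"
            )
        m = G.shape[0]
        Gp = G @ P["Wg"]
        Mp = M @ P["Wm"]
        X = (Mp[:, :, None] * Gp[:, None, :]).reshape(m, c.p * c.p)
        pre_t = X @ P["Wt"] + P["bt"]
        F = relu(pre_t)
        t = np.tanh(F @ P["V"])
        s = sigmoid(F @ P["U"])
        ts = t * s
        e = ts @ P["w_att"]
        a = softmax(e)
        Z = a @ F
        logit = float(Z @ P["w_out"] + P["b_out"][0])
        risk = float(sigmoid(logit))
        out = (risk, AttentionOutput(weights=a, slide_embedding=Z))
        if not cache:
            return out
        return out, {
            "G": G, "M": M, "Gp": Gp, "Mp": Mp, "X": X, "pre_t": pre_t,
            "F": F, "t": t, "s": s, "ts": ts, "a": a, "Z": Z, "risk": risk,
        }

    # -- backward --------------------------------------------------------

    def backward(self, cache: Dict[str, np.ndarray], label: int,
                 l1_coeff: float = 0.0) -> Params:
        """Gradients of BCE(risk, label) + L1 penalty w.r.t. all parameters."""
        P = self.params
        c = self.config
        m = cache["G"].shape[0]
        dlogit = cache["risk"] - float(label)
        grads: Params = {}
        grads["w_out"] = dlogit * cache["Z"]
        grads["b_out"] = np.array([dlogit])
        dZ = dlogit * P["w_out"]
        dF = cache["a"][:, None] * dZ[None, :]
        da = cache["F"] @ dZ
        a = cache["a"]
        de = a * (da - float(a @ da))
        dts = de[:, None] * P["w_att"][None, :]
        grads["w_att"] = cache["ts"].T @ de
        dt = dts * cache["s"]
        ds = dts * cache["t"]
        dpre_v = dt * (1.0 - cache["t"] ** 2)
        dpre_u = ds * cache["s"] * (1.0 - cache["s"])
        dF = dF + dpre_v @ P["V"].T + dpre_u @ P["U"].T
        grads["V"] = cache["F"].T @ dpre_v
        grads["U"] = cache["F"].T @ dpre_u
        dpre_t = dF * (cache["pre_t"] > 0)
        grads["Wt"] = cache["X"].T @ dpre_t
        grads["bt"] = dpre_t.sum(axis=0)
        dX = (dpre_t @ P["Wt"].T).reshape(m, c.p, c.p)
        dMp = np.einsum("jab,jb->ja", dX, cache["Gp"])
        dGp = np.einsum("jab,ja->jb", dX, cache["Mp"])
        grads["Wg"] = cache["G"].T @ dGp
        grads["Wm"] = cache["M"].T @ dMp
        if l1_coeff > 0.0:
            for k in WEIGHT_KEYS:
                grads[k] = grads[k] + l1_coeff * np.sign(P[k])
        return grads

    def copy_params(self) -> Params:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: Params) -> None:
        self.params = {k: v.copy() for k, v in params.items()}


# -- stateless stage functions (each also usable standalone) --------------


def project_streams(g: np.ndarray, mfeat: np.ndarray, Wg: np.ndarray,
                    Wm: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Row-wise bias-free linear projections of both feature streams."""
    g = np.asarray(g, dtype=np.float64)
    mfeat = np.asarray(mfeat, dtype=np.float64)
    if g.shape[1] != Wg.shape[0] or mfeat.shape[1] != Wm.shape[0]:
        raise ShapeError("projection dims do not match feature dims")
    if Wg.shape[1] != Wm.shape[1]:
        raise ShapeError("Wg and Wm must project to the same width")
    return g @ Wg, mfeat @ Wm


def cross_interaction(g_p: np.ndarray, m_p: np.ndarray) -> np.ndarray:
    """Outer product of projected features: entry (a, b) = m_p[a] * g_p[b]."""
    g_p = np.asarray(g_p, dtype=np.float64)
    m_p = np.asarray(m_p, dtype=np.float64)
    if g_p.ndim != 1 or m_p.ndim != 1 or g_p.shape != m_p.shape:
        raise ShapeError("cross_interaction expects two equal-length vectors")
    return np.outer(m_p, g_p)


def compress_interaction(f_raw: np.ndarray, Wt: np.ndarray,
                         bt: np.ndarray) -> np.ndarray:
    """Flatten (row-major) the interaction matrix, then affine + rectifier."""
    f_raw = np.asarray(f_raw, dtype=np.float64)
    flat = f_raw.reshape(-1)
    if flat.shape[0] != Wt.shape[0]:
        raise ShapeError(
            f"flattened size {flat.shape[0]} does not match T input {Wt.shape[0]}"
        )
    return relu(flat @ Wt + bt)


def gated_attention(F: np.ndarray, V: np.ndarray, U: np.ndarray,
                    w: np.ndarray) -> np.ndarray:
    """Gated-attention weights over the rows of ``F``; sums to 1."""
    F = np.asarray(F, dtype=np.float64)
    if F.ndim != 2 or F.shape[0] < 1:
        raise ShapeError("F must be a non-empty (m, d) matrix")
    e = (np.tanh(F @ V) * sigmoid(F @ U)) @ w
    return softmax(e)


def aggregate(F: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Attention-weighted sum of patch features: Z = Σ a_j f_j."""
    F = np.asarray(F, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    if F.shape[0] != a.shape[0]:
        raise ShapeError("weight vector length must equal number of patches")
    return a @ F


def predict_risk(Z: np.ndarray, w_out: np.ndarray, b_out: float) -> float:
    """Logistic survival head on the slide embedding."""
    return float(sigmoid(float(np.dot(Z, w_out)) + b_out))


def forward_bag(bag: PatchBag, model: FusionModel) -> Tuple[float, AttentionOutput]:
    """Full composition project → interact → compress → attend → predict."""
    return model.forward(bag.generic_features, bag.morph_features)


def export_attention(bag: PatchBag, model: FusionModel):
    """Per-patch attention weights with coordinates, for heatmap rendering."""
    import pandas as pd

    _, att = forward_bag(bag, model)
    return pd.DataFrame(
        {
            "patch_index": np.arange(bag.n_patches),
            "x": bag.coords[:, 0],
            "y": bag.coords[:, 1],
            "weight": att.weights,
        }
    )


def save_model(model: FusionModel, path) -> None:
    """Serialize weights (npz) with a JSON config sidecar."""
    path = Path(path)
    np.savez(path, **model.params)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(dataclasses.asdict(model.config), sort_keys=True))


def load_model(path) -> FusionModel:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = path.with_suffix(path.suffix + ".json")
    config = FusionConfig(**json.loads(sidecar.read_text()))
    model = FusionModel(config)
    with np.load(path) as data:
        model.params = {k: data[k].copy() for k in data.files}
    return model
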