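"""End-to-end optimization of the fusion-MIL model.

Training follows the slide-level protocol: one bag per optimizer step
(batch size 1), Adam at learning rate 2e-5, Xavier-uniform initialization,
binary cross-entropy plus an L1 penalty (coefficient 5e-4) on all linear
weights to promote feature sparsity; dropout is not used.  The epoch
budget is bounded by ``max_epochs`` with patience-based early stopping on
validation AUC, and the returned model is the snapshot from the best
validation epoch.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._nn import Adam, clip_global_norm
from .datamodel import PatchBag
from .errors import DegenerateLabelError, DivergenceError
from .fusion import WEIGHT_KEYS, FusionConfig, FusionModel

__all__ = ["TrainConfig", "loss", "fit", "predict_bags", "patient_risks",
           "cross_validate"]

EPS = 1e-7


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 2e-5
    l1_coeff: float = 5e-4
    batch_size: int = 1
    max_epochs: int = 60
    patience: int = 10
    clip_norm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.l1_coeff < 0:
            raise ValueError("l1_coeff must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def loss(pred: float, label: int, params: Optional[Dict[str, np.ndarray]] = None,
         l1_coeff: float = 0.0) -> float:
    """Binary cross-entropy plus L1 penalty on trainable weights.

    The prediction is clipped to [eps, 1-eps] before the logarithms; the
    penalty sums |w| over weight matrices only (biases excluded).
    """
    p = min(max(float(pred), EPS), 1.0 - EPS)
    y = float(label)
    bce = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    if params is not None and l1_coeff > 0.0:
        bce += l1_coeff * sum(
            float(np.sum(np.abs(params[k]))) for k in WEIGHT_KEYS if k in params
        )
    return float(bce)


def _val_auc(model: FusionModel, val_bags: Sequence[PatchBag]) -> float:
    from .evaluation import roc_auc
    from .errors import UndefinedMetricError

    risks = np.array([model.forward(b.generic_features, b.morph_features)[0]
                      for b in val_bags])
    labels = np.array([b.label for b in val_bags])
    try:
        return roc_auc(risks, labels)
    except UndefinedMetricError:
        return float("nan")


def fit(bags: Sequence[PatchBag], config: TrainConfig,
        val_bags: Sequence[PatchBag],
        fusion_config: Optional[FusionConfig] = None,
        ) -> Tuple[FusionModel, pd.DataFrame]:
    """Train on a list of bags; select the best-validation-AUC epoch.

    Returns the selected model and a history table with one row per epoch
    (epoch, train_loss, val_auc).  Identical (data, config, seed) inputs
    reproduce the history bit for bit.
    """
    labels = {b.label for b in bags}
    if labels != {0, 1}:
        raise DegenerateLabelError(
            f"training set must contain both labels; found {sorted(labels)}"
        )
    if fusion_config is None:
        fusion_config = FusionConfig(
            d_g=bags[0].generic_features.shape[1],
            d_m=bags[0].morph_features.shape[1],
            seed=config.seed,
        )
    model = FusionModel(fusion_config)
    opt = Adam(model.params, lr=config.learning_rate)
    rng = np.random.Generator(np.random.PCG64(config.seed))

    history: List[dict] = []
    best_auc = -np.inf
    best_loss = np.inf
    best_params = model.copy_params()
    stale = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(bags))
        epoch_losses = []
        pending: List[Dict[str, np.ndarray]] = []
        for idx in order:
            bag = bags[idx]
            (risk, _), cache = model.forward(
                bag.generic_features, bag.morph_features, cache=True
            )
            step_loss = loss(risk, bag.label, model.params, config.l1_coeff)
            if not np.isfinite(step_loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            epoch_losses.append(step_loss)
            grads = model.backward(cache, bag.label, config.l1_coeff)
            pending.append(grads)
            if len(pending) == config.batch_size:
                if len(pending) == 1:
                    avg = pending[0]
                else:
                    avg = {k: sum(g[k] for g in pending) / len(pending)
                           for k in pending[0]}
                opt.step(model.params, clip_global_norm(avg, config.clip_norm))
                pending = []
        if pending:
            avg = {k: sum(g[k] for g in pending) / len(pending)
                   for k in pending[0]}
            opt.step(model.params, clip_global_norm(avg, config.clip_norm))
        train_loss = float(np.mean(epoch_losses))
        val_auc = _val_auc(model, val_bags) if len(val_bags) else float("nan")
        history.append(
            {"epoch": epoch, "train_loss": train_loss, "val_auc": val_auc}
        )
        # model selection: best validation AUC; train loss breaks ties and
        # substitutes when the validation AUC is undefined
        improved = False
        if np.isfinite(val_auc):
            if val_auc > best_auc + 1e-12:
                improved = True
        elif train_loss < best_loss - 1e-12:
            improved = True
        if improved:
            best_auc = max(best_auc, val_auc) if np.isfinite(val_auc) else best_auc
            best_loss = train_loss
            best_params = model.copy_params()
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    model.set_params(best_params)
    return model, pd.DataFrame(history)


def predict_bags(model: FusionModel, bags: Sequence[PatchBag]) -> pd.DataFrame:
    """Slide-level risks for a list of bags."""
    rows = []
    for b in bags:
        risk, _ = model.forward(b.generic_features, b.morph_features)
        rows.append(
            {
                "slide_id": b.slide_id,
                "patient_id": b.patient_id,
                "risk": risk,
                "label": b.label,
                "time_months": b.time_months,
                "event": b.event,
            }
        )
    return pd.DataFrame(rows)


def patient_risks(slide_preds: pd.DataFrame) -> pd.DataFrame:
    """Average slide-level risks into one prediction per patient."""
    return (
        slide_preds.groupby("patient_id", sort=True)
        .agg(
            risk=("risk", "mean"),
            label=("label", "first"),
            time_months=("time_months", "first"),
            event=("event", "first"),
        )
        .reset_index()
    )


def cross_validate(bags: Sequence[PatchBag], folds: pd.DataFrame,
                   train_config: TrainConfig,
                   fusion_config: Optional[FusionConfig] = None,
                   ) -> dict:
    """Run the five-fold protocol: train, pick a threshold on validation,
    evaluate on the test fold, and pool patient-level predictions.

    ``folds`` is the table produced by
    :func:`morphomil.splits.build_folds`.  Returns per-fold metric rows,
    the pooled prediction table, and the pooled AUC.
    """
    from .evaluation import evaluate_predictions, roc_auc, select_threshold
    from .splits import get_fold

    by_patient: Dict[str, List[PatchBag]] = {}
    for b in bags:
        by_patient.setdefault(b.patient_id, []).append(b)

    n_folds = int(folds["test_fold"].max()) + 1
    fold_rows = []
    pooled = []
    models = []
    for f in range(n_folds):
        ids = get_fold(folds, f)
        train_bags = [b for pid in ids["train"] for b in by_patient.get(pid, [])]
        val_bags = [b for pid in ids["val"] for b in by_patient.get(pid, [])]
        test_bags = [b for pid in ids["test"] for b in by_patient.get(pid, [])]
        cfg = dataclasses.replace(train_config, seed=train_config.seed + f)
        model, _ = fit(train_bags, cfg, val_bags, fusion_config)
        val_pred = patient_risks(predict_bags(model, val_bags))
        threshold = select_threshold(
            val_pred["risk"].to_numpy(), val_pred["label"].to_numpy()
        )
        test_pred = patient_risks(predict_bags(model, test_bags))
        test_pred["fold"] = f
        test_pred["threshold"] = threshold
        metrics = evaluate_predictions(
            test_pred["risk"].to_numpy(), test_pred["label"].to_numpy(), threshold
        )
        metrics["fold"] = f
        fold_rows.append(metrics)
        pooled.append(test_pred)
        models.append(model)

    pooled_df = pd.concat(pooled, ignore_index=True)
    pooled_auc = roc_auc(pooled_df["risk"].to_numpy(), pooled_df["label"].to_numpy())
    return {
        "fold_metrics": pd.DataFrame(fold_rows),
        "predictions": pooled_df,
        "pooled_auc": float(pooled_auc),
        "models": models,
    }
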