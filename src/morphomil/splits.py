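"""Clinically stratified cross-validation splitting.

Patients are binned on age (<65 vs >=65 years), BMI (<25, 25-30, >=30
kg/m^2), median household income (cut at $43,194) and sex, clustered on
the four categorical bins with K-modes (K chosen by the elbow rule), and
dealt cluster-by-cluster into five test folds so every fold reflects the
cohort's covariate mix.  For each fold, 10% of the total cohort is carved
out of the non-test pool as a validation set, drawn cluster-
proportionally.  Survival labels never enter the clustering or the split.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InfeasibleKError, MissingDataError

__all__ = [
    "BinScheme",
    "DEFAULT_BINS",
    "bin_covariates",
    "ClusterAssignment",
    "kmodes",
    "elbow_select_k",
    "build_folds",
    "get_fold",
]

BIN_COLUMNS = ["age_bin", "sex_bin", "bmi_bin", "income_bin"]


@dataclasses.dataclass(frozen=True)
class BinScheme:
    """Cutpoints for covariate binning; boundaries go to the upper bin.

    The alternative ``bmi_mode="gapped"`` reproduces a published-figure
    variant with BMI groups <24, 24-30, >30 instead of the contiguous
    default <25, 25-30, >=30.
    """

    age_cut: float = 65.0
    bmi_low: float = 25.0
    bmi_high: float = 30.0
    income_cut: float = 43_194.0
    bmi_mode: str = "contiguous"  # or "gapped"


DEFAULT_BINS = BinScheme()


def bin_covariates(cohort: pd.DataFrame, scheme: BinScheme = DEFAULT_BINS
                   ) -> pd.DataFrame:
    """Append categorical bin columns for age, sex, BMI and income."""
    required = ["age", "sex", "bmi", "income"]
    missing_mask = cohort[required].isna().any(axis=1)
    if missing_mask.any():
        ids = cohort.loc[missing_mask, "patient_id"].tolist()
        raise MissingDataError(f"missing covariates for patients: {ids[:10]}")
    out = cohort.copy()
    out["age_bin"] = np.where(out["age"] < scheme.age_cut, "<65", ">=65")
    out["sex_bin"] = out["sex"].astype(str)
    if scheme.bmi_mode == "gapped":
        low, high = scheme.bmi_low - 1.0, scheme.bmi_high
        out["bmi_bin"] = np.select(
            [out["bmi"] < low, out["bmi"] <= high], ["<24", "24-30"], ">30"
        )
    else:
        out["bmi_bin"] = np.select(
            [out["bmi"] < scheme.bmi_low, out["bmi"] < scheme.bmi_high],
            ["<25", "25-30"],
            ">=30",
        )
    out["income_bin"] = np.where(
        out["income"] < scheme.income_cut, "<43194", ">=43194"
    )
    return out


@dataclasses.dataclass
class ClusterAssignment:
    labels: np.ndarray
    modes: np.ndarray
    K: int
    cost: int


def _encode(binned: pd.DataFrame) -> np.ndarray:
    """Categorical bin columns -> integer codes (per-column)."""
    cols = []
    for c in BIN_COLUMNS:
        cols.append(pd.Categorical(binned[c]).codes)
    return np.stack(cols, axis=1).astype(np.int64)


def _assign(X: np.ndarray, modes: np.ndarray) -> Tuple[np.ndarray, int]:
    # matching (Hamming) dissimilarity to each mode; ties -> lowest index
    d = (X[:, None, :] != modes[None, :, :]).sum(axis=2)
    labels = d.argmin(axis=1)
    return labels, int(d[np.arange(len(X)), labels].sum())


def _update_modes(X: np.ndarray, labels: np.ndarray, K: int,
                  modes: np.ndarray) -> np.ndarray:
    new = modes.copy()
    for k in range(K):
        members = X[labels == k]
        if len(members) == 0:
            continue
        for j in range(X.shape[1]):
            vals, counts = np.unique(members[:, j], return_counts=True)
            new[k, j] = vals[counts.argmax()]  # ties -> smallest code
    return new


def kmodes(binned, K: int, seed: int = 0, n_init: int = 10
           ) -> ClusterAssignment:
    """Huang-style K-modes on the categorical bin matrix.

    Modes are initialized from distinct data rows (seeded draw), points are
    assigned by matching dissimilarity, modes updated to per-column
    majority categories, iterated to convergence; the best of ``n_init``
    restarts by total cost wins.  Fully deterministic under ``seed``.
    """
    X = _encode(binned) if isinstance(binned, pd.DataFrame) else np.asarray(binned)
    distinct = np.unique(X, axis=0)
    if K > len(distinct):
        raise InfeasibleKError(
            f"K={K} exceeds the {len(distinct)} distinct covariate profiles"
        )
    rng = np.random.Generator(np.random.PCG64(seed))
    best: Optional[ClusterAssignment] = None
    for _ in range(n_init):
        # farthest-point initialization over the distinct rows: a random
        # first mode, then greedily the row farthest from the chosen set
        # (random tie-break) -- spreads modes across the category space far
        # more reliably than a uniform draw
        chosen = [int(rng.integers(len(distinct)))]
        while len(chosen) < K:
            d = (distinct[:, None, :] != distinct[chosen][None, :, :]).sum(
                axis=2).min(axis=1)
            far = np.flatnonzero(d == d.max())
            chosen.append(int(far[rng.integers(len(far))]))
        modes = distinct[chosen].copy()
        labels, cost = _assign(X, modes)
        for _it in range(100):
            modes = _update_modes(X, labels, K, modes)
            # re-seed empty clusters from rows far from their mode
            used = set(np.unique(labels))
            for k in range(K):
                if k not in used:
                    d_own = (X != modes[labels]).sum(axis=1)
                    modes[k] = X[int(d_own.argmax())]
            new_labels, new_cost = _assign(X, modes)
            if np.array_equal(new_labels, labels):
                cost = new_cost
                break
            labels, cost = new_labels, new_cost
        if best is None or cost < best.cost:
            best = ClusterAssignment(labels=labels, modes=modes, K=K, cost=cost)
    assert best is not None
    return best


def elbow_select_k(binned, k_range: Sequence[int] = range(1, 11),
                   seed: int = 0, n_init: int = 10) -> int:
    """Choose K by the knee of the K-modes cost curve.

    The knee is the K whose (K, cost) point lies farthest from the chord
    joining the curve's endpoints; ties break toward smaller K.  A flat
    curve yields the smallest K with a warning.  Ks beyond the number of
    distinct rows are infeasible and dropped from the scan.
    """
    X = _encode(binned) if isinstance(binned, pd.DataFrame) else np.asarray(binned)
    n_distinct = len(np.unique(X, axis=0))
    ks = [k for k in k_range if 1 <= k <= n_distinct]
    if not ks:
        raise InfeasibleKError("no feasible K in range")
    costs = np.array([kmodes(X, k, seed=seed, n_init=n_init).cost for k in ks],
                     dtype=float)
    if len(ks) == 1 or costs[0] == costs[-1]:
        warnings.warn("flat K-modes cost curve; returning smallest K")
        return ks[0]
    # distance from each point to the chord between the endpoints
    p1 = np.array([ks[0], costs[0]])
    p2 = np.array([ks[-1], costs[-1]])
    chord = p2 - p1
    chord = chord / np.linalg.norm(chord)
    pts = np.stack([np.array(ks, dtype=float), costs], axis=1) - p1
    proj = pts - np.outer(pts @ chord, chord)
    dist = np.linalg.norm(proj, axis=1)
    if np.allclose(dist, 0.0):
        warnings.warn("linear K-modes cost curve; returning smallest K")
        return ks[0]
    return ks[int(dist.argmax())]


def build_folds(binned: pd.DataFrame, K: Optional[int] = None,
                n_folds: int = 5, val_fraction: float = 0.10,
                seed: int = 0, n_init: int = 10) -> pd.DataFrame:
    """Construct cluster-stratified test folds plus per-fold validation sets.

    Within each K-modes cluster, patients are shuffled (seeded) and dealt
    round-robin into ``n_folds`` test folds, so each fold's cluster
    composition is within one patient of proportionality.  For every fold,
    ``val_fraction`` of the *total* cohort is drawn cluster-proportionally
    from the non-test pool as validation; the remainder trains.

    Returns a table with ``patient_id``, ``cluster_id``, ``test_fold`` and
    one boolean ``val_fold{f}`` column per fold.
    """
    if K is None:
        K = elbow_select_k(binned, seed=seed, n_init=n_init)
    assign = kmodes(binned, K, seed=seed, n_init=n_init)
    out = binned[["patient_id"]].copy().reset_index(drop=True)
    out["cluster_id"] = assign.labels
    n = len(out)

    rng = np.random.Generator(np.random.PCG64(seed + 1))
    test_fold = np.full(n, -1, dtype=int)
    offset = 0
    for k in range(K):
        members = np.flatnonzero(assign.labels == k)
        members = members[rng.permutation(len(members))]
        for i, idx in enumerate(members):
            test_fold[idx] = (i + offset) % n_folds
        offset = (offset + len(members)) % n_folds
    out["test_fold"] = test_fold

    n_val_total = int(round(val_fraction * n))
    for f in range(n_folds):
        col = np.zeros(n, dtype=bool)
        pool_mask = test_fold != f
        # largest-remainder allocation of the validation quota across clusters
        pool_sizes = np.array(
            [np.sum(pool_mask & (assign.labels == k)) for k in range(K)]
        )
        if pool_sizes.sum() > 0 and n_val_total > 0:
            quota = n_val_total * pool_sizes / pool_sizes.sum()
            base = np.floor(quota).astype(int)
            rem = n_val_total - base.sum()
            order = np.argsort(-(quota - base), kind="stable")
            for k in order[:rem]:
                base[k] += 1
            base = np.minimum(base, pool_sizes)
            for k in range(K):
                cand = np.flatnonzero(pool_mask & (assign.labels == k))
                chosen = cand[rng.permutation(len(cand))[: base[k]]]
                col[chosen] = True
        out[f"val_fold{f}"] = col
    return out


def get_fold(folds: pd.DataFrame, fold: int) -> Dict[str, List[str]]:
    """Train/val/test patient-id lists for one fold of a build_folds table."""
    test = folds["test_fold"] == fold
    val = folds[f"val_fold{fold}"].astype(bool) & ~test
    train = ~test & ~val
    return {
        "train": folds.loc[train, "patient_id"].tolist(),
        "val": folds.loc[val, "patient_id"].tolist(),
        "test": folds.loc[test, "patient_id"].tolist(),
    }
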