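"""Synthetic cohort generator with planted, tunable structure.

Emulates the study's data shape without any restricted download: per
patient, a covariate profile (age/sex/BMI/income drawn within bins from a
small set of planted templates); a 13-class tissue-morphology composition
whose risk-class share follows a three-component mixture (near-pure tumor
slides, slides free of the risk class, and a graded middle) with the
remaining share split over the other classes; patch embeddings from
class-conditional Gaussians in both the generic and the morphology
feature space (correlated class centers, independent noise); and an
exponential survival time whose log-hazard is linear in the fraction of
the designated risk class (default: high-grade adenocarcinoma) plus
covariate-bin effects.  The binary five-year label is derived from the
latent (time, event) pair; patients censored before 60 months without an
event are excluded from the binary cohort but kept in the truth record.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import PatchBag
from .errors import GenerationError
from .morphology import N_CLASSES

__all__ = ["SimConfig", "CohortTruth", "generate_cohort", "planted_k_check",
           "ablate_morphology"]

# Beta concentrations for the near-pure and near-zero risk-share components
_RISK_PURE = (50.0, 0.25)
_RISK_LOW = (0.25, 50.0)

# six planted profiles: (age_bin, sex_bin, bmi_bin, income_bin) codes,
# chosen so the K-modes cost curve of a balanced mixture drops near-linearly
# to a flat tail at K=6 (a well-defined elbow, with no good coarser split)
_BASE_PROFILES = [
    (0, 1, 1, 1),
    (0, 1, 2, 0),
    (1, 0, 1, 1),
    (1, 0, 2, 0),
    (1, 1, 1, 0),
    (1, 1, 2, 1),
]


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults define the reference study conditions.

    ``beta_signal`` is the log-hazard effect of the risk-class fraction
    pi[risk]; ``beta_covariates`` acts on the binary/ordinal covariate bin
    codes (age>=65, sex==F, BMI bin code, income>=cut).  Survival is
    exponential with rate ``baseline_hazard * exp(eta)`` per month and the
    binary endpoint is death before ``horizon_months``.
    """

    n_patients: int = 300
    patches_per_bag: Tuple[int, int] = (30, 60)
    d_g: int = 32
    d_m: int = 32
    n_morph_classes: int = N_CLASSES
    class_centers_scale: float = 3.0
    noise_sd: float = 1.0
    generic_noise_sd: float = 1.2  # generic encoder: weaker class separation
    # per-slide offset of all generic embeddings (stain/scanner batch
    # effects a generic encoder carries; the morphology head, trained on
    # the target domain, is modeled as robust to them), per-component sd
    generic_slide_shift_sd: float = 0.7
    center_correlation: float = 0.7
    # classes the generic encoder cannot tell apart (tumor/adenoma grade
    # pairs); the morphology stream keeps distinct centers for them
    generic_confusions: Tuple[Tuple[int, int], ...] = ((0, 1), (2, 3))
    # within-class phenotypic gradation: risk-class morphology embeddings
    # shift along a fixed direction with the slide's risk-class share, so
    # the purpose-trained stream carries prognostic detail inside the
    # tumor patches that the generic stream lacks
    severity_gradient: float = 0.0
    risk_class_index: int = 0  # high-grade adenocarcinoma
    risk_mix_pure: float = 0.0
    risk_mix_low: float = 0.0
    mid_beta: Tuple[float, float] = (0.036, 0.036)
    background_alpha: float = 0.3
    beta_signal: float = 3.0
    beta_covariates: Tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    censor_rate: float = 0.2
    baseline_hazard: float = 0.012
    horizon_months: float = 60.0
    n_covariate_profiles: int = 6
    covariate_noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be positive")
        if not (0 <= self.risk_class_index < self.n_morph_classes):
            raise ValueError("risk_class_index out of range")
        if self.patches_per_bag[0] < 1 or self.patches_per_bag[0] > self.patches_per_bag[1]:
            raise ValueError("patches_per_bag must be a nonempty (low, high) range")


@dataclasses.dataclass
class CohortTruth:
    """Latent per-patient record (all generated patients, retained or not)
    plus per-slide patch class labels for the retained ones."""

    table: pd.DataFrame
    patch_classes: Dict[str, np.ndarray]
    centers_g: np.ndarray
    centers_m: np.ndarray


def _profiles(n: int) -> List[Tuple[int, int, int, int]]:
    if n <= len(_BASE_PROFILES):
        return _BASE_PROFILES[:n]
    all_combos = list(itertools.product(range(2), range(2), range(3), range(2)))
    extra = [c for c in all_combos if c not in _BASE_PROFILES]
    if n > len(all_combos):
        raise GenerationError(
            f"cannot plant {n} distinct profiles in 24 possible bin combos"
        )
    return _BASE_PROFILES + extra[: n - len(_BASE_PROFILES)]


def _class_centers(cfg: SimConfig, rng: np.random.Generator
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Unit-direction class centers, correlated across the two spaces."""
    d = max(cfg.d_g, cfg.d_m)
    rho = cfg.center_correlation
    centers_m = np.empty((cfg.n_morph_classes, cfg.d_m))
    centers_g = np.empty((cfg.n_morph_classes, cfg.d_g))
    for c in range(cfg.n_morph_classes):
        z = rng.standard_normal(d)
        w = rng.standard_normal(d)
        zm = z[: cfg.d_m]
        centers_m[c] = cfg.class_centers_scale * zm / np.linalg.norm(zm)
        zg = rho * z[: cfg.d_g] + np.sqrt(1.0 - rho**2) * w[: cfg.d_g]
        centers_g[c] = cfg.class_centers_scale * zg / np.linalg.norm(zg)
    # grade pairs collapse in the generic space: a generic encoder sees
    # "adenocarcinoma" or "adenoma", not the grade the hazard depends on
    for a, b in cfg.generic_confusions:
        centers_g[b] = centers_g[a]
    return centers_g, centers_m


def _draw_covariates(profile: Tuple[int, int, int, int],
                     rng: np.random.Generator, noise: float):
    bins = list(profile)
    if noise > 0.0:
        for j, n_levels in enumerate((2, 2, 3, 2)):
            if rng.random() < noise:
                options = [v for v in range(n_levels) if v != bins[j]]
                bins[j] = int(rng.choice(options))
    age = rng.uniform(45.0, 64.9) if bins[0] == 0 else rng.uniform(65.0, 85.0)
    sex = "M" if bins[1] == 0 else "F"
    bmi = [rng.uniform(18.5, 24.9), rng.uniform(25.0, 29.9),
           rng.uniform(30.0, 40.0)][bins[2]]
    income = (rng.uniform(20_000.0, 43_193.0) if bins[3] == 0
              else rng.uniform(43_194.0, 90_000.0))
    return bins, age, sex, bmi, income


def generate_cohort(config: SimConfig = SimConfig()
                    ) -> Tuple[List[PatchBag], pd.DataFrame, CohortTruth]:
    """Generate bags, a clinical cohort table and the latent truth record.

    Patients are drawn until ``n_patients`` pass the binary-endpoint
    retention rule (event before the horizon, or followed beyond it);
    each retained patient gets one slide/bag.  Deterministic under the
    config seed.
    """
    cfg = config
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    centers_g, centers_m = _class_centers(cfg, rng)
    severity_dir = rng.standard_normal(cfg.d_m)
    severity_dir /= np.linalg.norm(severity_dir)
    profiles = _profiles(cfg.n_covariate_profiles)
    # hierarchical composition: the risk-class share has a Beta marginal
    # (near-bimodal at the defaults, so slides range from risk-dominated to
    # risk-free), while the remaining share is split over the other classes
    # with a milder concentration, giving each slide a *diverse* background
    bg_idx = [c for c in range(cfg.n_morph_classes) if c != cfg.risk_class_index]
    bg_alpha = np.full(len(bg_idx), cfg.background_alpha)
    # three-component risk share: near-pure tumor slides, near-tumor-free
    # slides, and a graded low-fraction middle; see the risk-share
    # concentrations in _RISK_PURE/_RISK_LOW
    p_pure, p_low = cfg.risk_mix_pure, cfg.risk_mix_low
    p_mid = 1.0 - p_pure - p_low
    if p_mid < 0 or p_pure < 0 or p_low < 0:
        raise GenerationError("risk mixture probabilities must be a simplex")
    ma, mb = cfg.mid_beta
    pi_risk_mean = (
        p_pure * _RISK_PURE[0] / sum(_RISK_PURE)
        + p_low * _RISK_LOW[0] / sum(_RISK_LOW)
        + p_mid * ma / (ma + mb)
    )
    beta_cov = np.asarray(cfg.beta_covariates, dtype=float)

    bags: List[PatchBag] = []
    cohort_rows, truth_rows = [], []
    patch_classes: Dict[str, np.ndarray] = {}
    max_draws = max(20 * cfg.n_patients, 200)
    n_retained = 0
    for i in range(max_draws):
        if n_retained >= cfg.n_patients:
            break
        pid = f"P{i:05d}"
        profile_idx = int(rng.integers(len(profiles)))
        bins, age, sex, bmi, income = _draw_covariates(
            profiles[profile_idx], rng, cfg.covariate_noise
        )
        u = rng.random()
        if u < p_pure:
            pi_risk = rng.beta(*_RISK_PURE)
        elif u < p_pure + p_low:
            pi_risk = rng.beta(*_RISK_LOW)
        else:
            pi_risk = rng.beta(ma, mb)
        pi = np.empty(cfg.n_morph_classes)
        pi[cfg.risk_class_index] = pi_risk
        pi[bg_idx] = (1.0 - pi_risk) * rng.dirichlet(bg_alpha)
        # centered linear predictor: baseline_hazard is the hazard of a
        # cohort-average composition, so beta_signal=0 reduces cleanly to it
        eta = cfg.beta_signal * (pi_risk - pi_risk_mean) + float(
            beta_cov @ np.asarray(bins, dtype=float)
        )
        hazard = cfg.baseline_hazard * np.exp(eta)
        t_event = rng.exponential(1.0 / hazard)
        if rng.random() < cfg.censor_rate:
            t_cens = rng.uniform(0.0, 2.0 * cfg.horizon_months)
        else:
            t_cens = np.inf
        observed = min(t_event, t_cens)
        event = int(t_event <= t_cens)
        label = int(event == 1 and observed < cfg.horizon_months)
        retained = bool(event == 1 or observed >= cfg.horizon_months)
        truth_rows.append({
            "patient_id": pid, "profile": profile_idx,
            "pi_risk": float(pi[cfg.risk_class_index]), "eta": float(eta),
            "time_months": float(observed), "event": event,
            "latent_event_time": float(t_event), "label": label,
            "retained": retained,
        })
        if not retained:
            continue
        n_retained += 1
        m = int(rng.integers(cfg.patches_per_bag[0], cfg.patches_per_bag[1] + 1))
        classes = rng.choice(cfg.n_morph_classes, size=m, p=pi)
        G = centers_g[classes] + cfg.generic_noise_sd * rng.standard_normal(
            (m, cfg.d_g))
        if cfg.generic_slide_shift_sd > 0.0:
            G += cfg.generic_slide_shift_sd * rng.standard_normal(cfg.d_g)
        M = centers_m[classes] + cfg.noise_sd * rng.standard_normal((m, cfg.d_m))
        risk_patches = classes == cfg.risk_class_index
        if risk_patches.any() and cfg.severity_gradient != 0.0:
            M[risk_patches] += (cfg.severity_gradient
                                * (pi_risk - pi_risk_mean) * severity_dir)
        cols = max(int(np.ceil(np.sqrt(m))), 1)
        coords = np.stack(
            [(np.arange(m) % cols) * 224, (np.arange(m) // cols) * 224], axis=1
        )
        slide_id = f"{pid}-S1"
        bag = PatchBag(
            slide_id=slide_id, patient_id=pid, coords=coords,
            generic_features=G.astype(np.float32),
            morph_features=M.astype(np.float32),
            label=label, time_months=float(observed), event=event,
        )
        bags.append(bag)
        patch_classes[slide_id] = classes
        cohort_rows.append({
            "patient_id": pid, "age": age, "sex": sex, "bmi": bmi,
            "income": income,
            "treatment": "FL" if rng.random() < 0.5 else "IFL",
        })
    if n_retained < cfg.n_patients:
        raise GenerationError(
            f"only {n_retained}/{cfg.n_patients} patients retained after "
            f"{max_draws} draws; config is infeasible"
        )
    truth = CohortTruth(
        table=pd.DataFrame(truth_rows),
        patch_classes=patch_classes,
        centers_g=centers_g,
        centers_m=centers_m,
    )
    return bags, pd.DataFrame(cohort_rows), truth


def planted_k_check(cohort: pd.DataFrame, k_true: int, seed: int = 0) -> bool:
    """True iff the elbow rule recovers the planted number of profiles."""
    from .splits import bin_covariates, elbow_select_k

    binned = bin_covariates(cohort)
    return elbow_select_k(binned, seed=seed) == k_true


def ablate_morphology(bags: Sequence[PatchBag], seed: int = 0) -> List[PatchBag]:
    """Replace morphology features with pure noise (ablation control)."""
    rng = np.random.Generator(np.random.PCG64(seed))
    out = []
    for b in bags:
        noise = rng.standard_normal(b.morph_features.shape).astype(np.float32)
        out.append(PatchBag(
            slide_id=b.slide_id, patient_id=b.patient_id, coords=b.coords,
            generic_features=b.generic_features, morph_features=noise,
            label=b.label, time_months=b.time_months, event=b.event,
        ))
    return out
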