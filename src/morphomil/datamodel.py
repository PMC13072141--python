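"""Core domain types and I/O: patch-embedding bags and clinical cohort tables.

A *bag* holds everything the survival model sees for one slide: per-patch
generic embeddings (from a pluggable foundation-model stream), per-patch
morphology embeddings (from the tissue-type classifier head), patch
coordinates, and the slide-level five-year outcome.  Bags are stored one
file per slide in an HDF5 layout so a cohort can be streamed slide by
slide.  Clinical covariates travel separately as a CSV-backed table.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError

__all__ = [
    "PatchBag",
    "SurvivalRecord",
    "write_bag",
    "load_bag",
    "read_cohort",
    "write_cohort",
]

COHORT_REQUIRED_COLUMNS = ("patient_id", "age", "sex", "bmi", "income")


@dataclasses.dataclass
class PatchBag:
    """All patch-level features for one slide plus its slide-level label.

    Attributes
    ----------
    slide_id, patient_id:
        Identifiers; several slides may map to one patient, in which case
        patient-level risk is the mean of slide-level risks.
    coords:
        ``(m, 2)`` integer array of level-0 pixel origins, 0-based,
        ``(x, y) = (column, row)``.
    generic_features:
        ``(m, d_g)`` float32 matrix of generic patch embeddings.
    morph_features:
        ``(m, d_m)`` float32 matrix of morphology-informed embeddings.
    label:
        Binary five-year outcome; 1 = died within 60 months of treatment
        initiation, 0 = alive at 60 months.
    time_months, event:
        Optional time-to-event pair for the survival-analysis metrics.
    """

    slide_id: str
    patient_id: str
    coords: np.ndarray
    generic_features: np.ndarray
    morph_features: np.ndarray
    label: int
    time_months: Optional[float] = None
    event: Optional[int] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64)
        self.generic_features = np.asarray(self.generic_features, dtype=np.float32)
        self.morph_features = np.asarray(self.morph_features, dtype=np.float32)
        self.validate()

    @property
    def n_patches(self) -> int:
        return self.generic_features.shape[0]

    def validate(self) -> None:
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError(
                f"coords must be (m, 2); got {self.coords.shape}"
            )
        if self.generic_features.ndim != 2 or self.morph_features.ndim != 2:
            raise ValidationError("feature arrays must be 2-D")
        m = self.generic_features.shape[0]
        if m < 1:
            raise ValidationError("a bag must contain at least one patch")
        if self.morph_features.shape[0] != m or self.coords.shape[0] != m:
            raise ValidationError(
                "row-count mismatch: generic "
                f"{self.generic_features.shape[0]}, morph "
                f"{self.morph_features.shape[0]}, coords {self.coords.shape[0]}"
            )
        if self.label not in (0, 1):
            raise ValidationError(f"label must be 0 or 1, got {self.label!r}")
        if not np.all(np.isfinite(self.generic_features)):
            raise ValidationError("generic_features contains non-finite values")
        if not np.all(np.isfinite(self.morph_features)):
            raise ValidationError("morph_features contains non-finite values")
        if self.event is not None:
            if self.event not in (0, 1):
                raise ValidationError(f"event must be 0 or 1, got {self.event!r}")
            if self.time_months is None:
                raise ValidationError("event present but time_months missing")
        if self.time_months is not None and self.time_months < 0:
            raise ValidationError("time_months must be nonnegative")


@dataclasses.dataclass
class SurvivalRecord:
    """One patient's model output carried into evaluation."""

    patient_id: str
    risk_score: float
    pred_label: int
    true_label: int
    time_months: Optional[float] = None
    event: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.risk_score <= 1.0:
            raise ValidationError(
                f"risk_score must lie in [0, 1], got {self.risk_score}"
            )


def write_bag(bag: PatchBag, path) -> None:
    """Write a validated bag to an HDF5 file (one file per slide).

    Layout: datasets ``/coords`` (int64), ``/generic`` and ``/morph``
    (float32); ``slide_id``, ``patient_id``, ``label`` and the optional
    ``time_months``/``event`` as root attributes.
    """
    bag.validate()
    path = Path(path)
    try:
        f = h5py.File(path, "w")
    except OSError as exc:  # unwritable path
        raise OSError(f"cannot write bag to {path}: {exc}") from exc
    with f:
        f.create_dataset("coords", data=bag.coords)
        f.create_dataset("generic", data=bag.generic_features)
        f.create_dataset("morph", data=bag.morph_features)
        f.attrs["slide_id"] = bag.slide_id
        f.attrs["patient_id"] = bag.patient_id
        f.attrs["label"] = np.int8(bag.label)
        if bag.time_months is not None:
            f.attrs["time_months"] = float(bag.time_months)
        if bag.event is not None:
            f.attrs["event"] = np.int8(bag.event)


def load_bag(path) -> PatchBag:
    """Read and validate a bag written by :func:`write_bag`."""
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except (OSError, FileNotFoundError) as exc:
        raise FormatError(f"not a readable bag file: {path} ({exc})") from exc
    with f:
        for member in ("coords", "generic", "morph"):
            if member not in f:
                raise FormatError(f"bag file {path} is missing '{member}'")
        for attr in ("slide_id", "patient_id", "label"):
            if attr not in f.attrs:
                raise FormatError(f"bag file {path} is missing attribute '{attr}'")
        return PatchBag(
            slide_id=str(f.attrs["slide_id"]),
            patient_id=str(f.attrs["patient_id"]),
            coords=f["coords"][()],
            generic_features=f["generic"][()],
            morph_features=f["morph"][()],
            label=int(f.attrs["label"]),
            time_months=(
                float(f.attrs["time_months"]) if "time_months" in f.attrs else None
            ),
            event=int(f.attrs["event"]) if "event" in f.attrs else None,
        )


def read_cohort(path) -> pd.DataFrame:
    """Read a clinical covariate table from CSV.

    Requires columns ``patient_id, age, sex, bmi, income``; numeric columns
    must parse cleanly (no silent coercion) and patient ids must be unique.
    Extra columns (treatment arm, outcome annotations, ...) pass through.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in COHORT_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing column(s): {', '.join(missing)}")
    for col in ("age", "bmi", "income"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad) > 0:
            raise SchemaError(
                f"column '{col}' has unparseable numeric values at rows "
                f"{list(bad[:5])}"
            )
        df[col] = parsed
    dupes = df["patient_id"][df["patient_id"].duplicated()].unique()
    if len(dupes) > 0:
        raise ValidationError(f"duplicate patient_id(s): {list(dupes[:5])}")
    bad_sex = sorted(set(df["sex"].dropna().unique()) - {"M", "F"})
    if bad_sex:
        raise ValidationError(f"sex must be 'M' or 'F'; got {bad_sex}")
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table as RFC-4180 CSV (UTF-8, header row)."""
    cohort.to_csv(path, index=False)
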