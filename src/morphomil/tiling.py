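"""Patch tiling and tissue-content filtering for rasterized slide images.

Slides are partitioned into non-overlapping fixed-size patches on a grid
anchored at the image origin; partial patches at the right/bottom edge are
discarded.  Before feature extraction, patches containing less than 25%
tissue are excluded.  Tissue is detected with a deterministic HSV rule:
a pixel is tissue iff its saturation exceeds 0.05 and its value is below
0.95 — background on an H&E slide is bright and unsaturated, stained
tissue is neither.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv

from .errors import EmptyGridError, ShapeError

__all__ = [
    "PatchGrid",
    "grid_patches",
    "tissue_fraction",
    "compute_tissue_fractions",
    "filter_patches",
    "read_image",
]

SATURATION_THRESHOLD = 0.05
VALUE_THRESHOLD = 0.95
DEFAULT_PATCH_SIZE = 224
DEFAULT_MIN_TISSUE_FRACTION = 0.25


@dataclasses.dataclass
class PatchGrid:
    """A set of patch origins for one image, with optional tissue fractions.

    Origins are 0-based ``(x, y) = (column, row)`` pixel coordinates at the
    raster's native scale; ``magnification_label`` is carried as metadata
    only (inputs are assumed pre-scaled).
    """

    patch_size_px: int
    origins: list
    magnification_label: str = "20x"
    tissue_fraction: Optional[list] = None

    def __post_init__(self) -> None:
        self.origins = [(int(x), int(y)) for x, y in self.origins]
        if len(set(self.origins)) != len(self.origins):
            raise ShapeError("patch origins must be pairwise distinct")
        if self.tissue_fraction is not None:
            self.tissue_fraction = [float(v) for v in self.tissue_fraction]
            if len(self.tissue_fraction) != len(self.origins):
                raise ShapeError("tissue_fraction length must match origins")

    def __len__(self) -> int:
        return len(self.origins)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (origin_x, origin_y, tissue_fraction) for CSV export."""
        frac = self.tissue_fraction
        return pd.DataFrame(
            {
                "origin_x": [x for x, _ in self.origins],
                "origin_y": [y for _, y in self.origins],
                "tissue_fraction": frac if frac is not None else np.nan,
            }
        )


def grid_patches(image: np.ndarray, patch_size: int = DEFAULT_PATCH_SIZE) -> PatchGrid:
    """Tile an H×W×3 raster into a non-overlapping patch grid.

    The grid is anchored at (0, 0) with stride = patch size; any remainder
    narrower than a patch is dropped.  Origins are listed row-major.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ShapeError(f"expected an H×W×3 RGB raster, got shape {image.shape}")
    h, w = image.shape[:2]
    if h < patch_size or w < patch_size:
        raise EmptyGridError(
            f"image {h}×{w} is smaller than patch size {patch_size}"
        )
    origins = [
        (x, y)
        for y in range(0, h - patch_size + 1, patch_size)
        for x in range(0, w - patch_size + 1, patch_size)
    ]
    return PatchGrid(patch_size_px=patch_size, origins=origins)


def tissue_fraction(patch: np.ndarray) -> float:
    """Fraction of pixels in an 8-bit RGB patch classified as tissue."""
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ShapeError(f"expected an H×W×3 RGB patch, got shape {patch.shape}")
    hsv = rgb2hsv(patch)
    tissue = (hsv[..., 1] > SATURATION_THRESHOLD) & (hsv[..., 2] < VALUE_THRESHOLD)
    return float(tissue.mean())


def compute_tissue_fractions(grid: PatchGrid, image: np.ndarray) -> PatchGrid:
    """Populate ``tissue_fraction`` for every patch of a grid."""
    ps = grid.patch_size_px
    fractions = [
        tissue_fraction(image[y : y + ps, x : x + ps]) for x, y in grid.origins
    ]
    return PatchGrid(
        patch_size_px=ps,
        origins=list(grid.origins),
        magnification_label=grid.magnification_label,
        tissue_fraction=fractions,
    )


def filter_patches(
    grid: PatchGrid, min_fraction: float = DEFAULT_MIN_TISSUE_FRACTION
) -> PatchGrid:
    """Drop patches whose tissue fraction is strictly below ``min_fraction``.

    A patch at exactly the threshold is kept ("less than 25% ... excluded").
    """
    if grid.tissue_fraction is None:
        raise ShapeError("tissue_fraction must be populated before filtering")
    keep = [i for i, f in enumerate(grid.tissue_fraction) if f >= min_fraction]
    return PatchGrid(
        patch_size_px=grid.patch_size_px,
        origins=[grid.origins[i] for i in keep],
        magnification_label=grid.magnification_label,
        tissue_fraction=[grid.tissue_fraction[i] for i in keep],
    )


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF raster into an 8-bit RGB array."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return arr
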