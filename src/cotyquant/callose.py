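"""Aniline-blue callose puncta counting on confocal fluorescence images.

Callose deposits appear as bright puncta on a dark background; dead
cells contribute dimmer autofluorescence. Puncta are counted in the
center tile of a 3x3 partition of the (square) image, above a single
global intensity floor calibrated so that control images — samples
processed without aniline blue — almost never exceed it. Counts are
converted to puncta per mm² of leaf area using the per-image pixel size.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .image_io import ConfigurationError, ImageRecord
from .necrosis import label_components

__all__ = [
    "PunctaThreshold",
    "CalloseMeasurement",
    "calibrate_threshold",
    "center_tile",
    "count_puncta",
    "select_representative_by_median",
]

DEFAULT_EPSILON = 1e-4
DEFAULT_MIN_AREA = 2  # px; suppresses single-pixel shot noise


@dataclasses.dataclass(frozen=True)
class PunctaThreshold:
    """Global intensity floor with its calibration provenance.

    ``intensity_floor`` is the smallest integer T such that, over the
    pooled control pixels, the fraction with value >= T is at most
    ``exceedance_epsilon``.
    """

    intensity_floor: int
    n_control_images: int
    pooled_pixels: int
    exceedance_epsilon: float


@dataclasses.dataclass
class CalloseMeasurement:
    """Puncta count and density for the center tile of one image."""

    image_id: str
    tile: tuple  # (row0, row1, col0, col1), half-open
    spot_count: int
    tile_area_mm2: float
    density_per_mm2: float


def _gray_pixels(image: ImageRecord) -> np.ndarray:
    if image.is_rgb:
        raise TypeError(
            f"image {image.image_id!r} is RGB; callose quantification expects "
            "single-channel fluorescence images"
        )
    return image.pixels


def calibrate_threshold(
    controls: Sequence[ImageRecord], epsilon: float = DEFAULT_EPSILON
) -> PunctaThreshold:
    """Smallest intensity floor whose pooled-control exceedance is <= epsilon.

    Pools all pixels of the no-stain control images and returns the
    smallest integer T with fraction(pixels >= T) <= epsilon. Pooling is
    order-invariant: two controls give the same floor as their
    concatenation.
    """
    if len(controls) == 0:
        raise ConfigurationError("calibration requires at least one control image")
    if not (0.0 < epsilon < 1.0):
        raise ValueError("epsilon must lie in (0, 1)")
    pools = [np.asarray(_gray_pixels(c)).ravel() for c in controls]
    pooled = np.concatenate(pools)
    n = pooled.size
    top = int(pooled.max())
    counts = np.bincount(pooled.astype(np.int64), minlength=top + 2)
    # survival[t] = number of pixels with value >= t, t = 0 .. top+1
    survival = np.concatenate([np.cumsum(counts[::-1])[::-1], [0]])[: top + 2]
    ok = survival / n <= epsilon
    floor = int(np.argmax(ok))  # smallest t satisfying the bound
    return PunctaThreshold(
        intensity_floor=floor,
        n_control_images=len(controls),
        pooled_pixels=int(n),
        exceedance_epsilon=float(epsilon),
    )


def center_tile(image: ImageRecord, square_tolerance_px: int = 2) -> tuple:
    """Center cell of the 3x3 grid partition of a square image.

    Returns half-open bounds ``(row0, row1, col0, col1)`` with
    ``row0 = floor(h/3)``, ``row1 = floor(2h/3)`` and likewise for
    columns, so every pixel belongs to exactly one of the nine tiles.
    Images whose width and height differ by more than
    ``square_tolerance_px`` are rejected.
    """
    h, w = image.shape
    if abs(w - h) > square_tolerance_px:
        raise ValueError(
            f"image {image.image_id!r} is not square (w={w}, h={h}, "
            f"aspect {w / h:.3f}); center-tile counting needs square fields"
        )
    return (h // 3, (2 * h) // 3, w // 3, (2 * w) // 3)


def count_puncta(
    image: ImageRecord,
    thr: PunctaThreshold,
    min_area: int = DEFAULT_MIN_AREA,
) -> CalloseMeasurement:
    """Count supra-threshold puncta in the center tile and their density.

    The center tile is binarized at ``intensity >= intensity_floor``;
    8-connected components with area >= ``min_area`` are puncta
    (components touching the tile border count — no border exclusion).
    Density is count over the tile area, ``(side_px * pixel_size_mm)²``
    per axis, in mm².
    """
    if image.pixel_size_um is None:
        raise ConfigurationError(
            f"image {image.image_id!r} lacks pixel_size_um; required for "
            "density per mm²"
        )
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    px = _gray_pixels(image)
    r0, r1, c0, c1 = center_tile(image)
    tile = px[r0:r1, c0:c1]
    mask = tile >= thr.intensity_floor
    regions = label_components(mask, connectivity=8)
    count = int((regions.areas_px >= min_area).sum()) if regions.n_components else 0
    mm_per_px = image.pixel_size_um / 1000.0
    tile_area_mm2 = (r1 - r0) * mm_per_px * (c1 - c0) * mm_per_px
    return CalloseMeasurement(
        image_id=image.image_id,
        tile=(r0, r1, c0, c1),
        spot_count=count,
        tile_area_mm2=tile_area_mm2,
        density_per_mm2=count / tile_area_mm2,
    )


def select_representative_by_median(
    table: pd.DataFrame,
    count_col: str = "spot_count",
    group_cols: Sequence[str] = ("genotype", "ca_mM", "day"),
) -> pd.DataFrame:
    """Representative image per condition: the one at the median count.

    For each group the representative is the image whose puncta count
    equals the group's lower median (the lower of the two central order
    statistics for even n); ties on the count go to the smallest
    image_id. Returns one row per group with the chosen image_id.
    """
    if table.empty:
        return pd.DataFrame(columns=[*group_cols, "image_id", count_col])
    rows = []
    for keys, grp in table.groupby(list(group_cols), sort=True):
        counts = np.sort(grp[count_col].to_numpy())
        lower_median = counts[(len(counts) - 1) // 2]
        match = grp[grp[count_col] == lower_median].sort_values("image_id")
        rep = match.iloc[0]
        rows.append(
            {
                **dict(zip(group_cols, keys if isinstance(keys, tuple) else (keys,))),
                "image_id": rep["image_id"],
                count_col: rep[count_col],
            }
        )
    return pd.DataFrame(rows)
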