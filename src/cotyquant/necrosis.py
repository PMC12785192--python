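"""Trypan-blue necrosis segmentation and per-cotyledon dead-area measures.

Dead (trypan-blue-stained) pixels are identified by a box threshold in
HSB color space with every channel scaled to 0–255, the convention of the
interactive color-threshold tools used for this kind of bright-field
histochemistry. Stained pixels are grouped into connected components
("particles"); two headline statistics are computed per cotyledon:

* **total dead area** — summed area of all components at or above a small
  noise floor (default 20 px), an indicator of overall cell death;
* **largest necrotic spot** — the maximal-area component at or above a
  necrosis floor (default 1000 px, several neighboring dead cells at
  roughly 100–200 px per cell), whose centroid feeds the positional
  analysis in :mod:`cotyquant.morphometry`.

Both size filters are inclusive (``area >= floor``); pass ``strict=True``
for the ``>`` reading.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from skimage import measure

from .image_io import ImageRecord

__all__ = [
    "HSBThreshold",
    "DEFAULT_STAIN_BOX",
    "DEFAULT_MIN_AREA",
    "DEFAULT_SPOT_FLOOR",
    "LabeledRegions",
    "NecrosisMeasurement",
    "rgb_to_hsb",
    "threshold_stain",
    "label_components",
    "total_dead_area",
    "largest_necrotic_spot",
    "measure_necrosis",
]

DEFAULT_MIN_AREA = 20
DEFAULT_SPOT_FLOOR = 1000


@dataclasses.dataclass(frozen=True)
class HSBThreshold:
    """Closed box threshold in 0–255-scaled HSB space.

    A pixel is stained iff hue, saturation and brightness each lie in the
    corresponding closed interval ``[lo, hi]``. Hue wraparound across
    0/255 is not supported: ``lo > hi`` is an error.
    """

    hue_lo: int
    hue_hi: int
    sat_lo: int
    sat_hi: int
    bri_lo: int
    bri_hi: int

    def __post_init__(self) -> None:
        for name in ("hue", "sat", "bri"):
            lo = getattr(self, f"{name}_lo")
            hi = getattr(self, f"{name}_hi")
            if not (0 <= lo <= 255 and 0 <= hi <= 255):
                raise ValueError(f"{name} bounds must lie in [0, 255]")
            if lo > hi:
                raise ValueError(
                    f"{name}: lo={lo} > hi={hi}; wraparound thresholds are "
                    "not supported"
                )


#: Trypan-blue stain box used throughout: hue 120–200, saturation
#: 120–255, brightness 0–190 on the 0–255 HSB scale.
DEFAULT_STAIN_BOX = HSBThreshold(120, 200, 120, 255, 0, 190)


@dataclasses.dataclass
class LabeledRegions:
    """Connected components of a binary stain mask.

    ``labels`` has the mask's shape with 0 for background; ``areas_px``
    and centroids are indexed by component, with ``labels_list[i]`` the
    label of the i-th record. Centroids are the unweighted means of the
    component's (x, y) pixel coordinates.
    """

    labels: np.ndarray
    labels_list: np.ndarray  # (n,) int, sorted ascending
    areas_px: np.ndarray  # (n,) int
    centroids: np.ndarray  # (n, 2) float, columns (x, y)
    connectivity: int = 8

    @property
    def n_components(self) -> int:
        return len(self.labels_list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "label": self.labels_list,
                "area_px": self.areas_px,
                "centroid_x": self.centroids[:, 0] if self.n_components else [],
                "centroid_y": self.centroids[:, 1] if self.n_components else [],
            }
        )


@dataclasses.dataclass
class NecrosisMeasurement:
    """Per-cotyledon dead-area summary."""

    image_id: str
    total_dead_area_px: int
    largest_spot_area_px: Optional[int]
    largest_spot_centroid: Optional[tuple]  # (x, y) px

    @property
    def has_spot(self) -> bool:
        return self.largest_spot_area_px is not None


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def rgb_to_hsb(image) -> np.ndarray:
    """Convert an 8-bit RGB image to 0–255-scaled HSB.

    With ``M = max(r, g, b)`` and ``m = min(r, g, b)``: brightness is
    ``M``; saturation is ``round(255 (M - m) / M)`` (0 when ``M = 0``);
    hue is the standard hexagonal hue fraction in [0, 1) (red 0, green
    1/3, blue 2/3) scaled by 255, rounded half-up, and 0 for achromatic
    pixels. Returns an ``(H, W, 3)`` uint8 array in H, S, B order.
    """
    if isinstance(image, ImageRecord):
        pixels = image.pixels
        where = f" (image {image.image_id!r})"
    else:
        pixels = np.asarray(image)
        where = ""
    if pixels.ndim != 3 or pixels.shape[-1] != 3:
        raise TypeError(
            "rgb_to_hsb expects an 8-bit RGB image" + where + "; "
            "grayscale fluorescence images are handled by cotyquant.callose"
        )
    if pixels.dtype != np.uint8:
        raise TypeError("rgb_to_hsb expects uint8 channel values" + where)

    rgb = pixels.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    M = np.max(rgb, axis=-1)
    m = np.min(rgb, axis=-1)
    d = M - m

    bri = M
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(M > 0, _round_half_up(255.0 * d / np.where(M > 0, M, 1)), 0.0)

    # hue fraction on the hexagonal color wheel, in [0, 1)
    safe_d = np.where(d > 0, d, 1.0)
    h_r = np.mod((g - b) / safe_d, 6.0) / 6.0
    h_g = (2.0 + (b - r) / safe_d) / 6.0
    h_b = (4.0 + (r - g) / safe_d) / 6.0
    frac = np.where(M == r, h_r, np.where(M == g, h_g, h_b))
    hue = np.where(d > 0, _round_half_up(255.0 * frac), 0.0)

    out = np.stack([hue, sat, bri], axis=-1)
    return np.clip(out, 0, 255).astype(np.uint8)


def threshold_stain(hsb: np.ndarray, thr: HSBThreshold = DEFAULT_STAIN_BOX) -> np.ndarray:
    """Binary stain mask: inside the closed HSB box on all three channels."""
    hsb = np.asarray(hsb)
    if hsb.ndim != 3 or hsb.shape[-1] != 3:
        raise TypeError("threshold_stain expects an (H, W, 3) HSB grid")
    if hsb.min() < 0 or hsb.max() > 255:
        raise ValueError("HSB channel values must lie in [0, 255]")
    h, s, b = hsb[..., 0], hsb[..., 1], hsb[..., 2]
    return (
        (h >= thr.hue_lo) & (h <= thr.hue_hi)
        & (s >= thr.sat_lo) & (s <= thr.sat_hi)
        & (b >= thr.bri_lo) & (b <= thr.bri_hi)
    )


def label_components(mask: np.ndarray, connectivity: int = 8) -> LabeledRegions:
    """Label connected foreground components of a binary mask.

    ``connectivity`` 8 (default) joins diagonal neighbors, matching
    common particle-analysis behavior; 4 joins edge neighbors only.
    """
    mask = np.asarray(mask)
    if mask.dtype != bool:
        if not np.isin(mask, (0, 1)).all():
            raise ValueError("mask must be binary")
        mask = mask.astype(bool)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    skc = 2 if connectivity == 8 else 1
    labels = measure.label(mask, connectivity=skc)
    n = int(labels.max())
    if n == 0:
        return LabeledRegions(
            labels=labels,
            labels_list=np.empty(0, dtype=int),
            areas_px=np.empty(0, dtype=int),
            centroids=np.empty((0, 2), dtype=float),
            connectivity=connectivity,
        )
    flat = labels.ravel()
    areas = np.bincount(flat, minlength=n + 1)[1:]
    ys, xs = np.nonzero(labels)
    lab = labels[ys, xs]
    sum_x = np.bincount(lab, weights=xs, minlength=n + 1)[1:]
    sum_y = np.bincount(lab, weights=ys, minlength=n + 1)[1:]
    centroids = np.stack([sum_x / areas, sum_y / areas], axis=1)
    return LabeledRegions(
        labels=labels,
        labels_list=np.arange(1, n + 1),
        areas_px=areas.astype(int),
        centroids=centroids,
        connectivity=connectivity,
    )


def total_dead_area(
    regions: LabeledRegions, min_area: int = DEFAULT_MIN_AREA, strict: bool = False
) -> int:
    """Sum of component areas at or above the noise floor ``min_area``."""
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    if regions.n_components == 0:
        return 0
    keep = regions.areas_px > min_area if strict else regions.areas_px >= min_area
    return int(regions.areas_px[keep].sum())


def largest_necrotic_spot(
    regions: LabeledRegions,
    spot_floor: int = DEFAULT_SPOT_FLOOR,
    strict: bool = False,
) -> Optional[tuple]:
    """Largest component at or above the necrosis floor, or ``None``.

    Returns ``(area_px, (centroid_x, centroid_y))``. Ties at the maximal
    area are broken toward the smallest label (deterministic).
    """
    if spot_floor < 1:
        raise ValueError("spot_floor must be >= 1")
    if regions.n_components == 0:
        return None
    keep = regions.areas_px > spot_floor if strict else regions.areas_px >= spot_floor
    if not keep.any():
        return None
    idx = np.flatnonzero(keep)
    best = idx[np.argmax(regions.areas_px[idx])]  # argmax → first max → smallest label
    return int(regions.areas_px[best]), tuple(regions.centroids[best])


def measure_necrosis(
    image: ImageRecord,
    thr: HSBThreshold = DEFAULT_STAIN_BOX,
    min_area: int = DEFAULT_MIN_AREA,
    spot_floor: int = DEFAULT_SPOT_FLOOR,
    connectivity: int = 8,
    strict: bool = False,
) -> tuple[NecrosisMeasurement, LabeledRegions]:
    """Full per-image necrosis quantification.

    Thresholds the image in HSB space, labels components, and returns the
    measurement together with the noise-filtered regions (components at
    or above ``min_area``, the rows written to spots.csv).
    """
    hsb = rgb_to_hsb(image)
    mask = threshold_stain(hsb, thr)
    regions = label_components(mask, connectivity=connectivity)
    total = total_dead_area(regions, min_area=min_area, strict=strict)
    spot = largest_necrotic_spot(regions, spot_floor=spot_floor, strict=strict)
    measurement = NecrosisMeasurement(
        image_id=image.image_id,
        total_dead_area_px=total,
        largest_spot_area_px=None if spot is None else spot[0],
        largest_spot_centroid=None if spot is None else spot[1],
    )
    keep = (
        regions.areas_px > min_area if strict else regions.areas_px >= min_area
    ) if regions.n_components else np.empty(0, dtype=bool)
    filtered = LabeledRegions(
        labels=np.where(np.isin(regions.labels, regions.labels_list[keep]), regions.labels, 0),
        labels_list=regions.labels_list[keep],
        areas_px=regions.areas_px[keep],
        centroids=regions.centroids[keep] if regions.n_components else regions.centroids,
        connectivity=connectivity,
    )
    return measurement, filtered
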