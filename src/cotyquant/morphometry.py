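"""Cotyledon ellipse fit and ellipse-normalized lesion position.

The cotyledon outline is summarized by its second-moment ("inertia")
ellipse, rescaled so the ellipse area matches the region's pixel area —
the classical moment-equivalent ellipse of particle analysis. The
largest necrotic spot's centroid is then expressed in dimensionless
coordinates anchored to that ellipse: origin at the ellipse center of
mass, ``y_rel`` the signed fraction of the major radius toward the leaf
tip (positive), ``x_rel`` the signed fraction of the minor radius toward
screen right (positive). Because input images are pre-rotated base-down,
the tip is "up" (decreasing row index) by default.

Angle convention: ``angle_deg`` is the major-axis direction in
[0, 180), measured from the +x axis toward decreasing y, i.e.
counterclockwise on screen; an upright leaf has angle near 90.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Union

import numpy as np
from scipy import ndimage
from skimage import filters

from .image_io import ImageRecord

__all__ = [
    "SegmentationError",
    "EllipseFit",
    "LesionPosition",
    "segment_cotyledon",
    "fit_ellipse_moments",
    "lesion_position",
]

#: Relative eigenvalue gap below which a fit is reported as circular.
_CIRCULAR_RTOL = 1e-6


class SegmentationError(RuntimeError):
    """Automatic cotyledon segmentation found no usable object."""


@dataclasses.dataclass
class EllipseFit:
    """Moment-equivalent ellipse of the cotyledon region.

    ``a`` (major) and ``b`` (minor) are semi-axes in pixels, rescaled so
    that pi*a*b equals ``source_area_px``. ``circular`` flags a
    degenerate orientation (equal eigenvalues), in which case the angle
    is reported as 0.
    """

    center: tuple  # (x, y) px
    a: float
    b: float
    angle_deg: float
    source_area_px: int
    circular: bool = False

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError(f"require a >= b > 0, got a={self.a}, b={self.b}")
        if not (0 <= self.angle_deg < 180):
            raise ValueError("angle_deg must lie in [0, 180)")


@dataclasses.dataclass
class LesionPosition:
    """Lesion centroid in ellipse-normalized, tip-positive coordinates."""

    x_rel: float  # fraction of the minor radius, screen-right positive
    y_rel: float  # fraction of the major radius, tip positive
    tilt_exceeded: bool = False  # major axis more than max_tilt from vertical


def segment_cotyledon(
    image: ImageRecord,
    mode: str = "auto",
    mask: Optional[np.ndarray] = None,
    min_fraction: float = 0.01,
) -> np.ndarray:
    """Binary mask of the whole cotyledon (lamina, stained areas included).

    ``provided`` mode returns the supplied mask unchanged (the canonical
    path when the leaf outline was selected manually). ``auto`` mode
    thresholds brightness with Otsu's method against the pale background,
    keeps the largest connected component and fills holes; it raises
    :class:`SegmentationError` when the largest component covers less
    than ``min_fraction`` of the image.
    """
    if mode == "provided":
        if mask is None:
            raise ValueError("provided mode requires a mask")
        mask = np.asarray(mask)
        if mask.shape != image.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match image shape {image.shape}"
            )
        return mask.astype(bool)
    if mode != "auto":
        raise ValueError(f"unknown segmentation mode {mode!r}")

    px = image.pixels
    brightness = px.max(axis=-1) if px.ndim == 3 else px
    flat = brightness.ravel()
    if flat.min() == flat.max():
        raise SegmentationError(
            f"image {image.image_id!r}: uniform brightness, no object to segment"
        )
    thr = filters.threshold_otsu(brightness)
    fg = brightness <= thr  # leaf darker than the pale background
    labels, n = ndimage.label(fg)
    if n == 0:
        raise SegmentationError(f"image {image.image_id!r}: no foreground object")
    areas = np.bincount(labels.ravel())[1:]
    biggest = int(np.argmax(areas)) + 1
    if areas[biggest - 1] < min_fraction * brightness.size:
        raise SegmentationError(
            f"image {image.image_id!r}: largest object covers "
            f"{areas[biggest - 1] / brightness.size:.2%} < {min_fraction:.0%} of the image"
        )
    return ndimage.binary_fill_holes(labels == biggest)


def fit_ellipse_moments(mask: np.ndarray) -> EllipseFit:
    """Area-matched second-moment ellipse of a binary region.

    The center is the coordinate mean. From the 2x2 central second-moment
    matrix with eigenvalues l1 >= l2 the raw semi-axes are 2*sqrt(l1) and
    2*sqrt(l2) (exact for a filled continuous ellipse); both are then
    rescaled by sqrt(A / (pi a0 b0)) so the ellipse area equals the pixel
    count A. The angle comes from the principal eigenvector, mapped into
    [0, 180) measured counterclockwise on screen from +x.
    """
    mask = np.asarray(mask).astype(bool)
    ys, xs = np.nonzero(mask)
    area = len(xs)
    if area < 5:
        raise ValueError(f"mask has {area} foreground pixels; need >= 5")
    cx, cy = xs.mean(), ys.mean()
    dx = xs - cx
    dy = ys - cy
    mxx = float(np.mean(dx * dx))
    myy = float(np.mean(dy * dy))
    mxy = float(np.mean(dx * dy))
    moment = np.array([[mxx, mxy], [mxy, myy]])
    evals, evecs = np.linalg.eigh(moment)  # ascending
    l2, l1 = float(evals[0]), float(evals[1])
    if l2 <= 0:
        raise ValueError("degenerate (collinear) mask: zero minor-axis variance")
    circular = (l1 - l2) <= _CIRCULAR_RTOL * l1
    a0, b0 = 2.0 * math.sqrt(l1), 2.0 * math.sqrt(l2)
    scale = math.sqrt(area / (math.pi * a0 * b0))
    a, b = a0 * scale, b0 * scale
    if circular:
        angle = 0.0
    else:
        vx, vy = float(evecs[0, 1]), float(evecs[1, 1])
        angle = math.degrees(math.atan2(-vy, vx)) % 180.0
        if angle >= 180.0:  # guard fp wrap at exactly 180
            angle = 0.0
    return EllipseFit(
        center=(float(cx), float(cy)),
        a=a,
        b=b,
        angle_deg=angle,
        source_area_px=area,
        circular=circular,
    )


def lesion_position(
    spot_centroid: tuple,
    fit: EllipseFit,
    tip_direction: str = "up",
    x_norm: str = "minor",
    max_tilt_deg: float = 45.0,
) -> LesionPosition:
    """Express a spot centroid in ellipse-normalized tip-positive coordinates.

    The centroid is translated by minus the ellipse center and projected
    onto the major/minor axes; the major-axis orientation pointing toward
    the tip (``up`` by default, images being base-down) is chosen, which
    for a roughly upright leaf is the alignment rotation of magnitude
    <= 45 degrees. ``y_rel`` is the tip-positive major-axis component
    over the major radius; ``x_rel`` is the screen-right-positive
    minor-axis component over the minor radius (or the major radius with
    ``x_norm="major"``). Leaves tilted beyond ``max_tilt_deg`` from
    vertical are flagged, not rejected.
    """
    if fit.a <= 0 or fit.b <= 0:
        raise ValueError("ellipse radii must be positive")
    if tip_direction not in ("up", "down"):
        raise ValueError("tip_direction must be 'up' or 'down'")
    if x_norm not in ("minor", "major"):
        raise ValueError("x_norm must be 'minor' or 'major'")

    theta = math.radians(fit.angle_deg)
    # unit vector along the major axis; for angle in (0, 180) this points
    # toward decreasing y, i.e. screen-up
    u = np.array([math.cos(theta), -math.sin(theta)])
    if tip_direction == "down":
        u = -u
    # screen-right-positive minor-axis direction in the leaf frame
    v = np.array([-u[1], u[0]])

    up = np.array([0.0, -1.0]) if tip_direction == "up" else np.array([0.0, 1.0])
    tilt = math.degrees(math.acos(float(np.clip(np.dot(u, up), -1.0, 1.0))))
    d = np.asarray(spot_centroid, dtype=float) - np.asarray(fit.center, dtype=float)
    y_rel = float(np.dot(d, u)) / fit.a
    x_rel = float(np.dot(d, v)) / (fit.b if x_norm == "minor" else fit.a)
    return LesionPosition(x_rel=x_rel, y_rel=y_rel, tilt_exceeded=tilt > max_tilt_deg)
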