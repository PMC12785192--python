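"""Ground-truth-known synthetic micrographs for every pipeline stage.

Generates (a) bright-field-like images of a single trypan-blue-stained
cotyledon — an elliptical leaf on a pale background with blue lesions
whose HSB values fall inside the stain threshold box, (b) dark-field
confocal-like images with bright callose puncta plus sub-threshold
autofluorescent blobs, and (c) whole simulated cohorts (genotype x day x
Ca x replicate) with configurable genotype effects on lesion size, the
largest-lesion share, lesion position and puncta abundance.

Ground truth is defined at the observable level: lesions that touch or
overlap are recorded as the merged connected component a perfect
segmenter would see, and the true puncta count is the number of
supra-threshold components in the clean image. All generation is
deterministic under the seed; cohort child seeds derive from the master
seed and the (genotype, day, Ca, replicate) cell.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import morphometry
from .image_io import ImageRecord, write_image
from .necrosis import (
    DEFAULT_SPOT_FLOOR,
    DEFAULT_STAIN_BOX,
    HSBThreshold,
    LabeledRegions,
    label_components,
    rgb_to_hsb,
    threshold_stain,
)

__all__ = [
    "LeafSpec",
    "Lesion",
    "LesionSpec",
    "PositionalLaw",
    "GroundTruth",
    "GenotypeParams",
    "CohortSpec",
    "Cohort",
    "make_leaf_image",
    "make_callose_image",
    "make_callose_controls",
    "make_cohort",
    "default_cohort_spec",
    "null_cohort_spec",
]

LEAF_COLOR = (170, 190, 150)  # pale cleared lamina; outside the stain box
BACKGROUND_COLOR = (252, 250, 248)  # near-white slide background
VASCULAR_COLOR = (150, 175, 135)  # slightly darker midvein streak
STAIN_COLOR = (70, 70, 160)  # trypan-blue lesion; inside the stain box


@dataclasses.dataclass
class LeafSpec:
    """Geometry and colors of one synthetic cotyledon.

    ``tilt_deg`` is the deviation of the leaf's long axis from upright,
    counterclockwise on screen positive; the ellipse's major-axis angle
    is therefore ``(90 + tilt_deg) mod 180``. The tip points up (images
    are base-down).
    """

    size: tuple = (384, 384)  # (height, width) px
    center: Optional[tuple] = None  # (x, y) px; default image center
    a: float = 130.0  # major semi-axis, px
    b: float = 75.0  # minor semi-axis, px
    tilt_deg: float = 0.0
    leaf_color: tuple = LEAF_COLOR
    background_color: tuple = BACKGROUND_COLOR
    vascular_color: Optional[tuple] = VASCULAR_COLOR
    vascular_width: float = 3.0

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError("require a >= b > 0")
        if self.center is None:
            h, w = self.size
            self.center = (w / 2.0, h / 2.0)

    @property
    def angle_deg(self) -> float:
        return (90.0 + self.tilt_deg) % 180.0

    def axes_unit_vectors(self) -> tuple:
        """(u, v): tip-pointing major-axis and right-pointing minor-axis units."""
        t = math.radians(self.tilt_deg)
        u = np.array([-math.sin(t), -math.cos(t)])  # up-ish for |tilt| < 90
        v = np.array([-u[1], u[0]])
        return u, v


@dataclasses.dataclass
class Lesion:
    """One circular stained lesion in ellipse-normalized coordinates."""

    center: tuple  # (x_rel, y_rel)
    radius_px: float
    color: tuple = STAIN_COLOR


@dataclasses.dataclass
class LesionSpec:
    lesions: list


@dataclasses.dataclass
class PositionalLaw:
    """Truncated-normal law for lesion centers in normalized coordinates.

    ``y_rel`` ~ Normal(mu_y, sigma_y) truncated to [-1, 1] (tip-biased
    when mu_y > 0, central when mu_y = 0); ``x_rel`` ~ Normal(mu_x,
    sigma_x) truncated to [-0.8, 0.8].
    """

    mu_y: float = 0.0
    sigma_y: float = 0.3
    mu_x: float = 0.0
    sigma_x: float = 0.15

    def draw(self, rng: np.random.Generator) -> tuple:
        def trunc(mu, sd, lo, hi):
            for _ in range(1000):
                x = rng.normal(mu, sd)
                if lo <= x <= hi:
                    return x
            return float(np.clip(mu, lo, hi))

        return (trunc(self.mu_x, self.sigma_x, -0.8, 0.8),
                trunc(self.mu_y, self.sigma_y, -1.0, 1.0))


@dataclasses.dataclass
class GroundTruth:
    """Per-image truth, bit-consistent with the pre-noise rendering.

    For leaf images: the leaf pixel mask, the generating ellipse, the
    per-lesion painted pixel sets, and the connected components of the
    pre-noise stain mask (the observable-level truth). For callose
    images: the supra-threshold component count in the center tile.
    """

    image_id: str
    leaf_mask: Optional[np.ndarray] = None
    ellipse_center: Optional[tuple] = None
    ellipse_a: Optional[float] = None
    ellipse_b: Optional[float] = None
    ellipse_angle_deg: Optional[float] = None
    lesion_mask: Optional[np.ndarray] = None
    lesion_pixel_counts: Optional[list] = None  # painted px per requested lesion
    components: Optional[LabeledRegions] = None  # 8-connected, pre-noise
    puncta_count: Optional[int] = None

    @property
    def total_lesion_px(self) -> int:
        return int(self.lesion_mask.sum()) if self.lesion_mask is not None else 0

    def largest_spot(self, floor: int = DEFAULT_SPOT_FLOOR):
        """True largest stained component at/above ``floor``: (area, centroid)."""
        if self.components is None or self.components.n_components == 0:
            return None
        keep = self.components.areas_px >= floor
        if not keep.any():
            return None
        idx = np.flatnonzero(keep)
        best = idx[np.argmax(self.components.areas_px[idx])]
        return (
            int(self.components.areas_px[best]),
            tuple(self.components.centroids[best]),
        )

    def largest_spot_position(
        self, floor: int = DEFAULT_SPOT_FLOOR, x_norm: str = "minor"
    ):
        """True normalized position of the largest spot under the true ellipse."""
        spot = self.largest_spot(floor)
        if spot is None:
            return None
        fit = morphometry.EllipseFit(
            center=self.ellipse_center,
            a=self.ellipse_a,
            b=self.ellipse_b,
            angle_deg=self.ellipse_angle_deg,
            source_area_px=int(self.leaf_mask.sum()),
        )
        return morphometry.lesion_position(spot[1], fit, x_norm=x_norm)

    def summary(self) -> dict:
        """JSON-serializable sidecar summary (no pixel sets)."""
        out = {"image_id": self.image_id}
        if self.leaf_mask is not None:
            out.update(
                leaf_area_px=int(self.leaf_mask.sum()),
                ellipse_center=list(self.ellipse_center),
                ellipse_a=self.ellipse_a,
                ellipse_b=self.ellipse_b,
                ellipse_angle_deg=self.ellipse_angle_deg,
                total_lesion_px=self.total_lesion_px,
                lesion_pixel_counts=self.lesion_pixel_counts,
                component_areas=[int(a) for a in self.components.areas_px],
            )
        if self.puncta_count is not None:
            out["puncta_count"] = int(self.puncta_count)
        return out


def _assert_color_side(color, box: HSBThreshold, inside: bool, what: str) -> None:
    px = np.array(color, dtype=np.uint8).reshape(1, 1, 3)
    hit = bool(threshold_stain(rgb_to_hsb(px), box)[0, 0])
    if hit != inside:
        side = "inside" if inside else "outside"
        raise ValueError(f"{what} color {tuple(color)} must map {side} the stain box")


def make_leaf_image(
    leaf: LeafSpec,
    lesions: Union[LesionSpec, Sequence[Lesion]],
    noise_sd: float = 0.0,
    seed: int = 0,
    stain_box: HSBThreshold = DEFAULT_STAIN_BOX,
    image_id: Optional[str] = None,
    metadata: Optional[dict] = None,
) -> tuple:
    """Render one stained-cotyledon image and its ground truth.

    Raster order: background, leaf ellipse, optional vascular streak,
    then lesions (disks in normalized coordinates, clipped to the leaf;
    the truth records the clipped pixel sets and the merged-component
    structure). Per-channel Gaussian noise of sd ``noise_sd`` is added
    last, clipped to [0, 255]. Deterministic given ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lesion_list = lesions.lesions if isinstance(lesions, LesionSpec) else list(lesions)
    _assert_color_side(leaf.leaf_color, stain_box, False, "leaf")
    _assert_color_side(leaf.background_color, stain_box, False, "background")
    if leaf.vascular_color is not None:
        _assert_color_side(leaf.vascular_color, stain_box, False, "vascular")
    for les in lesion_list:
        _assert_color_side(les.color, stain_box, True, "lesion")

    h, w = leaf.size
    cx, cy = leaf.center
    u, v = leaf.axes_unit_vectors()
    # leaf must fit inside the frame: projected half-extents of the ellipse
    ex = math.hypot(leaf.a * u[0], leaf.b * v[0])
    ey = math.hypot(leaf.a * u[1], leaf.b * v[1])
    if cx - ex < 0 or cx + ex > w - 1 or cy - ey < 0 or cy + ey > h - 1:
        raise ValueError("leaf ellipse does not fit inside the image")

    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - cx
    dy = yy - cy
    cm = dx * u[0] + dy * u[1]  # major-axis coordinate (tip positive)
    cn = dx * v[0] + dy * v[1]  # minor-axis coordinate (right positive)
    leaf_mask = (cm / leaf.a) ** 2 + (cn / leaf.b) ** 2 <= 1.0

    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = np.array(leaf.background_color, dtype=np.uint8)
    img[leaf_mask] = np.array(leaf.leaf_color, dtype=np.uint8)
    if leaf.vascular_color is not None and leaf.vascular_width > 0:
        vein = leaf_mask & (np.abs(cn) <= leaf.vascular_width / 2.0)
        img[vein] = np.array(leaf.vascular_color, dtype=np.uint8)

    lesion_mask = np.zeros((h, w), dtype=bool)
    painted_counts = []
    for les in lesion_list:
        x_rel, y_rel = les.center
        px = cx + x_rel * leaf.b * v[0] + y_rel * leaf.a * u[0]
        py = cy + x_rel * leaf.b * v[1] + y_rel * leaf.a * u[1]
        disk = (xx - px) ** 2 + (yy - py) ** 2 <= les.radius_px**2
        disk &= leaf_mask  # lesions cannot extend beyond the lamina
        img[disk] = np.array(les.color, dtype=np.uint8)
        lesion_mask |= disk
        painted_counts.append(int(disk.sum()))

    components = label_components(lesion_mask, connectivity=8)
    if image_id is None:
        image_id = f"leaf-{seed}"
    truth = GroundTruth(
        image_id=image_id,
        leaf_mask=leaf_mask,
        ellipse_center=(float(cx), float(cy)),
        ellipse_a=float(leaf.a),
        ellipse_b=float(leaf.b),
        ellipse_angle_deg=float(leaf.angle_deg),
        lesion_mask=lesion_mask,
        lesion_pixel_counts=painted_counts,
        components=components,
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = img.astype(np.float64) + rng.normal(0.0, noise_sd, img.shape)
        img = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    record = ImageRecord(image_id=image_id, pixels=img, **(metadata or {}))
    return record, truth


def _center_tile_bounds(h: int, w: int) -> tuple:
    return (h // 3, (2 * h) // 3, w // 3, (2 * w) // 3)


def make_callose_image(
    n_puncta: int,
    punctum_amp: int = 150,
    autofluor_count: int = 20,
    autofluor_amp: int = 40,
    size: int = 240,
    sigma_punctum: float = 2.0,
    sigma_autofluor: float = 6.0,
    min_separation: float = 12.0,
    noise_sd: float = 0.0,
    pixel_size_um: float = 2.0,
    seed: int = 0,
    truth_floor: Optional[int] = None,
    image_id: Optional[str] = None,
    metadata: Optional[dict] = None,
) -> tuple:
    """Render a confocal-like callose image and its ground truth.

    Bright Gaussian-profile puncta (peak ``punctum_amp``) are placed in
    the center tile of the 3x3 grid, with rejection sampling toward a
    pairwise ``min_separation``; dimmer autofluorescent blobs (peaks at
    0.4-1.0 x ``autofluor_amp``) fall anywhere. Blob profiles compose by
    maximum, so clean-image intensities never exceed the largest peak.
    The true count is the number of supra-``truth_floor`` components in
    the clean center tile (merged puncta count once), with
    ``truth_floor`` defaulting to ``autofluor_amp + 1``.
    """
    if not (0 < punctum_amp <= 255 and 0 <= autofluor_amp <= 255):
        raise ValueError("amplitudes must lie within the 8-bit range")
    if autofluor_amp >= punctum_amp:
        raise ValueError("autofluorescence amplitude must stay below punctum peaks")
    rng = np.random.default_rng(seed)
    canvas = np.zeros((size, size), dtype=np.float64)
    yy, xx = np.mgrid[0:size, 0:size]

    def splat(x0, y0, amp, sigma):
        r2 = (xx - x0) ** 2 + (yy - y0) ** 2
        np.maximum(canvas, amp * np.exp(-r2 / (2.0 * sigma**2)), out=canvas)

    for _ in range(autofluor_count):
        splat(rng.uniform(0, size), rng.uniform(0, size),
              rng.uniform(0.4, 1.0) * autofluor_amp, sigma_autofluor)

    r0, r1, c0, c1 = _center_tile_bounds(size, size)
    margin = 2.0
    centers = []
    for _ in range(n_puncta):
        for _ in range(200):
            x0 = rng.uniform(c0 + margin, c1 - margin)
            y0 = rng.uniform(r0 + margin, r1 - margin)
            if all((x0 - a) ** 2 + (y0 - b) ** 2 >= min_separation**2 for a, b in centers):
                break
        centers.append((x0, y0))
        splat(x0, y0, rng.uniform(0.85, 1.0) * punctum_amp, sigma_punctum)

    if truth_floor is None:
        truth_floor = autofluor_amp + 1
    clean = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    tile_regions = label_components(clean[r0:r1, c0:c1] >= truth_floor, connectivity=8)
    true_count = int((tile_regions.areas_px >= 2).sum()) if tile_regions.n_components else 0

    img = clean
    if noise_sd > 0:
        noisy = canvas + rng.normal(0.0, noise_sd, canvas.shape)
        img = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    if image_id is None:
        image_id = f"callose-{seed}"
    md = {"pixel_size_um": pixel_size_um}
    md.update(metadata or {})
    record = ImageRecord(image_id=image_id, pixels=img, **md)
    truth = GroundTruth(image_id=image_id, puncta_count=true_count)
    return record, truth


def make_callose_controls(
    n_images: int, seed: int = 0, **kwargs
) -> list:
    """No-stain control images (autofluorescence only) for calibration."""
    out = []
    for k in range(n_images):
        child = int(np.random.SeedSequence([seed, 9001, k]).generate_state(1)[0] % 2**31)
        rec, _ = make_callose_image(
            n_puncta=0, seed=child, image_id=f"control-{seed}-{k}", **kwargs
        )
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# cohort simulation


#: Leaf area (px) of the reference geometry (384-px frame, mean priors);
#: lesion-area laws are expressed at this scale and rescaled with the
#: actual leaf so that cohorts are invariant to the rendering resolution.
REFERENCE_LEAF_AREA = math.pi * (0.335 * 384) * (0.57 * 0.335 * 384)


@dataclasses.dataclass
class GenotypeParams:
    """Per-genotype generative laws for one simulated cohort.

    Total lesion area per cotyledon is lognormal with a per-day trend on
    the log mean (cell death accumulates with time under low Ca); the
    largest lesion takes a clipped-normal share of it and is placed by
    ``law``; the remainder is split over a Poisson number of secondary
    lesions placed by ``secondary_law``. Callose puncta per image are
    Poisson with a linear per-day mean, collapsed to near zero under
    Ca-replete (>= 1 mM) conditions.

    Area laws are stated in pixels at the reference leaf size
    (:data:`REFERENCE_LEAF_AREA`) and scale with the rendered leaf, so
    the stained *fraction* of the lamina — not the absolute pixel count —
    is what the law controls.
    """

    total_area_log_mean: float = math.log(3000.0)
    total_area_log_sd: float = 0.30
    day_log_slope: float = 0.15  # added to log mean per day past the first
    largest_share_mean: float = 0.45
    largest_share_sd: float = 0.08
    n_secondary_mean: float = 2.0
    law: PositionalLaw = dataclasses.field(
        default_factory=lambda: PositionalLaw(mu_y=0.6, sigma_y=0.2)
    )
    secondary_law: PositionalLaw = dataclasses.field(
        default_factory=lambda: PositionalLaw(mu_y=0.0, sigma_y=0.35)
    )
    puncta_base: float = 3.0  # mean puncta at the first day, low Ca
    puncta_per_day: float = 2.5
    puncta_high_ca: float = 0.3  # mean under Ca-replete conditions


@dataclasses.dataclass
class CohortSpec:
    """Design and generative parameters of a simulated experiment.

    Defaults mirror the study design under test: two genotypes (wild
    type and a callose-synthase mutant), growth days 4-7, low-Ca media
    at 0.2 and 0.1 mM, 15 cotyledons per cell split over two experiment
    replicates. The default genotype effects are: identical total-lesion
    laws, a larger largest-lesion share in the mutant, tip-biased
    largest-lesion placement in the wild type that is weaker in the
    mutant, and fewer callose puncta in the mutant.
    """

    genotypes: tuple = ("Col-0", "gsl10-5")
    days: tuple = (4, 5, 6, 7)
    ca_mM: tuple = (0.2, 0.1)
    n_per_cell: int = 15
    n_experiments: int = 2
    image_size: int = 384
    pixel_size_um: float = 5.0
    noise_sd: float = 2.0
    include_callose: bool = False
    callose_image_size: int = 240
    callose_pixel_size_um: float = 2.0
    master_seed: int = 0
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if not self.params:
            self.params = {
                self.genotypes[0]: GenotypeParams(),
                self.genotypes[1]: GenotypeParams(
                    largest_share_mean=0.70,
                    law=PositionalLaw(mu_y=0.15, sigma_y=0.35),
                    puncta_base=1.0,
                    puncta_per_day=0.8,
                ),
            }
        for g in self.genotypes:
            if g not in self.params:
                raise ValueError(f"no GenotypeParams for genotype {g!r}")


@dataclasses.dataclass
class Cohort:
    """In-memory simulated cohort: sample sheet plus images and truths."""

    sheet: pd.DataFrame
    leaf_images: list  # [(ImageRecord, GroundTruth)]
    callose_images: list  # [(ImageRecord, GroundTruth)]


def default_cohort_spec(master_seed: int = 0, **overrides) -> CohortSpec:
    """The standard simulated experiment (see :class:`CohortSpec`)."""
    return CohortSpec(master_seed=master_seed, **overrides)


def null_cohort_spec(master_seed: int = 0, **overrides) -> CohortSpec:
    """A cohort with no genotype effect on any response (both genotypes
    share one set of generative laws), for null calibration."""
    spec = CohortSpec(master_seed=master_seed, **overrides)
    if "params" not in overrides:
        spec.params = {g: GenotypeParams() for g in spec.genotypes}
    return spec


def _child_seed(master: int, *key: int) -> int:
    return int(np.random.SeedSequence([master, *key]).generate_state(1)[0] % 2**31)


def _draw_leaf_geometry(rng: np.random.Generator, size: int) -> LeafSpec:
    a = rng.uniform(0.31, 0.36) * size
    b = a * rng.uniform(0.52, 0.62)
    tilt = float(np.clip(rng.normal(0.0, 6.0), -15.0, 15.0))
    jitter = rng.uniform(-0.01 * size, 0.01 * size, size=2)
    return LeafSpec(
        size=(size, size),
        center=(size / 2.0 + jitter[0], size / 2.0 + jitter[1]),
        a=a,
        b=b,
        tilt_deg=tilt,
    )


def _contain(x_rel: float, y_rel: float, leaf: LeafSpec, r: float) -> tuple:
    """Shrink a normalized position until a disk of radius r fits in the leaf."""
    aa = max(leaf.a - r - 1.0, 1.0)
    bb = max(leaf.b - r - 1.0, 1.0)
    q = (x_rel * leaf.b / bb) ** 2 + (y_rel * leaf.a / aa) ** 2
    if q > 1.0:
        s = 0.999 / math.sqrt(q)
        return x_rel * s, y_rel * s
    return x_rel, y_rel


def _draw_lesions(
    rng: np.random.Generator, leaf: LeafSpec, gp: GenotypeParams, day_offset: int
) -> list:
    leaf_area = math.pi * leaf.a * leaf.b
    log_mu = (
        gp.total_area_log_mean
        + gp.day_log_slope * day_offset
        + math.log(leaf_area / REFERENCE_LEAF_AREA)
    )
    total = min(math.exp(rng.normal(log_mu, gp.total_area_log_sd)), 0.35 * leaf_area)
    share = float(np.clip(rng.normal(gp.largest_share_mean, gp.largest_share_sd), 0.10, 0.90))
    lesions = []
    placed = []  # (dx_px, dy_px, r) in the isometric ellipse frame

    def place(law: PositionalLaw, r: float) -> tuple:
        # rejection-sample toward non-overlapping spots (distinct lesions,
        # as in the stained material); give up after 200 tries and let the
        # observable-level truth absorb the merge
        for _ in range(200):
            x, y = law.draw(rng)
            x, y = _contain(x, y, leaf, r)
            dx, dy = x * leaf.b, y * leaf.a
            if all(
                math.hypot(dx - px, dy - py) >= r + pr + 2.0 for px, py, pr in placed
            ):
                break
        placed.append((dx, dy, r))
        return x, y

    main_area = share * total
    r_main = min(math.sqrt(main_area / math.pi), leaf.b - 5.0)
    lesions.append(Lesion(center=place(gp.law, r_main), radius_px=r_main))

    rest = total - main_area
    m = 1 + rng.poisson(gp.n_secondary_mean)
    shares = rng.dirichlet(np.ones(m))
    # satellite spots stay strictly smaller than the primary lesion;
    # oversized pieces are split (not truncated) so the drawn total-area
    # law is conserved identically across genotypes
    cap_area = math.pi * min(0.9 * r_main, leaf.b - 5.0) ** 2
    pieces = []
    for s in shares:
        area = s * rest
        if area < 8.0:
            continue
        n_parts = max(1, math.ceil(area / cap_area))
        pieces.extend([area / n_parts] * n_parts)
    for area in pieces:
        r = math.sqrt(area / math.pi)
        lesions.append(Lesion(center=place(gp.secondary_law, r), radius_px=r))
    return lesions


def _puncta_mean(gp: GenotypeParams, day_offset: int, ca: float) -> float:
    if ca >= 1.0:
        return gp.puncta_high_ca
    return max(gp.puncta_base + gp.puncta_per_day * day_offset, 0.0)


def make_cohort(spec: CohortSpec, out_dir: Optional[Union[str, Path]] = None) -> Cohort:
    """Simulate a full cohort; optionally write images + sheet to disk.

    Emits one stained-leaf image per (genotype, day, Ca, replicate) cell
    member, plus one callose image each when ``spec.include_callose``.
    Replicates are split evenly over ``n_experiments`` experiment labels.
    With ``out_dir`` set, images are written as TIFF, ground-truth
    summaries as JSON sidecars, and the sheet as ``samples.csv``.
    """
    rows = []
    leaf_images = []
    callose_images = []
    day0 = min(spec.days)
    for gi, genotype in enumerate(spec.genotypes):
        gp = spec.params[genotype]
        for di, day in enumerate(spec.days):
            for ci, ca in enumerate(spec.ca_mM):
                for k in range(spec.n_per_cell):
                    seed = _child_seed(spec.master_seed, gi, di, ci, k)
                    rng = np.random.default_rng(seed)
                    leaf = _draw_leaf_geometry(rng, spec.image_size)
                    lesions = _draw_lesions(rng, leaf, gp, day - day0)
                    image_id = f"{genotype}-d{day}-ca{ca:g}-{k:02d}"
                    experiment = f"exp{1 + (k * spec.n_experiments) // spec.n_per_cell}"
                    meta = {
                        "genotype": genotype,
                        "day": day,
                        "ca_mM": ca,
                        "experiment": experiment,
                        "pixel_size_um": spec.pixel_size_um,
                    }
                    rec, truth = make_leaf_image(
                        leaf,
                        lesions,
                        noise_sd=spec.noise_sd,
                        seed=_child_seed(spec.master_seed, gi, di, ci, k, 1),
                        image_id=image_id,
                        metadata=meta,
                    )
                    leaf_images.append((rec, truth))
                    rows.append(
                        {
                            "path": f"{image_id}.tif",
                            "image_id": image_id,
                            "genotype": genotype,
                            "day": day,
                            "ca_mM": ca,
                            "experiment": experiment,
                            "pixel_size_um": spec.pixel_size_um,
                            "qc_excluded": False,
                            "qc_reason": "",
                        }
                    )
                    if spec.include_callose:
                        cb_seed = _child_seed(spec.master_seed, gi, di, ci, k, 2)
                        mu = _puncta_mean(gp, day - day0, ca)
                        n_puncta = int(np.random.default_rng(cb_seed).poisson(mu))
                        cb_id = f"{image_id}-callose"
                        cb_rec, cb_truth = make_callose_image(
                            n_puncta=n_puncta,
                            size=spec.callose_image_size,
                            pixel_size_um=spec.callose_pixel_size_um,
                            seed=_child_seed(spec.master_seed, gi, di, ci, k, 3),
                            image_id=cb_id,
                            metadata={
                                "genotype": genotype,
                                "day": day,
                                "ca_mM": ca,
                                "experiment": experiment,
                            },
                        )
                        callose_images.append((cb_rec, cb_truth))
    sheet = pd.DataFrame(rows)
    cohort = Cohort(sheet=sheet, leaf_images=leaf_images, callose_images=callose_images)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: Cohort, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec, truth in [*cohort.leaf_images, *cohort.callose_images]:
        write_image(rec.pixels, out_dir / f"{rec.image_id}.tif")
        with open(out_dir / f"{rec.image_id}.truth.json", "w") as fh:
            json.dump(truth.summary(), fh, indent=1)
    cohort.sheet.to_csv(out_dir / "samples.csv", index=False)
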