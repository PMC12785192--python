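"""End-to-end per-cohort quantification built on the stage modules.

Turns a set of loaded images into the tidy per-cotyledon measurement
table (one row per image: dead-area responses plus, when available, the
ellipse fit and normalized largest-spot position) that feeds the
statistics layer. QC-excluded images are dropped here, before any
statistic is computed.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import pandas as pd

from . import callose as cq
from . import morphometry, necrosis
from .image_io import ImageRecord
from .necrosis import DEFAULT_MIN_AREA, DEFAULT_SPOT_FLOOR, DEFAULT_STAIN_BOX, HSBThreshold

__all__ = ["quantify_necrosis_cohort", "quantify_callose_cohort"]

logger = logging.getLogger(__name__)

_META = ("genotype", "day", "ca_mM", "experiment")


def quantify_necrosis_cohort(
    images: Iterable[ImageRecord],
    thr: HSBThreshold = DEFAULT_STAIN_BOX,
    min_area: int = DEFAULT_MIN_AREA,
    spot_floor: int = DEFAULT_SPOT_FLOOR,
    connectivity: int = 8,
    positions: bool = True,
    x_norm: str = "minor",
    masks: Optional[dict] = None,
) -> pd.DataFrame:
    """Per-image dead-area (and optionally lesion-position) table.

    With ``positions=True`` each image with a largest spot is also
    segmented (``masks[image_id]`` if supplied, else automatically),
    ellipse-fitted, and the spot centroid expressed in normalized
    coordinates; images without a qualifying spot keep NaN positions.
    Segmentation failures are flagged, not fatal.
    """
    rows = []
    for img in images:
        if img.qc_excluded:
            logger.info("skipping %s (qc: %s)", img.image_id, img.qc_reason)
            continue
        meas, _ = necrosis.measure_necrosis(
            img, thr=thr, min_area=min_area, spot_floor=spot_floor,
            connectivity=connectivity,
        )
        row = {
            "image_id": img.image_id,
            **{k: getattr(img, k) for k in _META},
            "total_dead_area_px": meas.total_dead_area_px,
            "largest_spot_area_px": meas.largest_spot_area_px,
            "a_px": None,
            "b_px": None,
            "angle_deg": None,
            "x_rel": None,
            "y_rel": None,
            "flags": "",
        }
        if positions and meas.has_spot:
            try:
                if masks is not None and img.image_id in masks:
                    mask = morphometry.segment_cotyledon(
                        img, mode="provided", mask=masks[img.image_id]
                    )
                else:
                    mask = morphometry.segment_cotyledon(img, mode="auto")
                fit = morphometry.fit_ellipse_moments(mask)
                pos = morphometry.lesion_position(
                    meas.largest_spot_centroid, fit, x_norm=x_norm
                )
                row.update(
                    a_px=fit.a, b_px=fit.b, angle_deg=fit.angle_deg,
                    x_rel=pos.x_rel, y_rel=pos.y_rel,
                )
                flags = []
                if fit.circular:
                    flags.append("circular")
                if pos.tilt_exceeded:
                    flags.append("tilt>45")
                row["flags"] = ";".join(flags)
            except (morphometry.SegmentationError, ValueError) as exc:
                logger.warning("position skipped for %s: %s", img.image_id, exc)
                row["flags"] = "segmentation_failed"
        rows.append(row)
    table = pd.DataFrame(rows)
    for col in ("largest_spot_area_px", "a_px", "b_px", "angle_deg", "x_rel", "y_rel"):
        if col in table:
            table[col] = pd.to_numeric(table[col])
    return table


def quantify_callose_cohort(
    images: Iterable[ImageRecord],
    thr: cq.PunctaThreshold,
    min_area: int = cq.DEFAULT_MIN_AREA,
) -> pd.DataFrame:
    """Per-image callose puncta count and density table."""
    rows = []
    for img in images:
        if img.qc_excluded:
            logger.info("skipping %s (qc: %s)", img.image_id, img.qc_reason)
            continue
        meas = cq.count_puncta(img, thr, min_area=min_area)
        rows.append(
            {
                "image_id": img.image_id,
                **{k: getattr(img, k) for k in _META},
                "spot_count": meas.spot_count,
                "density_per_mm2": meas.density_per_mm2,
            }
        )
    return pd.DataFrame(rows)
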