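"""Image and table I/O for the cotyledon quantification pipeline.

Reads single-cotyledon micrographs (TIFF/PNG/JPEG) together with a CSV
sample sheet carrying per-image metadata (genotype, day of growth, Ca
concentration, experiment replicate, pixel size), and writes the per-spot
and per-image result tables consumed by the downstream statistics.

Conventions
-----------
* Pixel coordinates are 0-based; ``x`` is the column index (rightward),
  ``y`` is the row index (downward).
* Color images keep channel order red, green, blue (8-bit per channel).
* Pixel size is carried per image in micrometers per pixel; necrosis
  areas are reported in pixels, callose densities in counts per mm².
* One cotyledon per image: images are assumed pre-cropped and pre-rotated
  so that the cotyledon base (petiole side) faces the bottom edge.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "ImageRecord",
    "SAMPLE_SHEET_COLUMNS",
    "read_sample_sheet",
    "load_image",
    "write_image",
    "write_spot_table",
    "write_cohort_tables",
]


class ConfigurationError(ValueError):
    """Missing or inconsistent metadata / configuration."""


#: Required header of the sample sheet CSV.
SAMPLE_SHEET_COLUMNS = (
    "path",
    "image_id",
    "genotype",
    "day",
    "ca_mM",
    "experiment",
    "pixel_size_um",
    "qc_excluded",
    "qc_reason",
)


@dataclasses.dataclass
class ImageRecord:
    """One micrograph plus its sample-sheet metadata.

    ``pixels`` is either an ``(H, W, 3)`` uint8 RGB array (bright-field
    trypan-blue images) or an ``(H, W)`` uint8/uint16 array (confocal
    aniline-blue fluorescence). Images flagged ``qc_excluded`` (e.g. a
    mounting bubble over the cotyledon) are carried through loading but
    never enter cohort statistics.
    """

    image_id: str
    pixels: np.ndarray
    pixel_size_um: Optional[float] = None
    genotype: Optional[str] = None
    day: Optional[int] = None
    ca_mM: Optional[float] = None
    experiment: Optional[str] = None
    qc_excluded: bool = False
    qc_reason: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.size == 0:
            raise ValueError(f"image {self.image_id!r}: empty pixel grid")
        if px.ndim == 3:
            if px.shape[2] != 3:
                raise ValueError(
                    f"image {self.image_id!r}: color images must have 3 "
                    f"channels (RGB), got shape {px.shape}"
                )
            if px.dtype != np.uint8:
                raise ValueError(
                    f"image {self.image_id!r}: color images must be 8-bit "
                    f"per channel, got dtype {px.dtype}"
                )
        elif px.ndim == 2:
            if px.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
                raise ValueError(
                    f"image {self.image_id!r}: grayscale images must be "
                    f"uint8 or uint16, got dtype {px.dtype}"
                )
        else:
            raise ValueError(
                f"image {self.image_id!r}: expected a 2-D grayscale or "
                f"(H, W, 3) RGB grid, got shape {px.shape}"
            )
        if self.pixel_size_um is not None and not self.pixel_size_um > 0:
            raise ValueError(
                f"image {self.image_id!r}: pixel_size_um must be positive"
            )
        self.pixels = px

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def shape(self) -> tuple:
        return self.pixels.shape[:2]


def read_sample_sheet(path: Union[str, os.PathLike]) -> pd.DataFrame:
    """Read and validate a sample sheet CSV.

    Relative ``path`` entries are resolved against the sheet's directory.
    Every non-excluded row must carry complete (genotype, day, ca_mM,
    experiment) metadata; ``pixel_size_um`` may be blank for
    necrosis-only analyses.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"sample sheet not found: {path}")
    sheet = pd.read_csv(path, dtype={"image_id": str, "qc_reason": str})
    missing = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ConfigurationError(
            f"sample sheet {path} lacks columns: {sorted(missing)}"
        )
    sheet = sheet.copy()
    sheet["qc_excluded"] = _as_bool(sheet["qc_excluded"])
    sheet["qc_reason"] = sheet["qc_reason"].fillna("")
    base = path.parent

    def _resolve(p: str) -> str:
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    sheet["path"] = sheet["path"].astype(str).map(_resolve)
    active = sheet[~sheet["qc_excluded"]]
    for col in ("genotype", "day", "ca_mM", "experiment"):
        if active[col].isna().any():
            bad = active.loc[active[col].isna(), "image_id"].tolist()
            raise ConfigurationError(
                f"sample sheet {path}: column {col!r} missing for "
                f"non-excluded images {bad}"
            )
    unresolved = [p for p in active["path"] if not Path(p).exists()]
    if unresolved:
        raise IOError(f"sample sheet {path}: unresolvable image paths {unresolved}")
    return sheet


def _as_bool(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col
    mapping = {
        "true": True, "1": True, "yes": True,
        "false": False, "0": False, "no": False, "": False, "nan": False,
    }
    return col.astype(str).str.strip().str.lower().map(mapping).fillna(False).astype(bool)


def load_image(path: Union[str, os.PathLike], sheet_row: Mapping) -> ImageRecord:
    """Load one raster image and attach its sample-sheet metadata.

    RGBA input is accepted and its alpha channel dropped; palette images
    are expanded by the reader. Raises ``IOError`` naming the path on an
    unreadable file and ``ConfigurationError`` on incomplete metadata.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        px = np.asarray(iio.imread(path))
    except Exception as exc:  # noqa: BLE001 - reader errors vary by plugin
        raise IOError(f"cannot decode image {path}: {exc}") from exc
    if px.ndim == 3 and px.shape[2] == 4:
        px = px[:, :, :3]
    row = dict(sheet_row)
    for key in ("image_id",):
        if key not in row or pd.isna(row[key]):
            raise ConfigurationError(f"metadata row for {path} lacks {key!r}")
    qc_excluded = bool(row.get("qc_excluded", False))
    if not qc_excluded:
        for key in ("genotype", "day", "ca_mM", "experiment"):
            if key not in row or pd.isna(row[key]):
                raise ConfigurationError(
                    f"metadata row for image {row.get('image_id')} lacks {key!r}"
                )
    pixel_size = row.get("pixel_size_um")
    if pixel_size is not None and (pd.isna(pixel_size) or pixel_size == ""):
        pixel_size = None
    return ImageRecord(
        image_id=str(row["image_id"]),
        pixels=px,
        pixel_size_um=float(pixel_size) if pixel_size is not None else None,
        genotype=None if pd.isna(row.get("genotype")) else str(row.get("genotype")),
        day=None if pd.isna(row.get("day")) else int(row.get("day")),
        ca_mM=None if pd.isna(row.get("ca_mM")) else float(row.get("ca_mM")),
        experiment=None if pd.isna(row.get("experiment")) else str(row.get("experiment")),
        qc_excluded=qc_excluded,
        qc_reason=str(row.get("qc_reason", "") or ""),
    )


def write_image(pixels: np.ndarray, path: Union[str, os.PathLike]) -> None:
    """Write an image array losslessly (TIFF or PNG; 8-bit round-trip safe)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".jpg", ".jpeg"):
        raise ValueError("JPEG is lossy; write TIFF or PNG for quantitative images")
    try:
        iio.imwrite(path, np.asarray(pixels))
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot write image {path}: {exc}") from exc


def write_spot_table(regions, destination: Union[str, os.PathLike], image_id: str) -> None:
    """Write the per-spot and per-image summary CSVs for one image.

    ``destination`` is a directory; it receives ``spots.csv`` (one row per
    retained component: image_id, area_px, centroid_x_px, centroid_y_px)
    and ``summary.csv`` (one row per image: image_id, n_spots,
    total_area_px).
    """
    write_cohort_tables([(image_id, regions)], destination)


def write_cohort_tables(
    items: Iterable[tuple], destination: Union[str, os.PathLike]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write spots.csv and summary.csv for many (image_id, LabeledRegions).

    Returns the two frames. The summary ``total_area_px`` is the sum of
    the per-spot areas of that image (conservation, asserted here).
    """
    destination = Path(destination)
    try:
        destination.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {destination}: {exc}") from exc
    spot_rows = []
    summary_rows = []
    for image_id, regions in items:
        frame = regions.to_frame()
        for rec in frame.itertuples(index=False):
            spot_rows.append(
                {
                    "image_id": image_id,
                    "area_px": int(rec.area_px),
                    "centroid_x_px": float(rec.centroid_x),
                    "centroid_y_px": float(rec.centroid_y),
                }
            )
        total = int(frame["area_px"].sum()) if len(frame) else 0
        summary_rows.append(
            {"image_id": image_id, "n_spots": int(len(frame)), "total_area_px": total}
        )
    spots = pd.DataFrame(
        spot_rows, columns=["image_id", "area_px", "centroid_x_px", "centroid_y_px"]
    )
    summary = pd.DataFrame(summary_rows, columns=["image_id", "n_spots", "total_area_px"])
    if len(spots):
        check = spots.groupby("image_id")["area_px"].sum()
        merged = summary.set_index("image_id")["total_area_px"]
        assert all(check[i] == merged[i] for i in check.index)
    try:
        spots.to_csv(destination / "spots.csv", index=False)
        summary.to_csv(destination / "summary.csv", index=False)
    except OSError as exc:
        raise IOError(f"cannot write tables under {destination}: {exc}") from exc
    return spots, summary
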