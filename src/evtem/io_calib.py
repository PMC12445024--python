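"""Image input, physical calibration and the particle-table CSV dialect.

Negative-stain TEM images carry no physical scale in their pixel data, so
every frame is paired with an explicit nm-per-pixel calibration supplied by
the user (flag, config file, or a user-editable magnification table).
Particle measurements are exchanged as a fixed CSV schema shared by all
modules; values are stored rounded (2 decimals for nm and nm^2, 4 for
circularity) while in-memory computation keeps full precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import imageio.v3 as iio

logger = logging.getLogger(__name__)

#: Recognised raster extensions (lower case), in read support order.
IMAGE_EXTENSIONS = (".tif", ".tiff", ".png")

#: Exact column contract of the particle CSV, in order.
CSV_COLUMNS = (
    "image",
    "particle_id",
    "x_px",
    "y_px",
    "x_nm",
    "y_nm",
    "area_nm2",
    "major_nm",
    "minor_nm",
    "angle_deg",
    "d_linear_nm",
    "d_area_nm",
    "circularity",
    "cup_shaped",
)

#: Convenience magnification -> nm/px lookup for a generic 4k CCD with
#: ~15 um pixel pitch.  Detector pitch varies between instruments, so this
#: table is a starting point the user is expected to edit or override.
MAGNIFICATION_TABLE = {
    30000: 0.50,
    50000: 0.30,
}


@dataclass(frozen=True)
class CalibrationInfo:
    """Physical pixel size and where it came from.

    origin is one of ``"flag"``, ``"config"``, ``"magnification-table"``.
    """

    nm_per_px: float
    origin: str = "flag"

    def __post_init__(self) -> None:
        if not self.nm_per_px > 0:
            raise ValueError(f"nm_per_px must be > 0, got {self.nm_per_px}")


@dataclass
class ImageFrame:
    """A calibrated single-channel TEM raster.

    pixels is a 2-D non-negative intensity array (uint8, uint16 or float),
    nm_per_px the physical size of one pixel edge, source a file identifier.
    """

    pixels: np.ndarray
    nm_per_px: float
    source: str = ""
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ValueError(
                f"pixels must be 2-D with >= 2 rows and columns, got shape "
                f"{self.pixels.shape}"
            )
        if not self.nm_per_px > 0:
            raise ValueError(f"nm_per_px must be > 0, got {self.nm_per_px}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def intensity_range(self) -> float:
        """Full-scale intensity for this bit depth."""
        return float(2**self.bit_depth - 1)


def calibration_from_magnification(magnification: int) -> CalibrationInfo:
    """Look up nm/px for a nominal magnification in the built-in table."""
    try:
        nm = MAGNIFICATION_TABLE[int(magnification)]
    except KeyError:
        known = sorted(MAGNIFICATION_TABLE)
        raise KeyError(
            f"magnification {magnification} not in table (known: {known}); "
            "supply nm_per_px explicitly"
        ) from None
    return CalibrationInfo(nm_per_px=nm, origin="magnification-table")


def read_image(path: str | Path, calibration: CalibrationInfo) -> ImageFrame:
    """Read a grayscale TIFF/PNG and attach the calibration.

    RGB(A) inputs whose colour channels are identical are collapsed to a
    single channel; genuinely multi-channel images are rejected.  Intensity
    values are passed through unmodified.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # truncated / undecodable file
        raise IOError(f"cannot read image file {path}: {exc}") from exc

    if arr.ndim == 3:
        # drop an opaque alpha channel, then require gray-as-RGB
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        elif np.array_equal(arr[:, :, 0], arr[:, :, 1]) and np.array_equal(
            arr[:, :, 0], arr[:, :, 2]
        ):
            arr = arr[:, :, 0]
        else:
            raise ValueError(
                f"{path} is a multi-channel colour image; expected grayscale"
            )
    elif arr.ndim != 2:
        raise ValueError(f"{path}: unsupported image dimensionality {arr.ndim}")

    if arr.dtype == np.uint16:
        bit_depth = 16
    else:
        bit_depth = 8
    return ImageFrame(
        pixels=arr,
        nm_per_px=calibration.nm_per_px,
        source=str(path),
        bit_depth=bit_depth,
    )


def list_images(folder: str | Path) -> list[Path]:
    """Lexicographically sorted top-level image files in *folder*.

    Only files with recognised extensions are returned; subfolders are not
    descended into.  An empty folder yields an empty list.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise IOError(f"image folder does not exist: {folder}")
    hits = [
        p
        for p in folder.iterdir()
        if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
    ]
    return sorted(hits, key=lambda p: p.name)


def particle_table_to_dataframe(table) -> pd.DataFrame:
    """Rounded, schema-ordered DataFrame view of a ParticleTable."""
    rows = []
    for rec in table.records:
        e = rec.ellipse
        rows.append(
            {
                "image": rec.source_image,
                "particle_id": int(rec.particle_id),
                "x_px": round(float(e.center_px[0]), 2),
                "y_px": round(float(e.center_px[1]), 2),
                "x_nm": round(float(e.center_nm[0]), 2),
                "y_nm": round(float(e.center_nm[1]), 2),
                "area_nm2": round(float(rec.area_nm2), 2),
                "major_nm": round(float(e.major_nm), 2),
                "minor_nm": round(float(e.minor_nm), 2),
                "angle_deg": round(float(e.angle_deg), 2),
                "d_linear_nm": round(float(rec.d_linear_nm), 2),
                "d_area_nm": round(float(rec.d_area_nm), 2),
                "circularity": round(float(rec.circularity), 4),
                "cup_shaped": int(bool(rec.cup_shaped)),
            }
        )
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def write_particle_csv(table, path: str | Path) -> Path:
    """Write a ParticleTable to the fixed CSV schema (UTF-8, LF, '.' decimal)."""
    path = Path(path)
    df = particle_table_to_dataframe(table)
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            df.to_csv(fh, index=False, lineterminator="\n")
    except OSError as exc:
        raise IOError(f"cannot write particle CSV {path}: {exc}") from exc
    return path


def read_particle_csv(path: str | Path):
    """Read a particle CSV back into a ParticleTable.

    Unknown extra columns are ignored with a logged warning; a missing
    mandatory column is a format error naming that column.  Records read
    from CSV carry no pixel masks.
    """
    from .detect import EllipseFit, ParticleRecord, ParticleTable

    path = Path(path)
    if not path.exists():
        raise IOError(f"particle CSV does not exist: {path}")
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"particle CSV {path} is missing mandatory column(s): "
            + ", ".join(missing)
        )
    extra = [c for c in df.columns if c not in CSV_COLUMNS]
    if extra:
        logger.warning(
            "particle CSV %s: ignoring unknown column(s) %s", path, extra
        )

    records = []
    for _, row in df.iterrows():
        area = float(row["area_nm2"])
        ellipse = EllipseFit(
            center_px=(float(row["x_px"]), float(row["y_px"])),
            center_nm=(float(row["x_nm"]), float(row["y_nm"])),
            major_nm=float(row["major_nm"]),
            minor_nm=float(row["minor_nm"]),
            angle_deg=float(row["angle_deg"]),
            area_nm2=area,
        )
        records.append(
            ParticleRecord(
                particle_id=int(row["particle_id"]),
                source_image=str(row["image"]),
                mask=None,
                ellipse=ellipse,
                area_nm2=area,
                d_linear_nm=float(row["d_linear_nm"]),
                d_area_nm=float(row["d_area_nm"]),
                circularity=float(row["circularity"]),
                cup_shaped=bool(int(row["cup_shaped"])),
            )
        )
    return ParticleTable(records=records)
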