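"""Maxima-seeded particle detection for negative-stain TEM images.

The pipeline mirrors the classic semi-automated workflow: seed candidate
particles at local intensity maxima whose prominence over their surrounding
saddle exceeds a noise tolerance (the h-maxima transform), grow each seed to
the connected level set at ``background + seg_fraction * (peak -
background)``, split contested pixels with a marker-controlled watershed,
filter the regions by physical size and circularity, and summarise each
survivor as an area-preserving moment ellipse plus both diameter estimates.

Because maxima-seeded segmentation claims only pixels bright enough to
belong to the peak, the darker outer rim of a stained vesicle is never part
of the detected region; detected diameters therefore systematically
underestimate true outer diameters.  That bias is a property of the method,
not a bug, and the stats module quantifies it.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian
from skimage.morphology import local_maxima, reconstruction
from skimage.segmentation import watershed

from . import measure
from .io_calib import (
    CalibrationInfo,
    ImageFrame,
    list_images,
    particle_table_to_dataframe,
    read_image,
    write_particle_csv,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionConfig",
    "EllipseFit",
    "ParticleRecord",
    "ParticleTable",
    "find_maxima",
    "segment_from_maxima",
    "filter_regions",
    "fit_ellipse",
    "detect_particles",
    "process_folder",
]


@dataclass(frozen=True)
class DetectionConfig:
    """All tunables of the detection pipeline.

    noise_tolerance is in the image's intensity units (defaults assume
    8-bit); size bounds are physical (nm^2) and converted to pixels with
    the frame's calibration; seg_fraction sets the level at which a seed's
    region is delimited, as a fraction of (peak - background) above the
    background (image median).
    """

    noise_tolerance: float = 30.0
    min_size_nm2: float = 75.0
    max_size_nm2: float = 7850.0
    min_circularity: float = 0.6
    seg_fraction: float = 0.5
    invert: bool = False
    exclude_border: bool = True
    gaussian_sigma: float = 0.0  # optional pre-blur, off by default
    cup_depth_threshold: float = measure.CUP_DEPTH_THRESHOLD

    def __post_init__(self) -> None:
        if self.noise_tolerance < 0:
            raise ValueError("noise_tolerance must be >= 0")
        if not self.min_size_nm2 < self.max_size_nm2:
            raise ValueError("min_size_nm2 must be < max_size_nm2")
        if not 0 <= self.min_circularity <= 1:
            raise ValueError("min_circularity must be in [0, 1]")
        if not 0 < self.seg_fraction < 1:
            raise ValueError("seg_fraction must be in (0, 1)")


@dataclass(frozen=True)
class EllipseFit:
    """Area-preserving moment ellipse of a region.

    Axes are full lengths in nm; angle_deg is the major-axis orientation in
    [0, 180), measured from the +x (column) axis toward +y (row).  By
    construction pi*(major/2)*(minor/2) equals the region area.
    """

    center_px: tuple[float, float]  # (x, y) = (col, row)
    center_nm: tuple[float, float]
    major_nm: float
    minor_nm: float
    angle_deg: float
    area_nm2: float


@dataclass
class ParticleRecord:
    """One detected particle with its region, ellipse and measurements."""

    particle_id: int
    source_image: str
    mask: np.ndarray | None  # (n, 2) array of (row, col) pixel indices
    ellipse: EllipseFit
    area_nm2: float
    d_linear_nm: float
    d_area_nm: float
    circularity: float
    cup_shaped: bool = False
    cup_score: float = 0.0


@dataclass
class ParticleTable:
    """Ordered particle records for one image or one pooled group."""

    records: list[ParticleRecord] = field(default_factory=list)
    group_label: str = ""
    nm_per_px: float = 1.0

    def __len__(self) -> int:
        return len(self.records)

    def diameters(self, kind: str = "d_area") -> np.ndarray:
        attr = {"d_area": "d_area_nm", "d_linear": "d_linear_nm"}[kind]
        return np.array([getattr(r, attr) for r in self.records], dtype=float)

    def to_dataframe(self):
        return particle_table_to_dataframe(self)


def _working_image(frame: ImageFrame, invert: bool, sigma: float = 0.0) -> np.ndarray:
    img = np.asarray(frame.pixels, dtype=float)
    if sigma > 0:
        img = gaussian(img, sigma=sigma, preserve_range=True)
    if invert:
        img = -img
    return img


def find_maxima(
    frame: ImageFrame, noise_tolerance: float, invert: bool = False
) -> list[tuple[int, int]]:
    """Seed coordinates at prominent intensity maxima.

    A maximum qualifies when its prominence over the surrounding saddle
    exceeds *noise_tolerance* (h-maxima transform).  A plateau of equal
    peak values contributes exactly one seed at the plateau centroid
    (snapped to the nearest plateau pixel).  Seeds are returned as (row,
    col), sorted by descending peak intensity with (row, col) tie-breaks.
    """
    if noise_tolerance < 0:
        raise ValueError("noise_tolerance must be >= 0")
    img = _working_image(frame, invert)
    if img.max() == img.min():
        return []
    h = noise_tolerance if noise_tolerance > 0 else 1e-9
    # reconstruction clips every maximum of prominence < h into its
    # surroundings; each surviving maximum becomes one flat dome-top
    # plateau of the reconstructed surface, i.e. exactly one seed per
    # noise-tolerant maximum however ragged its top is
    rec = reconstruction(img - h, img, method="dilation")
    peaks = local_maxima(rec, connectivity=2)
    labels, n = ndimage.label(peaks, structure=np.ones((3, 3), int))
    seeds: list[tuple[float, int, int]] = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        vals = img[coords[:, 0], coords[:, 1]]
        peak_val = vals.max()
        plateau = coords[vals == peak_val]
        centroid = plateau.mean(axis=0)
        # snap to nearest plateau pixel, ties broken by (row, col)
        d2 = ((plateau - centroid) ** 2).sum(axis=1)
        order = np.lexsort((plateau[:, 1], plateau[:, 0], d2))
        r, c = plateau[order[0]]
        seeds.append((-float(peak_val), int(r), int(c)))
    seeds.sort()
    return [(r, c) for _, r, c in seeds]


def segment_from_maxima(
    frame: ImageFrame,
    seeds: list[tuple[int, int]],
    config: DetectionConfig,
) -> np.ndarray:
    """Label raster growing each seed to its level-set region.

    Each seed claims the connected pixel set with intensity at or above
    ``background + seg_fraction * (peak - background)`` (background = image
    median); pixels reachable from two seeds are divided by a watershed of
    the intensity surface, leaving a one-pixel boundary line.  Labels are
    positive integers in seed order; unclaimed pixels are 0.
    """
    img = _working_image(frame, config.invert, config.gaussian_sigma)
    h, w = img.shape
    labels = np.zeros((h, w), dtype=np.int32)
    if not seeds:
        return labels
    markers = np.zeros((h, w), dtype=np.int32)
    for i, (r, c) in enumerate(seeds, start=1):
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"seed ({r}, {c}) lies outside the frame")
        markers[r, c] = i
    background = float(np.median(img))
    basins = watershed(-img, markers=markers, watershed_line=True)
    struct = np.ones((3, 3), int)
    for i, (r, c) in enumerate(seeds, start=1):
        peak = img[r, c]
        level = background + config.seg_fraction * (peak - background)
        cand = (basins == i) & (img >= level)
        comp, _ = ndimage.label(cand, structure=struct)
        lab_at_seed = comp[r, c]
        if lab_at_seed == 0:
            continue
        # fill interior holes: a cup particle's dark depression sits below
        # the level but belongs to the particle's projected outline; the
        # fill stays inside the seed's own basin so a background-plateau
        # seed (whose "holes" are the particles) cannot claim foreign pixels
        region = ndimage.binary_fill_holes(comp == lab_at_seed) & (basins == i)
        labels[region] = i
    return labels


def filter_regions(
    labels: np.ndarray, frame: ImageFrame, config: DetectionConfig
) -> list[int]:
    """Labels surviving the size, circularity and border filters.

    Bounds are inclusive; with exclude_border, any region touching the
    image edge is dropped (partial particles bias sizes low).
    """
    px_area = frame.nm_per_px**2
    retained = []
    border = set()
    if config.exclude_border:
        for edge in (labels[0], labels[-1], labels[:, 0], labels[:, -1]):
            border.update(np.unique(edge).tolist())
    for lab in np.unique(labels):
        if lab == 0 or lab in border:
            continue
        coords = np.argwhere(labels == lab)
        area_nm2 = len(coords) * px_area
        if not config.min_size_nm2 <= area_nm2 <= config.max_size_nm2:
            continue
        if len(coords) >= 3:
            circ = measure.circularity(coords)
        else:
            circ = 0.0
        if circ < config.min_circularity:
            continue
        retained.append(int(lab))
    return retained


def fit_ellipse(coords: np.ndarray, nm_per_px: float) -> EllipseFit:
    """Moment ellipse of a pixel region, rescaled to preserve its area.

    Semi-axes come from the eigenvalues of the second central moments
    (2*sqrt(lambda), the solid-ellipse relation) and are then scaled so the
    ellipse area equals the pixel area exactly.  The center is the plain
    (intensity-agnostic) centroid.  Degenerate collinear regions get a
    one-pixel minor-axis floor with a warning.
    """
    coords = np.asarray(coords)
    n = len(coords)
    if n < 3:
        raise ValueError("ellipse fit needs a region of >= 3 pixels")
    cy, cx = coords.mean(axis=0)
    d = coords - (cy, cx)
    # covariance in (x, y) order: x = col, y = row
    mu20 = float((d[:, 1] ** 2).mean())
    mu02 = float((d[:, 0] ** 2).mean())
    mu11 = float((d[:, 1] * d[:, 0]).mean())
    common = math.sqrt(max((mu20 - mu02) ** 2 / 4.0 + mu11**2, 0.0))
    lam1 = (mu20 + mu02) / 2.0 + common
    lam2 = (mu20 + mu02) / 2.0 - common
    semi_major = 2.0 * math.sqrt(max(lam1, 0.0))
    semi_minor = 2.0 * math.sqrt(max(lam2, 0.0))
    if semi_minor < 0.5:
        warnings.warn("degenerate (collinear) region; flooring minor axis at 1 px")
        semi_minor = 0.5
        semi_major = max(semi_major, n / (math.pi * semi_minor))
    else:
        scale = math.sqrt(n / (math.pi * semi_major * semi_minor))
        semi_major *= scale
        semi_minor *= scale
    angle = math.degrees(0.5 * math.atan2(2.0 * mu11, mu20 - mu02)) % 180.0
    area_nm2 = n * nm_per_px**2
    return EllipseFit(
        center_px=(cx, cy),
        center_nm=(cx * nm_per_px, cy * nm_per_px),
        major_nm=2.0 * semi_major * nm_per_px,
        minor_nm=2.0 * semi_minor * nm_per_px,
        angle_deg=angle,
        area_nm2=area_nm2,
    )


def detect_particles(frame: ImageFrame, config: DetectionConfig) -> ParticleTable:
    """Full pipeline: seeds -> regions -> filters -> ellipses -> measures.

    Regions come out of segmentation hole-filled, so a particle with a dark
    interior depression (cup morphology) is measured over its full
    projected outline, not an annulus.  Deterministic for fixed inputs.
    """
    seeds = find_maxima(frame, config.noise_tolerance, config.invert)
    labels = segment_from_maxima(frame, seeds, config)
    retained = filter_regions(labels, frame, config)
    records: list[ParticleRecord] = []
    pid = 0
    for lab in retained:
        coords = np.argwhere(labels == lab)
        pid += 1
        ellipse = fit_ellipse(coords, frame.nm_per_px)
        area_nm2 = ellipse.area_nm2
        rec = ParticleRecord(
            particle_id=pid,
            source_image=frame.source,
            mask=coords,
            ellipse=ellipse,
            area_nm2=area_nm2,
            d_linear_nm=measure.linear_diameter(coords, frame.nm_per_px),
            d_area_nm=measure.area_diameter(area_nm2),
            circularity=measure.circularity(coords),
        )
        rec.cup_score, rec.cup_shaped = measure.cup_shape_score(
            frame, rec, config.cup_depth_threshold
        )
        records.append(rec)
    return ParticleTable(records=records, nm_per_px=frame.nm_per_px)


def process_folder(
    folder: str | Path,
    config: DetectionConfig,
    out: str | Path,
    calibration: CalibrationInfo,
    group_label: str = "",
) -> ParticleTable:
    """Detect particles in every image of *folder* and write CSV outputs.

    Writes one CSV per readable image, a concatenated ``combined.csv``, and
    a ``run_log.json`` recording the configuration and per-image counts.
    Unreadable images are logged and skipped; a folder with no readable
    image is an error.  Returns the combined table.
    """
    folder = Path(folder)
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    paths = list_images(folder)
    combined = ParticleTable(group_label=group_label, nm_per_px=calibration.nm_per_px)
    per_image: dict[str, int] = {}
    skipped: list[str] = []
    for p in paths:
        try:
            frame = read_image(p, calibration)
        except Exception as exc:
            logger.warning("skipping unreadable image %s: %s", p, exc)
            skipped.append(p.name)
            continue
        frame.source = p.name
        table = detect_particles(frame, config)
        write_particle_csv(table, out / (p.stem + ".csv"))
        per_image[p.name] = len(table)
        combined.records.extend(table.records)
    if not per_image:
        raise IOError(f"no readable images in {folder}")
    write_particle_csv(combined, out / "combined.csv")
    log = {
        "config": {
            k: getattr(config, k)
            for k in (
                "noise_tolerance",
                "min_size_nm2",
                "max_size_nm2",
                "min_circularity",
                "seg_fraction",
                "invert",
                "exclude_border",
                "gaussian_sigma",
            )
        },
        "nm_per_px": calibration.nm_per_px,
        "n_images": len(per_image),
        "particles_per_image": per_image,
        "skipped": skipped,
    }
    with open(out / "run_log.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return combined
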