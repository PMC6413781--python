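"""Semiquantitative scoring of iris transillumination (TI) photographs.

In iris TI photography, light reflected off the retina shines back through
the iris; the more melanin the iris holds, the less red signal passes.
Given a hand-annotated circle model of the iris (center, iris radius,
pupil radius), the scorer

1. lays 16 sampling sites over the iris: the circle's bounding square is
   split through the center into 4 quadrant squares, each split again into
   4 equal sub-squares, and the sites are the sub-square centers —
   offsets of (+/-R/4 or +/-3R/4, +/-R/4 or +/-3R/4) from the center;
2. smooths the red channel locally (Gaussian blur restricted to the iris
   annulus, so neither the bright pupillary red reflex nor the dark
   background bleeds into iris pixels);
3. averages the smoothed red signal over each site's sampling disk
   intersected with the annulus (sites falling wholly inside the pupil or
   outside the iris are excluded and recorded);
4. maps the grand mean linearly to a 0–8 score: 8 * mean / 255, so 0 is
   no transmitted light and 8 a fully saturated red reflex.

Sampling disks default to radius 75 px at a reference iris radius
(matching a 150 px diameter marker on native-resolution photographs) and
scale proportionally with the annotated iris radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

#: iris radius (px) at which the sampling disk has its nominal 75 px radius
NATIVE_IRIS_RADIUS = 1000.0
NATIVE_DISK_RADIUS = 75.0
#: Gaussian blur standard deviation (px) at the native iris radius
NATIVE_BLUR_SIGMA = 25.0


class GeometryError(ValueError):
    """Iris circle model invalid or incompatible with the image."""


class ScoringError(ValueError):
    """Image cannot be scored (e.g. no valid sampling site)."""


@dataclass(frozen=True)
class IrisGeometry:
    """Annotated circle model of one TI photograph.

    Coordinates are 0-based pixel coordinates with x rightward and y
    downward; sub-pixel centers are allowed. A pixel belongs to a disk if
    its center does.
    """

    center_x: float
    center_y: float
    iris_radius: float
    pupil_radius: float

    def __post_init__(self) -> None:
        if not 0 < self.pupil_radius < self.iris_radius:
            raise GeometryError(
                f"require 0 < pupil_radius < iris_radius, got "
                f"pupil={self.pupil_radius}, iris={self.iris_radius}"
            )

    def check_bounds(self, height: int, width: int) -> None:
        r = self.iris_radius
        if (
            self.center_x - r < -0.5
            or self.center_y - r < -0.5
            or self.center_x + r > width - 0.5
            or self.center_y + r > height - 0.5
        ):
            raise GeometryError(
                f"iris circle (center=({self.center_x}, {self.center_y}), "
                f"R={r}) exceeds image bounds {width}x{height}"
            )


@dataclass(frozen=True)
class TIImage:
    """8-bit RGB TI photograph plus its geometry and identifiers."""

    pixels: np.ndarray
    geometry: IrisGeometry
    participant: str
    eye: str
    visit_month: int
    image_index: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.dtype != np.uint8:
            raise ValueError("pixels must be an HxWx3 uint8 array (RGB)")
        object.__setattr__(self, "pixels", px)
        self.geometry.check_bounds(px.shape[0], px.shape[1])


@dataclass(frozen=True)
class SamplingLayout:
    """The 16 nominal sampling sites and the excluded subset."""

    sites: np.ndarray  # (16, 2) array of (x, y)
    disk_radius: float
    excluded_sites: tuple[tuple[int, str], ...] = ()

    @property
    def retained_indices(self) -> list[int]:
        excluded = {i for i, _ in self.excluded_sites}
        return [i for i in range(len(self.sites)) if i not in excluded]


@dataclass(frozen=True)
class SemiquantScore:
    score: float
    per_site_red: tuple[float, ...]
    n_sites_used: int


def default_disk_radius(geometry: IrisGeometry, scale_reference: float = NATIVE_IRIS_RADIUS) -> float:
    return NATIVE_DISK_RADIUS * geometry.iris_radius / scale_reference


def default_blur_sigma(geometry: IrisGeometry, scale_reference: float = NATIVE_IRIS_RADIUS) -> float:
    return NATIVE_BLUR_SIGMA * geometry.iris_radius / scale_reference


def sampling_layout(
    geometry: IrisGeometry,
    scale_reference: float = NATIVE_IRIS_RADIUS,
    disk_radius: float | None = None,
) -> SamplingLayout:
    """Place the 16 quadrant-subdivision sampling sites.

    Sites sit at offsets (+/-R/4, +/-3R/4 in each axis) from the center,
    R the iris radius. A site is excluded when its sampling disk cannot
    overlap the iris annulus at all: wholly inside the pupil (inner sites
    with a large pupil) or wholly outside the iris circle (corner sites
    with a small disk).
    """
    r = geometry.iris_radius
    if disk_radius is None:
        disk_radius = default_disk_radius(geometry, scale_reference)
    offsets = np.array([-0.75 * r, -0.25 * r, 0.25 * r, 0.75 * r])
    sites = np.array(
        [(geometry.center_x + dx, geometry.center_y + dy) for dy in offsets for dx in offsets]
    )
    excluded: list[tuple[int, str]] = []
    for i, (x, y) in enumerate(sites):
        d = float(np.hypot(x - geometry.center_x, y - geometry.center_y))
        if d + disk_radius <= geometry.pupil_radius:
            excluded.append((i, "inside_pupil"))
        elif d - disk_radius >= geometry.iris_radius:
            excluded.append((i, "outside_iris"))
    return SamplingLayout(
        sites=sites, disk_radius=float(disk_radius), excluded_sites=tuple(excluded)
    )


def annulus_mask(geometry: IrisGeometry, height: int, width: int) -> np.ndarray:
    """Boolean mask of pixels whose centers lie in the iris annulus."""
    yy, xx = np.mgrid[0:height, 0:width]
    rr = np.hypot(xx - geometry.center_x, yy - geometry.center_y)
    return (rr > geometry.pupil_radius) & (rr <= geometry.iris_radius)


def _masked_gaussian(values: np.ndarray, mask: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blur confined to ``mask`` (normalized convolution).

    Pixels outside the mask contribute nothing, so the bright pupil and the
    dark background never leak into annulus values. For sigma == 0 the
    input is returned unchanged.
    """
    if sigma <= 0:
        return values.astype(float)
    weighted = ndimage.gaussian_filter(values * mask, sigma=sigma, mode="constant")
    norm = ndimage.gaussian_filter(mask.astype(float), sigma=sigma, mode="constant")
    out = np.zeros_like(weighted)
    np.divide(weighted, norm, out=out, where=norm > 1e-12)
    return out


def semiquant_score(
    image: TIImage,
    blur_sigma: float | None = None,
    disk_radius: float | None = None,
    scale_reference: float = NATIVE_IRIS_RADIUS,
    layout: SamplingLayout | None = None,
) -> SemiquantScore:
    """Score one TI image on the 0–8 semiquantitative scale.

    Raises
    ------
    ScoringError
        If every sampling site is excluded or empty after intersection
        with the annulus.
    """
    geom = image.geometry
    if layout is None:
        layout = sampling_layout(geom, scale_reference=scale_reference, disk_radius=disk_radius)
    if blur_sigma is None:
        blur_sigma = default_blur_sigma(geom, scale_reference)

    h, w = image.pixels.shape[:2]
    mask = annulus_mask(geom, h, w)
    red = image.pixels[:, :, 0].astype(float)
    blurred = _masked_gaussian(red, mask, blur_sigma)

    yy, xx = np.mgrid[0:h, 0:w]
    site_means: list[float] = []
    for i in layout.retained_indices:
        sx, sy = layout.sites[i]
        in_disk = np.hypot(xx - sx, yy - sy) <= layout.disk_radius
        sel = in_disk & mask
        if not sel.any():
            continue
        site_means.append(float(blurred[sel].mean()))
    if not site_means:
        raise ScoringError("no valid sampling sites")
    score = 8.0 * float(np.mean(site_means)) / 255.0
    return SemiquantScore(
        score=score, per_site_red=tuple(site_means), n_sites_used=len(site_means)
    )


def score_image_set(
    images: Sequence[TIImage],
    blur_sigma: float | None = None,
    disk_radius: float | None = None,
    scale_reference: float = NATIVE_IRIS_RADIUS,
) -> pd.DataFrame:
    """Per eye-visit mean of the available image scores.

    Returns one row per participant x eye x visit with the mean
    semiquantitative score and the number of images averaged.
    """
    seen: set[tuple] = set()
    rows = []
    for img in images:
        key = (img.participant, img.eye, img.visit_month, img.image_index)
        if key in seen:
            raise ValueError(f"duplicate image identifiers {key}")
        seen.add(key)
        res = semiquant_score(
            img, blur_sigma=blur_sigma, disk_radius=disk_radius,
            scale_reference=scale_reference,
        )
        rows.append(
            {
                "participant": img.participant,
                "eye": img.eye,
                "visit_month": img.visit_month,
                "image_index": img.image_index,
                "score": res.score,
                "n_sites_used": res.n_sites_used,
            }
        )
    per_image = pd.DataFrame(rows)
    out = (
        per_image.groupby(["participant", "eye", "visit_month"], sort=True)
        .agg(semiquant_score=("score", "mean"), n_images=("score", "size"))
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# File I/O

def load_ti_image(
    path: str | Path,
    geometry: IrisGeometry,
    participant: str,
    eye: str,
    visit_month: int,
    image_index: int,
) -> TIImage:
    """Load an 8-bit RGB PNG/TIFF as a TIImage."""
    px = iio.imread(path)
    if px.ndim == 3 and px.shape[2] == 4:
        px = px[:, :, :3]
    return TIImage(
        pixels=np.ascontiguousarray(px, dtype=np.uint8),
        geometry=geometry,
        participant=participant,
        eye=eye,
        visit_month=visit_month,
        image_index=image_index,
    )


def read_geometry_table(path: str | Path) -> pd.DataFrame:
    """Geometry sidecar: CSV or YAML list with filename + circle parameters."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            rows = yaml.safe_load(fh)
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path)
    required = {
        "filename", "participant", "eye", "visit_month", "image_index",
        "center_x", "center_y", "iris_radius", "pupil_radius",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"geometry table missing columns: {sorted(missing)}")
    return df


def load_image_set(image_dir: str | Path, geometry_table: pd.DataFrame) -> list[TIImage]:
    image_dir = Path(image_dir)
    images = []
    for _, row in geometry_table.iterrows():
        geom = IrisGeometry(
            center_x=float(row["center_x"]),
            center_y=float(row["center_y"]),
            iris_radius=float(row["iris_radius"]),
            pupil_radius=float(row["pupil_radius"]),
        )
        images.append(
            load_ti_image(
                image_dir / row["filename"], geom,
                participant=str(row["participant"]), eye=str(row["eye"]),
                visit_month=int(row["visit_month"]), image_index=int(row["image_index"]),
            )
        )
    return images
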