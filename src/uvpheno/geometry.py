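"""Spherical-coordinate geometry of PC score space and HSV "optical stains".

A pixel's 3-PC score vector (x, y, z) is re-expressed in spherical
coordinates: azimuth = atan2(y, x) in (-pi, pi], elevation =
atan2(z, hypot(x, y)) in [-pi/2, pi/2], radius = |(x, y, z)|.  The two
angles encode spectral *shape* (molecular composition); the radius is a
relative measure of concentration, i.e. how far the spectrum sits from the
pooled mean.  False-color renderings assign hue from one angle, value from
the radius, and fix saturation at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.color import hsv2rgb

__all__ = [
    "SphericalField",
    "StainScheme",
    "SCHEMES",
    "to_spherical",
    "render_stain",
    "write_stain",
    "angle_histogram",
    "AngleHistogram2D",
]


@dataclass
class SphericalField:
    """Per-pixel spherical coordinates of a PC-triplet projection.

    Angles are radians; invalid pixels are NaN.  Azimuth is 0 by convention
    at the poles and at the origin (atan2(0, 0) = 0), making the conversion
    a total function.
    """

    azimuth: np.ndarray
    elevation: np.ndarray
    radius: np.ndarray
    triplet: tuple[int, int, int]
    validity: np.ndarray

    def to_cartesian(self) -> np.ndarray:
        """Inverse map back to H x W x 3 scores (round-trip identity)."""
        x = self.radius * np.cos(self.elevation) * np.cos(self.azimuth)
        y = self.radius * np.cos(self.elevation) * np.sin(self.azimuth)
        z = self.radius * np.sin(self.elevation)
        return np.stack([x, y, z], axis=-1)


def to_spherical(proj) -> SphericalField:
    """Convert a :class:`~uvpheno.pca.ProjectionField` to spherical coordinates."""
    scores = proj.data
    if scores.shape[-1] != 3:
        raise ValueError("projection must have exactly 3 channels")
    x, y, z = scores[..., 0], scores[..., 1], scores[..., 2]
    with np.errstate(invalid="ignore"):
        radius = np.sqrt(x * x + y * y + z * z)
        azimuth = np.arctan2(y, x)
        elevation = np.arctan2(z, np.hypot(x, y))
    return SphericalField(
        azimuth=azimuth,
        elevation=elevation,
        radius=radius,
        triplet=proj.triplet,
        validity=proj.validity.copy(),
    )


@dataclass
class StainScheme:
    """Recipe for one HSV false-color rendering.

    ``hue_angle_range=None`` maps the [1st, 99th] percentile of the rendered
    image's own angle distribution onto the full hue wheel (high contrast,
    image-specific); pass a fixed ``(lo, hi)`` in radians whenever stains of
    different images must be color-comparable.
    """

    name: str
    triplet: tuple[int, int, int]
    hue_source: str  # "azimuth" | "elevation"
    hue_angle_range: tuple[float, float] | None = None
    value_percentile_clip: tuple[float, float] = (1.0, 99.0)

    def __post_init__(self) -> None:
        if self.hue_source not in ("azimuth", "elevation"):
            raise ValueError(f"unknown hue source {self.hue_source!r}")
        if self.hue_angle_range is not None and not self.hue_angle_range[0] < self.hue_angle_range[1]:
            raise ValueError("hue_angle_range must satisfy lo < hi")


#: The three stains: nuclear-contrast elevation stain over PCs 1-2-3,
#: stroma-contrast azimuth stain over PCs 2-3-4, and the malignancy stain
#: (azimuth over PCs 1-2-3) whose hue tracks scattering vs absorber balance.
SCHEMES: dict[str, StainScheme] = {
    "elevation_123": StainScheme("elevation_123", (1, 2, 3), "elevation"),
    "azimuth_234": StainScheme("azimuth_234", (2, 3, 4), "azimuth"),
    "malignancy_123": StainScheme("malignancy_123", (1, 2, 3), "azimuth"),
}


def render_stain(sph: SphericalField, scheme: StainScheme) -> np.ndarray:
    """Render an H x W x 3 RGB image in [0, 1] from a spherical field.

    Hue is a linear clamp of the chosen angle onto [0, 1]; saturation is 1
    on every valid pixel; value is the radius rescaled by the scheme's
    percentile clip.  Invalid pixels render black.
    """
    if tuple(sph.triplet) != tuple(scheme.triplet):
        raise ValueError(
            f"field triplet {sph.triplet} does not match scheme {scheme.name} "
            f"triplet {scheme.triplet}"
        )
    angle = sph.azimuth if scheme.hue_source == "azimuth" else sph.elevation
    valid = sph.validity & np.isfinite(angle) & np.isfinite(sph.radius)
    if scheme.hue_angle_range is None:
        if valid.any():
            lo, hi = np.percentile(angle[valid], [1.0, 99.0])
        else:
            lo, hi = -np.pi, np.pi
        if hi <= lo:  # constant-angle image
            hi = lo + 1e-12
    else:
        lo, hi = scheme.hue_angle_range
    hue = np.clip((angle - lo) / (hi - lo), 0.0, 1.0)

    p_lo, p_hi = scheme.value_percentile_clip
    if valid.any():
        r_lo, r_hi = np.percentile(sph.radius[valid], [p_lo, p_hi])
    else:
        r_lo, r_hi = 0.0, 1.0
    if r_hi <= r_lo:
        r_hi = r_lo + 1e-12
    value = np.clip((sph.radius - r_lo) / (r_hi - r_lo), 0.0, 1.0)

    hsv = np.zeros(sph.azimuth.shape + (3,), dtype=np.float64)
    hsv[..., 0] = np.where(valid, hue, 0.0)
    hsv[..., 1] = np.where(valid, 1.0, 0.0)
    hsv[..., 2] = np.where(valid, value, 0.0)
    rgb = hsv2rgb(hsv)
    rgb[~valid] = 0.0
    return rgb


def write_stain(rgb: np.ndarray, path: str | Path) -> Path:
    """Write an RGB stain in [0, 1] as an 8-bit PNG/TIFF."""
    path = Path(path)
    iio.imwrite(path, (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8))
    return path


@dataclass
class AngleHistogram2D:
    """Joint azimuth x elevation histogram of a masked region.

    ``counts[j, k]`` is the mass in azimuth bin j, elevation bin k; with
    ``weight_kind="count"`` the total mass equals ``n_pixels`` exactly.
    """

    counts: np.ndarray
    az_edges: np.ndarray
    el_edges: np.ndarray
    weight_kind: str
    n_pixels: int

    @property
    def az_centers(self) -> np.ndarray:
        return 0.5 * (self.az_edges[:-1] + self.az_edges[1:])

    @property
    def el_centers(self) -> np.ndarray:
        return 0.5 * (self.el_edges[:-1] + self.el_edges[1:])

    def __add__(self, other: "AngleHistogram2D") -> "AngleHistogram2D":
        """Accumulate two histograms over identical bins (cumulative pooling)."""
        if self.weight_kind != other.weight_kind:
            raise ValueError("cannot add histograms with different weight kinds")
        if not (np.array_equal(self.az_edges, other.az_edges)
                and np.array_equal(self.el_edges, other.el_edges)):
            raise ValueError("cannot add histograms with different bin edges")
        return AngleHistogram2D(
            counts=self.counts + other.counts,
            az_edges=self.az_edges,
            el_edges=self.el_edges,
            weight_kind=self.weight_kind,
            n_pixels=self.n_pixels + other.n_pixels,
        )

    def to_csv(self, path: str | Path) -> Path:
        """Flat CSV of bin edges and counts (one row per 2D bin)."""
        import pandas as pd

        az_i, el_i = np.meshgrid(
            np.arange(self.counts.shape[0]), np.arange(self.counts.shape[1]), indexing="ij"
        )
        pd.DataFrame(
            {
                "az_lo": self.az_edges[az_i.ravel()],
                "az_hi": self.az_edges[az_i.ravel() + 1],
                "el_lo": self.el_edges[el_i.ravel()],
                "el_hi": self.el_edges[el_i.ravel() + 1],
                "count": self.counts.ravel(),
            }
        ).to_csv(path, index=False)
        return Path(path)


def angle_histogram(
    sph: SphericalField,
    mask: np.ndarray | None = None,
    az_bins: int = 360,
    el_bins: int = 180,
    weight: str = "count",
) -> AngleHistogram2D:
    """Bin the masked valid pixels of a spherical field into a joint
    azimuth x elevation histogram with uniform edges over
    (-pi, pi] x [-pi/2, pi/2].

    ``weight="radius"`` accumulates each pixel's radius instead of 1,
    emphasising concentrated spectra.
    """
    if az_bins < 1 or el_bins < 1:
        raise ValueError("need at least one bin per axis")
    if weight not in ("count", "radius"):
        raise ValueError(f"unknown weight kind {weight!r}")
    keep = sph.validity & np.isfinite(sph.azimuth) & np.isfinite(sph.elevation)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != sph.azimuth.shape:
            raise ValueError("mask incongruent with field")
        keep &= mask
    az = sph.azimuth[keep]
    el = sph.elevation[keep]
    # atan2 can return exactly -pi (y = -0.0); fold onto +pi so every pixel
    # lands inside the (-pi, pi] bin range and mass is conserved exactly
    az = np.where(az == -np.pi, np.pi, az)
    if az.size == 0:
        raise ValueError("empty mask: no spectra to histogram")
    az_edges = np.linspace(-np.pi, np.pi, az_bins + 1)
    el_edges = np.linspace(-np.pi / 2, np.pi / 2, el_bins + 1)
    w = sph.radius[keep] if weight == "radius" else None
    counts, _, _ = np.histogram2d(az, el, bins=[az_edges, el_edges], weights=w)
    return AngleHistogram2D(
        counts=counts,
        az_edges=az_edges,
        el_edges=el_edges,
        weight_kind=weight,
        n_pixels=int(az.size),
    )
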