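"""EPID non-gap test analysis.

The non-gap test delivers abutting rectangular MLC strips with zero leaf
gap; the summed ("composite") portal image shows over/underdose lines at
each leaf-abutment position.  This module builds composites, removes
reticule (mechanical-center surrogate) offsets, measures field size by
FWHM, and reduces composites to per-abutment pixel-value ratios
A/B x 100 (A = abutment ROI, B = mean of the two flanking open-field
ROIs) plus their replicate reproducibility.

ROI sizes and abutment coordinates are expressed at isocenter scale
(detector coordinates divided by the sid/sad magnification), matching the
clinical reporting convention used throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import DetectionError, ValidationError
from .rt_io import GeometryConstants

__all__ = [
    "EPIDImage",
    "CompositeImage",
    "AbutmentGrid",
    "NonGapResult",
    "FieldSizeResult",
    "build_composite",
    "correct_reticle_offset",
    "measure_field_size",
    "make_abutment_grid",
    "compute_abutment_ratios",
    "reproducibility_cov",
]


@dataclass
class EPIDImage:
    """One portal exposure: pixel intensities plus acquisition metadata.

    ``reticle_offset`` is ``(rotation_deg, (drow, dcol))`` describing where
    the reticule cross-point sits relative to the physical center pixel; it
    is ``None`` once corrected (or for synthetic images born aligned).
    """

    pixels: np.ndarray
    pitch: float  # mm/px at the detector plane
    sid: float
    gantry_angle: float
    reticle_offset: tuple[float, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValidationError("EPID image must be 2D")
        if self.pitch <= 0:
            raise ValidationError("pixel pitch must be positive")
        if np.any(self.pixels < 0):
            raise ValidationError("pixel intensities must be non-negative")

    @property
    def center_px(self) -> tuple[int, int]:
        """Physical center pixel (row, col): (511, 511) for a 1024^2 panel."""
        return ((self.pixels.shape[0] - 1) // 2, (self.pixels.shape[1] - 1) // 2)

    def iso_coords(self, geometry: GeometryConstants) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) pixel-center coordinates in mm at isocenter scale.

        x runs along columns (leaf travel), y along rows (leaf width).
        """
        scale = self.pitch * geometry.sad / self.sid
        r0, c0 = self.center_px
        x = (np.arange(self.pixels.shape[1]) - c0) * scale
        y = (np.arange(self.pixels.shape[0]) - r0) * scale
        return x, y


@dataclass
class CompositeImage(EPIDImage):
    n_exposures: int = 1

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.n_exposures < 1:
            raise ValidationError("composite needs >= 1 exposure")


def build_composite(exposures: list[EPIDImage]) -> CompositeImage:
    """Per-pixel sum of the strip exposures (linear detector response)."""
    if not exposures:
        raise ValidationError("no exposures given")
    first = exposures[0]
    for img in exposures[1:]:
        if img.pixels.shape != first.pixels.shape:
            raise ValidationError("exposures have mismatched shapes")
        if not (
            np.isclose(img.pitch, first.pitch)
            and np.isclose(img.sid, first.sid)
            and np.isclose(img.gantry_angle, first.gantry_angle)
        ):
            raise ValidationError("exposures have mismatched acquisition metadata")
    total = np.zeros_like(first.pixels)
    for img in exposures:
        total += img.pixels
    return CompositeImage(
        pixels=total,
        pitch=first.pitch,
        sid=first.sid,
        gantry_angle=first.gantry_angle,
        reticle_offset=first.reticle_offset,
        n_exposures=len(exposures),
    )


def correct_reticle_offset(image: EPIDImage) -> EPIDImage:
    """Resample the image so the reticule cross lands on the center pixel.

    The stored offset models the acquired image as the ideal image rotated
    by ``rot`` about the center pixel and then translated by ``(drow,
    dcol)``; the correction applies the inverse map with bilinear
    resampling and zeroes the metadata offset.  Offsets larger than 50 px
    trigger a suspicious-input warning but are still applied.
    """
    if image.reticle_offset is None:
        raise ValidationError("image carries no reticle offset")
    rot_deg, (drow, dcol) = image.reticle_offset
    if float(np.hypot(drow, dcol)) > 50.0:
        warnings.warn(
            "reticle offset exceeds 50 px; check the acquisition", stacklevel=2
        )
    if rot_deg == 0.0 and drow == 0.0 and dcol == 0.0:
        return replace(image, reticle_offset=None)
    theta = np.deg2rad(rot_deg)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    center = np.asarray(image.center_px, dtype=float)
    t = np.array([drow, dcol], dtype=float)
    # out(o) = in(R (o - c) + c + t): maps the displaced cross back to c
    offset = center + t - rot @ center
    corrected = ndimage.affine_transform(
        image.pixels, rot, offset=offset, order=1, mode="nearest"
    )
    return replace(image, pixels=np.clip(corrected, 0.0, None), reticle_offset=None)


@dataclass(frozen=True)
class FieldSizeResult:
    """FWHM field edges (isocenter mm) and their signed errors vs nominal.

    Positive errors mean the measured opening is larger than nominal.
    """

    leaf_index: int
    x1_edge: float  # negative-side edge position
    x2_edge: float
    x1_error: float
    x2_error: float

    def __post_init__(self) -> None:
        if not self.x2_edge > self.x1_edge:
            raise ValidationError("X2 edge must exceed X1 edge")

    @property
    def size(self) -> float:
        return self.x2_edge - self.x1_edge


def _edge_crossings(x: np.ndarray, profile: np.ndarray, half: float) -> tuple[float, float]:
    """Locate 50% crossings scanning from outside inward, sub-pixel linear."""
    above = profile >= half
    if not above.any() or above.all():
        raise DetectionError("no half-maximum crossing found")
    rising = np.flatnonzero(~above[:-1] & above[1:])
    falling = np.flatnonzero(above[:-1] & ~above[1:])
    if rising.size == 0 or falling.size == 0:
        raise DetectionError("field edge missing on one side")
    i = rising[0]  # first crossing from the left
    j = falling[-1]  # last crossing from the right
    x1 = x[i] + (half - profile[i]) / (profile[i + 1] - profile[i]) * (x[i + 1] - x[i])
    x2 = x[j] + (half - profile[j]) / (profile[j + 1] - profile[j]) * (x[j + 1] - x[j])
    return float(x1), float(x2)


def measure_field_size(
    image: EPIDImage,
    nominal_half_sizes: tuple[float, float],
    leaf_index: int,
    geometry: GeometryConstants = GeometryConstants(),
    n_leaves: int = 19,
    leaf_width: float = 10.0,
) -> FieldSizeResult:
    """Measure the field opening along leaf travel by FWHM for one leaf.

    The profile is the mean over the central 5 mm of the leaf's width; the
    plateau reference is the mean over the central 50% of the nominal
    field (robust to abutment lines), and each edge is the 50%-of-plateau
    crossing found by linear sub-pixel interpolation from outside inward.
    Positions are at isocenter scale; per-side error = |measured edge| -
    nominal half-size (positive = opening larger than nominal).
    """
    x1_nom, x2_nom = nominal_half_sizes
    x, y = image.iso_coords(geometry)
    leaf_center = (leaf_index - (n_leaves + 1) / 2) * leaf_width
    rows = np.abs(y - leaf_center) <= 2.5
    if not rows.any():
        raise ValidationError(f"leaf {leaf_index} lies outside the image")
    profile = image.pixels[rows].mean(axis=0)

    center = (x2_nom - x1_nom) / 2.0
    width = x1_nom + x2_nom
    core = np.abs(x - center) <= width / 4.0
    plateau = profile[core].mean()
    if plateau <= 0:
        raise DetectionError("plateau level is non-positive")
    x1_edge, x2_edge = _edge_crossings(x, profile, plateau / 2.0)
    return FieldSizeResult(
        leaf_index=leaf_index,
        x1_edge=x1_edge,
        x2_edge=x2_edge,
        x1_error=(-x1_edge) - x1_nom,
        x2_error=x2_edge - x2_nom,
    )


@dataclass(frozen=True)
class AbutmentGrid:
    """Geometry of the non-gap abutment lattice and its sampling ROIs.

    ``abutment_x`` are the strip-junction positions (A ROIs) and ``b_x``
    the open-field strip centers (B ROIs), all in isocenter mm.  ROIs are
    ``roi_travel`` mm along leaf travel by ``roi_width`` mm along leaf
    width.
    """

    abutment_x: np.ndarray
    b_x: np.ndarray
    leaf_centers: np.ndarray
    leaf_indices: np.ndarray
    strip_width: float
    roi_travel: float = 10.0
    roi_width: float = 5.0

    def __post_init__(self) -> None:
        for name in ("abutment_x", "b_x", "leaf_centers", "leaf_indices"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if np.any(np.diff(self.abutment_x) <= 0):
            raise ValidationError("abutment positions must be strictly increasing")
        for a in self.abutment_x:
            if not np.any(np.isclose(self.b_x, a - self.strip_width / 2)) and not np.any(
                np.isclose(self.b_x, a + self.strip_width / 2)
            ):
                raise ValidationError(f"abutment at {a} mm has no flanking B ROI")

    @property
    def n_abutments(self) -> int:
        return int(self.abutment_x.size * self.leaf_indices.size)

    def matches(self, other: "AbutmentGrid") -> bool:
        return (
            self.abutment_x.shape == other.abutment_x.shape
            and np.allclose(self.abutment_x, other.abutment_x)
            and np.allclose(self.leaf_centers, other.leaf_centers)
        )


def make_abutment_grid(
    n_strips: int = 10,
    strip_width: float = 20.0,
    n_leaves: int = 19,
    leaf_width: float = 10.0,
    roi_travel: float = 10.0,
    roi_width: float = 5.0,
) -> AbutmentGrid:
    """Lay out the abutment lattice for ``n_strips`` abutting strips.

    The default 10 strips of 20 mm x 19 leaves of 10 mm gives the 9 x 19 =
    171 abutment positions at x in {-80, ..., +80} mm with open-field B
    ROIs at {-90, ..., +90} mm.
    """
    if n_strips < 2:
        raise ValidationError("need at least two strips to form an abutment")
    if strip_width <= 0 or leaf_width <= 0:
        raise ValidationError("strip and leaf widths must be positive")
    half = n_strips * strip_width / 2.0
    abutment_x = -half + strip_width * np.arange(1, n_strips)
    b_x = -half + strip_width * (np.arange(n_strips) + 0.5)
    leaf_indices = np.arange(1, n_leaves + 1)
    leaf_centers = (leaf_indices - (n_leaves + 1) / 2) * leaf_width
    return AbutmentGrid(
        abutment_x=abutment_x,
        b_x=b_x,
        leaf_centers=leaf_centers,
        leaf_indices=leaf_indices,
        strip_width=strip_width,
        roi_travel=roi_travel,
        roi_width=roi_width,
    )


@dataclass
class NonGapResult:
    """Per-abutment pixel-value ratios A/B x 100 for one composite.

    ``ratio_percent`` is indexed ``[leaf, abutment]`` following the grid's
    ``leaf_indices`` / ``abutment_x``.  Ratios above 100 flag overdose
    lines, below 100 underdose lines.
    """

    ratio_percent: np.ndarray
    grid: AbutmentGrid
    gantry_angle: float

    def __post_init__(self) -> None:
        self.ratio_percent = np.asarray(self.ratio_percent, dtype=float)
        expected = (self.grid.leaf_indices.size, self.grid.abutment_x.size)
        if self.ratio_percent.shape != expected:
            raise ValidationError(
                f"ratio array {self.ratio_percent.shape} != grid layout {expected}"
            )
        if np.any(self.ratio_percent <= 0):
            raise ValidationError("ratios must be positive")

    def to_frame(self) -> pd.DataFrame:
        leaves = np.repeat(self.grid.leaf_indices, self.grid.abutment_x.size)
        xs = np.tile(self.grid.abutment_x, self.grid.leaf_indices.size)
        return pd.DataFrame(
            {"leaf": leaves, "x_mm": xs, "ratio_percent": self.ratio_percent.ravel()}
        )


def _roi_mean(
    pixels: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    cx: float,
    cy: float,
    half_travel: float,
    half_width: float,
) -> float:
    c0 = np.searchsorted(x, cx - half_travel, side="left")
    c1 = np.searchsorted(x, cx + half_travel, side="right")
    r0 = np.searchsorted(y, cy - half_width, side="left")
    r1 = np.searchsorted(y, cy + half_width, side="right")
    if c1 <= c0 or r1 <= r0:
        raise ValidationError("ROI falls outside the composite image")
    return float(pixels[r0:r1, c0:c1].mean())


def compute_abutment_ratios(
    composite: CompositeImage,
    grid: AbutmentGrid,
    geometry: GeometryConstants = GeometryConstants(),
) -> NonGapResult:
    """Reduce a composite to A/B x 100 ratios on the abutment lattice.

    A is the mean pixel value in the ROI centered on (abutment x, leaf
    center); B is the mean of the two flanking open-field strip-center
    ROIs (one at edge abutments of non-default geometries).
    """
    x, y = composite.iso_coords(geometry)
    ht, hw = grid.roi_travel / 2.0, grid.roi_width / 2.0
    n_leaf, n_ab = grid.leaf_centers.size, grid.abutment_x.size
    ratios = np.empty((n_leaf, n_ab))
    for i, yc in enumerate(grid.leaf_centers):
        b_means = {
            float(bx): _roi_mean(composite.pixels, x, y, bx, yc, ht, hw)
            for bx in grid.b_x
        }
        for j, ax in enumerate(grid.abutment_x):
            a_val = _roi_mean(composite.pixels, x, y, ax, yc, ht, hw)
            flank = [
                b_means[float(bx)]
                for bx in (ax - grid.strip_width / 2, ax + grid.strip_width / 2)
                if float(bx) in b_means
            ]
            b_val = float(np.mean(flank))
            if b_val <= 0:
                raise ZeroDivisionError(
                    f"open-field reference non-positive at leaf {i + 1}, x={ax}"
                )
            ratios[i, j] = a_val / b_val * 100.0
    return NonGapResult(
        ratio_percent=ratios, grid=grid, gantry_angle=composite.gantry_angle
    )


def reproducibility_cov(results: list[NonGapResult]) -> np.ndarray:
    """Per-abutment coefficient of variation (%) across replicates.

    CoV = sample standard deviation (ddof=1) / mean x 100 per abutment.
    """
    if len(results) < 2:
        raise ValidationError("need at least two replicates")
    first = results[0]
    for r in results[1:]:
        if not r.grid.matches(first.grid) or not np.isclose(
            r.gantry_angle, first.gantry_angle
        ):
            raise ValidationError("replicates have mismatched grids or angle")
    stack = np.stack([r.ratio_percent for r in results])
    return stack.std(axis=0, ddof=1) / stack.mean(axis=0) * 100.0
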