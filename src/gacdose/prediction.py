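"""Per-beam error maps, GAC injection and 3D back-projection.

The prediction chain per beam is

    planned plane + diode measurement -> 2D fractional error map e(u, v)
    segmented intensity map           -> detected MLC abutments
    GAC table                         -> additive delta on abutment bands
    e(u, v) back-projected            -> corrected per-beam 3D dose

and the predicted total is the voxelwise sum over beams.  The
back-projection is divergent and multiplicative: each voxel is projected
to the beam's-eye-view isocenter plane and scaled by 1 + e(u, v).  GAC
deltas combine *additively* with the measured relative error (the two
differ only at second order for the few-percent magnitudes involved) and
are weighted by the MU fraction of the segment that formed the abutment.
The error map's depth dependence is ignored: one measurement plane at
10 cm depth, matching the QA geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .exceptions import GeometryError, ValidationError
from .gac import GACTable, gac_at
from .rt_io import (
    BeamSpec,
    DoseGrid3D,
    DosePlane2D,
    GeometryConstants,
    PlanSpec,
    project_voxel_to_bev,
)

__all__ = [
    "SegmentIntensityMap",
    "Abutment",
    "AbutmentSet",
    "ErrorMap2D",
    "compute_error_map",
    "detect_abutments",
    "apply_gac",
    "backproject",
    "predict_dose",
]


@dataclass
class SegmentIntensityMap:
    """Per-beam relative intensity on a 1-mm isocenter-plane grid.

    Rows follow the MLC leaf-row geometry (``n_leaves`` rows of
    ``leaf_width`` mm, centered on the beam axis).
    """

    plane: DosePlane2D
    n_leaves: int = 19
    leaf_width: float = 10.0

    def __post_init__(self) -> None:
        if not np.allclose(self.plane.spacing, (1.0, 1.0)):
            raise ValidationError("segment intensity maps must be on a 1-mm grid")
        if np.any(self.plane.values < 0):
            raise ValidationError("intensities must be non-negative")

    @property
    def leaf_centers(self) -> np.ndarray:
        idx = np.arange(1, self.n_leaves + 1)
        return (idx - (self.n_leaves + 1) / 2) * self.leaf_width


@dataclass(frozen=True)
class Abutment:
    """One detected abutment: its leaf row, position and MU weighting."""

    leaf_index: int
    x: float
    mu_fraction: float  # NaN when no segment leaf end matched
    segment_index: int = -1


@dataclass
class AbutmentSet:
    abutments: list[Abutment] = field(default_factory=list)

    def __iter__(self):
        return iter(self.abutments)

    def __len__(self) -> int:
        return len(self.abutments)

    def for_leaf(self, leaf_index: int) -> list[Abutment]:
        return [a for a in self.abutments if a.leaf_index == leaf_index]


@dataclass
class ErrorMap2D:
    """Fractional dose error e(u, v) on a 1-mm isocenter-plane grid.

    ``mask`` is True where the planned dose exceeded the low-dose
    threshold and the measurement covered the point; e is zero off-mask.
    """

    origin: tuple[float, float]
    spacing: tuple[float, float]
    e: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.e.shape != self.mask.shape:
            raise ValidationError("error and mask shapes differ")
        if np.any(~np.isfinite(self.e[self.mask])):
            raise ValidationError("error values must be finite on the mask")
        if np.any(self.e[~self.mask] != 0.0):
            raise ValidationError("error must be zero off-mask")

    @property
    def u(self) -> np.ndarray:
        return self.origin[0] + self.spacing[0] * np.arange(self.e.shape[1])

    @property
    def v(self) -> np.ndarray:
        return self.origin[1] + self.spacing[1] * np.arange(self.e.shape[0])


def compute_error_map(
    planned: DosePlane2D,
    measured: DosePlane2D,
    threshold: float = 0.10,
) -> ErrorMap2D:
    """Measured-vs-planned fractional error on the planned 1-mm grid.

    The fractional error (measured - planned)/planned is formed at each
    measurement sample (against the planned dose interpolated to the
    sample position) and then bilinearly interpolated onto the planned
    grid wherever it is surrounded by usable samples.  Interpolating the
    *ratio* rather than the raw measured dose keeps the map exact for a
    perfect measurement even across steep penumbra between sparse diode
    samples.  Points where the planned dose falls below ``threshold`` of
    its maximum get e = 0 with mask False.
    """
    pmax = planned.values.max()
    if pmax <= 0:
        raise ValidationError("planned plane has no dose")
    p_interp = RegularGridInterpolator(
        (planned.v, planned.u),
        planned.values,
        method="linear",
        bounds_error=False,
        fill_value=np.nan,
    )
    uu_m, vv_m = np.meshgrid(measured.u, measured.v)
    p_at_m = p_interp(
        np.stack([vv_m.ravel(), uu_m.ravel()], axis=1)
    ).reshape(measured.values.shape)
    # samples in very low planned dose carry no usable ratio
    usable = np.isfinite(p_at_m) & (p_at_m >= 0.5 * threshold * pmax)
    ratio = np.where(usable, measured.values / np.where(usable, p_at_m, 1.0), np.nan)

    interp = RegularGridInterpolator(
        (measured.v, measured.u),
        ratio,
        method="linear",
        bounds_error=False,
        fill_value=np.nan,
    )
    uu, vv = np.meshgrid(planned.u, planned.v)
    r = interp(np.stack([vv.ravel(), uu.ravel()], axis=1)).reshape(planned.values.shape)
    covered = np.isfinite(r)
    if not covered.any():
        raise GeometryError("measured and planned planes do not overlap")
    mask = covered & (planned.values >= threshold * pmax)
    e = np.zeros_like(planned.values)
    e[mask] = r[mask] - 1.0
    return ErrorMap2D(origin=planned.origin, spacing=planned.spacing, e=e, mask=mask)


def detect_abutments(
    simap: SegmentIntensityMap,
    beam: BeamSpec,
    min_step_fraction: float = 0.01,
    merge_mm: float = 1.0,
    match_mm: float = 1.5,
) -> AbutmentSet:
    """Scan each leaf row for intensity steps marking segment abutments.

    Adjacent-sample differences of at least ``min_step_fraction`` of the
    beam maximum mark an abutment at the step midpoint; steps within
    ``merge_mm`` are merged (|difference|-weighted centroid).  Each
    abutment is annotated with the MU fraction of the segment whose leaf
    end lies within ``match_mm``; where two adjacent segments share the
    boundary, the lowest-index match wins.  An empty set is legal.
    """
    plane = simap.plane
    vmax = plane.values.max()
    out = AbutmentSet()
    if vmax <= 0:
        return out
    u = plane.u
    v = plane.v
    for leaf_pos, leaf_index in zip(
        simap.leaf_centers, range(1, simap.n_leaves + 1)
    ):
        rows = (v >= leaf_pos - simap.leaf_width / 2) & (
            v < leaf_pos + simap.leaf_width / 2
        )
        if not rows.any():
            continue
        profile = plane.values[rows].mean(axis=0)
        d = np.diff(profile)
        hits = np.flatnonzero(np.abs(d) >= min_step_fraction * vmax)
        if hits.size == 0:
            continue
        mids = (u[hits] + u[hits + 1]) / 2.0
        weights = np.abs(d[hits])
        # merge runs of hits closer than merge_mm into one weighted centroid
        breaks = np.flatnonzero(np.diff(mids) > merge_mm) + 1
        for seg_idx in np.split(np.arange(hits.size), breaks):
            pos = float(np.average(mids[seg_idx], weights=weights[seg_idx]))
            out.abutments.append(
                _annotate(beam, leaf_index, pos, match_mm)
            )
    return out


def _annotate(beam: BeamSpec, leaf_index: int, x: float, match_mm: float) -> Abutment:
    best: tuple[float, int] | None = None  # (distance, segment index)
    for si, seg in enumerate(beam.segments):
        if leaf_index - 1 >= seg.left.size:
            continue
        left = seg.left[leaf_index - 1]
        right = seg.right[leaf_index - 1]
        if right <= left:  # closed leaf pair
            continue
        for end in (left, right):
            dist = abs(end - x)
            if dist <= match_mm and (best is None or dist < best[0] - 1e-12):
                best = (dist, si)
    if best is None:
        return Abutment(leaf_index=leaf_index, x=x, mu_fraction=np.nan)
    si = best[1]
    return Abutment(
        leaf_index=leaf_index,
        x=x,
        mu_fraction=beam.segments[si].mu / beam.beam_mu,
        segment_index=si,
    )


def apply_gac(
    emap: ErrorMap2D,
    abutments: AbutmentSet,
    table: GACTable,
    gantry_angle: float,
    band_mm: float = 2.0,
    leaf_width: float = 10.0,
    n_leaves: int = 19,
) -> ErrorMap2D:
    """Inject GAC deltas additively on bands around each abutment.

    For each abutment, ``g = gac_at(table, angle, leaf, x) * mu_fraction``
    is added to e over a ``band_mm``-wide column band within the leaf row,
    on masked (in-field) points only; elsewhere the map is unchanged.
    """
    e = emap.e.copy()
    u = emap.u
    v = emap.v
    for ab in abutments:
        if not np.isfinite(ab.mu_fraction):
            continue
        g = gac_at(table, gantry_angle, ab.leaf_index, ab.x) * ab.mu_fraction
        if g == 0.0:
            continue
        leaf_center = (ab.leaf_index - (n_leaves + 1) / 2) * leaf_width
        cols = np.abs(u - ab.x) <= band_mm / 2.0
        rows = (v >= leaf_center - leaf_width / 2.0) & (
            v < leaf_center + leaf_width / 2.0
        )
        band = np.outer(rows, cols) & emap.mask
        e[band] += g
    return ErrorMap2D(origin=emap.origin, spacing=emap.spacing, e=e, mask=emap.mask)


def backproject(
    emap: ErrorMap2D,
    beam_dose: DoseGrid3D,
    gantry_angle: float,
    geometry: GeometryConstants = GeometryConstants(),
) -> DoseGrid3D:
    """Scale each voxel of the per-beam grid by 1 + e at its BEV position.

    Voxel centers are divergently projected onto the isocenter plane and
    the error looked up bilinearly; e = 0 outside the map or off-mask.
    """
    x = beam_dose.axis(0)
    y = beam_dose.axis(1)
    z = beam_dose.axis(2)
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    u, v = project_voxel_to_bev(pts, gantry_angle, geometry)
    interp = RegularGridInterpolator(
        (emap.v, emap.u),
        emap.e,
        method="linear",
        bounds_error=False,
        fill_value=0.0,
    )
    e = interp(np.stack([v, u], axis=1)).reshape(beam_dose.values.shape)
    corrected = beam_dose.values * (1.0 + e)
    return DoseGrid3D(
        origin=beam_dose.origin,
        spacing=beam_dose.spacing,
        values=corrected,
        scope="per-beam",
    )


def predict_dose(
    plan: PlanSpec,
    planned_planes: Sequence[DosePlane2D],
    measured_planes: Sequence[DosePlane2D],
    simaps: Sequence[SegmentIntensityMap],
    beam_grids: Sequence[DoseGrid3D],
    table: GACTable | None = None,
    use_gac: bool = True,
    geometry: GeometryConstants = GeometryConstants(),
    band_mm: float = 2.0,
    threshold: float = 0.10,
) -> DoseGrid3D:
    """Assemble the predicted total 3D dose, with or without GAC.

    Per beam: error map -> (optionally GAC injection) -> back-projection;
    the total is the voxelwise sum of the corrected per-beam grids.  With
    ``use_gac`` False the GAC step is skipped entirely.
    """
    n = len(plan.beams)
    if not (
        len(planned_planes) == len(measured_planes) == len(beam_grids) == n
    ) or (use_gac and table is not None and len(simaps) != n):
        raise ValidationError("per-beam inputs must match the plan's beam count")
    if use_gac and table is None:
        raise ValidationError("use_gac requires a GAC table")
    total: np.ndarray | None = None
    ref = beam_grids[0]
    for i, beam in enumerate(plan.beams):
        emap = compute_error_map(planned_planes[i], measured_planes[i], threshold)
        if use_gac:
            abutments = detect_abutments(simaps[i], beam)
            emap = apply_gac(
                emap, abutments, table, beam.gantry_angle, band_mm=band_mm,
                leaf_width=simaps[i].leaf_width, n_leaves=simaps[i].n_leaves,
            )
        corrected = backproject(emap, beam_grids[i], beam.gantry_angle, geometry)
        total = corrected.values if total is None else total + corrected.values
    return DoseGrid3D(origin=ref.origin, spacing=ref.spacing, values=total, scope="total")
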