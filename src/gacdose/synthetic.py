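"""Seeded synthetic fixtures with the structure the pipeline assumes.

The generators emulate the study conditions end to end with no external
data: non-gap strip exposures on a 1024 x 1024 EPID (0.40 mm/px, SID
150 cm) with error-function penumbras and controllable per-abutment
ratio perturbations; film-vs-EPID calibration pairs; and a five-beam
step-and-shoot prostate-like plan (gantry 45/105/180/255/315 deg, 78 Gy
in 39 fractions prescribed) with per-beam planes, segment maps, sparse
diode measurements, per-beam/total 3D grids and ellipsoidal structures.

The toy forward model is NOT a dose engine: it guarantees only the
geometric and statistical relationships the pipeline consumes (per-beam
planes consistent with per-beam grids, abutments consistent with segment
maps, injected errors recoverable by construction).  All generators are
pure functions of their configuration: the same seed yields identical
bytes.
"""

from __future__ import annotations

import functools
import operator
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.special import erf

from .calibration import CalibrationPair
from .epid_nongap import EPIDImage, build_composite
from .exceptions import ValidationError
from .prediction import SegmentIntensityMap
from .rt_io import (
    BeamSpec,
    DoseGrid3D,
    DosePlane2D,
    GeometryConstants,
    PlanSpec,
    Segment,
    StructureSet,
    write_rtdose,
    write_rtplan,
    write_rtstruct,
    write_text_plane,
)

__all__ = [
    "SyntheticConfig",
    "default_delta_r",
    "gen_nongap_images",
    "gen_nongap_composite",
    "gen_open_field",
    "gen_calibration_pairs",
    "calibration_noise_for_r",
    "PlanFixture",
    "gen_plan_fixture",
    "write_plan_fixture",
]


def _erf_step(t: np.ndarray | float) -> np.ndarray | float:
    """Edge profile 0 -> 1 with its half-maximum exactly at t = 0."""
    return 0.5 * (1.0 + erf(np.asarray(t) / np.sqrt(2.0)))


@dataclass(frozen=True)
class SyntheticConfig:
    """All the knobs of the synthetic study, with study-condition defaults."""

    seed: int = 0
    # EPID / non-gap geometry
    epid_pixels: int = 1024
    epid_pitch: float = 0.40  # mm/px at the detector
    sad: float = 1000.0
    sid: float = 1500.0
    n_strips: int = 10
    strip_width_mm: float = 20.0
    n_leaves: int = 19
    leaf_width_mm: float = 10.0
    field_height_mm: float = 200.0
    penumbra_sigma_mm: float = 2.0  # isocenter scale
    gain: float = 1000.0  # arbitrary linear detector units
    # noise: multiplicative Gaussian gain per 10-mm cell per exposure
    noise_sigma_pct: float = 0.55
    noise_cell_mm: float = 10.0
    # measured QA angle set and per-angle ratio perturbations
    angles: tuple[float, ...] = (0, 45, 90, 105, 135, 180, 225, 255, 270, 315)
    delta_r: str | None = "default"  # "default" | None (zeros)
    # plan fixture
    beam_angles: tuple[float, ...] = (45.0, 105.0, 180.0, 255.0, 315.0)
    beam_mu: float = 100.0
    segment_mu_fractions: tuple[float, ...] = (0.40, 0.35, 0.25)
    segment_boundaries_mm: tuple[float, ...] = (-50.0, -15.0, 22.0, 50.0)
    aperture_half_height_mm: float = 45.0  # leaves with |center| <= this are open
    simap_penumbra_mm: float = 0.8
    plane_penumbra_mm: float = 3.0
    plane_half_size_mm: float = 80.0  # 1-mm planned-plane grid extent
    # calibrated so the planned PTV mean dose matches the 78 Gy prescription
    dose_per_mu_gy: float = 0.0113
    diode_pitch_mm: float = 7.0
    diode_half_size_mm: float = 63.0
    grid_spacing_mm: float = 2.0
    grid_half_size_mm: float = 60.0
    depth_tau_mm: float = 300.0  # exponential depth factor scale
    error_blobs: tuple[tuple[float, float, float, float], ...] = (
        (10.0, 5.0, 15.0, 0.03),  # (u, v, sigma, amplitude)
        (-20.0, -12.0, 18.0, -0.02),
    )
    prescription_gy: float = 78.0
    fractions: int = 39

    def __post_init__(self) -> None:
        if self.noise_sigma_pct < 0:
            raise ValidationError("noise sigma must be >= 0")

    @property
    def geometry(self) -> GeometryConstants:
        return GeometryConstants(
            sad=self.sad,
            sid=self.sid,
            epid_pixels=(self.epid_pixels, self.epid_pixels),
            epid_pitch=self.epid_pitch,
        )

    def iso_axes(self) -> tuple[np.ndarray, np.ndarray]:
        scale = self.epid_pitch * self.sad / self.sid
        c = (self.epid_pixels - 1) // 2
        x = (np.arange(self.epid_pixels) - c) * scale
        return x, x.copy()


def default_delta_r(config: SyntheticConfig) -> dict[float, np.ndarray]:
    """Characteristic per-angle ratio-perturbation fields, seeded.

    Emulates the gravity pattern of the physical effect: no change at the
    reference, near-none at 90/270 deg, and the largest positive changes
    at 180 deg with mean ~3.43 ratio units (i.e. ~7% in dose through the
    2.03%-per-unit slope) and node-to-node scatter ~1.6 units.
    """
    rng = np.random.default_rng([config.seed, 101])
    n_ab = config.n_strips - 1
    out: dict[float, np.ndarray] = {}
    for angle in config.angles:
        shape_factor = float(np.sin(np.deg2rad(angle) / 2.0) ** 4)
        mean = 3.4335 * shape_factor
        sd = 1.581 * shape_factor
        field_ = mean + sd * rng.standard_normal((config.n_leaves, n_ab))
        if np.isclose(angle % 360.0, 180.0):
            field_ = np.clip(field_, 0.1, None)  # all-positive at 180 deg
        if np.isclose(angle % 360.0, 0.0):
            field_ = np.zeros_like(field_)
        out[float(angle)] = field_
    return out


def _resolve_delta_r(
    config: SyntheticConfig,
    delta_r: Mapping[float, np.ndarray] | None,
) -> dict[float, np.ndarray]:
    if delta_r is not None:
        return {float(a): np.asarray(v, dtype=float) for a, v in delta_r.items()}
    if config.delta_r == "default":
        return default_delta_r(config)
    zeros = np.zeros((config.n_leaves, config.n_strips - 1))
    return {float(a): zeros.copy() for a in config.angles}


def _noise_field(
    config: SyntheticConfig,
    x: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multiplicative gain noise, constant on ROI-lattice-aligned cells.

    Cells are ``noise_cell_mm`` squares centered on multiples of the cell
    size, so every A/B sampling ROI falls inside a single cell and the
    replicate CoV of the A/B ratio equals the cell sigma by construction.
    """
    sigma = config.noise_sigma_pct / 100.0
    cell = config.noise_cell_mm
    ix = np.floor((x + cell / 2.0) / cell).astype(int)
    iy = np.floor((y + cell / 2.0) / cell).astype(int)
    ix -= ix.min()
    iy -= iy.min()
    draws = rng.normal(1.0, sigma, size=(iy.max() + 1, ix.max() + 1))
    return draws[iy[:, None], ix[None, :]]


def _strip_image(
    config: SyntheticConfig,
    x: np.ndarray,
    y: np.ndarray,
    xl: float,
    xr: float,
    bump: np.ndarray | None,
    gantry_angle: float,
    rng: np.random.Generator | None,
) -> EPIDImage:
    s = config.penumbra_sigma_mm
    half_h = config.field_height_mm / 2.0
    ex = _erf_step((x - xl) / s) * _erf_step((xr - x) / s)
    ey = _erf_step((y + half_h) / s) * _erf_step((half_h - y) / s)
    base = ey[:, None] * ex[None, :]
    if bump is not None:
        base = base + bump
    if rng is not None and config.noise_sigma_pct > 0:
        base = base * _noise_field(config, x, y, rng)
    return EPIDImage(
        pixels=np.clip(base, 0.0, None) * config.gain,
        pitch=config.epid_pitch,
        sid=config.sid,
        gantry_angle=gantry_angle,
    )


def _junction_bump(
    config: SyntheticConfig,
    x: np.ndarray,
    y: np.ndarray,
    junction_x: float,
    delta_r_col: np.ndarray,
    roi_travel: float = 10.0,
) -> np.ndarray | None:
    """Additive junction-line perturbation making A/B = 100 + delta_r."""
    if not np.any(delta_r_col):
        return None
    cols = np.abs(x - junction_x) <= roi_travel / 2.0
    bump = np.zeros((y.size, x.size))
    leaf_centers = (
        np.arange(1, config.n_leaves + 1) - (config.n_leaves + 1) / 2
    ) * config.leaf_width_mm
    for leaf, yc in enumerate(leaf_centers):
        rows = np.abs(y - yc) <= config.leaf_width_mm / 2.0
        bump[np.ix_(rows, cols)] = delta_r_col[leaf] / 100.0
    return bump


def gen_nongap_images(
    config: SyntheticConfig,
    angles: tuple[float, ...] | None = None,
    delta_r: Mapping[float, np.ndarray] | None = None,
) -> dict[float, list[EPIDImage]]:
    """Per-angle lists of the ten abutting strip exposures.

    Each strip is a 2 cm x 20 cm field with error-function penumbra;
    junction columns are perturbed so the downstream A/B ratio equals
    100 + delta_r(angle, leaf, abutment) exactly (before noise), and the
    cell-wise multiplicative gain noise is applied per exposure.
    """
    dr = _resolve_delta_r(config, delta_r)
    use_angles = tuple(config.angles if angles is None else angles)
    x, y = config.iso_axes()
    w = config.strip_width_mm
    half = config.n_strips * w / 2.0
    out: dict[float, list[EPIDImage]] = {}
    for ai, angle in enumerate(use_angles):
        rng = np.random.default_rng([config.seed, 11, ai])
        dr_field = dr.get(float(angle))
        strips = []
        for s in range(config.n_strips):
            xl = -half + s * w
            bump = None
            if s >= 1 and dr_field is not None:
                bump = _junction_bump(config, x, y, xl, dr_field[:, s - 1])
            strips.append(
                _strip_image(config, x, y, xl, xl + w, bump, float(angle), rng)
            )
        out[float(angle)] = strips
    return out


def gen_nongap_composite(
    config: SyntheticConfig,
    angle: float,
    delta_r: Mapping[float, np.ndarray] | None = None,
):
    """Composite image for one angle (sums the ten strips)."""
    images = gen_nongap_images(config, angles=(angle,), delta_r=delta_r)
    return build_composite(images[float(angle)])


def gen_open_field(
    config: SyntheticConfig,
    half_sizes: tuple[float, float] = (100.0, 100.0),
    gantry_angle: float = 0.0,
    shift_mm: float = 0.0,
) -> EPIDImage:
    """A single rectangular open field with the strip penumbra model.

    The X1/X2 half-maximum edges sit exactly at ``-half_sizes[0] +
    shift_mm`` and ``half_sizes[1] + shift_mm`` at isocenter scale.
    """
    x, y = config.iso_axes()
    rng = np.random.default_rng([config.seed, 13])
    return _strip_image(
        config,
        x,
        y,
        -half_sizes[0] + shift_mm,
        half_sizes[1] + shift_mm,
        None,
        gantry_angle,
        rng if config.noise_sigma_pct > 0 else None,
    )


# ---------------------------------------------------------------------------
# Calibration pairs


def gen_calibration_pairs(
    slope: float = 0.0203,
    intercept: float = -1.0153,
    noise_sd: float = 0.0,
    n: int = 171,
    seed: int = 0,
    x_range: tuple[float, float] = (90.0, 110.0),
) -> list[CalibrationPair]:
    """Pixel-ratio/dose-ratio pairs on a line plus Gaussian y-noise."""
    if n < 3:
        raise ValidationError("need n >= 3 pairs")
    rng = np.random.default_rng([seed, 23])
    x = rng.uniform(*x_range, size=n)
    y = slope * x + intercept + rng.normal(0.0, noise_sd, size=n)
    return [CalibrationPair(float(xi), float(yi)) for xi, yi in zip(x, y)]


def calibration_noise_for_r(
    target_r: float,
    slope: float = 0.0203,
    x_range: tuple[float, float] = (90.0, 110.0),
) -> float:
    """Noise SD giving an expected Pearson r for uniform-x pairs.

    From r^2 = var(signal)/(var(signal) + sd^2) with var(signal) =
    slope^2 (b-a)^2/12 for x ~ U(a, b).
    """
    sd_signal = abs(slope) * (x_range[1] - x_range[0]) / np.sqrt(12.0)
    return sd_signal * np.sqrt(1.0 / target_r**2 - 1.0)


# ---------------------------------------------------------------------------
# Plan fixture


@dataclass
class PlanFixture:
    """A fully self-consistent five-beam QA scenario.

    ``error_field`` is the injected ground-truth fractional error
    e(u, v); ``true_abutments`` lists, per beam, the (leaf_index, x_mm,
    segment_index, mu_fraction) tuples of every aperture boundary.
    """

    plan: PlanSpec
    planned_planes: list[DosePlane2D]
    measured_planes: list[DosePlane2D]
    simaps: list[SegmentIntensityMap]
    beam_grids: list[DoseGrid3D]
    total_grid: DoseGrid3D
    structures: StructureSet
    error_field: Callable[[np.ndarray, np.ndarray], np.ndarray]
    true_abutments: list[list[tuple[int, float, int, float]]] = field(
        default_factory=list
    )
    geometry: GeometryConstants = GeometryConstants()


def _blob_error(config: SyntheticConfig) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    blobs = config.error_blobs

    def e(u: np.ndarray, v: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        total = np.zeros(np.broadcast(u, v).shape)
        for u0, v0, sig, amp in blobs:
            total += amp * np.exp(-(((u - u0) ** 2) + (v - v0) ** 2) / (2 * sig**2))
        return total

    return e


def _fluence_plane(
    config: SyntheticConfig,
    beam: BeamSpec,
    penumbra_mm: float,
    grid_axis: np.ndarray,
) -> np.ndarray:
    """Relative intensity map: MU-weighted sum of segment apertures."""
    u = grid_axis
    v = grid_axis
    leaf_centers = (
        np.arange(1, config.n_leaves + 1) - (config.n_leaves + 1) / 2
    ) * config.leaf_width_mm
    values = np.zeros((v.size, u.size))
    for seg in beam.segments:
        for li, yc in enumerate(leaf_centers):
            left, right = seg.left[li], seg.right[li]
            if right <= left:
                continue
            # half-open leaf rows tile the plane with no gap lines
            rows = (v >= yc - config.leaf_width_mm / 2.0) & (
                v < yc + config.leaf_width_mm / 2.0
            )
            prof = _erf_step((u - left) / penumbra_mm) * _erf_step(
                (right - u) / penumbra_mm
            )
            values[rows] += seg.mu / beam.beam_mu * prof[None, :]
    return values


def _make_beam(config: SyntheticConfig, angle: float) -> tuple[BeamSpec, list]:
    bounds = config.segment_boundaries_mm
    fractions = config.segment_mu_fractions
    if len(bounds) != len(fractions) + 1:
        raise ValidationError("need one more segment boundary than MU fraction")
    leaf_centers = (
        np.arange(1, config.n_leaves + 1) - (config.n_leaves + 1) / 2
    ) * config.leaf_width_mm
    open_leaves = np.abs(leaf_centers) <= config.aperture_half_height_mm
    segments = []
    for k, frac in enumerate(fractions):
        left = np.zeros(config.n_leaves)
        right = np.zeros(config.n_leaves)
        left[open_leaves] = bounds[k]
        right[open_leaves] = bounds[k + 1]
        segments.append(Segment(mu=frac * config.beam_mu, left=left, right=right))
    beam = BeamSpec(gantry_angle=angle, beam_mu=config.beam_mu, segments=tuple(segments))
    # bookkeeping: each boundary attributed to the lowest-index segment
    # whose leaf end sits there (shared boundaries go to the earlier one)
    truth = []
    for li in np.flatnonzero(open_leaves):
        for bi, bx in enumerate(bounds):
            seg_idx = min(max(bi - 1, 0), len(fractions) - 1)
            truth.append(
                (int(li + 1), float(bx), seg_idx, fractions[seg_idx])
            )
    return beam, truth


def _ellipsoid_contours(
    center: tuple[float, float, float],
    radii: tuple[float, float, float],
    y_slices: np.ndarray,
    n_vertices: int = 48,
) -> list[tuple[float, np.ndarray]]:
    cx, cy, cz = center
    ax, ay, az = radii
    contours = []
    phi = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    for y in y_slices:
        t = (y - cy) / ay
        if abs(t) >= 0.999:
            continue
        scale = np.sqrt(1.0 - t * t)
        xs = cx + ax * scale * np.cos(phi)
        zs = cz + az * scale * np.sin(phi)
        contours.append((float(y), np.stack([xs, zs], axis=1)))
    return contours


def gen_plan_fixture(config: SyntheticConfig) -> PlanFixture:
    """Five-beam plan with internally consistent planes, grids and truth.

    The toy forward model is fluence (from the planned plane, divergently
    projected) times an exponential depth factor; per-beam 3D grids sum
    to the total exactly, diode measurements are the planned plane times
    1 + the injected error field sampled on the diode lattice.
    """
    geometry = config.geometry
    e_true = _blob_error(config)
    half = config.plane_half_size_mm
    plane_axis = np.arange(-half, half + 0.5, 1.0)

    n_d = int(round(2 * config.diode_half_size_mm / config.diode_pitch_mm)) + 1
    diode_axis = -config.diode_half_size_mm + config.diode_pitch_mm * np.arange(n_d)
    g = config.grid_half_size_mm
    grid_axis = np.arange(-g, g + config.grid_spacing_mm / 2, config.grid_spacing_mm)

    beams, planned_planes, measured_planes, simaps, beam_grids, truths = (
        [], [], [], [], [], []
    )
    zz, yy, xx = np.meshgrid(grid_axis, grid_axis, grid_axis, indexing="ij")
    for angle in config.beam_angles:
        beam, truth = _make_beam(config, float(angle))
        beams.append(beam)
        truths.append(truth)

        simap_vals = _fluence_plane(config, beam, config.simap_penumbra_mm, plane_axis)
        simaps.append(
            SegmentIntensityMap(
                plane=DosePlane2D(
                    origin=(-half, -half), spacing=(1.0, 1.0), values=simap_vals
                ),
                n_leaves=config.n_leaves,
                leaf_width=config.leaf_width_mm,
            )
        )

        plane_vals = (
            _fluence_plane(config, beam, config.plane_penumbra_mm, plane_axis)
            * config.beam_mu
            * config.dose_per_mu_gy
        )
        planned = DosePlane2D(origin=(-half, -half), spacing=(1.0, 1.0), values=plane_vals)
        planned_planes.append(planned)

        uu_d, vv_d = np.meshgrid(diode_axis, diode_axis)
        plane_interp = RegularGridInterpolator(
            (plane_axis, plane_axis), plane_vals, method="linear",
            bounds_error=False, fill_value=0.0,
        )
        diode_planned = plane_interp(
            np.stack([vv_d.ravel(), uu_d.ravel()], axis=1)
        ).reshape(vv_d.shape)
        measured_planes.append(
            DosePlane2D(
                origin=(-config.diode_half_size_mm, -config.diode_half_size_mm),
                spacing=(config.diode_pitch_mm, config.diode_pitch_mm),
                values=diode_planned * (1.0 + e_true(uu_d, vv_d)),
            )
        )

        theta = np.deg2rad(angle)
        zb = xx * np.sin(theta) + zz * np.cos(theta)
        xb = xx * np.cos(theta) - zz * np.sin(theta)
        mag = geometry.sad / (geometry.sad - zb)
        u_proj = xb * mag
        v_proj = yy * mag
        fluence = plane_interp(
            np.stack([v_proj.ravel(), u_proj.ravel()], axis=1)
        ).reshape(xx.shape)
        dose = fluence * np.exp(zb / config.depth_tau_mm)
        beam_grids.append(
            DoseGrid3D(
                origin=(-g, -g, -g),
                spacing=(config.grid_spacing_mm,) * 3,
                values=dose,
                scope="per-beam",
            )
        )

    total = functools.reduce(operator.add, (b.values for b in beam_grids))
    total_grid = DoseGrid3D(
        origin=(-g, -g, -g), spacing=(config.grid_spacing_mm,) * 3,
        values=total, scope="total",
    )

    structures = StructureSet(
        structures={
            "PTV": _ellipsoid_contours((0, 0, 0), (28, 32, 25), grid_axis),
            "CTV": _ellipsoid_contours((0, 0, 0), (23, 27, 20), grid_axis),
            "Rectum": _ellipsoid_contours((0, 0, -38), (16, 45, 13), grid_axis),
            "Bladder": _ellipsoid_contours((0, 30, 28), (22, 28, 18), grid_axis),
        }
    )
    plan = PlanSpec(
        beams=tuple(beams),
        prescription_dose=config.prescription_gy,
        fractions=config.fractions,
    )
    return PlanFixture(
        plan=plan,
        planned_planes=planned_planes,
        measured_planes=measured_planes,
        simaps=simaps,
        beam_grids=beam_grids,
        total_grid=total_grid,
        structures=structures,
        error_field=e_true,
        true_abutments=truths,
        geometry=geometry,
    )


def write_plan_fixture(fixture: PlanFixture, outdir: str | Path) -> None:
    """Write the fixture to disk in the package's standard formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_rtplan(fixture.plan, out / "rtplan.dcm")
    write_rtstruct(fixture.structures, out / "rtstruct.dcm")
    write_rtdose(fixture.total_grid, out / "rtdose_total.dcm")
    for i, (planned, measured, simap, grid) in enumerate(
        zip(
            fixture.planned_planes,
            fixture.measured_planes,
            fixture.simaps,
            fixture.beam_grids,
        ),
        start=1,
    ):
        write_text_plane(planned, out / f"planned_beam{i}.txt")
        write_text_plane(measured, out / f"measured_beam{i}.txt")
        write_text_plane(simap.plane, out / f"simap_beam{i}.txt")
        write_rtdose(grid, out / f"rtdose_beam{i}.dcm")
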