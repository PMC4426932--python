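"""Dose-distribution comparison and plan evaluation metrics.

Implements the gamma index (global normalization to the reference
maximum), signed relative dose-difference maps, distance-to-agreement
maps, DVH indices (ICRU-83 Dx convention: dose received by at least x%
of the structure volume) and the paired Student's t-test used to compare
per-case pass rates.

The gamma search evaluates the evaluated distribution on a fine offset
lattice (step <= DTA/10 by default) within a radius of 3x the DTA
criterion; a brute-force oracle in the test-suite validates this
shortcut.  Gamma is not symmetric in its arguments: the reference
distribution supplies both the grid and the normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from scipy import stats
from scipy.interpolate import RegularGridInterpolator

from .exceptions import GeometryError, ValidationError
from .rt_io import DoseGrid3D, DosePlane2D, StructureSet

__all__ = [
    "GammaResult",
    "DVHIndices",
    "PairedComparison",
    "gamma_map",
    "dose_difference_map",
    "dta_map",
    "dvh_indices",
    "rasterize_structure",
    "paired_comparison",
]

_PASS_TOL = 1e-9  # gamma == 1 is a boundary pass


def _axes_and_values(dist: DosePlane2D | DoseGrid3D) -> tuple[list[np.ndarray], np.ndarray]:
    """Grid axes in array-index order plus the value array."""
    if isinstance(dist, DosePlane2D):
        return [dist.v, dist.u], dist.values
    return [dist.axis(2), dist.axis(1), dist.axis(0)], dist.values


def _offsets(ndim: int, step: float, radius: float) -> np.ndarray:
    k = int(np.floor(radius / step))
    axes = [np.arange(-k, k + 1) * step] * ndim
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, ndim)
    keep = np.einsum("ij,ij->i", grid, grid) <= radius**2 + 1e-12
    return grid[keep]


@dataclass
class GammaResult:
    gamma: np.ndarray
    pass_rate: float
    criteria: tuple[float, float, float]  # (dose %, DTA mm, threshold %)
    evaluated_mask: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.pass_rate <= 100.0:
            raise ValidationError("pass rate must lie in [0, 100]")


def gamma_map(
    reference: DosePlane2D | DoseGrid3D,
    evaluated: DosePlane2D | DoseGrid3D,
    dose_pct: float,
    dta_mm: float,
    threshold_pct: float = 10.0,
    search_step: float | None = None,
    search_radius: float | None = None,
) -> GammaResult:
    """Gamma index of ``evaluated`` against ``reference``.

    gamma(r) = min over search points s of
        sqrt( ((D_e(r+s) - D_r(r)) / (dose_pct% of max D_r))^2
              + (|s| / dta_mm)^2 )

    computed on every reference grid point; the pass rate counts
    reference points at or above ``threshold_pct`` of the reference
    maximum with gamma <= 1.  Search lattice step defaults to dta/10 and
    the search radius to 3*dta (set ``search_step`` coarser for 3D grids
    if runtime matters).
    """
    if type(reference) is not type(evaluated):
        raise ValidationError("reference and evaluated must be the same kind")
    ref_axes, ref_values = _axes_and_values(reference)
    ev_axes, ev_values = _axes_and_values(evaluated)
    rmax = ref_values.max()
    if rmax <= 0:
        raise ValidationError("reference maximum must be positive")
    step = dta_mm / 10.0 if search_step is None else search_step
    radius = 3.0 * dta_mm if search_radius is None else search_radius
    delta_d = dose_pct / 100.0 * rmax

    interp = RegularGridInterpolator(
        ev_axes, ev_values, method="linear", bounds_error=False, fill_value=np.nan
    )
    mesh = np.meshgrid(*ref_axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    ref_d = ref_values.ravel()

    best = np.full(ref_d.shape, np.inf)
    any_valid = np.zeros(ref_d.shape, dtype=bool)
    for off in _offsets(len(ref_axes), step, radius):
        dist2 = float(off @ off) / dta_mm**2
        ev = interp(pts + off)
        ok = np.isfinite(ev)
        if not ok.any():
            continue
        g2 = ((ev[ok] - ref_d[ok]) / delta_d) ** 2 + dist2
        np.minimum.at(best, np.flatnonzero(ok), g2)
        any_valid |= ok
    if not any_valid.any():
        raise GeometryError("reference and evaluated grids do not overlap")
    gamma = np.sqrt(best)
    gamma[~any_valid] = np.nan
    gamma = gamma.reshape(ref_values.shape)

    eval_mask = (ref_values >= threshold_pct / 100.0 * rmax) & np.isfinite(gamma)
    if not eval_mask.any():
        raise ValidationError("no reference points above the low-dose threshold")
    pass_rate = 100.0 * float(np.mean(gamma[eval_mask] <= 1.0 + _PASS_TOL))
    return GammaResult(
        gamma=gamma,
        pass_rate=pass_rate,
        criteria=(dose_pct, dta_mm, threshold_pct),
        evaluated_mask=eval_mask,
    )


def dose_difference_map(
    reference: DosePlane2D | DoseGrid3D,
    evaluated: DosePlane2D | DoseGrid3D,
    threshold_pct: float = 10.0,
) -> np.ndarray:
    """Signed relative dose difference in percent of the reference maximum.

    (evaluated - reference) / max(reference) x 100 on the reference grid,
    zero below the low-dose threshold.
    """
    ref_axes, ref_values = _axes_and_values(reference)
    ev_axes, ev_values = _axes_and_values(evaluated)
    interp = RegularGridInterpolator(
        ev_axes, ev_values, method="linear", bounds_error=False, fill_value=np.nan
    )
    mesh = np.meshgrid(*ref_axes, indexing="ij")
    ev = interp(np.stack([m.ravel() for m in mesh], axis=1)).reshape(ref_values.shape)
    rmax = ref_values.max()
    mask = (ref_values >= threshold_pct / 100.0 * rmax) & np.isfinite(ev)
    out = np.zeros_like(ref_values)
    out[mask] = (ev[mask] - ref_values[mask]) / rmax * 100.0
    return out


def dta_map(
    reference: DosePlane2D | DoseGrid3D,
    evaluated: DosePlane2D | DoseGrid3D,
    search_radius: float,
    search_step: float | None = None,
    dose_tol_fraction: float = 0.001,
) -> np.ndarray:
    """Distance to agreement (mm) per reference point, capped at the radius.

    Agreement at offset s means the evaluated dose there equals the
    reference point's dose within interpolation: either within
    ``dose_tol_fraction`` of the reference maximum, or the residual
    changes sign relative to the on-site residual (an equal-dose surface
    crossing).  Flat regions with unequal dose saturate at the cap.
    """
    ref_axes, ref_values = _axes_and_values(reference)
    ev_axes, ev_values = _axes_and_values(evaluated)
    step = min(min(np.diff(a).min() for a in ref_axes) / 2.0, search_radius) \
        if search_step is None else search_step
    tol = dose_tol_fraction * ref_values.max()

    interp = RegularGridInterpolator(
        ev_axes, ev_values, method="linear", bounds_error=False, fill_value=np.nan
    )
    mesh = np.meshgrid(*ref_axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    ref_d = ref_values.ravel()

    offs = _offsets(len(ref_axes), step, search_radius)
    radii = np.sqrt(np.einsum("ij,ij->i", offs, offs))
    order = np.argsort(radii)
    offs, radii = offs[order], radii[order]

    onsite = interp(pts) - ref_d
    dta = np.full(ref_d.shape, float(search_radius))
    done = np.zeros(ref_d.shape, dtype=bool)
    for off, r in zip(offs, radii):
        if done.all():
            break
        resid = interp(pts + off) - ref_d
        agree = np.isfinite(resid) & (
            (np.abs(resid) <= tol)
            | (np.isfinite(onsite) & (resid * onsite < 0))
        )
        newly = agree & ~done
        dta[newly] = r
        done |= newly
    return dta.reshape(ref_values.shape)


# ---------------------------------------------------------------------------
# DVH


@dataclass(frozen=True)
class DVHIndices:
    """Dose-volume indices in Gy (Dx) and % volume (VxGy)."""

    d98: float
    d2: float
    d95: float
    dmean: float
    v_gy: dict[str, float]  # e.g. {"V65Gy": 12.3, "V40Gy": 31.0}

    def __post_init__(self) -> None:
        if not (self.d2 >= self.d95 >= self.d98):
            raise ValidationError("expected D2 >= D95 >= D98")


def dvh_indices(
    dose: DoseGrid3D,
    mask: np.ndarray,
    v_thresholds_gy: Sequence[float] = (65.0, 40.0),
) -> DVHIndices:
    """DVH indices over the masked voxels of a 3D dose grid.

    Dx = dose received by at least x% of the structure volume, read off
    the linearly interpolated cumulative DVH; VxGy = 100 x fraction of
    structure voxels with dose >= x Gy.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.values.shape:
        raise ValidationError("mask shape must match the dose grid")
    doses = dose.values[mask]
    if doses.size == 0:
        raise ValidationError("structure mask is empty")

    def dx(x_pct: float) -> float:
        return float(np.quantile(doses, 1.0 - x_pct / 100.0, method="linear"))

    v_gy = {
        f"V{g:g}Gy": 100.0 * float(np.mean(doses >= g)) for g in v_thresholds_gy
    }
    return DVHIndices(
        d98=dx(98.0), d2=dx(2.0), d95=dx(95.0), dmean=float(doses.mean()), v_gy=v_gy
    )


def rasterize_structure(
    structures: StructureSet,
    name: str,
    grid: DoseGrid3D,
) -> np.ndarray:
    """Voxel-center-in-polygon mask (even-odd rule) for one structure.

    Contours are matched to the nearest grid slice along the longitudinal
    axis (within half a voxel); several contours on one slice combine by
    exclusive-or, so holes and islands follow the even-odd rule.
    """
    contours = structures[name]
    x = grid.axis(0)
    y = grid.axis(1)
    z = grid.axis(2)
    zz, xx = np.meshgrid(z, x, indexing="ij")  # per-slice (z, x) voxel centers
    mask = np.zeros(grid.values.shape, dtype=bool)
    for y_slice, poly in contours:
        iy = int(np.argmin(np.abs(y - y_slice)))
        if abs(y[iy] - y_slice) > grid.spacing[1] / 2.0 + 1e-9:
            continue
        ring = shapely.Polygon(np.asarray(poly, dtype=float))
        inside = shapely.contains_xy(ring, xx.ravel(), zz.ravel()).reshape(zz.shape)
        mask[:, iy, :] ^= inside
    return mask


# ---------------------------------------------------------------------------
# Paired comparison


@dataclass(frozen=True)
class PairedComparison:
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError("p-value must lie in [0, 1]")


def paired_comparison(a: Sequence[float], b: Sequence[float]) -> PairedComparison:
    """Two-tailed paired Student's t-test on a - b.

    Reports per-group means and sample SDs (ddof=1).  Identical groups
    give t = 0, p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("groups must be 1D and of equal length")
    if a.size < 2:
        raise ValidationError("need at least two pairs")
    diffs = a - b
    if np.all(diffs == diffs[0]) and diffs[0] == 0.0:
        t_stat, p_val = 0.0, 1.0
    else:
        res = stats.ttest_rel(a, b)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return PairedComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        t=t_stat,
        p=p_val,
        n=int(a.size),
    )
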