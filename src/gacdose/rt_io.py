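"""Standard-format I/O and the shared beam/patient geometry model.

All lengths are millimetres and all doses Gray.  A single right-handed
patient frame is used throughout the package (IEC 61217 fixed system):

* ``x`` -- lateral (crossplane, the MLC leaf-travel direction at gantry 0),
* ``y`` -- longitudinal (inplane, the leaf-width direction),
* ``z`` -- vertical, pointing from the isocenter toward the source at
  gantry 0.

Gantry angles follow IEC 61217: the source sits at
``(sad*sin(theta), 0, sad*cos(theta))`` for gantry angle ``theta``.
Grids are 0-based, row-major and voxel/pixel-center addressed; dose planes
use the half-open extent ``[origin, origin + shape*spacing)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .exceptions import FormatError, GeometryError, ValidationError

__all__ = [
    "GeometryConstants",
    "DoseGrid3D",
    "DosePlane2D",
    "Segment",
    "BeamSpec",
    "PlanSpec",
    "StructureSet",
    "read_rtdose",
    "write_rtdose",
    "read_text_plane",
    "write_text_plane",
    "read_rtstruct",
    "write_rtstruct",
    "read_rtplan",
    "write_rtplan",
    "project_voxel_to_bev",
]

_RTDOSE_UID = "1.2.840.10008.5.1.4.1.1.481.2"
_RTSTRUCT_UID = "1.2.840.10008.5.1.4.1.1.481.3"
_RTPLAN_UID = "1.2.840.10008.5.1.4.1.1.481.5"


@dataclass(frozen=True)
class GeometryConstants:
    """Machine geometry: SAD 100 cm, EPID at SID 150 cm, 0.40 mm pixels."""

    sad: float = 1000.0
    sid: float = 1500.0
    measurement_depth: float = 100.0
    epid_pixels: tuple[int, int] = (1024, 1024)
    epid_pitch: float = 0.40

    def __post_init__(self) -> None:
        if not (self.sid > self.sad > 0):
            raise ValidationError("geometry requires sid > sad > 0")

    @property
    def magnification(self) -> float:
        """Detector-plane magnification sid/sad."""
        return self.sid / self.sad


@dataclass
class DoseGrid3D:
    """A 3D dose grid in Gy.

    ``values`` is indexed ``[iz, iy, ix]``; ``origin``/``spacing`` are
    ``(x, y, z)`` triplets referring to the first voxel center.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    values: np.ndarray
    scope: str = "total"  # "per-beam" | "total"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValidationError("DoseGrid3D requires a non-empty 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be positive on all axes")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValidationError("dose values must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # (nz, ny, nx)

    def axis(self, i: int) -> np.ndarray:
        """Voxel-center coordinates along axis i (0=x, 1=y, 2=z)."""
        n = self.values.shape[2 - i]
        return self.origin[i] + self.spacing[i] * np.arange(n)


@dataclass
class DosePlane2D:
    """A 2D dose/intensity plane on the isocenter plane.

    ``values`` is indexed ``[iv, iu]`` (rows = inplane v, cols = crossplane
    u); ``origin``/``spacing`` are ``(u, v)`` pairs.
    """

    origin: tuple[float, float]
    spacing: tuple[float, float]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValidationError("DosePlane2D requires a non-empty 2D array")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be positive")
        if np.any(~np.isfinite(self.values)):
            raise ValidationError("plane values must be finite")

    @property
    def u(self) -> np.ndarray:
        return self.origin[0] + self.spacing[0] * np.arange(self.values.shape[1])

    @property
    def v(self) -> np.ndarray:
        return self.origin[1] + self.spacing[1] * np.arange(self.values.shape[0])


@dataclass(frozen=True)
class Segment:
    """One static MLC aperture: its MU and per-leaf-pair leaf positions.

    ``left``/``right`` are arrays of X1/X2 leaf-end positions (mm at
    isocenter) per leaf pair, with left <= right for open pairs.
    """

    mu: float
    left: np.ndarray
    right: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "left", np.asarray(self.left, dtype=float))
        object.__setattr__(self, "right", np.asarray(self.right, dtype=float))
        if self.mu < 0:
            raise ValidationError("segment MU must be >= 0")
        if self.left.shape != self.right.shape:
            raise ValidationError("left/right leaf banks must have equal length")


@dataclass(frozen=True)
class BeamSpec:
    gantry_angle: float
    beam_mu: float
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.gantry_angle < 360.0):
            raise ValidationError("gantry angle must be in [0, 360)")
        object.__setattr__(self, "segments", tuple(self.segments))
        total = sum(s.mu for s in self.segments)
        if abs(total - self.beam_mu) > 1e-6:
            raise ValidationError(
                f"segment MU sum {total} != beam MU {self.beam_mu}"
            )


@dataclass(frozen=True)
class PlanSpec:
    beams: tuple[BeamSpec, ...]
    prescription_dose: float
    fractions: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "beams", tuple(self.beams))
        if len(self.beams) < 1:
            raise ValidationError("a plan needs at least one beam")
        if self.prescription_dose <= 0:
            raise ValidationError("prescription dose must be positive")


@dataclass
class StructureSet:
    """Named structures, each a stack of closed planar polygons.

    Slicing is along the longitudinal (y) axis: each contour is a
    ``(y_slice, vertices)`` pair with ``vertices`` an (N, 2) array of
    (x, z) mm.  Polygons are implicitly closed.
    """

    structures: dict[str, list[tuple[float, np.ndarray]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.structures)) != len(self.structures):
            raise ValidationError("structure names must be unique")
        for name, contours in self.structures.items():
            for y, poly in contours:
                poly = np.asarray(poly, dtype=float)
                if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                    raise ValidationError(f"{name}: contour needs >= 3 (x, z) vertices")

    def names(self) -> list[str]:
        return list(self.structures)

    def __getitem__(self, name: str) -> list[tuple[float, np.ndarray]]:
        return self.structures[name]


# ---------------------------------------------------------------------------
# DICOM RT Dose


def _file_meta(sop_class: str, sop_instance: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _base_dataset(sop_class: str, modality: str) -> Dataset:
    ds = Dataset()
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = generate_uid()
    ds.Modality = modality
    ds.PatientName = "QA^Phantom"
    ds.PatientID = "QA"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.file_meta = _file_meta(sop_class, ds.SOPInstanceUID)
    return ds


def write_rtdose(grid: DoseGrid3D, path: str | Path) -> None:
    """Write ``grid`` as a standard RT Dose object.

    Doses are stored as 32-bit unsigned integers with ``DoseGridScaling``
    chosen so the grid maximum fills the integer range; the quantization
    error is at most one scaling quantum.
    """
    if np.any(grid.values < 0) or np.any(~np.isfinite(grid.values)):
        raise ValidationError("dose must be finite and non-negative")
    nz, ny, nx = grid.values.shape
    vmax = float(grid.values.max())
    scaling = vmax / (2**32 - 1) if vmax > 0 else 1e-9

    ds = _base_dataset(_RTDOSE_UID, "RTDOSE")
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.PixelSpacing = [float(grid.spacing[1]), float(grid.spacing[0])]  # row, col
    ds.ImagePositionPatient = [float(v) for v in grid.origin]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [float(grid.spacing[2] * k) for k in range(nz)]
    ds.FrameOfReferenceUID = generate_uid()
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "BEAM" if grid.scope == "per-beam" else "PLAN"
    ds.DoseGridScaling = scaling
    stored = np.round(grid.values / scaling).astype(np.uint32)
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def read_rtdose(path: str | Path) -> DoseGrid3D:
    """Read an RT Dose file into a :class:`DoseGrid3D` (values in Gy)."""
    ds = pydicom.dcmread(str(path))
    if "DoseGridScaling" not in ds:
        raise FormatError("RT Dose object lacks DoseGridScaling")
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    if len(offsets) > 1:
        steps = np.diff(offsets)
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
            raise FormatError("non-uniform frame offsets are not supported")
        dz = float(steps[0])
    else:
        dz = 1.0
    values = ds.pixel_array.astype(float) * float(ds.DoseGridScaling)
    if values.ndim == 2:
        values = values[None]
    dy, dx = (float(v) for v in ds.PixelSpacing)
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    scope = "per-beam" if str(getattr(ds, "DoseSummationType", "PLAN")) == "BEAM" else "total"
    return DoseGrid3D(origin=origin, spacing=(dx, dy, dz), values=values, scope=scope)


# ---------------------------------------------------------------------------
# Text dose planes (TPS coronal-plane export dialect)
#
# Two header lines (origin, spacing), then the matrix row-major:
#   # origin_mm: <u0> <v0>
#   # spacing_mm: <du> <dv>


def write_text_plane(plane: DosePlane2D, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# origin_mm: {plane.origin[0]:.17g} {plane.origin[1]:.17g}\n")
        fh.write(f"# spacing_mm: {plane.spacing[0]:.17g} {plane.spacing[1]:.17g}\n")
        for row in plane.values:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def _parse_header_line(line: str, key: str) -> tuple[float, float]:
    if not line.startswith("#") or key not in line:
        raise FormatError(f"expected header line '# {key}: <a> <b>', got {line!r}")
    parts = line.split(":", 1)[1].replace(",", " ").split()
    if len(parts) != 2:
        raise FormatError(f"header '{key}' must carry two numbers")
    return float(parts[0]), float(parts[1])


def read_text_plane(path: str | Path) -> DosePlane2D:
    """Parse the two-header-line text dose-plane dialect."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise FormatError("text plane needs 2 header lines and a matrix")
    origin = _parse_header_line(lines[0], "origin_mm")
    spacing = _parse_header_line(lines[1], "spacing_mm")
    rows = [ln.replace(",", " ").split() for ln in lines[2:]]
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"ragged rows: widths {sorted(widths)}")
    try:
        values = np.array(rows, dtype=float)
    except ValueError as exc:  # non-numeric token
        raise FormatError(f"non-numeric matrix entry: {exc}") from exc
    return DosePlane2D(origin=origin, spacing=spacing, values=values)


# ---------------------------------------------------------------------------
# DICOM RT Structure Set (standard tags only)


def write_rtstruct(structures: StructureSet, path: str | Path) -> None:
    ds = _base_dataset(_RTSTRUCT_UID, "RTSTRUCT")
    ds.StructureSetLabel = "gacdose"
    roi_seq, contour_seq = [], []
    for number, (name, contours) in enumerate(structures.structures.items(), start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = generate_uid()
        roi.ROIGenerationAlgorithm = "MANUAL"
        roi_seq.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = number
        cs = []
        for y_slice, poly in contours:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            poly = np.asarray(poly, dtype=float)
            c.NumberOfContourPoints = poly.shape[0]
            data: list[float] = []
            for x, z in poly:
                data.extend([float(x), float(y_slice), float(z)])
            c.ContourData = data
            cs.append(c)
        rc.ContourSequence = cs
        contour_seq.append(rc)
    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.save_as(str(path), enforce_file_format=True)


def read_rtstruct(path: str | Path) -> StructureSet:
    ds = pydicom.dcmread(str(path))
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    out: dict[str, list[tuple[float, np.ndarray]]] = {}
    for rc in ds.ROIContourSequence:
        name = names[int(rc.ReferencedROINumber)]
        contours = []
        for c in getattr(rc, "ContourSequence", []):
            pts = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            y_vals = pts[:, 1]
            if not np.allclose(y_vals, y_vals[0], atol=1e-6):
                raise FormatError(f"{name}: contour not planar along the slicing axis")
            contours.append((float(y_vals[0]), pts[:, [0, 2]].copy()))
        out[name] = contours
    return StructureSet(structures=out)


# ---------------------------------------------------------------------------
# DICOM RT Plan (minimal, standard tags; step-and-shoot control points)


def write_rtplan(plan: PlanSpec, path: str | Path) -> None:
    """Write a minimal step-and-shoot RT Plan (standard tags only)."""
    ds = _base_dataset(_RTPLAN_UID, "RTPLAN")
    ds.RTPlanLabel = "gacdose"
    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = plan.fractions
    refs = []
    beams = []
    for bn, beam in enumerate(plan.beams, start=1):
        rb = Dataset()
        rb.ReferencedBeamNumber = bn
        rb.BeamMeterset = float(beam.beam_mu)
        refs.append(rb)

        b = Dataset()
        b.BeamNumber = bn
        b.BeamName = f"B{bn}"
        b.BeamType = "STATIC"
        b.RadiationType = "PHOTON"
        b.FinalCumulativeMetersetWeight = 1.0
        cps = []
        cumulative = 0.0
        for si, seg in enumerate(beam.segments):
            cp = Dataset()
            cp.ControlPointIndex = len(cps)
            cp.CumulativeMetersetWeight = cumulative / beam.beam_mu
            if si == 0:
                cp.GantryAngle = float(beam.gantry_angle)
                cp.GantryRotationDirection = "NONE"
            bld = Dataset()
            bld.RTBeamLimitingDeviceType = "MLCX"
            bld.LeafJawPositions = [float(v) for v in seg.left] + [
                float(v) for v in seg.right
            ]
            cp.BeamLimitingDevicePositionSequence = [bld]
            cps.append(cp)
            cumulative += seg.mu
            cp_end = Dataset()
            cp_end.ControlPointIndex = len(cps)
            cp_end.CumulativeMetersetWeight = cumulative / beam.beam_mu
            cps.append(cp_end)
        b.NumberOfControlPoints = len(cps)
        b.ControlPointSequence = cps
        beams.append(b)
    fg.ReferencedBeamSequence = refs
    ds.FractionGroupSequence = [fg]
    ds.BeamSequence = beams
    # prescription carried on the fraction group dose reference
    dr = Dataset()
    dr.DoseReferenceNumber = 1
    dr.DoseReferenceStructureType = "SITE"
    dr.DoseReferenceType = "TARGET"
    dr.TargetPrescriptionDose = float(plan.prescription_dose)
    ds.DoseReferenceSequence = [dr]
    ds.save_as(str(path), enforce_file_format=True)


def read_rtplan(path: str | Path) -> PlanSpec:
    ds = pydicom.dcmread(str(path))
    fg = ds.FractionGroupSequence[0]
    mus = {
        int(rb.ReferencedBeamNumber): float(rb.BeamMeterset)
        for rb in fg.ReferencedBeamSequence
    }
    beams = []
    for b in ds.BeamSequence:
        beam_mu = mus[int(b.BeamNumber)]
        cps = list(b.ControlPointSequence)
        gantry = float(cps[0].GantryAngle)
        segments = []
        for i in range(0, len(cps) - 1, 2):
            w0 = float(cps[i].CumulativeMetersetWeight)
            w1 = float(cps[i + 1].CumulativeMetersetWeight)
            bld = cps[i].BeamLimitingDevicePositionSequence[0]
            pos = np.asarray(bld.LeafJawPositions, dtype=float)
            n = pos.size // 2
            segments.append(
                Segment(mu=(w1 - w0) * beam_mu, left=pos[:n], right=pos[n:])
            )
        # repair rounding so segment MUs sum exactly to the beam MU
        total = sum(s.mu for s in segments)
        if segments and total > 0 and abs(total - beam_mu) > 0:
            segments[-1] = replace(
                segments[-1], mu=segments[-1].mu + (beam_mu - total)
            )
        beams.append(BeamSpec(gantry_angle=gantry, beam_mu=beam_mu, segments=tuple(segments)))
    presc = 1.0
    if "DoseReferenceSequence" in ds:
        presc = float(ds.DoseReferenceSequence[0].TargetPrescriptionDose)
    return PlanSpec(
        beams=tuple(beams),
        prescription_dose=presc,
        fractions=int(fg.NumberOfFractionsPlanned),
    )


# ---------------------------------------------------------------------------
# Beam's-eye-view projection


def project_voxel_to_bev(
    point: Sequence[float] | np.ndarray,
    gantry_angle: float,
    geometry: GeometryConstants = GeometryConstants(),
) -> tuple[np.ndarray, np.ndarray]:
    """Project patient-frame point(s) onto the BEV isocenter plane.

    The point is rotated into the beam frame (IEC 61217 gantry rotation
    about the isocenter) and then divergently projected from the source,
    which lies at distance ``sad`` along the beam axis:

        u = x_b * sad / (sad - z_b),   v = y_b * sad / (sad - z_b)

    where ``z_b`` is the beam-frame coordinate toward the source.  Accepts
    a single (3,) point or an (..., 3) array; returns (u, v) arrays.
    """
    p = np.asarray(point, dtype=float)
    if p.shape[-1] != 3:
        raise ValidationError("point must have three components (x, y, z)")
    theta = np.deg2rad(gantry_angle)
    x, y, z = p[..., 0], p[..., 1], p[..., 2]
    xb = x * np.cos(theta) - z * np.sin(theta)
    zb = x * np.sin(theta) + z * np.cos(theta)
    denom = geometry.sad - zb
    if np.any(denom <= 0):
        raise GeometryError("point at or behind the source (z_b >= sad)")
    mag = geometry.sad / denom
    return xb * mag, y * mag
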