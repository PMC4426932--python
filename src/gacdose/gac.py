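"""Gantry-angle-correction (GAC) lookup tables.

A GAC table stores, per measured gantry angle and per abutment node
(leaf row x abutment position), the fractional dose change of the
abutment line relative to the gantry-0 reference:

    delta(theta, leaf, x) = slope * (R(theta) - R(0))

where R is the non-gap pixel ratio (A/B x 100) and ``slope`` comes from
the film calibration.  Queries interpolate linearly between abutment
nodes of the same leaf (constant extrapolation beyond the outermost
nodes) and linearly on the circle between the two adjacent measured
angles; leaf rows are physically independent and never interpolated
across.  The table is purely empirical — it does not model the
gravity-induced leaf sag that causes the effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .calibration import DoseConversion
from .epid_nongap import NonGapResult
from .exceptions import ConfigurationError, TableLookupError, ValidationError

__all__ = ["GACTable", "build_gac_table", "gac_at"]

_ANGLE_TOL = 1e-9


@dataclass
class GACTable:
    """Fractional dose deltas on (angle, leaf, abutment-x) nodes."""

    angles: np.ndarray  # sorted, unique, in [0, 360)
    leaf_indices: np.ndarray
    x_nodes: np.ndarray
    delta: np.ndarray  # shape (n_angles, n_leaves, n_x)
    reference_angle: float = 0.0

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.leaf_indices = np.asarray(self.leaf_indices, dtype=int)
        self.x_nodes = np.asarray(self.x_nodes, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        if np.any(self.angles < 0) or np.any(self.angles >= 360):
            raise ValidationError("angles must lie in [0, 360)")
        if np.any(np.diff(self.angles) <= 0):
            raise ValidationError("angles must be sorted and unique")
        expected = (self.angles.size, self.leaf_indices.size, self.x_nodes.size)
        if self.delta.shape != expected:
            raise ValidationError(f"delta shape {self.delta.shape} != {expected}")
        ref = np.flatnonzero(np.isclose(self.angles, self.reference_angle))
        if ref.size and np.any(self.delta[ref[0]] != 0.0):
            raise ValidationError("delta at the reference angle must be zero")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "angles": self.angles.tolist(),
            "leaf_indices": self.leaf_indices.tolist(),
            "x_nodes": self.x_nodes.tolist(),
            "delta": self.delta.tolist(),
            "reference_angle": self.reference_angle,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GACTable":
        payload = json.loads(Path(path).read_text())
        return cls(
            angles=np.asarray(payload["angles"]),
            leaf_indices=np.asarray(payload["leaf_indices"]),
            x_nodes=np.asarray(payload["x_nodes"]),
            delta=np.asarray(payload["delta"]),
            reference_angle=float(payload["reference_angle"]),
        )

    def angle_frame(self, angle: float) -> pd.DataFrame:
        """Per-angle CSV-ready table (leaf, x_mm, delta)."""
        i = np.flatnonzero(np.isclose(self.angles, angle % 360.0))
        if i.size == 0:
            raise TableLookupError(f"angle {angle} not in the table")
        leaves = np.repeat(self.leaf_indices, self.x_nodes.size)
        xs = np.tile(self.x_nodes, self.leaf_indices.size)
        return pd.DataFrame(
            {"leaf": leaves, "x_mm": xs, "delta": self.delta[i[0]].ravel()}
        )


def build_gac_table(
    nongap_by_angle: Mapping[float, NonGapResult],
    conv: DoseConversion,
) -> GACTable:
    """Build the lookup table from per-angle non-gap results.

    Per node, ``delta(theta) = slope * (ratio(theta) - ratio(0))`` — a
    fraction; the reference-angle row is identically zero.  All results
    must share the abutment grid and include the 0 deg reference.
    """
    normalized = {float(a) % 360.0: r for a, r in nongap_by_angle.items()}
    ref_key = None
    for a in normalized:
        if abs(a) < _ANGLE_TOL or abs(a - 360.0) < _ANGLE_TOL:
            ref_key = a
    if ref_key is None:
        raise ConfigurationError("the 0 deg reference result is required")
    ref = normalized[ref_key]
    angles = np.array(sorted(normalized))
    deltas = np.empty((angles.size, *ref.ratio_percent.shape))
    for i, a in enumerate(angles):
        result = normalized[float(a)]
        if not result.grid.matches(ref.grid):
            raise ValidationError(f"grid mismatch at angle {a}")
        deltas[i] = conv.slope * (result.ratio_percent - ref.ratio_percent)
    deltas[np.isclose(angles, ref_key)] = 0.0  # identically zero by construction
    return GACTable(
        angles=angles,
        leaf_indices=ref.grid.leaf_indices,
        x_nodes=ref.grid.abutment_x,
        delta=deltas,
        reference_angle=0.0,
    )


def _angle_weights(angles: np.ndarray, query: float) -> tuple[int, int, float]:
    """Circularly adjacent measured angles bracketing ``query`` + weight."""
    a = query % 360.0
    exact = np.flatnonzero(np.isclose(angles, a, atol=_ANGLE_TOL))
    if exact.size:
        return int(exact[0]), int(exact[0]), 0.0
    i_hi = int(np.searchsorted(angles, a))
    i_lo = i_hi - 1
    if i_hi == angles.size:  # wrap above the last measured angle
        i_hi = 0
    if i_lo < 0:  # wrap below the first measured angle
        i_lo = angles.size - 1
    lo, hi = angles[i_lo], angles[i_hi]
    span = (hi - lo) % 360.0
    if span == 0.0:
        return i_lo, i_hi, 0.0
    w = ((a - lo) % 360.0) / span
    return i_lo, i_hi, float(w)


def gac_at(
    table: GACTable,
    angle: float,
    leaf_index: int,
    x: float | np.ndarray,
) -> float | np.ndarray:
    """Interpolated fractional dose delta at (angle, leaf, x).

    Exact at table nodes; piecewise linear in x with constant
    extrapolation beyond the outermost nodes, and linear on the circle
    between the two adjacent measured angles (wrapping across 360 deg).
    """
    rows = np.flatnonzero(table.leaf_indices == leaf_index)
    if rows.size == 0:
        raise TableLookupError(f"leaf {leaf_index} not in the table")
    leaf_row = int(rows[0])
    i_lo, i_hi, w = _angle_weights(table.angles, angle)
    node_values = (
        (1.0 - w) * table.delta[i_lo, leaf_row] + w * table.delta[i_hi, leaf_row]
    )
    result = np.interp(x, table.x_nodes, node_values)
    return float(result) if np.isscalar(x) else result
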