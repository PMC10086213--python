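"""Cutting-angle derivation and slice planning for the agarose block.

After the rigid ex vivo -> in vivo registration, the specimen block must be
physically re-oriented so that horizontal microtome cuts reproduce the in
vivo axial slice planes.  The required tilt is obtained by a virtual
back-rotation (Rodrigues' rotation formula) of the sectioning-plane normal:
the block normal (world z) is carried through the inverse of the composed
in-vivo-angulation x rigid transform, and the resulting unit vector ``n`` is
expressed as plate *elevation* (tilt of n from world z) and *azimuth*
(direction of the tilt in the horizontal plane).  A third *in-plane* angle
(rotation about the plate normal) is reported for completeness; planar
trimming needs only the first two.

Slice planning mirrors the 4 mm measuring-grid localizer used for the
second ex vivo scan: slice centers every ``spacing`` mm starting half a
spacing from the block face, which makes histology section *k* correspond
directly to MRI slice *k*.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass

import numpy as np

from .imaging_io import (
    DegenerateGeometryError,
    FormatError,
    RigidTransform,
    SectionImage,
    Volume,
)
from .rigid_registration import compose

__all__ = [
    "PlateAngles",
    "SlicePlan",
    "rodrigues_rotate",
    "rotation_matrix_from_axis_angle",
    "compute_plate_angles",
    "plate_rotation_matrix",
    "plan_slices",
    "match_section_to_slice",
]

_ELEVATION_EPS_DEG = 1e-9


@dataclass
class PlateAngles:
    """Angle-plate settings, degrees.

    elevation: tilt of the plate normal away from the world z axis,
    in [0, 180).  azimuth: direction of the tilt, measured counter-clockwise
    from world +x in the horizontal plane, in [-180, 180); 0 by convention
    at zero elevation.  in_plane: residual rotation about the plate normal,
    in [-180, 180) — reported but not needed for planar trimming.
    """

    elevation: float
    azimuth: float
    in_plane: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.elevation < 180.0):
            raise FormatError("elevation must lie in [0, 180) degrees")
        if not (-180.0 <= self.azimuth < 180.0):
            raise FormatError("azimuth must lie in [-180, 180) degrees")
        if not (-180.0 <= self.in_plane < 180.0):
            raise FormatError("in_plane must lie in [-180, 180) degrees")

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "elevation_deg": round(self.elevation, 6),
            "azimuth_deg": round(self.azimuth, 6),
            "in_plane_deg": round(self.in_plane, 6),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


@dataclass
class SlicePlan:
    """Planned slice-center offsets (mm) from the block face along one axis."""

    axis: int
    positions: np.ndarray
    spacing: float = 4.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.spacing <= 0:
            raise FormatError("slice spacing must be positive")
        gaps = np.diff(self.positions)
        if len(gaps) and not (
            np.all(gaps > 0) and np.allclose(gaps, self.spacing, atol=1e-9)
        ):
            raise FormatError(
                "slice positions must be strictly increasing at constant spacing"
            )

    def __len__(self) -> int:
        return len(self.positions)

    def to_tsv(self, path: str | os.PathLike) -> None:
        import pandas as pd

        pd.DataFrame(
            {"slice": np.arange(len(self.positions)), "offset_mm": self.positions}
        ).to_csv(path, sep="\t", index=False)


def rodrigues_rotate(axis, angle: float, v) -> np.ndarray:
    """Rotate vector ``v`` about unit ``axis`` by ``angle`` radians.

    Closed form: ``v cos(t) + (axis x v) sin(t) + axis (axis . v)(1 - cos(t))``.
    Preserves the norm of ``v``.
    """
    axis = np.asarray(axis, dtype=float)
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise DegenerateGeometryError("rotation axis must be non-zero")
    if abs(norm - 1.0) > 1e-9:
        raise DegenerateGeometryError("rotation axis must be a unit vector")
    c, s = math.cos(angle), math.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1.0 - c)


def rotation_matrix_from_axis_angle(axis, angle: float) -> np.ndarray:
    """3x3 rotation matrix for rotation about unit ``axis`` by ``angle`` rad."""
    return np.column_stack(
        [rodrigues_rotate(axis, angle, e) for e in np.eye(3)]
    )


def plate_rotation_matrix(angles: PlateAngles) -> np.ndarray:
    """Rotation realized by the plate set to ``angles``.

    Tilting by (elevation, azimuth) rotates world z onto the target normal
    about the horizontal axis perpendicular to the azimuth direction; the
    in-plane angle then rotates about that normal.  The full matrix
    reconstructs the back-rotation whose angles were derived by
    :func:`compute_plate_angles`.
    """
    theta = math.radians(angles.elevation)
    phi = math.radians(angles.azimuth)
    if angles.elevation < _ELEVATION_EPS_DEG:
        tilt = np.eye(3)
        n = np.array([0.0, 0.0, 1.0])
    else:
        tilt_axis = np.array([-math.sin(phi), math.cos(phi), 0.0])
        tilt = rotation_matrix_from_axis_angle(tilt_axis, theta)
        n = tilt @ np.array([0.0, 0.0, 1.0])
    spin = rotation_matrix_from_axis_angle(n, math.radians(angles.in_plane))
    return spin @ tilt


def _wrap_half_open(deg: float) -> float:
    """Wrap an angle to [-180, 180)."""
    wrapped = (deg + 180.0) % 360.0 - 180.0
    return -180.0 if wrapped >= 180.0 else wrapped


def compute_plate_angles(
    r: RigidTransform,
    in_vivo_angulation: RigidTransform | None = None,
) -> PlateAngles:
    """Derive the angle-plate settings from the rigid registration.

    ``r`` maps ex vivo (block) coordinates to in vivo coordinates; if the
    original in vivo scan was angulated, that correction is composed in
    first.  The back-rotation is the inverse of the composed rotation; the
    sectioning normal is its image of world z.  Guarantee: applying
    :func:`plate_rotation_matrix` to the returned angles maps world z onto
    that normal to < 1e-9 rad, so slicing the re-oriented block along
    world-z planes reproduces the in vivo axial planes.

    At the elevation -> 0 degeneracy the azimuth is reported as 0 and the
    in-plane angle is the z-rotation extracted from the matrix.
    """
    total = r if in_vivo_angulation is None else compose(in_vivo_angulation, r)
    r_back = total.rotation.T  # back-rotation (inverse of a proper rotation)
    z = np.array([0.0, 0.0, 1.0])
    n = r_back @ z
    elevation = math.degrees(math.acos(float(np.clip(n[2], -1.0, 1.0))))
    if elevation < _ELEVATION_EPS_DEG or elevation > 180.0 - 1e-12:
        azimuth = 0.0
        elevation = min(elevation, math.nextafter(180.0, 0.0))
        tilt = plate_rotation_matrix(PlateAngles(elevation, azimuth, 0.0))
    else:
        azimuth = _wrap_half_open(math.degrees(math.atan2(n[1], n[0])))
        tilt = plate_rotation_matrix(PlateAngles(elevation, azimuth, 0.0))
    # residual spin about n: r_back = spin(n, in_plane) @ tilt
    residual = r_back @ tilt.T
    # extract signed angle of the residual rotation about axis n
    cos_a = float(np.clip((np.trace(residual) - 1.0) / 2.0, -1.0, 1.0))
    skew = np.array(
        [
            residual[2, 1] - residual[1, 2],
            residual[0, 2] - residual[2, 0],
            residual[1, 0] - residual[0, 1],
        ]
    )
    sin_a = float(np.dot(skew, n)) / 2.0
    in_plane = _wrap_half_open(math.degrees(math.atan2(sin_a, cos_a)))
    return PlateAngles(elevation=elevation, azimuth=azimuth, in_plane=in_plane)


def plan_slices(block: Volume, spacing_mm: float = 4.0, axis: int = 2) -> SlicePlan:
    """Plan slice centers every ``spacing_mm`` along ``axis`` of the block.

    The first slice is centered half a spacing from the block face;
    ``floor(extent / spacing)`` slices cover the block.
    """
    if spacing_mm <= 0:
        raise FormatError("slice spacing must be positive")
    extent = float(block.extent_mm[axis])
    if extent < spacing_mm:
        raise DegenerateGeometryError(
            f"block extent {extent:.1f} mm along axis {axis} is smaller "
            f"than the slice spacing {spacing_mm:.1f} mm"
        )
    n = int(math.floor(extent / spacing_mm))
    positions = spacing_mm / 2.0 + spacing_mm * np.arange(n)
    return SlicePlan(axis=axis, positions=positions, spacing=spacing_mm)


def match_section_to_slice(
    section: SectionImage, plan: SlicePlan, mri: Volume
) -> int:
    """Match a histology section to its MRI slice via the measuring grid.

    Because the second ex vivo scan is planned on the same 4 mm grid that
    guides the cutting device, section *k* lies at slice-plan position *k*,
    which is MRI slice *k*.  The MRI slice spacing must equal the plan
    spacing (within 1e-6 mm).
    """
    if abs(float(mri.spacing[plan.axis]) - plan.spacing) > 1e-6:
        raise FormatError(
            "grid/slice spacing mismatch: MRI slice spacing "
            f"{mri.spacing[plan.axis]:.6g} mm vs plan spacing {plan.spacing:.6g} mm"
        )
    idx = section.section_index
    if idx >= len(plan.positions):
        raise FormatError(
            f"section_index {idx} outside the {len(plan.positions)}-slice plan"
        )
    if idx >= mri.shape[plan.axis]:
        raise FormatError(f"section_index {idx} outside the MRI volume")
    return idx
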