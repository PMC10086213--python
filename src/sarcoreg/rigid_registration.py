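"""Landmark-driven rigid (rotation + translation) 3D registration.

The ex vivo scan of the agarose-embedded specimen is acquired in an
arbitrary orientation; this module aligns it to the in vivo scan from
user-supplied corresponding landmarks with the closed-form least-squares
rigid fit (Kabsch/Procrustes via SVD, reflection-corrected).  No scaling is
estimated: the transform class is translation + proper rotation only.
Intensity-based refinement is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging_io import (
    DegenerateGeometryError,
    LandmarkSet,
    PairedLandmarks,
    RigidTransform,
    Volume,
)

__all__ = ["RigidFitReport", "estimate_rigid", "apply_rigid", "compose"]


@dataclass
class RigidFitReport:
    """Result of a least-squares rigid fit."""

    transform: RigidTransform
    rms_residual: float  # mm
    n_landmarks: int


def estimate_rigid(pairs: PairedLandmarks) -> RigidFitReport:
    """Least-squares rigid fit moving(source) -> fixed(target).

    Closed-form Kabsch solution: the returned rotation is the proper
    (det=+1) minimizer of ``sum ||R s_i + t - f_i||^2``; if the unconstrained
    SVD optimum is a reflection, the sign of the smallest singular vector is
    flipped.  Residuals are reported as the RMS distance in mm.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 pairs, or a collinear configuration (centered source
        or target points of rank < 2), for which the rotation about the
        common line is unconstrained.
    """
    if pairs.dimensionality != 3:
        raise DegenerateGeometryError("rigid fit requires 3D landmark pairs")
    src = pairs.source.points
    tgt = pairs.target.points
    n = len(src)
    if n < 3:
        raise DegenerateGeometryError(
            f"rigid fit requires at least 3 landmark pairs, got {n}"
        )
    src_mean = src.mean(axis=0)
    tgt_mean = tgt.mean(axis=0)
    src_c = src - src_mean
    tgt_c = tgt - tgt_mean
    for name, pts in (("source", src_c), ("target", tgt_c)):
        if np.linalg.matrix_rank(pts, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
            raise DegenerateGeometryError(
                f"collinear {name} landmarks: rotation is underdetermined"
            )
    h = src_c.T @ tgt_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = tgt_mean - rotation @ src_mean
    residuals = src @ rotation.T + translation - tgt
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    transform = RigidTransform(
        rotation,
        translation,
        fixed_space=pairs.target.space_name or None,
        moving_space=pairs.source.space_name or None,
    )
    return RigidFitReport(transform=transform, rms_residual=rms, n_landmarks=n)


def apply_rigid(
    transform: RigidTransform,
    x: LandmarkSet | Volume,
    reference: Volume | None = None,
):
    """Apply a rigid transform to landmarks or a volume.

    Landmarks are mapped pointwise ``p -> R p + t``.  Volumes are resampled
    onto the fixed grid (``reference`` if given, else the input's own grid):
    each output voxel pulls from the moving volume at the inverse-mapped
    world position, with linear interpolation for scalar data and nearest-
    neighbour for integer label volumes; out-of-field voxels are 0.
    """
    if isinstance(x, LandmarkSet):
        return LandmarkSet(
            transform.fixed_space or x.space_name,
            list(x.labels),
            transform.apply(x.points),
        )
    if not isinstance(x, Volume):
        raise TypeError(f"apply_rigid expects LandmarkSet or Volume, got {type(x)}")
    ref = reference if reference is not None else x
    inv = transform.inverse()
    idx = np.indices(ref.shape).reshape(3, -1).T.astype(float)
    world = ref.world_of_index(idx)
    moving_idx = x.index_of_world(inv.apply(world))
    is_label = np.issubdtype(x.data.dtype, np.integer) or np.issubdtype(
        x.data.dtype, np.bool_
    )
    order = 0 if is_label else 1
    resampled = ndimage.map_coordinates(
        x.data.astype(float if not is_label else x.data.dtype, copy=False),
        moving_idx.T,
        order=order,
        mode="grid-constant",
        cval=0.0,
    ).reshape(ref.shape)
    if is_label:
        resampled = resampled.astype(x.data.dtype)
    return Volume(
        resampled,
        ref.spacing,
        ref.origin,
        ref.direction,
        space_name=transform.fixed_space or ref.space_name,
    )


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Composition ``(a o b)(p) = a(b(p))``."""
    return RigidTransform(
        a.rotation @ b.rotation,
        a.rotation @ b.translation + a.translation,
        fixed_space=a.fixed_space,
        moving_space=b.moving_space,
    )
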