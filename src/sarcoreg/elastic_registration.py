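"""Thin-plate-spline (TPS) nonrigid 2D registration from landmarks.

A digitized section and its matched MRI slice are related by a smooth
nonrigid deformation (fixation, trimming and microtomy artifacts).  Given
corresponding control landmarks, the section is warped onto the slice with
the canonical landmark-interpolating elastic model: the thin-plate spline
with radial kernel ``U(r) = r^2 log r``, which minimizes bending energy
among all interpolants.  At regularization ``lambda = 0`` the warp maps
every control source point exactly onto its target; ``lambda > 0`` trades
interpolation accuracy for smoothness.  All TPS math is carried out in mm,
never pixels, so histology pixel size and MRI spacing interoperate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging_io import (
    DegenerateGeometryError,
    FormatError,
    LandmarkSet,
    PairedLandmarks,
    SectionImage,
)

__all__ = ["TPSWarp", "fit_tps", "warp_points", "warp_image", "tps_kernel"]

logger = logging.getLogger(__name__)


def tps_kernel(r: np.ndarray) -> np.ndarray:
    """TPS radial basis ``U(r) = r^2 log r`` with ``U(0) = 0``."""
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = r[pos] ** 2 * np.log(r[pos])
    return out


@dataclass
class TPSWarp:
    """A fitted 2D thin-plate-spline map source -> target (mm).

    The map is ``f(x) = c + B x + sum_i w_i U(|x - s_i|)`` with affine part
    ``affine_part = [c | B]`` (2x3) and kernel weights ``w_i`` (n x 2).  The
    weights satisfy the TPS side conditions (they sum to zero and are
    orthogonal to the control coordinates), which makes the map affine-
    reproducing: affinely related landmark sets yield zero bending.
    """

    control_source: np.ndarray  # (n, 2)
    control_target: np.ndarray  # (n, 2)
    affine_part: np.ndarray  # (2, 3): column 0 constant, columns 1:3 linear
    kernel_weights: np.ndarray  # (n, 2)
    regularization: float = 0.0

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return tps_evaluate(self, points)

    def side_condition_residual(self) -> float:
        """Max abs residual of the side conditions sum(w)=0, sum(w x)=0."""
        p = np.column_stack([np.ones(len(self.control_source)), self.control_source])
        return float(np.abs(p.T @ self.kernel_weights).max())

    def bending_energy(self) -> float:
        """Integral bending energy (up to the 8*pi constant): tr(W^T K W)."""
        k = tps_kernel(
            np.linalg.norm(
                self.control_source[:, None, :] - self.control_source[None, :, :],
                axis=-1,
            )
        )
        return float(np.trace(self.kernel_weights.T @ k @ self.kernel_weights))

    def inverse_approximation(self) -> "TPSWarp":
        """TPS fitted in the swapped direction (target -> source).

        An exact closed-form inverse of a TPS does not exist; the swapped
        fit is deterministic and adequate at the smoothness scale of
        section deformations.
        """
        return fit_tps(
            _pairs_from_arrays(self.control_target, self.control_source),
            regularization=self.regularization,
        )


def _pairs_from_arrays(src: np.ndarray, tgt: np.ndarray) -> PairedLandmarks:
    labels = [f"c{i}" for i in range(len(src))]
    return PairedLandmarks(
        LandmarkSet("source", labels, src), LandmarkSet("target", labels, tgt)
    )


def fit_tps(pairs: PairedLandmarks, regularization: float = 0.0) -> TPSWarp:
    """Fit a 2D TPS mapping the paired source landmarks onto the targets.

    Solves the standard bordered linear system

        [K + lam*I  P] [W]   [T]
        [P^T        0] [A] = [0]

    with ``K_ij = U(|s_i - s_j|)`` and ``P = [1, x, y]``.  ``lam = 0`` gives
    exact interpolation at the controls.

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 pairs, duplicate source points, or collinear controls
        (singular system at lam = 0).
    """
    if pairs.dimensionality != 2:
        raise DegenerateGeometryError("TPS registration requires 2D landmark pairs")
    if regularization < 0:
        raise FormatError("regularization must be >= 0")
    src = np.asarray(pairs.source.points, dtype=float)
    tgt = np.asarray(pairs.target.points, dtype=float)
    n = len(src)
    if n < 3:
        raise DegenerateGeometryError(
            f"TPS fit requires at least 3 landmark pairs, got {n}"
        )
    d = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=-1)
    off_diag = d[~np.eye(n, dtype=bool)]
    if off_diag.size and off_diag.min() < 1e-12:
        raise DegenerateGeometryError("duplicate source control points")
    scale = max(np.abs(src - src.mean(axis=0)).max(), 1.0)
    if np.linalg.matrix_rank(src - src.mean(axis=0), tol=1e-9 * scale) < 2:
        raise DegenerateGeometryError(
            "collinear control points: TPS system is singular"
        )
    k = tps_kernel(d) + regularization * np.eye(n)
    p = np.column_stack([np.ones(n), src])
    lhs = np.zeros((n + 3, n + 3))
    lhs[:n, :n] = k
    lhs[:n, n:] = p
    lhs[n:, :n] = p.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = tgt
    try:
        sol = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometryError(f"singular TPS system: {exc}") from exc
    weights = sol[:n]
    affine = sol[n:].T  # (2, 3): [c | B]
    return TPSWarp(
        control_source=src,
        control_target=tgt,
        affine_part=affine,
        kernel_weights=weights,
        regularization=regularization,
    )


def tps_evaluate(warp: TPSWarp, points: np.ndarray) -> np.ndarray:
    """Evaluate the TPS map at an (m, 2) array of mm points."""
    x = np.atleast_2d(np.asarray(points, dtype=float))
    u = tps_kernel(
        np.linalg.norm(x[:, None, :] - warp.control_source[None, :, :], axis=-1)
    )
    out = (
        warp.affine_part[:, 0]
        + x @ warp.affine_part[:, 1:].T
        + u @ warp.kernel_weights
    )
    return out[0] if np.asarray(points).ndim == 1 else out


def warp_points(warp: TPSWarp, landmarks: LandmarkSet) -> LandmarkSet:
    """Forward-map a 2D landmark set through the warp; labels preserved."""
    if landmarks.dimensionality != 2:
        raise FormatError("warp_points requires 2D landmarks")
    return LandmarkSet(
        landmarks.space_name, list(landmarks.labels), tps_evaluate(warp, landmarks.points)
    )


def warp_image(
    warp: TPSWarp,
    section: SectionImage,
    target_shape: tuple[int, int],
    target_pixel_size: float,
    folding_threshold: float = 0.01,
) -> SectionImage:
    """Resample a section onto a target grid under the warp.

    Inverse-mapped resampling: every target pixel pulls from the source via
    the reverse-direction TPS (the approximate inverse), with linear
    interpolation; out-of-field pixels are 0.  If the inverse map folds
    (negative Jacobian determinant) at more than ``folding_threshold`` of
    the pixels, a warning is recorded in the output's provenance ``meta``
    and emitted — the result is still returned.
    """
    if target_pixel_size <= 0:
        raise FormatError("target pixel size must be positive")
    inv = warp.inverse_approximation()
    rows, cols = np.indices(target_shape).astype(float)
    # pixel (row, col) -> mm (x, y) = (col * px, row * px)
    xy = np.column_stack([cols.ravel() * target_pixel_size,
                          rows.ravel() * target_pixel_size])
    src_xy = tps_evaluate(inv, xy)
    src_cols = src_xy[:, 0] / section.pixel_size
    src_rows = src_xy[:, 1] / section.pixel_size
    coords = np.stack([src_rows, src_cols])

    data = section.data
    if data.ndim == 2:
        out = ndimage.map_coordinates(
            data.astype(float), coords, order=1, mode="grid-constant", cval=0.0
        ).reshape(target_shape)
    else:
        out = np.stack(
            [
                ndimage.map_coordinates(
                    data[..., c].astype(float), coords, order=1,
                    mode="grid-constant", cval=0.0,
                ).reshape(target_shape)
                for c in range(data.shape[2])
            ],
            axis=-1,
        )

    meta = dict(section.meta)
    frac = _negative_jacobian_fraction(src_xy, target_shape)
    if frac > folding_threshold:
        msg = (
            f"inverse warp folds at {100 * frac:.1f}% of target pixels "
            f"(negative Jacobian); result may be unreliable"
        )
        meta["folding_warning"] = msg
        warnings.warn(msg)
        logger.warning(msg)

    return SectionImage(
        out,
        pixel_size=target_pixel_size,
        section_index=section.section_index,
        kind=section.kind,
        meta=meta,
    )


def _negative_jacobian_fraction(
    src_xy: np.ndarray, target_shape: tuple[int, int]
) -> float:
    """Fraction of target pixels where the mapped grid folds."""
    sx = src_xy[:, 0].reshape(target_shape)
    sy = src_xy[:, 1].reshape(target_shape)
    # finite-difference Jacobian of the inverse map on the target lattice
    dx_dr, dx_dc = np.gradient(sx)
    dy_dr, dy_dc = np.gradient(sy)
    det = dx_dc * dy_dr - dx_dr * dy_dc  # (col, row) order is a consistent sign
    # orientation-preserving maps keep one consistent sign; compare to the
    # dominant sign so a globally flipped convention is not flagged
    ref_sign = np.sign(np.median(det))
    if ref_sign == 0:
        return 0.0
    return float(np.mean(det * ref_sign < 0))
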