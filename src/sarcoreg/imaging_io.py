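"""Domain types and file I/O for the co-registration pipeline.

All world coordinates are RAS millimetres, matching NIfTI affine semantics.
Voxel *centers* carry coordinates: the world position of index ``i`` is
``origin + direction @ (spacing * i)``, so index (0,0,0) sits exactly at
``origin``.  Every transform in this package operates in world mm, never in
voxel indices.

Formats handled here:

* NIfTI-1/2 (``.nii``/``.nii.gz``) for 3D volumes, ROI masks and label maps
  (via nibabel);
* TIFF/PNG for digitized sections (via tifffile / imageio);
* CSV (``label,x,y[,z]`` with a ``# space_name:`` header line) for landmarks;
* JSON (4x4 homogeneous matrix, row-major) for rigid transforms.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "SarcoregError",
    "FormatError",
    "DegenerateGeometryError",
    "Volume",
    "SectionImage",
    "LandmarkSet",
    "PairedLandmarks",
    "RigidTransform",
    "ParametricMapStack",
    "CHANNEL_ORDER",
    "CHANNEL_ALIASES",
    "CHANNEL_UNITS",
    "SECTION_KINDS",
    "pair_landmarks",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "read_rigid_json",
    "write_rigid_json",
    "read_section",
    "write_section",
]

#: Fixed order of the eight quantitative mpMRI channels (DWI, IVIM, DCE).
CHANNEL_ORDER: tuple[str, ...] = (
    "ADC", "D_star", "f", "fD_star", "Ktrans", "kep", "ve", "vp",
)

#: Alternate channel spellings accepted on read.  ``iAUC`` (initial area
#: under the enhancement curve) is accepted as an alternate name for the
#: fourth DCE channel slot ``vp``.
CHANNEL_ALIASES: dict[str, str] = {
    "D*": "D_star",
    "fD*": "fD_star",
    "Kep": "kep",
    "Ve": "ve",
    "Vp": "vp",
    "iAUC": "vp",
    "ktrans": "Ktrans",
    "adc": "ADC",
}

#: Reporting units per channel.
CHANNEL_UNITS: dict[str, str] = {
    "ADC": "1e-3 mm^2/s",
    "D_star": "1e-3 mm^2/s",
    "f": "%",
    "fD_star": "1e-3 mm^2/s",
    "Ktrans": "1/min",
    "kep": "1/min",
    "ve": "mL/mL",
    "vp": "a.u.",
}

SECTION_KINDS = ("macroscopic", "histology_HE", "histology_IHC")

_ORTHO_TOL = 1e-6


class SarcoregError(Exception):
    """Base class for errors raised by this package."""


class FormatError(SarcoregError):
    """Malformed or unsupported input file / metadata."""


class DegenerateGeometryError(SarcoregError):
    """Geometric configuration that admits no well-posed solution."""


def _as_float_array(x, shape, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != shape:
        raise FormatError(f"{name} must have shape {shape}, got {a.shape}")
    return a


def _check_rotation(r: np.ndarray, tol: float = _ORTHO_TOL) -> None:
    if not np.allclose(r.T @ r, np.eye(3), atol=tol):
        raise FormatError("rotation matrix is not orthonormal")
    if abs(np.linalg.det(r) - 1.0) > tol:
        raise FormatError("improper rotation (det != +1)")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """A 3D scalar image with world geometry (spacing in mm, RAS)."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray
    space_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(
                f"expected 3D volume, got {self.data.ndim}D payload"
            )
        self.spacing = _as_float_array(self.spacing, (3,), "spacing")
        if np.any(self.spacing <= 0):
            raise FormatError("spacing must be strictly positive")
        self.origin = _as_float_array(self.origin, (3,), "origin")
        self.direction = _as_float_array(self.direction, (3, 3), "direction")
        if not np.allclose(
            self.direction.T @ self.direction, np.eye(3), atol=_ORTHO_TOL
        ):
            raise FormatError("direction matrix is not orthonormal")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (voxel centers)."""
        a = np.eye(4)
        a[:3, :3] = self.direction @ np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    def world_of_index(self, index) -> np.ndarray:
        """World mm position(s) of (fractional) voxel index/indices."""
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        w = idx * self.spacing @ self.direction.T + self.origin
        return w[0] if np.asarray(index).ndim == 1 else w

    def index_of_world(self, point) -> np.ndarray:
        """(Fractional) voxel index/indices of world mm position(s)."""
        p = np.atleast_2d(np.asarray(point, dtype=float))
        idx = (p - self.origin) @ self.direction / self.spacing
        return idx[0] if np.asarray(point).ndim == 1 else idx

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical extent of the voxel grid along each axis, in mm."""
        return self.spacing * np.asarray(self.shape)

    def same_grid(self, other: "Volume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


@dataclass
class SectionImage:
    """A digitized 2D section (macroscopic photo or histology scan).

    In-plane mm coordinates: pixel (row, col) maps to
    ``(x, y) = (col * pixel_size, row * pixel_size)``.
    """

    data: np.ndarray
    pixel_size: float
    section_index: int = 0
    kind: str = "histology_HE"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise FormatError("section image must be 2D grayscale or RGB")
        if self.data.ndim == 3 and self.data.shape[2] not in (3, 4):
            raise FormatError("3D section payload must be RGB(A)")
        if self.pixel_size <= 0:
            raise FormatError("pixel_size must be positive")
        if self.section_index < 0:
            raise FormatError("section_index must be >= 0")
        if self.kind not in SECTION_KINDS:
            raise FormatError(
                f"kind must be one of {SECTION_KINDS}, got {self.kind!r}"
            )

    @property
    def height_mm(self) -> float:
        return self.data.shape[0] * self.pixel_size

    @property
    def width_mm(self) -> float:
        return self.data.shape[1] * self.pixel_size


@dataclass
class LandmarkSet:
    """Labeled points (mm) in a named coordinate space."""

    space_name: str
    labels: list[str]
    points: np.ndarray  # (n, dim), dim in {2, 3}

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] not in (2, 3):
            raise FormatError("points must be an (n, 2) or (n, 3) array")
        if len(self.labels) != len(self.points):
            raise FormatError("labels and points length mismatch")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise FormatError(f"duplicate landmark labels: {dupes}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def dimensionality(self) -> int:
        return self.points.shape[1]

    def subset(self, indices: Sequence[int]) -> "LandmarkSet":
        idx = list(indices)
        return LandmarkSet(
            self.space_name,
            [self.labels[i] for i in idx],
            self.points[idx],
        )


@dataclass
class PairedLandmarks:
    """Corresponding landmarks in two spaces, matched by label."""

    source: LandmarkSet
    target: LandmarkSet

    def __post_init__(self) -> None:
        if self.source.labels != self.target.labels:
            raise FormatError(
                "paired landmark sets must carry identical labels in "
                "identical order; use pair_landmarks() to match by label"
            )
        if self.source.dimensionality != self.target.dimensionality:
            raise FormatError("paired landmark sets differ in dimensionality")

    def __len__(self) -> int:
        return len(self.source)

    @property
    def dimensionality(self) -> int:
        return self.source.dimensionality

    def subset(self, indices: Sequence[int]) -> "PairedLandmarks":
        return PairedLandmarks(self.source.subset(indices), self.target.subset(indices))


def pair_landmarks(source: LandmarkSet, target: LandmarkSet) -> PairedLandmarks:
    """Match two landmark sets by label (target reordered to source order)."""
    missing = set(source.labels) ^ set(target.labels)
    if missing:
        raise FormatError(f"landmark labels not present in both sets: {sorted(missing)}")
    order = [target.labels.index(l) for l in source.labels]
    return PairedLandmarks(source, target.subset(order))


@dataclass
class RigidTransform:
    """Proper rigid transform ``p -> R @ p + t`` in world mm."""

    rotation: np.ndarray
    translation: np.ndarray
    fixed_space: str | None = None
    moving_space: str | None = None

    def __post_init__(self) -> None:
        self.rotation = _as_float_array(self.rotation, (3, 3), "rotation")
        self.translation = _as_float_array(self.translation, (3,), "translation")
        _check_rotation(self.rotation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation,
                              fixed_space=self.moving_space,
                              moving_space=self.fixed_space)


@dataclass
class ParametricMapStack:
    """Eight co-registered quantitative mpMRI maps plus a tumor ROI mask."""

    channels: dict[str, Volume]
    roi: Volume
    units: dict[str, str] = field(default_factory=lambda: dict(CHANNEL_UNITS))

    def __post_init__(self) -> None:
        normalized: dict[str, Volume] = {}
        for name, vol in self.channels.items():
            normalized[CHANNEL_ALIASES.get(name, name)] = vol
        if set(normalized) != set(CHANNEL_ORDER):
            raise FormatError(
                f"channel set must be exactly {CHANNEL_ORDER}, "
                f"got {tuple(normalized)}"
            )
        self.channels = {name: normalized[name] for name in CHANNEL_ORDER}
        for name, vol in self.channels.items():
            if not vol.same_grid(self.roi):
                raise FormatError(f"channel {name} is not on the ROI grid")

    @property
    def channel_order(self) -> tuple[str, ...]:
        return CHANNEL_ORDER

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.roi.shape


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def read_volume(path: str | os.PathLike, space_name: str = "") -> Volume:
    """Read a 3D NIfTI volume; geometry decoded from the affine.

    Rejects non-3D payloads and non-orthonormal direction matrices with an
    explicit :class:`FormatError`.
    """
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"expected 3D volume, got {data.ndim}D payload in {path.name}")
    aff = np.asarray(img.affine, dtype=float)
    m = aff[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    if np.any(spacing <= 0):
        raise FormatError(f"non-positive voxel spacing in {path.name}")
    direction = m / spacing
    if not np.allclose(direction.T @ direction, np.eye(3), atol=1e-4):
        raise FormatError(f"non-orthonormal direction matrix in {path.name}")
    # re-orthonormalize residual float error from the stored affine
    u, _, vt = np.linalg.svd(direction)
    direction = u @ vt
    return Volume(data, spacing, aff[:3, 3], direction, space_name=space_name)


def write_volume(volume: Volume, path: str | os.PathLike) -> None:
    """Write a :class:`Volume` as NIfTI-1; round-trips data bit-exactly."""
    import nibabel as nib

    img = nib.Nifti1Image(volume.data, volume.affine)
    img.header.set_zooms(tuple(volume.spacing))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Landmark CSV
# ---------------------------------------------------------------------------

def read_landmarks(path: str | os.PathLike) -> LandmarkSet:
    """Read a landmark CSV: ``# space_name: <name>`` line, then
    ``label,x,y[,z]`` rows (coordinates in mm, file order preserved)."""
    path = Path(path)
    space_name = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            key, _, value = first.lstrip("# ").partition(":")
            if key.strip() == "space_name":
                space_name = value.strip()
            skip = 1
        else:
            skip = 0
    df = pd.read_csv(path, skiprows=skip)
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if "label" not in cols or "x" not in cols or "y" not in cols:
        raise FormatError(f"landmark CSV must have columns label,x,y[,z]: {path.name}")
    coord_cols = ["x", "y"] + (["z"] if "z" in cols else [])
    coords = df[coord_cols].to_numpy(dtype=float)
    if np.isnan(coords).any():
        raise FormatError(f"mixed dimensionality / missing coordinates in {path.name}")
    return LandmarkSet(space_name, df["label"].astype(str).tolist(), coords)


def write_landmarks(landmarks: LandmarkSet, path: str | os.PathLike) -> None:
    cols = ["x", "y", "z"][: landmarks.dimensionality]
    df = pd.DataFrame(landmarks.points, columns=cols)
    df.insert(0, "label", landmarks.labels)
    with open(path, "w") as fh:
        fh.write(f"# space_name: {landmarks.space_name}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# Rigid-transform JSON
# ---------------------------------------------------------------------------

def read_rigid_json(path: str | os.PathLike) -> RigidTransform:
    """Read a rigid transform stored as a 4x4 homogeneous matrix in JSON.

    Dialect: ``{"matrix": [[...]x4], "fixed_space": str, "moving_space": str}``.
    A rotation block with det <= 0 is rejected as an improper rotation.
    """
    with open(path) as fh:
        payload = json.load(fh)
    m = _as_float_array(payload["matrix"], (4, 4), "matrix")
    if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-9):
        raise FormatError("last row of homogeneous matrix must be [0,0,0,1]")
    r = m[:3, :3]
    if np.linalg.det(r) <= 0:
        raise FormatError("improper rotation (det <= 0) in transform file")
    _check_rotation(r)
    return RigidTransform(
        r, m[:3, 3],
        fixed_space=payload.get("fixed_space"),
        moving_space=payload.get("moving_space"),
    )


def write_rigid_json(transform: RigidTransform, path: str | os.PathLike) -> None:
    payload = {
        "matrix": transform.matrix.tolist(),
        "fixed_space": transform.fixed_space or "fixed",
        "moving_space": transform.moving_space or "moving",
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Section images (TIFF / PNG)
# ---------------------------------------------------------------------------

def read_section(
    path: str | os.PathLike,
    pixel_size: float,
    section_index: int = 0,
    kind: str = "histology_HE",
) -> SectionImage:
    """Read a digitized section from TIFF or PNG.

    RGB images keep 3 channels; grayscale stays single-channel.
    """
    path = Path(path)
    if pixel_size <= 0:
        raise FormatError("pixel_size must be positive")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            data = tifffile.imread(str(path))
        else:
            data = iio.imread(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # unreadable / corrupt file
        raise FormatError(f"unreadable section image {path.name}: {exc}") from exc
    return SectionImage(np.asarray(data), pixel_size, section_index, kind)


def write_section(section: SectionImage, path: str | os.PathLike) -> None:
    path = Path(path)
    data = section.data
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), data)
    else:
        if data.dtype != np.uint8:
            lo, hi = float(np.min(data)), float(np.max(data))
            scale = 255.0 / (hi - lo) if hi > lo else 1.0
            data = ((data - lo) * scale).astype(np.uint8)
        iio.imwrite(str(path), data)
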