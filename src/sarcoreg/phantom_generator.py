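"""Synthetic specimen phantoms with known ground truth.

No imaging or landmark data are publicly deposited for this workflow, so
every pipeline input is emulated here with a recorded ground truth that is
sufficient to score every downstream stage: an in vivo tumor volume with
30-40 contour landmarks, a rigidly re-oriented (optionally concentrically
shrunken) "ex vivo" copy, smoothly deformed 2D "histology" sections with
noisy paired landmarks, and 8-channel parametric map stacks whose four
habitats follow the reported per-region mean +/- SD values.  Every
generator is a pure function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .elastic_registration import TPSWarp, fit_tps, tps_evaluate, warp_image
from .imaging_io import (
    CHANNEL_ORDER,
    FormatError,
    LandmarkSet,
    PairedLandmarks,
    ParametricMapStack,
    RigidTransform,
    SectionImage,
    Volume,
)
from .sectioning_planner import rotation_matrix_from_axis_angle

__all__ = [
    "PhantomTruth",
    "SectionPhantom",
    "TABLE_HABITAT_PARAMS",
    "HABITAT_REGION_NAMES",
    "make_invivo_phantom",
    "make_exvivo_phantom",
    "make_section_phantom",
    "make_map_stack",
    "make_block_roi",
    "random_rigid",
]

#: Default per-habitat (mean, sd) for the 8 channels, regions A-D.
#: Units: ADC/D*/fD* in 1e-3 mm^2/s (scaled), f in %, Ktrans/kep in 1/min,
#: ve in mL/mL (scaled), vp slot carries the alternate DCE channel (a.u.).
TABLE_HABITAT_PARAMS: dict[str, tuple[tuple[float, float], ...]] = {
    # channel: ((mean, sd) for region A, B, C, D)
    "ADC": ((1776.2, 184.0), (1181.7, 93.4), (1647.3, 203.6), (2212.3, 188.3)),
    "D_star": ((34.7, 1.9), (39.4, 6.5), (31.6, 4.3), (35.4, 2.4)),
    "f": ((4.4, 2.1), (8.6, 5.5), (10.1, 5.0), (4.8, 1.0)),
    "fD_star": ((1.2, 0.6), (2.8, 1.4), (2.3, 1.0), (1.3, 0.3)),
    "Ktrans": ((313.2, 130.9), (347.3, 110.4), (112.2, 42.8), (64.2, 61.4)),
    "kep": ((44.2, 15.1), (88.3, 22.6), (22.3, 12.3), (18.6, 10.7)),
    "ve": ((759.8, 360.1), (388.6, 61.5), (710.8, 397.0), (705.9, 724.7)),
    "vp": ((17.6, 6.7), (16.7, 4.3), (6.5, 2.3), (4.8, 4.1)),
}

HABITAT_REGION_NAMES = ("A", "B", "C", "D")


@dataclass
class PhantomTruth:
    """Ground truth recorded by the generators for parameter recovery."""

    rigid_truth: RigidTransform | None = None
    section_warps: dict[int, TPSWarp] | None = None
    landmark_noise_sigma: float = 0.0
    habitat_labels: Volume | None = None
    habitat_params: np.ndarray | None = None  # (n_habitats, 8, 2): mean, sd
    seed: int = 0


@dataclass
class SectionPhantom:
    """A deformed 2D section with paired landmarks and its truth warp."""

    section: SectionImage
    pairs: PairedLandmarks  # source: histology mm; target: MRI-slice mm
    truth_warp: TPSWarp  # maps MRI-slice mm -> histology mm
    landmark_noise_sigma: float
    seed: int


def _smooth_noise(shape, rng: np.random.Generator, sigma_vox: float) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    sd = field.std()
    return field / sd if sd > 0 else field


def make_invivo_phantom(
    shape: tuple[int, int, int] = (48, 48, 32),
    spacing: tuple[float, float, float] = (1.5, 1.5, 2.0),
    tumor_radii_mm: tuple[float, float, float] = (22.0, 16.0, 18.0),
    lobulation: float = 0.25,
    n_landmarks: int = 36,
    seed: int = 0,
) -> tuple[Volume, Volume, LandmarkSet]:
    """Simulate the in vivo anatomy scan of a lobulated soft-tissue tumor.

    A smooth ellipsoid with a low-frequency radial lobulation carries an
    internal smoothed-noise texture; 30-40 landmarks are placed on interior
    intensity contours (mimicking manually annotated tumor-portion
    contours).  Returns (T2-like volume, ROI label volume, landmarks),
    deterministic under the seed.
    """
    if not (30 <= n_landmarks <= 40):
        raise FormatError("n_landmarks must lie in 30..40")
    shape = tuple(int(s) for s in shape)
    spacing_arr = np.asarray(spacing, dtype=float)
    extent = spacing_arr * shape
    radii = np.asarray(tumor_radii_mm, dtype=float)
    if np.any(2 * radii * (1 + lobulation) >= extent):
        raise FormatError("tumor larger than grid: shrink radii or enlarge field")
    rng = np.random.default_rng(seed)
    center = extent / 2.0

    idx = np.indices(shape).astype(float)
    world = idx * spacing_arr[:, None, None, None]
    rel = (world - center[:, None, None, None]) / radii[:, None, None, None]
    ellipsoid = np.sqrt(np.sum(rel**2, axis=0))
    lobes = _smooth_noise(shape, rng, sigma_vox=6.0) * lobulation
    level = ellipsoid + lobes
    # pick the iso-level enclosing the requested (ellipsoid) volume, so the
    # lobulation reshapes the boundary without changing the tumor volume
    target_voxels = int(round(4.0 / 3.0 * math.pi * np.prod(radii) / np.prod(spacing_arr)))
    threshold = float(np.partition(level.ravel(), target_voxels)[target_voxels])
    roi_mask = level < threshold

    texture = _smooth_noise(shape, rng, sigma_vox=2.5)
    data = 0.12 * _smooth_noise(shape, rng, sigma_vox=4.0) + 0.05
    data[roi_mask] = 1.0 + 0.35 * texture[roi_mask]

    volume = Volume(data, spacing_arr, np.zeros(3), np.eye(3), space_name="in_vivo")
    roi = Volume(
        roi_mask.astype(np.int16), spacing_arr, np.zeros(3), np.eye(3),
        space_name="in_vivo",
    )

    # landmarks: interior voxels on texture iso-contours (band around median)
    interior = ndimage.binary_erosion(roi_mask, iterations=2)
    tex_vals = texture[interior]
    med = np.median(tex_vals)
    band = np.abs(texture - med) < 0.15 * tex_vals.std()
    candidates = np.argwhere(interior & band)
    if len(candidates) < n_landmarks:
        candidates = np.argwhere(interior)
    pick = rng.choice(len(candidates), size=n_landmarks, replace=False)
    points = volume.world_of_index(candidates[pick].astype(float))
    landmarks = LandmarkSet(
        "in_vivo", [f"L{i + 1}" for i in range(n_landmarks)], points
    )
    return volume, roi, landmarks


def random_rigid(
    rng: np.random.Generator,
    max_angle_deg: float = 40.0,
    max_translation_mm: float = 10.0,
) -> RigidTransform:
    """Draw a random proper rigid transform (uniform axis, bounded angle)."""
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = math.radians(rng.uniform(-max_angle_deg, max_angle_deg))
    rotation = rotation_matrix_from_axis_angle(axis, angle)
    translation = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return RigidTransform(rotation, translation)


def make_exvivo_phantom(
    invivo: Volume,
    landmarks: LandmarkSet,
    rigid: RigidTransform,
    shrink_factor: float = 1.0,
    seed: int = 0,
) -> tuple[Volume, LandmarkSet]:
    """Re-orient the in vivo phantom into a random "agarose block" pose.

    The specimen's pose in the block is arbitrary, so the ex vivo copy is
    the in vivo volume mapped by ``p -> R (s (p - c)) + c + t`` where ``c``
    is the intensity centroid and ``s`` the optional concentric shrink
    factor modelling slight formalin shrinkage.  Landmarks are transformed
    consistently.  Resampling noise is the only approximation; the exact
    transform is the recorded truth.
    """
    if not (0.8 <= shrink_factor <= 1.0):
        raise FormatError("shrink_factor must lie in [0.8, 1.0]")
    del seed  # deterministic: the transform itself is the only variation
    data = np.asarray(invivo.data, dtype=float)
    weights = np.clip(data, 0, None)
    idx = np.indices(invivo.shape).astype(float)
    total = weights.sum()
    centroid_idx = (
        np.array([float((idx[a] * weights).sum() / total) for a in range(3)])
        if total > 0
        else (np.asarray(invivo.shape, float) - 1) / 2
    )
    c = invivo.world_of_index(centroid_idx)

    def forward(points: np.ndarray) -> np.ndarray:
        return (points - c) * shrink_factor @ rigid.rotation.T + c + rigid.translation

    def backward(points: np.ndarray) -> np.ndarray:
        return ((points - c - rigid.translation) @ rigid.rotation) / shrink_factor + c

    out_idx = np.indices(invivo.shape).reshape(3, -1).T.astype(float)
    sample_world = backward(invivo.world_of_index(out_idx))
    sample_idx = invivo.index_of_world(sample_world)
    resampled = ndimage.map_coordinates(
        data, sample_idx.T, order=1, mode="constant", cval=0.0
    ).reshape(invivo.shape)
    exvivo = Volume(
        resampled,
        invivo.spacing,
        invivo.origin,
        invivo.direction,
        space_name="ex_vivo_1",
    )
    moved = LandmarkSet("ex_vivo_1", list(landmarks.labels), forward(landmarks.points))
    return exvivo, moved


def _control_grid(height_mm: float, width_mm: float, n_per_side: int) -> np.ndarray:
    xs = np.linspace(0.0, width_mm, n_per_side)
    ys = np.linspace(0.0, height_mm, n_per_side)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def make_section_phantom(
    mri_slice: np.ndarray,
    pixel_size: float,
    deformation_amplitude_mm: float = 3.0,
    n_controls_per_side: int = 3,
    n_landmarks: int = 36,
    landmark_noise_sigma: float = 0.0,
    seed: int = 0,
    deformation: str = "tps",
    noise_on: str = "source",
    section_index: int = 0,
) -> SectionPhantom:
    """Simulate a deformed "histology" section of an MRI slice.

    The truth warp maps MRI-slice mm coordinates to histology mm
    coordinates.  ``deformation="tps"`` draws independent N(0, amplitude^2)
    displacements at a coarse control grid (smooth cutting-edge-style
    deformation); ``deformation="affine"`` draws a small random affine map
    of comparable magnitude, which lies in the span of a TPS fitted on any
    non-collinear landmark subset and therefore supports exact parameter
    recovery.  Paired landmarks are (histology position + noise, MRI
    position); annotation noise is isotropic Gaussian per axis on the
    histology side by default (``noise_on="both"`` jitters both sides).
    """
    if deformation_amplitude_mm < 0:
        raise FormatError("deformation amplitude must be >= 0")
    if landmark_noise_sigma < 0:
        raise FormatError("landmark noise sigma must be >= 0")
    if deformation not in ("tps", "affine"):
        raise FormatError("deformation must be 'tps' or 'affine'")
    if noise_on not in ("source", "both"):
        raise FormatError("noise_on must be 'source' or 'both'")
    mri_slice = np.asarray(mri_slice, dtype=float)
    if mri_slice.ndim != 2:
        raise FormatError("mri_slice must be a 2D array")
    rng = np.random.default_rng(seed)
    h_mm = mri_slice.shape[0] * pixel_size
    w_mm = mri_slice.shape[1] * pixel_size

    controls = _control_grid(h_mm, w_mm, n_controls_per_side)
    if deformation == "tps":
        displacements = rng.normal(
            0.0, deformation_amplitude_mm, size=controls.shape
        )
        targets = controls + displacements
    else:
        center = np.array([w_mm / 2.0, h_mm / 2.0])
        half_span = max(w_mm, h_mm) / 2.0
        lin = np.eye(2) + rng.normal(
            0.0, deformation_amplitude_mm / max(half_span, 1e-9), size=(2, 2)
        )
        shift = rng.normal(0.0, deformation_amplitude_mm, size=2)
        targets = (controls - center) @ lin.T + center + shift
    truth_warp = fit_tps(_pairs(controls, targets))

    mri_section = SectionImage(
        mri_slice, pixel_size, section_index=section_index, kind="macroscopic"
    )
    section = warp_image(
        truth_warp, mri_section, mri_slice.shape, pixel_size
    )
    section = SectionImage(
        section.data, pixel_size, section_index=section_index,
        kind="histology_HE", meta=section.meta,
    )

    # landmarks in the central region of the slice (away from the border)
    margin = 0.15
    lm = np.column_stack(
        [
            rng.uniform(margin * w_mm, (1 - margin) * w_mm, size=n_landmarks),
            rng.uniform(margin * h_mm, (1 - margin) * h_mm, size=n_landmarks),
        ]
    )
    histo = tps_evaluate(truth_warp, lm)
    mri_pts = lm.copy()
    if landmark_noise_sigma > 0:
        histo = histo + rng.normal(0, landmark_noise_sigma, size=histo.shape)
        if noise_on == "both":
            mri_pts = mri_pts + rng.normal(0, landmark_noise_sigma, size=mri_pts.shape)
    labels = [f"L{i + 1}" for i in range(n_landmarks)]
    pairs = PairedLandmarks(
        LandmarkSet("histology", labels, histo),
        LandmarkSet("mri_slice", labels, mri_pts),
    )
    return SectionPhantom(
        section=section,
        pairs=pairs,
        truth_warp=truth_warp,
        landmark_noise_sigma=landmark_noise_sigma,
        seed=seed,
    )


def _pairs(src: np.ndarray, tgt: np.ndarray) -> PairedLandmarks:
    labels = [f"c{i}" for i in range(len(src))]
    return PairedLandmarks(
        LandmarkSet("a", labels, src), LandmarkSet("b", labels, tgt)
    )


def make_block_roi(
    shape: tuple[int, int, int] = (24, 24, 10),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> Volume:
    """A filled rectangular ROI block — a convenient clustering substrate."""
    return Volume(
        np.ones(shape, dtype=np.int16), np.asarray(spacing, float),
        np.zeros(3), np.eye(3), space_name="in_vivo",
    )


def _farthest_point_seeds(
    coords: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Farthest-point sampling: well-spread Voronoi seeds -> balanced blobs."""
    chosen = [int(rng.integers(len(coords)))]
    d = np.linalg.norm(coords - coords[chosen[0]], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(coords - coords[nxt], axis=1))
    return coords[chosen]


def make_map_stack(
    roi: Volume,
    n_habitats: int = 4,
    habitat_params: dict[str, tuple[tuple[float, float], ...]] | None = None,
    seed: int = 0,
) -> tuple[ParametricMapStack, Volume, int]:
    """Simulate an 8-channel parametric map stack with spatial habitats.

    The ROI is partitioned into ``n_habitats`` contiguous Voronoi blobs
    (seeded by farthest-point sampling, mimicking coherent habitat fields);
    each voxel's 8 channel values are drawn independently from the
    N(mean, sd) of its habitat.  Channel noise is independent across
    channels — only per-region mean +/- SD are modelled, no covariance.
    Negative draws are clipped at 0 and counted.  Returns
    (stack, habitat-label truth volume, n_clipped).
    """
    params = habitat_params if habitat_params is not None else TABLE_HABITAT_PARAMS
    if not (2 <= n_habitats <= 8):
        raise FormatError("n_habitats must lie in 2..8")
    if set(params) != set(CHANNEL_ORDER):
        raise FormatError(f"habitat_params must cover exactly {CHANNEL_ORDER}")
    for name, per_region in params.items():
        if len(per_region) < n_habitats:
            raise FormatError(f"channel {name}: parameters for {n_habitats} habitats required")
        if any(sd < 0 for _, sd in per_region):
            raise FormatError(f"channel {name}: negative sd")
    rng = np.random.default_rng(seed)
    roi_mask = np.asarray(roi.data) > 0
    if not roi_mask.any():
        raise FormatError("empty ROI")
    coords = np.argwhere(roi_mask).astype(float) * np.asarray(roi.spacing)
    seeds = _farthest_point_seeds(coords, n_habitats, rng)
    assignment = np.argmin(
        np.linalg.norm(coords[:, None, :] - seeds[None, :, :], axis=-1), axis=1
    )
    labels = np.zeros(roi.shape, dtype=np.int16)
    labels[roi_mask] = assignment + 1

    n_clipped = 0
    channels: dict[str, Volume] = {}
    for name in CHANNEL_ORDER:
        data = np.zeros(roi.shape, dtype=float)
        vals = np.empty(len(coords))
        for h in range(n_habitats):
            mean, sd = params[name][h]
            sel = assignment == h
            vals[sel] = rng.normal(mean, sd, size=int(sel.sum()))
        clipped = vals < 0
        n_clipped += int(clipped.sum())
        vals[clipped] = 0.0
        data[roi_mask] = vals
        channels[name] = Volume(
            data, roi.spacing, roi.origin, roi.direction, space_name=roi.space_name
        )
    stack = ParametricMapStack(channels=channels, roi=roi)
    truth = Volume(
        labels, roi.spacing, roi.origin, roi.direction, space_name=roi.space_name
    )
    return stack, truth, n_clipped
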