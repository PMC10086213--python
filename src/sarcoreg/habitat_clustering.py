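"""Voxel-wise multiparametric habitat clustering within the tumor ROI.

The eight co-registered quantitative maps (ADC; IVIM D*, f, fD*; DCE
Ktrans, kep, ve and the fourth DCE channel) are sampled at every tumor-ROI
voxel, z-scored per channel so that channels with wildly different units
enter the classification with equal weight, and partitioned by k-means
(Lloyd's algorithm, k-means++ seeding, default k = 4 habitats matching the
predominant histological patterns).  Spatial coordinates are *not* features:
voxel positions serve only to map the resulting labels back onto the
anatomical (T2) grid.  Per-habitat statistics are reported in native units
and compared channel-by-channel with one-way ANOVA followed by pairwise
t-tests with Holm-Bonferroni step-down adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .imaging_io import (
    CHANNEL_ORDER,
    CHANNEL_UNITS,
    FormatError,
    ParametricMapStack,
    Volume,
)

__all__ = [
    "ClusterResult",
    "RegionStats",
    "Standardizer",
    "extract_features",
    "standardize",
    "kmeans_cluster",
    "map_labels",
    "region_stats",
    "compare_regions",
    "regions_from_stack",
    "cluster_stack",
    "holm_adjust",
    "significance_stars",
]

logger = logging.getLogger(__name__)

#: Figure-legend significance thresholds and their star codes.
STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class ClusterResult:
    """Habitat labels on the anatomy grid plus the fitted centroids."""

    labels: Volume  # 0 outside ROI, 1..k inside
    k: int
    feature_means: np.ndarray  # (k, 8), standardized units, row i = label i+1
    channel_order: tuple[str, ...]
    seed: int
    inertia: float
    centroids_native: np.ndarray | None = None  # (k, 8), native units
    n_dropped_voxels: int = 0


@dataclass
class RegionStats:
    """Per-region x channel mean, SD and voxel count in native units."""

    table: pd.DataFrame  # columns: region, channel, mean, sd, n_voxels, unit
    flags: list[str] = field(default_factory=list)


class Standardizer:
    """Per-column z-scoring with retained parameters for inverse mapping."""

    def __init__(self, mean: np.ndarray, sd: np.ndarray):
        self.mean = np.asarray(mean, dtype=float)
        self.sd = np.asarray(sd, dtype=float)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sd + self.mean


def extract_features(
    stack: ParametricMapStack,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Extract the 8-channel feature matrix over the tumor ROI.

    Returns ``(features, voxel_indices, n_dropped)`` with one row per ROI
    voxel in fixed channel order; rows containing non-finite values are
    dropped and counted.
    """
    roi_mask = np.asarray(stack.roi.data) > 0
    if not roi_mask.any():
        raise FormatError("empty tumor ROI")
    idx = np.argwhere(roi_mask)
    features = np.column_stack(
        [
            np.asarray(stack.channels[name].data, dtype=float)[roi_mask]
            for name in CHANNEL_ORDER
        ]
    )
    for j, name in enumerate(CHANNEL_ORDER):
        if not np.isfinite(features[:, j]).any():
            raise FormatError(f"channel {name} is entirely non-finite inside the ROI")
    finite = np.isfinite(features).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("dropped %d ROI voxels with non-finite map values", n_dropped)
    return features[finite], idx[finite], n_dropped


def standardize(features: np.ndarray) -> tuple[np.ndarray, Standardizer]:
    """Z-score each column to mean 0, SD 1 ("equal weighting" of channels)."""
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or len(x) < 2:
        raise FormatError("standardize requires a 2D feature matrix with >= 2 rows")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    zero = np.nonzero(sd == 0)[0]
    if zero.size:
        names = [CHANNEL_ORDER[j] if j < len(CHANNEL_ORDER) else str(j) for j in zero]
        raise FormatError(f"zero-variance channel(s): {names}")
    scaler = Standardizer(mean, sd)
    return scaler.transform(x), scaler


def kmeans_cluster(
    features: np.ndarray,
    k: int = 4,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Lloyd's k-means with k-means++ seeding, best of ``n_restarts``.

    Returns ``(assignments 0..k-1, inertia, centers)``; deterministic under
    the seed.  Only map features enter — never voxel coordinates.
    """
    x = np.asarray(features, dtype=float)
    if k < 2:
        raise FormatError("k must be >= 2")
    if k > len(x):
        raise FormatError(f"k={k} exceeds the {len(x)} available voxels")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        algorithm="lloyd",
        random_state=seed,
    ).fit(x)
    return km.labels_.astype(int), float(km.inertia_), km.cluster_centers_


def map_labels(
    assignments: np.ndarray,
    voxel_indices: np.ndarray,
    reference: Volume,
) -> tuple[Volume, np.ndarray]:
    """Map cluster assignments back onto the reference (T2) grid.

    Clusters are renumbered 1..k by descending size (ties broken by the
    original cluster index) so label 1 is always the largest habitat;
    voxels outside the ROI stay 0.  Returns the label volume and the
    old->new renumbering (``new_label = renumber[old_assignment]``).
    """
    assignments = np.asarray(assignments, dtype=int)
    voxel_indices = np.asarray(voxel_indices, dtype=int)
    if len(assignments) != len(voxel_indices):
        raise FormatError("assignments and voxel indices length mismatch")
    if voxel_indices.size and (
        voxel_indices.min() < 0
        or np.any(voxel_indices.max(axis=0) >= np.asarray(reference.shape))
    ):
        raise FormatError("voxel indices outside the reference grid")
    old = np.unique(assignments)
    sizes = np.array([(assignments == c).sum() for c in old])
    order = old[np.lexsort((old, -sizes))]
    renumber = np.zeros(old.max() + 1, dtype=int)
    for new, c in enumerate(order, start=1):
        renumber[c] = new
    labels = np.zeros(reference.shape, dtype=np.int16)
    labels[tuple(voxel_indices.T)] = renumber[assignments]
    vol = Volume(
        labels,
        reference.spacing,
        reference.origin,
        reference.direction,
        space_name=reference.space_name,
    )
    return vol, renumber


def cluster_stack(
    stack: ParametricMapStack,
    k: int = 4,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusterResult:
    """Full habitat pipeline: extract -> standardize -> k-means -> map back."""
    features, voxel_idx, n_dropped = extract_features(stack)
    z, scaler = standardize(features)
    assignments, inertia, centers = kmeans_cluster(
        z, k=k, seed=seed, n_restarts=n_restarts
    )
    labels, renumber = map_labels(assignments, voxel_idx, stack.roi)
    # reorder centroid rows so row i corresponds to final label i+1
    new_order = np.argsort(renumber[np.arange(centers.shape[0])])
    centers_by_label = centers[new_order]
    return ClusterResult(
        labels=labels,
        k=k,
        feature_means=centers_by_label,
        channel_order=CHANNEL_ORDER,
        seed=seed,
        inertia=inertia,
        centroids_native=scaler.inverse(centers_by_label),
        n_dropped_voxels=n_dropped,
    )


def region_stats(stack: ParametricMapStack, labels: Volume) -> RegionStats:
    """Mean +/- SD per region per channel in native units.

    Regions with a single voxel get SD 0 and a flag (sample SD undefined).
    """
    if not labels.same_grid(stack.roi):
        raise FormatError("label volume is not on the stack grid")
    lab = np.asarray(labels.data)
    regions = sorted(int(r) for r in np.unique(lab) if r > 0)
    if not regions:
        raise FormatError("label volume contains no regions")
    rows = []
    flags: list[str] = []
    for r in regions:
        mask = lab == r
        n = int(mask.sum())
        for name in CHANNEL_ORDER:
            vals = np.asarray(stack.channels[name].data, dtype=float)[mask]
            vals = vals[np.isfinite(vals)]
            if len(vals) < 2:
                sd = 0.0
                flag = f"region {r} channel {name}: <2 voxels, sd set to 0"
                if flag not in flags:
                    flags.append(flag)
            else:
                sd = float(np.std(vals, ddof=1))
            rows.append(
                {
                    "region": r,
                    "channel": name,
                    "mean": float(np.mean(vals)) if len(vals) else np.nan,
                    "sd": sd,
                    "n_voxels": n,
                    "unit": CHANNEL_UNITS.get(name, ""),
                }
            )
    return RegionStats(table=pd.DataFrame(rows), flags=flags)


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment (monotone, >= raw p, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        running_max = max(running_max, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running_max)
    return adjusted


def significance_stars(p: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


def compare_regions(
    values_by_region: dict[str, list[np.ndarray]],
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-channel one-way ANOVA plus Holm-adjusted pairwise t-tests.

    ``values_by_region`` maps channel name -> list of per-region voxel-value
    arrays.  Pairwise tests are Welch by default (``equal_var=True`` gives
    the pooled-variance textbook form).  Returns one row per channel per
    pairwise comparison with the ANOVA F/p repeated per channel, the raw
    and Holm-adjusted pairwise p, and the figure-legend star code.
    """
    rows = []
    for channel, groups in values_by_region.items():
        groups = [np.asarray(g, dtype=float) for g in groups]
        if len(groups) < 2:
            raise FormatError(f"channel {channel}: need >= 2 regions")
        for i, g in enumerate(groups):
            if len(g) < 2:
                raise FormatError(
                    f"channel {channel}: region {i} has fewer than 2 voxels"
                )
        if np.ptp(np.concatenate(groups)) == 0:
            f_stat, p_anova = 0.0, 1.0
        else:
            f_stat, p_anova = stats.f_oneway(*groups)
        raw = []
        pairs = []
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if np.ptp(np.concatenate([groups[i], groups[j]])) == 0:
                    p_raw = 1.0
                else:
                    _, p_raw = stats.ttest_ind(
                        groups[i], groups[j], equal_var=equal_var
                    )
                raw.append(float(p_raw))
                pairs.append((i + 1, j + 1))
        adjusted = holm_adjust(np.array(raw))
        for (a, b), p_raw, p_adj in zip(pairs, raw, adjusted):
            rows.append(
                {
                    "channel": channel,
                    "anova_F": float(f_stat),
                    "anova_p": float(p_anova),
                    "region_a": a,
                    "region_b": b,
                    "p_raw": p_raw,
                    "p_adjusted": float(p_adj),
                    "stars": significance_stars(float(p_adj)),
                }
            )
    return pd.DataFrame(rows)


def regions_from_stack(
    stack: ParametricMapStack, labels: Volume
) -> dict[str, list[np.ndarray]]:
    """Collect per-region voxel values per channel, ready for compare_regions."""
    lab = np.asarray(labels.data)
    regions = sorted(int(r) for r in np.unique(lab) if r > 0)
    out: dict[str, list[np.ndarray]] = {}
    for name in CHANNEL_ORDER:
        data = np.asarray(stack.channels[name].data, dtype=float)
        out[name] = [data[lab == r][np.isfinite(data[lab == r])] for r in regions]
    return out
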