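"""Target-registration-error (TRE) accuracy protocol and group statistics.

Accuracy of the nonrigid co-registration is quantified without touching the
landmarks it was fitted on: the paired landmarks of a section/slice pair
are randomly split into two independent sets, one used to fit the elastic
warp and the other held out; the TRE of a held-out landmark is the
Euclidean distance (mm) between its warped source position and its target.
The split is repeated (default 100 iterations) and the held-out distances
are pooled before computing the median and interquartile range.  Group
comparisons (section pairs; caudal/middle/cranial levels) use the
Kruskal-Wallis test followed by Bonferroni-corrected Wilcoxon rank-sum
tests, mirroring the right-skewed, nonparametric character of TRE data.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .elastic_registration import fit_tps, tps_evaluate
from .imaging_io import FormatError, PairedLandmarks, SarcoregError

__all__ = [
    "TREResult",
    "TRESummary",
    "GroupComparison",
    "ProtocolError",
    "split_landmarks",
    "run_tre_protocol",
    "summarize",
    "tre_per_volume",
    "compare_tre_groups",
    "write_tre_tsv",
    "plot_tre",
]

PAIR_KINDS = ("histology_exvivo", "histology_invivo", "exvivo_invivo")
SECTION_LEVELS = ("caudal", "middle", "cranial")


class ProtocolError(SarcoregError):
    """The repeated-split protocol could not be completed."""


@dataclass
class TREResult:
    """Pooled held-out distances from the repeated random-split protocol."""

    distances: np.ndarray  # mm, pooled over iterations
    n_iterations: int
    split_fraction: float
    seed: int
    pair_kind: str = "histology_invivo"
    section_level: str = "middle"
    patient_id: str = ""
    per_iteration_medians: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_failed_iterations: int = 0

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.distances < 0):
            raise FormatError("TRE distances must be non-negative")


@dataclass
class TRESummary:
    median_mm: float
    iqr_mm: float
    mean_mm: float
    sd_mm: float


@dataclass
class GroupComparison:
    """Kruskal-Wallis omnibus plus Bonferroni-corrected pairwise rank-sums."""

    kruskal_h: float
    kruskal_p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, p_raw, p_adjusted, significant
    alpha: float = 0.05

    @property
    def any_significant(self) -> bool:
        return bool(self.pairwise["significant"].any())


def split_landmarks(
    pairs: PairedLandmarks, fraction: float = 0.5, rng_seed: int | np.random.Generator = 0
) -> tuple[PairedLandmarks, PairedLandmarks]:
    """Randomly split paired landmarks into registration and evaluation sets.

    The partition is disjoint and exhaustive; the registration set receives
    ``round(fraction * n)`` landmarks (the extra point on odd counts), and
    the draw is reproducible under the seed.
    """
    if not (0.0 < fraction < 1.0):
        raise FormatError("split fraction must lie strictly between 0 and 1")
    n = len(pairs)
    if n < 6:
        raise FormatError(f"need at least 6 landmark pairs to split, got {n}")
    n_reg = int(math.floor(fraction * n + 0.5))  # half-up: reg gets the odd point
    n_eval = n - n_reg
    if n_reg < 3 or n_eval < 3:
        raise FormatError(
            f"split {n_reg}/{n_eval} leaves fewer than 3 landmarks in one set"
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    perm = rng.permutation(n)
    return pairs.subset(sorted(perm[:n_reg])), pairs.subset(sorted(perm[n_reg:]))


def run_tre_protocol(
    pairs: PairedLandmarks,
    n_iter: int = 100,
    fraction: float = 0.5,
    regularization: float = 0.0,
    seed: int = 0,
    pair_kind: str = "histology_invivo",
    section_level: str = "middle",
    patient_id: str = "",
) -> TREResult:
    """Run the repeated random-split TRE protocol on one section pair.

    Each iteration: split, fit the TPS on the registration subset, warp the
    held-out source landmarks, and record Euclidean distances to the
    held-out targets.  Distances are pooled across iterations; the
    per-iteration medians are retained as well.  A failed elastic fit
    aborts that iteration only; more than 10% failures abort the protocol.
    """
    rng = np.random.default_rng(seed)
    pooled: list[np.ndarray] = []
    per_iter_medians: list[float] = []
    n_failed = 0
    for _ in range(n_iter):
        reg, held_out = split_landmarks(pairs, fraction=fraction, rng_seed=rng)
        assert not set(reg.source.labels) & set(held_out.source.labels)
        try:
            warp = fit_tps(reg, regularization=regularization)
        except SarcoregError:
            n_failed += 1
            continue
        warped = tps_evaluate(warp, held_out.source.points)
        d = np.linalg.norm(warped - held_out.target.points, axis=1)
        pooled.append(d)
        per_iter_medians.append(float(np.median(d)))
    if n_failed > 0.1 * n_iter:
        raise ProtocolError(
            f"{n_failed}/{n_iter} elastic fits failed; protocol aborted"
        )
    return TREResult(
        distances=np.concatenate(pooled) if pooled else np.empty(0),
        n_iterations=n_iter,
        split_fraction=fraction,
        seed=seed,
        pair_kind=pair_kind,
        section_level=section_level,
        patient_id=patient_id,
        per_iteration_medians=np.asarray(per_iter_medians),
        n_failed_iterations=n_failed,
    )


def summarize(result: TREResult | np.ndarray) -> TRESummary:
    """Median, IQR (Q3 - Q1, linear-interpolation quantiles), mean and sample SD."""
    d = result.distances if isinstance(result, TREResult) else np.asarray(result, float)
    if d.size == 0:
        raise FormatError("cannot summarize an empty distance list")
    q1, q3 = np.percentile(d, [25, 75])  # linear interpolation (type 7)
    return TRESummary(
        median_mm=float(np.median(d)),
        iqr_mm=float(q3 - q1),
        mean_mm=float(np.mean(d)),
        sd_mm=float(np.std(d, ddof=1)) if d.size > 1 else 0.0,
    )


def tre_per_volume(mean_tre_mm: float, volume_ml: float) -> float:
    """TRE normalized by tumor volume, mm/mL, rounded to 3 decimals."""
    if volume_ml <= 0:
        raise FormatError("tumor volume must be positive")
    if mean_tre_mm < 0:
        raise FormatError("TRE must be non-negative")
    return round(mean_tre_mm / volume_ml, 3)


def compare_tre_groups(
    groups: list[TREResult] | list[np.ndarray],
    labels: list[str] | None = None,
    alpha: float = 0.05,
) -> GroupComparison:
    """Compare TRE distributions across >= 2 groups.

    Kruskal-Wallis H across all groups; every pairwise comparison by the
    Wilcoxon rank-sum test with Bonferroni correction (raw p multiplied by
    the number of comparisons, capped at 1).
    """
    arrays = [
        g.distances if isinstance(g, TREResult) else np.asarray(g, float)
        for g in groups
    ]
    if len(arrays) < 2:
        raise FormatError("need at least 2 groups to compare")
    for i, a in enumerate(arrays):
        if a.size == 0:
            raise FormatError(f"group {i} is empty")
    if labels is None:
        labels = []
        for i, g in enumerate(groups):
            if isinstance(g, TREResult) and g.pair_kind:
                labels.append(f"{g.pair_kind}:{g.section_level}:{i}")
            else:
                labels.append(f"group{i}")
    if all(np.ptp(a) == 0 for a in arrays) and np.ptp(np.concatenate(arrays)) == 0:
        # identical constant data: no evidence of any difference
        h, p_omni = 0.0, 1.0
    else:
        h, p_omni = stats.kruskal(*arrays)
    rows = []
    m = len(arrays) * (len(arrays) - 1) // 2
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            _, p_raw = stats.ranksums(arrays[i], arrays[j])
            p_adj = min(1.0, p_raw * m)
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "p_raw": p_raw,
                    "p_adjusted": p_adj,
                    "significant": p_adj < alpha,
                }
            )
    return GroupComparison(
        kruskal_h=float(h),
        kruskal_p=float(p_omni),
        pairwise=pd.DataFrame(rows),
        alpha=alpha,
    )


def write_tre_tsv(results: list[TREResult], path: str | os.PathLike) -> None:
    """One row per pooled distance: pair kind, level, patient, distance."""
    frames = []
    for r in results:
        frames.append(
            pd.DataFrame(
                {
                    "pair_kind": r.pair_kind,
                    "section_level": r.section_level,
                    "patient_id": r.patient_id,
                    "tre_mm": r.distances,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def plot_tre(results: list[TREResult], path: str | os.PathLike) -> None:
    """Box + jitter plot of pooled TRE per group (optional; needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [f"{r.pair_kind}\n{r.section_level}" for r in results]
    data = [r.distances for r in results]
    fig, ax = plt.subplots(figsize=(1.8 * len(results) + 1.5, 4))
    ax.boxplot(data, tick_labels=labels, showfliers=False)
    rng = np.random.default_rng(0)
    for i, d in enumerate(data, start=1):
        ax.plot(i + rng.uniform(-0.15, 0.15, size=len(d)), d, ".", alpha=0.4, ms=3)
    ax.set_ylabel("TRE (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
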