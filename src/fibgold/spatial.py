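"""Spatial statistics of immunogold label point patterns.

Implements the particle-level quantities of the workflow: per-particle
minimum separation (nearest-neighbour) distances and their histogram,
regional label densities per µm³ inside the 150 nm peripheral shell vs
the nuclear centre, the peripheral-to-central count ratio, the
percentage of labels associated with envelope invaginations, fold
changes between conditions, and two-group nonparametric comparisons
(two-tailed Mann–Whitney for independent groups, Wilcoxon signed-rank
for paired designs).

All distances are 3D Euclidean in physical nm — never voxel units —
so the ~9:1 z anisotropy of FIB-SEM stacks is honoured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy import stats

from .morphometry import InvaginationSet, ShellDecomposition

__all__ = [
    "NNDistanceSummary",
    "RegionDensity",
    "GroupComparison",
    "nn_min_distances",
    "region_density",
    "peripheral_central_ratio",
    "region_conditional_nn",
    "invagination_association",
    "fold_change",
    "compare_groups",
]


@dataclass
class NNDistanceSummary:
    distances_nm: np.ndarray  # per-particle minimum separation
    mean_nm: float
    sd_nm: float
    hist_counts: np.ndarray
    hist_edges_nm: np.ndarray


@dataclass
class RegionDensity:
    region: str
    count: int
    volume_um3: float
    density_per_um3: float


@dataclass
class GroupComparison:
    metric: str
    test: str  # "mann-whitney" | "wilcoxon-paired"
    statistic: float
    p_value: float  # two-sided
    n_a: int
    n_b: int


def _coords(particles: pd.DataFrame) -> np.ndarray:
    return particles[["z_nm", "y_nm", "x_nm"]].to_numpy(dtype=float)


def nn_min_distances(
    particles: pd.DataFrame, bin_width_nm: float = 25.0, scope: str = "all particles"
) -> NNDistanceSummary:
    """Per-particle minimum separation distances, in nm.

    For every particle, the Euclidean distance to its nearest other
    particle, via a k-d tree (exact; equal to the exhaustive pairwise
    computation).  The histogram over per-particle minima uses
    ``bin_width_nm`` bins from zero.
    """
    pts = _coords(particles)
    if len(pts) < 2:
        raise ValueError(f"need at least 2 particles for separation distances in {scope}")
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=2)
    minima = dists[:, 1]
    edges = np.arange(0.0, minima.max() + bin_width_nm, bin_width_nm)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width_nm])
    counts, edges = np.histogram(minima, bins=edges)
    return NNDistanceSummary(
        distances_nm=minima,
        mean_nm=float(minima.mean()),
        sd_nm=float(minima.std(ddof=1)),
        hist_counts=counts,
        hist_edges_nm=edges,
    )


def region_conditional_nn(
    particles: pd.DataFrame, region: str, bin_width_nm: float = 25.0
) -> NNDistanceSummary:
    """Minimum separation summary among the particles of one shell region."""
    sub = particles[particles["region"] == region]
    return nn_min_distances(sub, bin_width_nm=bin_width_nm, scope=f"region '{region}'")


def region_density(particles: pd.DataFrame, shell: ShellDecomposition) -> dict[str, RegionDensity]:
    """Nuclear label densities per µm³ for peripheral, central and whole nucleus."""
    volumes = {
        "peripheral": shell.peripheral_volume_um3,
        "central": shell.central_volume_um3,
    }
    volumes["nuclear"] = volumes["peripheral"] + volumes["central"]
    nuclear = particles[particles["compartment"] == "nuclear"]
    counts = {
        "peripheral": int((nuclear["region"] == "peripheral").sum()),
        "central": int((nuclear["region"] == "central").sum()),
        "nuclear": int(len(nuclear)),
    }
    out = {}
    for region, vol in volumes.items():
        if vol <= 0 and counts[region] > 0:
            raise ValueError(f"region '{region}' has zero volume but {counts[region]} particles")
        density = counts[region] / vol if vol > 0 else 0.0
        out[region] = RegionDensity(region, counts[region], vol, density)
    return out


def peripheral_central_ratio(densities: dict[str, RegionDensity]) -> float | None:
    """Peripheral/central label-count ratio; ``None`` when the centre is empty."""
    central = densities["central"].count
    if central == 0:
        import warnings

        warnings.warn("central region holds no labels; peripheral/central ratio undefined")
        return None
    return densities["peripheral"].count / central


def invagination_association(
    particles: pd.DataFrame,
    invaginations: InvaginationSet,
    max_dist_nm: float = 100.0,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> float | None:
    """Percentage of nuclear labels within ``max_dist_nm`` of an invagination.

    Association uses the anisotropic distance transform of the
    invagination volume; the default 100 nm is roughly one NPC diameter.
    Returns ``None`` when there are no nuclear labels (undefined, not
    zero); returns 0.0 when there are labels but no invaginations.
    """
    nuclear = particles[particles["compartment"] == "nuclear"]
    if len(nuclear) == 0:
        return None
    if invaginations.labels.max() == 0:
        return 0.0
    spacing = np.asarray(invaginations.spacing)
    dist = ndimage.distance_transform_edt(invaginations.labels == 0, sampling=spacing)
    idx = np.rint((_coords(nuclear) - np.asarray(origin)) / spacing).astype(int)
    idx = np.clip(idx, 0, np.asarray(dist.shape) - 1)
    associated = dist[idx[:, 0], idx[:, 1], idx[:, 2]] <= max_dist_nm
    return 100.0 * float(associated.sum()) / len(nuclear)


def fold_change(count_a: float, count_b: float) -> float:
    """Ratio a/b, e.g. label count on one condition over another."""
    if count_b <= 0:
        raise ValueError("fold change needs a positive denominator")
    return float(count_a) / float(count_b)


def compare_groups(
    values_a,
    values_b,
    test: str = "mann-whitney",
    metric: str = "",
) -> GroupComparison:
    """Two-tailed nonparametric comparison of two samples.

    ``mann-whitney`` for independent groups, ``wilcoxon-paired`` for
    matched pairs (equal sizes required).  For small samples (both
    n ≤ 10, no ties) the exact permutation null is used; larger samples
    fall back to the standard normal approximation with tie/continuity
    corrections.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError(f"need at least 3 observations per group, got {len(a)} and {len(b)}")
    small = len(a) <= 10 and len(b) <= 10
    if test == "mann-whitney":
        method = "exact" if small and not _has_ties(a, b) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    elif test == "wilcoxon-paired":
        if len(a) != len(b):
            raise ValueError("paired test requires equal sample sizes")
        diffs = a - b
        method = "exact" if small and not np.any(diffs == 0) else "approx"
        res = stats.wilcoxon(a, b, alternative="two-sided", method=method)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        metric=metric,
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
    )


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)
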