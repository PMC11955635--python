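"""Cluster bipartition scan over clonotype tumor-to-nontumor ratios.

Single-cell expression clustering assigns each T cell a cluster label; joining
cells to their clonotypes asks which clusters concentrate clonotypes with high
tumor-to-nontumor frequency ratios.  The scan enumerates every bipartition of
the cluster labels into two non-empty groups ((2^k - 2)/2 of them, e.g. 15 for
five clusters), compares the two groups' clonotype ratios with a two-sided
Mann-Whitney U test and Bonferroni-adjusts the p-values by the number of
bipartitions.

Because a ratio belongs to a clonotype, not to a cell, each clonotype
contributes its ratio at most once per group — by default once to every group
in which it has at least one cell (a clonotype spanning both groups appears in
both); alternatively it can be assigned to its majority cluster only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CellRecord",
    "PartitionTestResult",
    "map_clonotypes_to_clusters",
    "enumerate_bipartitions",
    "mann_whitney_u",
    "partition_scan",
]

EXACT_MAX_N = 8  # exact p-value enumeration below/at this smaller-sample size


@dataclass(frozen=True)
class CellRecord:
    barcode: str
    clonotype: tuple  # clonotype key, e.g. (junction_nt, v_call, j_call)
    cluster_id: int


@dataclass(frozen=True)
class PartitionTestResult:
    group_a: frozenset
    group_b: frozenset
    n_a: int
    n_b: int
    U: float
    p_raw: float
    p_adjusted: float


def map_clonotypes_to_clusters(
    cells: Iterable[CellRecord],
) -> tuple[dict, int]:
    """Per-clonotype cell counts per cluster.

    Returns ``(distribution, n_excluded)`` where ``distribution`` maps each
    clonotype key to ``{cluster_id: n_cells}`` and ``n_excluded`` counts cells
    lacking a clonotype (``clonotype`` falsy).  Duplicate barcodes raise.
    """
    seen: set[str] = set()
    dist: dict = {}
    n_excluded = 0
    for cell in cells:
        if cell.barcode in seen:
            raise ValueError(f"duplicate barcode {cell.barcode}")
        seen.add(cell.barcode)
        if not cell.clonotype:
            n_excluded += 1
            continue
        per = dist.setdefault(cell.clonotype, {})
        per[cell.cluster_id] = per.get(cell.cluster_id, 0) + 1
    return dist, n_excluded


def enumerate_bipartitions(cluster_ids: Iterable[int]) -> list[tuple[frozenset, frozenset]]:
    """All unordered splits of the cluster labels into two non-empty groups.

    For k labels there are (2^k - 2)/2 such splits.  Canonical order: group_a
    is the group containing the smallest label.
    """
    ids = sorted(set(cluster_ids))
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters")
    anchor, rest = ids[0], ids[1:]
    partitions = []
    for r in range(len(rest) + 1):
        for extra in combinations(rest, r):
            group_a = frozenset((anchor, *extra))
            group_b = frozenset(ids) - group_a
            if group_b:
                partitions.append((group_a, group_b))
    return partitions


def _u_from_ranks(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r_x = ranks[: len(x)].sum()
    u_x = r_x - len(x) * (len(x) + 1) / 2
    has_ties = len(np.unique(pooled)) < len(pooled)
    return u_x, has_ties


def _u_null_distribution(nx: int, ny: int) -> np.ndarray:
    """Counts of label assignments per U value under the tie-free null.

    Uses the rank-sum counting recurrence (Gaussian binomial coefficients):
    N(u; m, n) = N(u - n; m - 1, n) + N(u; m, n - 1) — the largest pooled
    value belongs either to x (adding n to U) or to y.
    """
    max_u = nx * ny
    # dp[n] is the count array over u for the current m
    dp = [np.zeros(max_u + 1) for _ in range(ny + 1)]
    for n in range(ny + 1):
        dp[n][0] = 1.0  # m = 0: U is always 0
    for _ in range(1, nx + 1):
        new = [np.zeros(max_u + 1) for _ in range(ny + 1)]
        new[0][0] = 1.0  # n = 0: U is always 0
        for n in range(1, ny + 1):
            shifted = np.zeros(max_u + 1)
            shifted[n:] = dp[n][: max_u + 1 - n]
            new[n] = shifted + new[n - 1]
        dp = new
    return dp[ny]


def _exact_two_sided_p(nx: int, ny: int, u_x: float) -> float:
    """Exact two-sided p for tie-free samples: doubled smaller tail, capped."""
    counts = _u_null_distribution(nx, ny)
    total = counts.sum()
    u = int(round(u_x))
    lower = counts[: u + 1].sum()
    upper = counts[u:].sum()
    return float(min(1.0, 2 * min(lower, upper) / total))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    U is computed from midrank sums.  The p-value is exact (full enumeration
    of label assignments) when the smaller sample has at most 8 observations
    and the pooled data are tie-free; otherwise the normal approximation with
    tie correction and continuity correction is used.  Degenerate case: if
    every pooled value is identical the p-value is 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    u_x, has_ties = _u_from_ranks(x, y)
    nx, ny = len(x), len(y)

    if not has_ties and min(nx, ny) <= EXACT_MAX_N:
        return u_x, _exact_two_sided_p(nx, ny, u_x)

    n = nx + ny
    mu = nx * ny / 2
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = nx * ny / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return u_x, 1.0
    z = (abs(u_x - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = 2 * stats.norm.sf(z)
    return u_x, min(1.0, p)


def partition_scan(
    ratios_by_clonotype: Mapping,
    clusters_by_clonotype: Mapping,
    cluster_ids: Iterable[int],
    membership: str = "any",
) -> list[PartitionTestResult]:
    """Mann-Whitney scan over all cluster bipartitions.

    ``ratios_by_clonotype`` maps clonotype keys to finite tumor-to-nontumor
    ratios; ``clusters_by_clonotype`` maps the same keys to per-cluster cell
    counts (the output of :func:`map_clonotypes_to_clusters`).  With
    ``membership="any"`` a clonotype contributes its ratio once to every group
    in which it has at least one cell; with ``membership="majority"`` it is
    assigned only to the group holding its majority cluster (ties excluded).
    Bipartitions leaving a group without clonotypes are skipped.  Results are
    Bonferroni-adjusted by the number of enumerated bipartitions and sorted by
    adjusted p ascending.
    """
    if membership not in ("any", "majority"):
        raise ValueError("membership must be 'any' or 'majority'")
    partitions = enumerate_bipartitions(cluster_ids)
    n_tests = len(partitions)

    clono_clusters = {}
    for key, ratio in ratios_by_clonotype.items():
        if not math.isfinite(ratio):
            raise ValueError(f"non-finite ratio for clonotype {key}")
        dist = clusters_by_clonotype.get(key)
        if not dist:
            raise ValueError(f"clonotype {key} has no cells")
        clono_clusters[key] = dist

    results = []
    for group_a, group_b in partitions:
        xs, ys = [], []
        for key, dist in sorted(clono_clusters.items()):
            ratio = ratios_by_clonotype[key]
            if membership == "any":
                if any(c in group_a for c in dist):
                    xs.append(ratio)
                if any(c in group_b for c in dist):
                    ys.append(ratio)
            else:
                top = max(dist.values())
                leaders = [c for c, n in dist.items() if n == top]
                if len(leaders) != 1:
                    continue
                (xs if leaders[0] in group_a else ys).append(ratio)
        if not xs or not ys:
            continue  # flagged by absence from the result list
        u, p = mann_whitney_u(xs, ys)
        results.append(PartitionTestResult(
            group_a=group_a,
            group_b=group_b,
            n_a=len(xs),
            n_b=len(ys),
            U=u,
            p_raw=p,
            p_adjusted=min(1.0, n_tests * p),
        ))
    results.sort(key=lambda r: (r.p_adjusted, r.p_raw,
                                tuple(sorted(r.group_a))))
    return results
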