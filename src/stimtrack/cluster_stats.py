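"""Cluster-based permutation tests over the channel x frequency grid.

Controls the family-wise error rate of mass-univariate tests: cell-wise t
statistics are thresholded at the two-tailed critical value, supra-
threshold cells are grouped into sign-consistent clusters connected over
sensor adjacency (and adjacent frequency bins), and each observed
cluster's size (cell count) is compared with the permutation distribution
of the *maximum* cluster size.  Permutations are sign-flips of
per-subject differences (dependent design) or group-label shuffles
(independent design).  When the requested number of permutations covers
the full permutation group, the test enumerates it exhaustively and the
p-value is exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .containers import InputError, ParameterError


@dataclass
class SensorAdjacency:
    """Symmetric channel neighbor structure (no self-neighbors)."""

    neighbors: np.ndarray  # (n_channels, n_channels) bool
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.neighbors = np.asarray(self.neighbors, dtype=bool)
        n = self.neighbors.shape[0]
        if self.neighbors.shape != (n, n):
            raise InputError("adjacency must be square")
        if not np.array_equal(self.neighbors, self.neighbors.T):
            raise InputError("adjacency must be symmetric")
        if np.any(np.diag(self.neighbors)):
            raise InputError("no self-neighbors allowed")

    @property
    def n_channels(self) -> int:
        return self.neighbors.shape[0]


@dataclass
class Cluster:
    """One sign-consistent connected component of supra-threshold cells."""

    cells: list[tuple[int, int]]  # (channel, bin) indices
    sign: int
    size: int
    sum_t: float
    p_value: float = np.nan


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    null_max_stat: np.ndarray
    k: int
    alpha_cluster: float
    min_chans: int
    exact: bool = False
    seed: int | None = None
    t_map: np.ndarray | None = None

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value <= 0.05]

    @property
    def min_p(self) -> float:
        if not self.clusters:
            return 1.0
        return min(c.p_value for c in self.clusters)


def build_adjacency(
    positions: np.ndarray,
    max_dist: float,
    labels: list[str] | None = None,
) -> SensorAdjacency:
    """Neighbor sensors are those within ``max_dist`` (Euclidean)."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[0] < 2:
        raise InputError("need >= 2 sensors with coordinate rows")
    if not np.all(np.isfinite(positions)):
        raise InputError("sensor positions must be finite")
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    adj = (d <= max_dist) & ~np.eye(positions.shape[0], dtype=bool)
    if adj.shape[0] > 1 and not adj.any():
        warnings.warn(
            "adjacency graph is fully isolated (max_dist too small?)",
            stacklevel=2,
        )
    return SensorAdjacency(neighbors=adj, labels=labels)


def _find_clusters(
    t_map: np.ndarray,
    threshold: float,
    adjacency: SensorAdjacency,
    min_chans: int,
) -> list[Cluster]:
    """Sign-consistent connected components of |t| > threshold cells.

    Two supra-threshold cells are connected if they share a sign and are
    either (same channel, adjacent bins) or (neighbor channels, same bin).
    Clusters spanning fewer than ``min_chans`` distinct channels are
    discarded.
    """
    n_ch, n_bins = t_map.shape
    supra = np.abs(t_map) > threshold
    if not supra.any():
        return []
    sign = np.sign(t_map)
    idx = -np.ones((n_ch, n_bins), dtype=int)
    cells = np.argwhere(supra)
    idx[supra] = np.arange(len(cells))

    rows: list[int] = []
    cols: list[int] = []
    nb = adjacency.neighbors
    for ci, (c, b) in enumerate(cells):
        s = sign[c, b]
        if b + 1 < n_bins and supra[c, b + 1] and sign[c, b + 1] == s:
            rows.append(ci)
            cols.append(idx[c, b + 1])
        for c2 in np.flatnonzero(nb[c]):
            if c2 > c and supra[c2, b] and sign[c2, b] == s:
                rows.append(ci)
                cols.append(idx[c2, b])
    n = len(cells)
    graph = coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    n_comp, comp = connected_components(graph, directed=False)
    clusters = []
    for k in range(n_comp):
        members = [tuple(cells[i]) for i in np.flatnonzero(comp == k)]
        chans = {c for c, _ in members}
        if len(chans) < min_chans:
            continue
        c0, b0 = members[0]
        clusters.append(
            Cluster(
                cells=members,
                sign=int(sign[c0, b0]),
                size=len(members),
                sum_t=float(sum(t_map[c, b] for c, b in members)),
            )
        )
    return clusters


def _max_cluster_stat(
    t_map: np.ndarray,
    threshold: float,
    adjacency: SensorAdjacency,
    min_chans: int,
    statistic: str,
) -> float:
    clusters = _find_clusters(t_map, threshold, adjacency, min_chans)
    if not clusters:
        return 0.0
    if statistic == "size":
        return float(max(c.size for c in clusters))
    return float(max(abs(c.sum_t) for c in clusters))


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Per-cell one-sample t over subject difference maps (n, ch, bins)."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def _indep_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-cell pooled-variance two-sample t (a: (n1,ch,bins), b: (n2,...))."""
    n1, n2 = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(
            sp2 * (1.0 / n1 + 1.0 / n2)
        )
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def cluster_permutation_test(
    data_a: np.ndarray,
    data_b: np.ndarray,
    design: str,
    adjacency: SensorAdjacency,
    k: int = 10_000,
    alpha_cluster: float = 0.05,
    min_chans: int = 2,
    seed: int | None = None,
    statistic: str = "size",
) -> ClusterTestResult:
    """Cluster permutation test between two sets of channel x bin maps.

    Parameters
    ----------
    data_a, data_b
        (n_subjects, n_channels, n_bins) stacks.  ``design="dependent"``
        requires equal, paired stacks and permutes by flipping the sign of
        each subject's (a - b) difference; ``design="independent"``
        shuffles group membership.
    k
        Number of permutations.  If k covers the full permutation group
        the test switches to exhaustive enumeration (exact p = b / n_perms,
        counting the identity); otherwise Monte-Carlo with the conservative
        p = (b + 1) / (k + 1).
    alpha_cluster
        Two-tailed cell-wise threshold defining cluster membership.
    min_chans
        Minimum number of distinct channels a cluster must span.
    statistic
        "size" (cell count, the default) or "sum_t".
    """
    data_a = np.asarray(data_a, dtype=float)
    data_b = np.asarray(data_b, dtype=float)
    if design not in ("dependent", "independent"):
        raise ParameterError(f"unknown design {design!r}")
    if data_a.ndim != 3 or data_b.ndim != 3:
        raise InputError("data must be (n_subjects, n_channels, n_bins)")
    if data_a.shape[1:] != data_b.shape[1:]:
        raise InputError("map shapes differ between conditions")
    if data_a.shape[1] != adjacency.n_channels:
        raise InputError("adjacency size does not match channel count")
    if min(data_a.shape[0], data_b.shape[0]) < 2:
        raise InputError("need at least 2 subjects per condition/group")

    rng = np.random.default_rng(seed)

    if design == "dependent":
        if data_a.shape != data_b.shape:
            raise InputError("dependent design requires paired stacks")
        diffs = data_a - data_b
        n = diffs.shape[0]
        df = n - 1
        threshold = stats.t.ppf(1 - alpha_cluster / 2, df)
        t_obs = _paired_t(diffs)
        observed = _find_clusters(t_obs, threshold, adjacency, min_chans)

        n_total = 2**n
        exact = n_total <= k
        if exact:
            flips = np.array(list(product((1.0, -1.0), repeat=n)))
        else:
            flips = rng.choice([1.0, -1.0], size=(k, n))
            flips[0] = 1.0  # identity always included
        null = np.empty(len(flips))
        for i, fl in enumerate(flips):
            t_perm = _paired_t(diffs * fl[:, None, None])
            null[i] = _max_cluster_stat(
                t_perm, threshold, adjacency, min_chans, statistic
            )
    else:
        n1, n2 = data_a.shape[0], data_b.shape[0]
        pooled = np.concatenate([data_a, data_b], axis=0)
        df = n1 + n2 - 2
        threshold = stats.t.ppf(1 - alpha_cluster / 2, df)
        t_obs = _indep_t(data_a, data_b)
        observed = _find_clusters(t_obs, threshold, adjacency, min_chans)

        n_total = math.comb(n1 + n2, n1)
        exact = n_total <= k
        if exact:
            assignments = list(combinations(range(n1 + n2), n1))
        else:
            assignments = [tuple(range(n1))]  # identity first
            for _ in range(k - 1):
                assignments.append(
                    tuple(rng.permutation(n1 + n2)[:n1])
                )
        null = np.empty(len(assignments))
        all_idx = set(range(n1 + n2))
        for i, ga in enumerate(assignments):
            gb = sorted(all_idx - set(ga))
            t_perm = _indep_t(pooled[list(ga)], pooled[gb])
            null[i] = _max_cluster_stat(
                t_perm, threshold, adjacency, min_chans, statistic
            )

    for c in observed:
        obs_stat = c.size if statistic == "size" else abs(c.sum_t)
        b = int(np.sum(null >= obs_stat))
        if exact:
            c.p_value = b / len(null)
        else:
            c.p_value = (b + 1) / (len(null) + 1)
        c.p_value = min(1.0, max(c.p_value, 1.0 / (len(null) + 1)))

    return ClusterTestResult(
        clusters=sorted(observed, key=lambda c: c.p_value),
        null_max_stat=null,
        k=len(null),
        alpha_cluster=alpha_cluster,
        min_chans=min_chans,
        exact=exact,
        seed=seed,
        t_map=t_obs,
    )


def interaction_test(
    group1_maps_stim_a: np.ndarray,
    group1_maps_stim_b: np.ndarray,
    group2_maps_stim_a: np.ndarray,
    group2_maps_stim_b: np.ndarray,
    adjacency: SensorAdjacency,
    k: int = 10_000,
    alpha_cluster: float = 0.05,
    min_chans: int = 2,
    seed: int | None = None,
    statistic: str = "size",
) -> ClusterTestResult:
    """Group x stimulus interaction as a difference-of-differences test.

    Each subject's (stimulus A - stimulus B) difference map is computed
    within group, and the two groups' difference stacks are compared with
    an independent-design cluster permutation test.  A significant cluster
    means the stimulus effect differs between groups — the expertise
    interaction — while group or stimulus main effects cancel.
    """
    g1a = np.asarray(group1_maps_stim_a, dtype=float)
    g1b = np.asarray(group1_maps_stim_b, dtype=float)
    g2a = np.asarray(group2_maps_stim_a, dtype=float)
    g2b = np.asarray(group2_maps_stim_b, dtype=float)
    if g1a.shape != g1b.shape or g2a.shape != g2b.shape:
        raise InputError("within-group stacks must be paired by subject")
    return cluster_permutation_test(
        g1a - g1b,
        g2a - g2b,
        design="independent",
        adjacency=adjacency,
        k=k,
        alpha_cluster=alpha_cluster,
        min_chans=min_chans,
        seed=seed,
        statistic=statistic,
    )
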