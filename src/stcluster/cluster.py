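"""Density-based clustering: k-distance profile, knee selection, and DBSCAN.

The neighborhood radius (eps) is chosen from the k-nearest-neighbor distance
profile: distances from each point to its k-th nearest neighbor are sorted in
ascending order, and the "knee" of that curve — the point of maximum
perpendicular deviation from the chord joining its endpoints — is the
automated stand-in for the conventional visual choice.  A manual eps override
is always available.

The DBSCAN implementation follows the classical semantics: a point is *core*
iff its closed eps-ball (distance <= eps, the point itself included) contains
at least ``min_pts`` points; clusters are the maximal density-connected sets;
non-core points within eps of a core point are *border*; everything else is
*noise*.  Counting the query point itself means a triple of mutually close
points forms a cluster at min_pts = 3.

Border points within eps of cores from several clusters are assigned to the
cluster of their lowest-index core neighbor, making the labeling independent
of input presentation order (classical DBSCAN leaves this ambiguous).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embed import pairwise_distance

NOISE = 0


@dataclass(frozen=True)
class DbscanParams:
    """DBSCAN parameters: neighborhood radius and minimum neighborhood size.

    ``min_pts`` counts the point itself, so ``min_pts=3`` means a cluster
    needs at least three mutually density-connected cases.
    """

    eps: float
    min_pts: int = 3

    def __post_init__(self):
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")


@dataclass(frozen=True)
class KDistProfile:
    """Per-point distance to the k-th nearest neighbor, plus the sorted curve."""

    k: int
    distances: np.ndarray  # in input point order
    sorted_curve: np.ndarray  # ascending

    def __len__(self) -> int:
        return len(self.distances)


@dataclass(frozen=True)
class ClusterLabeling:
    """Per-point cluster id (0 = noise, 1..C) and role (core/border/noise)."""

    labels: np.ndarray  # int, 0 = noise
    roles: np.ndarray  # str: "core" | "border" | "noise"

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def noise_mask(self) -> np.ndarray:
        return self.labels == NOISE

    def members(self, cluster_id: int) -> np.ndarray:
        """Indices of the points belonging to a cluster."""
        return np.flatnonzero(self.labels == cluster_id)


class NoKneeError(ValueError):
    """The sorted k-distance curve has no knee (constant or linear)."""


def knn_profile(points: np.ndarray, k: int = 3) -> KDistProfile:
    """Distance from each point to its k-th nearest *other* point.

    Self-distances are excluded; ties are broken by distance value only, so
    the k-th smallest of the n-1 distances to the other points is returned.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    dmat = pairwise_distance(points)
    # drop the zero self-distance column-wise by partial sort: the k-th
    # nearest other point is the (k+1)-th order statistic including self
    part = np.partition(dmat, k, axis=1)
    dist = part[:, k]
    return KDistProfile(k=k, distances=dist, sorted_curve=np.sort(dist))


def knee_epsilon(
    profile: KDistProfile, rel_tol: float = 1e-12
) -> tuple[float, int]:
    """Eps at the knee of the sorted k-distance curve.

    The knee is the index of maximum perpendicular deviation of the curve
    from the chord joining its first and last points; ties go to the smallest
    index.  Returns ``(eps, knee_index)``.

    Raises
    ------
    NoKneeError
        If the curve is constant or linear (maximum deviation below
        ``rel_tol`` times the curve's range), in which case eps must be
        supplied manually.
    """
    y = np.asarray(profile.sorted_curve, dtype=float)
    n = len(y)
    if n < 3:
        raise NoKneeError("need at least 3 points on the k-distance curve")
    x = np.arange(n, dtype=float)
    x0, y0 = x[0], y[0]
    x1, y1 = x[-1], y[-1]
    rng = y1 - y0
    if rng <= 0:
        raise NoKneeError("k-distance curve is constant; choose eps manually")
    # perpendicular distance of (x, y) from the chord (x0,y0)-(x1,y1)
    dx, dy = x1 - x0, y1 - y0
    dev = np.abs(dy * (x - x0) - dx * (y - y0)) / np.hypot(dx, dy)
    idx = int(np.argmax(dev))  # argmax returns the first maximizer
    if dev[idx] < rel_tol * rng:
        raise NoKneeError("k-distance curve is linear; no knee, choose eps manually")
    return float(y[idx]), idx


def dbscan(points: np.ndarray, params: DbscanParams) -> ClusterLabeling:
    """Classical DBSCAN on Euclidean distances in the embedded space.

    Cluster ids are numbered 1..C in order of the first core point
    encountered in ascending index order; border assignment is to the
    lowest-index core neighbor.  Degenerate inputs never error: they produce
    all-noise or a single cluster.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    labels = np.zeros(n, dtype=int)
    roles = np.full(n, "noise", dtype=object)
    if n == 0:
        return ClusterLabeling(labels=labels, roles=roles.astype(str))

    dmat = pairwise_distance(points)
    within = dmat <= params.eps  # closed balls; diagonal True (self counted)
    neighbor_counts = within.sum(axis=1)
    core = neighbor_counts >= params.min_pts

    # clusters = connected components of the core-core "within eps" graph,
    # discovered by BFS from cores in ascending index order
    cluster_id = 0
    for i in range(n):
        if not core[i] or labels[i] != NOISE:
            continue
        cluster_id += 1
        queue = [i]
        labels[i] = cluster_id
        while queue:
            j = queue.pop()
            for m in np.flatnonzero(within[j] & core):
                if labels[m] == NOISE:
                    labels[m] = cluster_id
                    queue.append(int(m))
    roles[core] = "core"

    # border points: non-core within eps of a core; tie -> lowest-index core
    for i in np.flatnonzero(~core):
        core_neighbors = np.flatnonzero(within[i] & core)
        if len(core_neighbors):
            labels[i] = labels[core_neighbors[0]]
            roles[i] = "border"

    return ClusterLabeling(labels=labels, roles=roles.astype(str))
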