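"""Per-cluster summaries, ranking by mean pairwise distance, and selection
of the meaningful space-time clusters.

Each detected cluster is summarized by its size, its *mdis* (mean pairwise
Euclidean distance among member points in the full 3-D embedded space — the
spatiotemporal closeness measure; lower = tighter), its date span, covariate
composition, geographic centroid (mean of member longitudes/latitudes), and
the convex-hull area of its spatial embedded coordinates.

Density clustering over a whole country typically yields, besides genuinely
tight space-time clusters, one or more large loose clusters that merely trace
dense urban population.  The *significance* step excludes those: either a
manual rank cutoff, or an automated elbow rule that cuts where the
rank-ordered metric curve (mdis, hull area, or size) shows its largest
relative jump.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .cluster import ClusterLabeling
from .embed import pairwise_distance
from .events import EventSet


@dataclass
class ClusterSummary:
    """Summary statistics of one detected cluster."""

    cluster_id: int
    n: int
    mdis: float
    prop_male: float  # percent among members with known sex
    prop_high: float  # percent high-school among known school type
    prop_middle: float
    mean_age: float | None
    first_date: dt.date
    last_date: dt.date
    span_days: int
    centroid_lon: float
    centroid_lat: float
    hull_area: float
    rank: int | None = None
    significant: bool = False


@dataclass(frozen=True)
class SignificanceRule:
    """How to flag the meaningful clusters among the ranked summaries.

    ``manual_rank``: flag all clusters with rank <= ``cutoff``.
    ``elbow``: flag ranks up to the rank r (r >= ``min_rank``) that maximizes
    the relative jump metric(r+1)/metric(r) along the rank-ordered curve of
    ``metric`` (one of ``mdis``, ``hull_area``, ``n``).  A maximum ratio of
    at most ``1 + jump_tol`` does not count as a jump: the default
    ``jump_tol = 1.0`` demands that the metric at least double, the working
    definition of a "rapid increase"; gentler curves flag every cluster and
    warn.
    """

    method: str = "elbow"
    cutoff: int = 15
    min_rank: int = 1
    metric: str = "mdis"
    jump_tol: float = 1.0

    def __post_init__(self):
        if self.method not in ("manual_rank", "elbow"):
            raise ValueError(f"unknown significance method {self.method!r}")
        if self.cutoff < 1 or self.min_rank < 1:
            raise ValueError("cutoff and min_rank must be >= 1")
        if self.metric not in ("mdis", "hull_area", "n"):
            raise ValueError(f"unknown jump metric {self.metric!r}")


def hull_area(points: np.ndarray) -> float:
    """Area of the convex hull of 2-D points; 0 for degenerate (<3 or collinear)."""
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        return 0.0
    try:
        return float(ConvexHull(points[:, :2]).volume)  # 2-D "volume" is area
    except QhullError:
        return 0.0  # collinear / coincident members


def _prop(values: list[str], level: str) -> float:
    known = [v for v in values if v != "missing"]
    if not known:
        return float("nan")
    return 100.0 * sum(v == level for v in known) / len(known)


def summarize_clusters(
    labeling: ClusterLabeling,
    events: EventSet,
    points: np.ndarray,
    spatial_mdis: bool = False,
) -> list[ClusterSummary]:
    """Summarize every non-noise cluster and rank ascending by mdis.

    ``mdis`` is the mean over unordered member pairs of Euclidean distance in
    the full embedded 3-space (set ``spatial_mdis=True`` for an xy-only
    variant).  Ranks 1..C are assigned ascending by mdis, ties broken by
    smaller cluster id.
    """
    points = np.asarray(points, dtype=float)
    if not (len(labeling.labels) == len(events) == len(points)):
        raise ValueError("labeling, events and points must have equal length")
    summaries = []
    for cid in range(1, labeling.n_clusters + 1):
        idx = labeling.members(cid)
        if len(idx) == 0:
            continue
        if len(idx) == 1:
            raise ValueError(
                f"cluster {cid} has a single member; inconsistent with min_pts >= 2"
            )
        members = [events[int(i)] for i in idx]
        pts = points[idx]
        dsub = pairwise_distance(pts if not spatial_mdis else pts[:, :2])
        iu = np.triu_indices(len(idx), k=1)
        mdis = float(dsub[iu].mean())
        dates = [e.date for e in members]
        first, last = min(dates), max(dates)
        ages = [e.age for e in members if e.age is not None]
        summaries.append(
            ClusterSummary(
                cluster_id=cid,
                n=len(idx),
                mdis=mdis,
                prop_male=_prop([e.sex for e in members], "male"),
                prop_high=_prop([e.school_type for e in members], "high"),
                prop_middle=_prop([e.school_type for e in members], "middle"),
                mean_age=float(np.mean(ages)) if ages else None,
                first_date=first,
                last_date=last,
                span_days=(last - first).days,
                centroid_lon=float(np.mean([e.lon for e in members])),
                centroid_lat=float(np.mean([e.lat for e in members])),
                hull_area=hull_area(pts[:, :2]),
            )
        )
    summaries.sort(key=lambda s: (s.mdis, s.cluster_id))
    for rank, s in enumerate(summaries, start=1):
        s.rank = rank
    return summaries


def select_significant(
    summaries: list[ClusterSummary], rule: SignificanceRule
) -> list[ClusterSummary]:
    """Flag the meaningful clusters; returns the summaries with flags set.

    With the elbow rule, the cutoff rank r maximizes metric(r+1)/metric(r)
    over r >= min_rank; if no ratio exceeds 1 + jump_tol every cluster is
    flagged and a warning is emitted.
    """
    if not summaries:
        return summaries
    ranked = sorted(summaries, key=lambda s: s.rank)
    if rule.method == "manual_rank":
        cutoff = rule.cutoff
    else:
        if len(ranked) < 3:
            raise ValueError("elbow selection needs at least 3 clusters")
        vals = np.array([getattr(s, rule.metric) for s in ranked], dtype=float)
        if np.any(vals <= 0):
            vals = vals + 1e-12  # guard zero mdis / degenerate hulls
        ratios = vals[1:] / vals[:-1]
        lo = rule.min_rank - 1
        if lo >= len(ratios):
            raise ValueError("min_rank leaves no candidate jump positions")
        best = lo + int(np.argmax(ratios[lo:]))
        if ratios[best] <= 1.0 + rule.jump_tol:
            warnings.warn(
                "no jump found on the rank-ordered curve; flagging all clusters",
                stacklevel=2,
            )
            cutoff = len(ranked)
        else:
            cutoff = best + 1  # ranks are 1-based
    for s in ranked:
        s.significant = s.rank <= cutoff
    return ranked


def clustered_fraction(summaries: list[ClusterSummary], total_events: int) -> float:
    """Fraction of all events belonging to significant clusters, in [0, 1]."""
    n_sig = sum(s.n for s in summaries if s.significant)
    if total_events < n_sig:
        raise ValueError("total_events smaller than significant-cluster membership")
    if total_events == 0:
        return 0.0
    return n_sig / total_events
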