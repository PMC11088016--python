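"""Model/Results interface tying the detection pipeline together.

:class:`SpaceTimeClusterModel` is built from an :class:`~stcluster.events.EventSet`
plus configuration; ``fit()`` runs the pipeline

    embed -> k-distance profile -> knee eps (unless given) -> DBSCAN
          -> per-cluster summaries -> significance selection

and returns a :class:`SpaceTimeClusterResults` carrying the labeling, the
ranked summaries, diagnostics, and a ``summary()`` table.  Group comparisons
(contingency chi-squares, SDQ t-tests, the clustered-membership logistic
regression) hang off the results object via :meth:`SpaceTimeClusterResults.compare_groups`.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd

from .cluster import ClusterLabeling, DbscanParams, KDistProfile, dbscan, knee_epsilon, knn_profile
from .embed import EmbedConfig, embed
from .events import CATEGORICAL_LEVELS, EventSet
from .stats import (
    ChiSquareResult,
    LogisticFit,
    LogisticSpec,
    TTestResult,
    chi_square,
    crosstab,
    fit_logistic,
    two_sample_t,
)
from .summary import (
    ClusterSummary,
    SignificanceRule,
    clustered_fraction,
    select_significant,
    summarize_clusters,
)

SDQ_SCALES = (
    "sdq_prosocial",
    "sdq_hyperactivity",
    "sdq_emotional",
    "sdq_conduct",
    "sdq_peer",
    "sdq_total",
)


class SpaceTimeClusterModel:
    """Space-time cluster detection model for point-located events.

    Parameters
    ----------
    events
        The validated event set.
    embed_config
        Space-time embedding configuration (default: z-score standardization
        of longitude, latitude and day index with unit axis weights).
    eps
        DBSCAN radius in embedded units.  If None (default) it is chosen
        automatically at the knee of the sorted k-distance curve.
    min_pts
        Minimum neighborhood size for a core point, counting the point
        itself (default 3: at least three mutually close cases form a
        cluster).
    k
        Neighbor order of the k-distance profile (default 3, matching
        ``min_pts``).
    significance
        Rule for flagging the meaningful clusters (default: elbow on the
        rank-ordered mdis curve).
    """

    def __init__(
        self,
        events: EventSet,
        embed_config: EmbedConfig | None = None,
        eps: float | None = None,
        min_pts: int = 3,
        k: int = 3,
        significance: SignificanceRule | None = None,
    ):
        self.events = events
        self.embed_config = embed_config or EmbedConfig()
        self.eps = eps
        self.min_pts = min_pts
        self.k = k
        self.significance = significance or SignificanceRule()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "SpaceTimeClusterModel":
        """Build a model from a pandas DataFrame of event records."""
        return cls(EventSet.from_frame(df), **kwargs)

    def fit(self) -> "SpaceTimeClusterResults":
        """Run the full detection pipeline and return the results."""
        points = embed(self.events, self.embed_config)
        profile = knn_profile(points, k=self.k)
        if self.eps is not None:
            eps, eps_source, knee_index = float(self.eps), "manual", None
        else:
            eps, knee_index = knee_epsilon(profile)
            eps_source = "knee"
        labeling = dbscan(points, DbscanParams(eps=eps, min_pts=self.min_pts))
        summaries = summarize_clusters(labeling, self.events, points)
        if summaries:
            summaries = select_significant(summaries, self.significance)
        return SpaceTimeClusterResults(
            model=self,
            points=points,
            k_profile=profile,
            eps=eps,
            eps_source=eps_source,
            knee_index=knee_index,
            labeling=labeling,
            summaries=summaries,
        )


@dataclass
class GroupComparison:
    """Clustered-vs-non-clustered comparison tables and fits."""

    chi_squares: dict[str, tuple[ChiSquareResult, np.ndarray]]
    t_tests: dict[str, TTestResult]
    logistic: LogisticFit | None
    n_clustered: int
    n_non_clustered: int

    def summary(self) -> str:
        buf = StringIO()
        buf.write(
            f"Clustered vs non-clustered comparison "
            f"(n = {self.n_clustered} vs {self.n_non_clustered})\n\n"
        )
        buf.write("Chi-square tests (Yates correction on 2x2 tables)\n")
        for var, (res, _counts) in self.chi_squares.items():
            star = "*" if res.p_value < 0.05 else ""
            buf.write(
                f"  {var:<22s} chi2 = {res.statistic:6.2f}{star:<2s} "
                f"df = {res.df}  p = {res.p_value:.3f}\n"
            )
        if self.t_tests:
            buf.write("\nSDQ two-sample t-tests (pooled variance)\n")
            for scale, res in self.t_tests.items():
                buf.write(
                    f"  {scale:<22s} t = {res.statistic:6.2f}  "
                    f"p = {res.p_value:.3f}  (n = {res.n_x} vs {res.n_y})\n"
                )
        if self.logistic is not None:
            buf.write(
                f"\nLogistic regression on clustered membership "
                f"(n = {self.logistic.n_used} complete cases, "
                f"{self.logistic.iterations} IRLS iterations)\n"
            )
            buf.write(self.logistic.to_frame().round(3).to_string())
            buf.write("\n")
        return buf.getvalue()


@dataclass
class SpaceTimeClusterResults:
    """Fitted results: labeling, ranked cluster summaries, diagnostics."""

    model: SpaceTimeClusterModel
    points: np.ndarray
    k_profile: KDistProfile
    eps: float
    eps_source: str  # "knee" or "manual"
    knee_index: int | None
    labeling: ClusterLabeling
    summaries: list[ClusterSummary]

    # -- basic accessors ----------------------------------------------------

    @property
    def n_events(self) -> int:
        return len(self.model.events)

    @property
    def n_clusters(self) -> int:
        return self.labeling.n_clusters

    @property
    def n_noise(self) -> int:
        return int(self.labeling.noise_mask.sum())

    @property
    def significant_summaries(self) -> list[ClusterSummary]:
        return [s for s in self.summaries if s.significant]

    @property
    def cluster_flags(self) -> np.ndarray:
        """Per-event boolean: member of a *significant* cluster."""
        sig_ids = {s.cluster_id for s in self.significant_summaries}
        return np.asarray([lab in sig_ids for lab in self.labeling.labels])

    @property
    def significant_labeling(self) -> ClusterLabeling:
        """Labeling with members of non-significant clusters set to noise."""
        sig_ids = {s.cluster_id for s in self.significant_summaries}
        labels = np.where(np.isin(self.labeling.labels, list(sig_ids)), self.labeling.labels, 0)
        roles = np.where(labels == 0, "noise", self.labeling.roles)
        return ClusterLabeling(labels=labels, roles=roles.astype(str))

    @property
    def clustered_fraction(self) -> float:
        return clustered_fraction(self.summaries, self.n_events)

    # -- tables -------------------------------------------------------------

    def summary_frame(self) -> pd.DataFrame:
        """Per-cluster summary table, one row per cluster, ranked by mdis."""
        rows = []
        for s in self.summaries:
            rows.append(
                {
                    "rank": s.rank,
                    "cluster_id": s.cluster_id,
                    "mdis": s.mdis,
                    "n": s.n,
                    "prop_male": s.prop_male,
                    "prop_high": s.prop_high,
                    "prop_middle": s.prop_middle,
                    "mean_age": s.mean_age,
                    "first_date": s.first_date.isoformat(),
                    "last_date": s.last_date.isoformat(),
                    "span_days": s.span_days,
                    "centroid_lon": s.centroid_lon,
                    "centroid_lat": s.centroid_lat,
                    "hull_area": s.hull_area,
                    "significant": s.significant,
                }
            )
        return pd.DataFrame(rows)

    def labeling_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "event_id": [e.id for e in self.model.events],
                "label": self.labeling.labels,
                "role": self.labeling.roles,
                "significant": self.cluster_flags,
            }
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        buf = StringIO()
        n_sig = len(self.significant_summaries)
        buf.write("Space-time cluster detection results\n")
        buf.write("=" * 52 + "\n")
        buf.write(f"events:               {self.n_events}\n")
        buf.write(f"embedding:            {self.model.embed_config.mode}\n")
        buf.write(
            f"eps:                  {self.eps:.4g} ({self.eps_source}, k={self.model.k})\n"
        )
        buf.write(f"min_pts:              {self.model.min_pts}\n")
        buf.write(f"clusters detected:    {self.n_clusters}\n")
        buf.write(f"noise points:         {self.n_noise}\n")
        buf.write(f"significant clusters: {n_sig}\n")
        n_clustered = int(self.cluster_flags.sum())
        buf.write(
            f"clustered events:     {n_clustered} "
            f"({100 * self.clustered_fraction:.1f}%)\n"
        )
        if self.summaries:
            spans = [s.span_days for s in self.significant_summaries]
            if spans:
                buf.write(f"temporal range:       {min(spans)}-{max(spans)} days\n")
            buf.write("\n")
            cols = ["rank", "cluster_id", "mdis", "n", "span_days", "significant"]
            buf.write(self.summary_frame()[cols].round(3).to_string(index=False))
            buf.write("\n")
        return buf.getvalue()

    # -- group statistics -----------------------------------------------------

    def compare_groups(
        self,
        variables: tuple[str, ...] | None = None,
        logistic_spec: LogisticSpec | None = None,
        fit_regression: bool = True,
    ) -> GroupComparison:
        """Compare significant-cluster members against everyone else."""
        flags = self.cluster_flags
        if variables is None:
            variables = tuple(CATEGORICAL_LEVELS)
        chis = {}
        for var in variables:
            table = crosstab(self.model.events, var, flags)
            chis[var] = (chi_square(table), table.counts)
        tts = {}
        for scale in SDQ_SCALES:
            x = [getattr(e, scale) for e, f in zip(self.model.events, flags) if not f]
            y = [getattr(e, scale) for e, f in zip(self.model.events, flags) if f]
            x = [v for v in x if v is not None]
            y = [v for v in y if v is not None]
            if len(x) >= 2 and len(y) >= 2:
                tts[scale] = two_sample_t(x, y, variant="pooled")
        logit = None
        if fit_regression:
            logit = fit_logistic(self.model.events, logistic_spec or LogisticSpec(), flags)
        return GroupComparison(
            chi_squares=chis,
            t_tests=tts,
            logistic=logit,
            n_clustered=int(flags.sum()),
            n_non_clustered=int((~flags).sum()),
        )

    # -- exports and plots ----------------------------------------------------

    def hulls_geojson(self, significant_only: bool = True) -> dict:
        """Significant-cluster convex hulls as GeoJSON polygons (lon-lat)."""
        from scipy.spatial import ConvexHull, QhullError

        features = []
        for s in self.summaries:
            if significant_only and not s.significant:
                continue
            idx = self.labeling.members(s.cluster_id)
            coords = [[self.model.events[int(i)].lon, self.model.events[int(i)].lat] for i in idx]
            try:
                hull = ConvexHull(np.asarray(coords))
                ring = [coords[int(v)] for v in hull.vertices]
                ring.append(ring[0])
                geom = {"type": "Polygon", "coordinates": [ring]}
            except QhullError:
                geom = {"type": "MultiPoint", "coordinates": coords}
            features.append(
                {
                    "type": "Feature",
                    "geometry": geom,
                    "properties": {
                        "cluster_id": s.cluster_id,
                        "rank": s.rank,
                        "n": s.n,
                        "mdis": s.mdis,
                        "significant": s.significant,
                    },
                }
            )
        return {"type": "FeatureCollection", "features": features}

    def write_hulls_geojson(self, path, significant_only: bool = True) -> None:
        with open(path, "w") as fh:
            json.dump(self.hulls_geojson(significant_only), fh)

    def plot_k_distance(self, ax=None):
        """Sorted k-distance curve with the selected eps marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.k_profile.sorted_curve, lw=1.5)
        ax.axhline(self.eps, color="crimson", ls="--", label=f"eps = {self.eps:.3g}")
        ax.set_xlabel("points sorted by k-NN distance")
        ax.set_ylabel(f"{self.model.k}-NN distance")
        ax.legend()
        return ax

    def plot_rank_curve(self, metric: str = "mdis", ax=None):
        """Rank-ordered cluster metric with the significance cutoff marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        vals = [getattr(s, metric) for s in self.summaries]
        ax.plot(range(1, len(vals) + 1), vals, "o-")
        n_sig = len(self.significant_summaries)
        if 0 < n_sig < len(vals):
            ax.axvline(n_sig + 0.5, color="crimson", ls="--", label=f"cutoff rank {n_sig}")
            ax.legend()
        ax.set_xlabel("cluster rank")
        ax.set_ylabel(metric)
        return ax
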