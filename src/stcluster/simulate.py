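"""Synthetic space-time event generator with planted clusters.

Real student suicide reports are restricted data, so end-to-end testing uses
a generator that reproduces the statistical structure the detection pipeline
assumes:

* a 5-year observation window (default 2016-01-01 .. 2020-12-31);
* background events whose locations follow a Gaussian-mixture-plus-uniform
  intensity surface — a stand-in for population concentrated in a few large
  cities over a sparse rural background — with dates uniform over the window
  (so the dense metropolis component produces the characteristic large,
  temporally diffuse density cluster that the significance step must
  exclude);
* planted space-time clusters of 3-9 events each, spanning 7-59 days within
  a small spatial radius;
* categorical covariates drawn per a logistic model: baseline prevalences
  for background events and log-odds shifts for planted-cluster members
  (defaults: poverty +0.70, psychiatric history -0.72).

Covariates are generated independently of one another given cluster
membership; no covariate correlation structure is imposed.

One NumPy generator seeded once drives every draw, in a fixed documented
order (background locations, background dates, then per-cluster anchor,
span, member jitter; covariates last, event by event), so a given seed
reproduces the event set bitwise.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .cluster import ClusterLabeling
from .events import Event, EventSet, MISSING
from .embed import KM_PER_DEG

#: default urban mixture, loosely shaped like South Korea's largest cities:
#: (lon, lat, weight, sd_km)
DEFAULT_CENTERS: tuple[tuple[float, float, float, float], ...] = (
    (126.98, 37.56, 0.50, 6.0),  # capital metropolis: half the mass, dense core
    (129.08, 35.18, 0.06, 28.0),  # secondary cities: broad regional concentrations
    (128.60, 35.87, 0.05, 28.0),
    (126.85, 35.16, 0.04, 25.0),
    (127.38, 36.35, 0.04, 25.0),
)
DEFAULT_BBOX = (126.1, 129.6, 34.3, 38.5)  # lon_min, lon_max, lat_min, lat_max

#: baseline covariate prevalences of background (non-clustered) events
DEFAULT_PREVALENCES: dict[str, dict[str, float]] = {
    "sex": {"male": 0.52, "female": 0.48},
    "school_type": {"elementary": 0.04, "middle": 0.32, "high": 0.64},
    "family_structure": {"both_parents": 0.70, "other": 0.30},
    "economic_status": {"upper": 0.10, "middle": 0.68, "lower": 0.22},
    "method": {"jumping": 0.70, "hanging": 0.25, "other": 0.05},
    "concern_family": {"yes": 0.37, "no": 0.63},
    "concern_academic": {"yes": 0.36, "no": 0.64},
    "concern_peer": {"yes": 0.15, "no": 0.85},
    "psychiatric_history": {"yes": 0.41, "no": 0.59},
    "attempt_history": {"yes": 0.08, "no": 0.92},
    "selfharm_history": {"yes": 0.12, "no": 0.88},
}

#: log-odds shifts applied to planted-cluster members: (field, level, shift)
DEFAULT_CLUSTER_EFFECTS: tuple[tuple[str, str, float], ...] = (
    ("economic_status", "lower", 0.70),
    ("psychiatric_history", "yes", -0.72),
)

#: per-field probability of a missing cell (mimics uneven column totals)
DEFAULT_MISSING_RATES: dict[str, float] = {
    "sex": 0.006,
    "family_structure": 0.006,
    "economic_status": 0.17,
    "method": 0.006,
    "concern_family": 0.002,
    "concern_academic": 0.0,
    "concern_peer": 0.0,
    "psychiatric_history": 0.003,
    "attempt_history": 0.005,
    "selfharm_history": 0.006,
}

#: teacher-rated SDQ subscale (mean, sd), collected from 2018 onward
SDQ_MOMENTS: dict[str, tuple[float, float]] = {
    "sdq_prosocial": (5.95, 2.57),
    "sdq_hyperactivity": (2.61, 2.21),
    "sdq_emotional": (2.29, 2.29),
    "sdq_conduct": (1.23, 1.33),
    "sdq_peer": (2.03, 2.03),
}
SDQ_START = dt.date(2018, 1, 1)


@dataclass
class SimConfig:
    """Scenario definition for the synthetic generator."""

    window_start: dt.date = dt.date(2016, 1, 1)
    window_days: int = 1826  # 2016-01-01 .. 2020-12-31 inclusive
    n_background: int = 560
    centers: tuple[tuple[float, float, float, float], ...] = DEFAULT_CENTERS
    uniform_weight: float = 0.31
    bbox: tuple[float, float, float, float] = DEFAULT_BBOX
    n_planted: int = 15
    cluster_size_range: tuple[int, int] = (3, 9)
    cluster_span_range_days: tuple[int, int] = (7, 59)
    cluster_radius_km: float = 3.0
    anchor_exclude_components: tuple[int, ...] = (0,)
    prevalences: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    cluster_effects: tuple = DEFAULT_CLUSTER_EFFECTS
    missing_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.window_start, str):
            self.window_start = dt.date.fromisoformat(self.window_start)
        if self.n_background < 0 or self.n_planted < 0:
            raise ValueError("counts must be non-negative")
        lo, hi = self.cluster_size_range
        if not (0 < lo <= hi):
            raise ValueError("cluster_size_range must be ordered and positive")
        slo, shi = self.cluster_span_range_days
        if not (0 < slo <= shi):
            raise ValueError("cluster_span_range_days must be ordered and positive")
        if shi >= self.window_days:
            raise ValueError("planted cluster span exceeds the observation window")
        w = self.uniform_weight + sum(c[2] for c in self.centers)
        if not math.isclose(w, 1.0, abs_tol=1e-9):
            raise ValueError(f"mixture weights must sum to 1, got {w}")

    @property
    def window(self) -> tuple[dt.date, dt.date]:
        return (
            self.window_start,
            self.window_start + dt.timedelta(days=self.window_days - 1),
        )

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "centers" in raw:
            raw["centers"] = tuple(tuple(c) for c in raw["centers"])
        if "cluster_effects" in raw:
            raw["cluster_effects"] = tuple(tuple(c) for c in raw["cluster_effects"])
        for key in (
            "bbox",
            "cluster_size_range",
            "cluster_span_range_days",
            "anchor_exclude_components",
        ):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["window_start"] = self.window_start.isoformat()
        raw["centers"] = [list(c) for c in self.centers]
        raw["cluster_effects"] = [list(c) for c in self.cluster_effects]
        for key in (
            "bbox",
            "cluster_size_range",
            "cluster_span_range_days",
            "anchor_exclude_components",
        ):
            raw[key] = list(raw[key])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass(frozen=True)
class GroundTruth:
    """Per-event planted-cluster id, 0 for background."""

    planted_id: np.ndarray

    def __len__(self) -> int:
        return len(self.planted_id)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _inv_logit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _shifted_probs(probs: dict[str, float], level: str, shift: float) -> dict[str, float]:
    """Shift the log-odds of one level versus the rest; renormalize the rest."""
    p = probs[level]
    p_new = _inv_logit(_logit(p) + shift)
    rest = 1.0 - p
    out = {}
    for lv, q in probs.items():
        out[lv] = p_new if lv == level else q * (1.0 - p_new) / rest
    return out


def _draw_location(
    rng: np.random.Generator,
    config: SimConfig,
    exclude: tuple[int, ...] = (),
) -> tuple[float, float]:
    """One (lon, lat) from the mixture intensity surface.

    ``exclude`` removes mixture components (by index) before drawing; used
    for planted-cluster anchors, which are kept away from the densest
    component where a planted cluster would be indistinguishable from the
    ambient concentration.
    """
    weights = [
        0.0 if i in exclude else c[2] for i, c in enumerate(config.centers)
    ] + [config.uniform_weight]
    comp = rng.choice(len(weights), p=np.asarray(weights) / sum(weights))
    lon_min, lon_max, lat_min, lat_max = config.bbox
    if comp == len(config.centers):
        return float(rng.uniform(lon_min, lon_max)), float(rng.uniform(lat_min, lat_max))
    clon, clat, _w, sd_km = config.centers[comp]
    dy = rng.normal(0.0, sd_km)
    dx = rng.normal(0.0, sd_km)
    lat = clat + dy / KM_PER_DEG
    lon = clon + dx / (KM_PER_DEG * math.cos(math.radians(clat)))
    return float(np.clip(lon, -180, 180)), float(np.clip(lat, -90, 90))


def _draw_covariates(
    rng: np.random.Generator, config: SimConfig, clustered: bool, date: dt.date
) -> dict:
    out: dict = {}
    effects = {(f, lv): s for f, lv, s in config.cluster_effects}
    for name, probs in config.prevalences.items():
        if rng.random() < config.missing_rates.get(name, 0.0):
            out[name] = MISSING
            continue
        if clustered:
            for (f, lv), s in effects.items():
                if f == name:
                    probs = _shifted_probs(probs, lv, s)
        levels = list(probs)
        out[name] = str(rng.choice(levels, p=np.asarray([probs[lv] for lv in levels])))
    # age follows school type
    ages = {"elementary": (9, 12), "middle": (13, 15), "high": (16, 18)}
    st = out.get("school_type", MISSING)
    if st in ages:
        lo, hi = ages[st]
        out["age"] = float(rng.integers(lo, hi + 1))
    else:
        out["age"] = None
    # SDQ collected only in the later part of the window
    if date >= SDQ_START:
        total = 0.0
        for name, (m, sd) in SDQ_MOMENTS.items():
            v = float(np.clip(round(rng.normal(m, sd)), 0, 10))
            out[name] = v
            if name != "sdq_prosocial":
                total += v
        out["sdq_total"] = total
    return out


def simulate(config: SimConfig | None = None) -> tuple[EventSet, GroundTruth]:
    """Generate one synthetic event set with ground-truth planted labels.

    Background events come first (ids b0001..), then planted clusters in
    order (ids c01-1..); row order is the draw order.
    """
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(config.seed)
    start = config.window_start
    events: list[Event] = []
    truth: list[int] = []

    for i in range(config.n_background):
        lon, lat = _draw_location(rng, config)
        date = start + dt.timedelta(days=int(rng.integers(0, config.window_days)))
        cov = _draw_covariates(rng, config, clustered=False, date=date)
        events.append(Event(id=f"b{i + 1:04d}", lat=lat, lon=lon, date=date, **cov))
        truth.append(0)

    size_lo, size_hi = config.cluster_size_range
    span_lo, span_hi = config.cluster_span_range_days
    for k in range(1, config.n_planted + 1):
        anchor_lon, anchor_lat = _draw_location(
            rng, config, exclude=tuple(config.anchor_exclude_components)
        )
        size = int(rng.integers(size_lo, size_hi + 1))
        span = int(rng.integers(span_lo, span_hi + 1))
        anchor_day = int(rng.integers(0, config.window_days - span))
        for j in range(size):
            dx = rng.normal(0.0, config.cluster_radius_km)
            dy = rng.normal(0.0, config.cluster_radius_km)
            lat = anchor_lat + dy / KM_PER_DEG
            lon = anchor_lon + dx / (KM_PER_DEG * math.cos(math.radians(anchor_lat)))
            day = anchor_day + int(rng.integers(0, span + 1))
            date = start + dt.timedelta(days=day)
            cov = _draw_covariates(rng, config, clustered=True, date=date)
            events.append(
                Event(id=f"c{k:02d}-{j + 1}", lat=float(lat), lon=float(lon), date=date, **cov)
            )
            truth.append(k)

    return (
        EventSet(events=events, window=config.window),
        GroundTruth(planted_id=np.asarray(truth, dtype=int)),
    )


# ---------------------------------------------------------------------------
# recovery evaluation


def adjusted_rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Chance-corrected agreement between two labelings of the same items."""
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b):
        raise ValueError("labelings must have equal length")
    n = len(a)
    if n < 2:
        return 1.0
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(cont, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(cont).sum()
    sum_a = comb2(cont.sum(axis=1)).sum()
    sum_b = comb2(cont.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def evaluate_recovery(truth: GroundTruth, labeling: ClusterLabeling) -> dict:
    """Compare a predicted labeling against the planted ground truth.

    A planted cluster counts as *recovered* iff some predicted cluster
    contains at least half of its members and that predicted cluster's
    plurality truth class is this planted cluster.  Background/noise is
    treated as its own class for the adjusted Rand index.
    """
    t = np.asarray(truth.planted_id)
    pred = np.asarray(labeling.labels)
    if len(t) != len(pred):
        raise ValueError("ground truth and labeling lengths differ")
    planted_ids = [k for k in np.unique(t) if k != 0]
    recovered: dict[int, bool] = {}
    for k in planted_ids:
        members = np.flatnonzero(t == k)
        ok = False
        pred_in = pred[members]
        for c in np.unique(pred_in):
            if c == 0:
                continue
            if (pred_in == c).sum() * 2 >= len(members):
                truth_in_c = t[pred == c]
                vals, counts = np.unique(truth_in_c, return_counts=True)
                if vals[np.argmax(counts)] == k:
                    ok = True
                    break
        recovered[int(k)] = ok
    n_planted = len(planted_ids)
    n_rec = sum(recovered.values())
    return {
        "ari": adjusted_rand_index(t, pred),
        "n_planted": n_planted,
        "n_recovered": n_rec,
        "recovery_rate": n_rec / n_planted if n_planted else float("nan"),
        "recovered": recovered,
    }
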