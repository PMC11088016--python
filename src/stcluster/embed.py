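"""Standardized 3-D space-time embedding of events.

Events are mapped to points (x, y, t) so that spatial and temporal proximity
are measured on a common scale and density clustering can operate in the
joint space.  Two modes are provided:

``zscore`` (default)
    Each raw axis (longitude, latitude, day index) is centered to mean 0 and
    scaled to sample standard deviation 1, then multiplied by its axis
    weight.  This is the conventional "standardize everything" embedding; the
    resulting units are data-dependent.

``metric``
    Longitude/latitude are projected to kilometres east/north with an
    equirectangular projection about the mean latitude, time is counted in
    days, and each axis is divided by an explicit, interpretable scale
    (km per spatial unit, days per temporal unit).  At intra-country extents
    the equirectangular error versus a great-circle distance is below 0.5%.

Distances in the embedded space are Euclidean.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .events import EventSet

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius
KM_PER_DEG = EARTH_RADIUS_KM * math.pi / 180.0  # ~111.195 km per degree of latitude


@dataclass(frozen=True)
class EmbedConfig:
    """Configuration of the space-time embedding.

    Parameters
    ----------
    mode
        ``"zscore"`` or ``"metric"`` (see module docstring).
    axis_weights
        Dimensionless multipliers (w_x, w_y, w_t) applied after scaling;
        they expose the space-versus-time trade-off.  Default (1, 1, 1).
    time_origin
        Date mapped to day 0.  Default: earliest event date.
    km_scale, day_scale
        Metric-mode units: kilometres per embedded spatial unit and days per
        embedded temporal unit.  Ignored in zscore mode.
    """

    mode: str = "zscore"
    axis_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    time_origin: dt.date | None = None
    km_scale: float = 1.0
    day_scale: float = 1.0

    def __post_init__(self):
        if self.mode not in ("zscore", "metric"):
            raise ValueError(f"unknown embed mode {self.mode!r}")
        if any(w <= 0 for w in self.axis_weights):
            raise ValueError("axis weights must be positive")
        if self.km_scale <= 0 or self.day_scale <= 0:
            raise ValueError("scales must be positive")


def to_day_index(date: dt.date, origin: dt.date) -> int:
    """Signed whole-day difference (date - origin); day resolution only."""
    return (date - origin).days


def embed(events: EventSet, config: EmbedConfig | None = None) -> np.ndarray:
    """Embed events into standardized 3-space.

    Returns an (n, 3) float array of (x, y, t) points, one per event, in the
    same order as the event set.

    Raises
    ------
    ValueError
        In zscore mode, if fewer than 2 events are given or any axis has
        zero variance (the standardization is then undefined).
    """
    if config is None:
        config = EmbedConfig()
    n = len(events)
    if n == 0:
        return np.empty((0, 3))
    origin = config.time_origin or min(e.date for e in events)
    lon = np.array([e.lon for e in events], dtype=float)
    lat = np.array([e.lat for e in events], dtype=float)
    day = np.array([to_day_index(e.date, origin) for e in events], dtype=float)
    wx, wy, wt = config.axis_weights

    if config.mode == "zscore":
        if n < 2:
            raise ValueError("zscore embedding needs at least 2 events")
        cols = []
        for name, v, w in (("lon", lon, wx), ("lat", lat, wy), ("time", day, wt)):
            sd = v.std(ddof=1)
            if sd == 0:
                raise ValueError(f"zero variance on {name} axis; zscore embedding undefined")
            cols.append((v - v.mean()) / sd * w)
        return np.column_stack(cols)

    # metric mode: equirectangular projection about the mean latitude
    lat0 = lat.mean()
    x = lon * KM_PER_DEG * math.cos(math.radians(lat0)) / config.km_scale * wx
    y = lat * KM_PER_DEG / config.km_scale * wy
    t = day / config.day_scale * wt
    return np.column_stack([x, y, t])


def pairwise_distance(points: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix with zero diagonal."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) == 0:
        raise ValueError("points must be a non-empty 2-D array")
    if len(points) == 1:
        return np.zeros((1, 1))
    return squareform(pdist(points, metric="euclidean"))


def haversine_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance in km (used as the projection accuracy oracle)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))
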