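"""Available-environment (background) construction and annotation.

The background defines what conditions a population could have used: all of
a flyway's locations are pooled into a 100% minimum convex polygon, the
polygon is dilated by a buffer (default 300 km, the maximum home-range scale
of the study species during staging and wintering), and background points
are sampled uniformly from the buffered area.  Each background point is then
annotated with environmental values in one of two modes: ``climate`` (the
mean of the season's two long-term monthly layers) or ``weather`` (the daily
layer of a season-specific random date drawn uniformly over the tracked
period).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import MultiPoint, Polygon
from shapely.geometry.polygon import orient
from shapely import wkt as shapely_wkt

from ._rng import substream
from .seasons import SEASON_MONTHS
from .synthetic import VARIABLES, EnvironmentSet

__all__ = [
    "BackgroundSample",
    "compute_mcp",
    "buffer_polygon",
    "sample_background",
    "annotate",
    "annotate_occurrences",
    "build_background",
]


@dataclass
class BackgroundSample:
    """Uniform background points for one flyway with per-season annotations.

    ``annotations[(season, mode)]`` holds one row per background point with
    columns temperature, precipitation, ndvi (plus date in weather mode).
    """

    flyway: str
    polygon: Polygon
    points: pd.DataFrame  # columns x_km, y_km
    annotations: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)

    def annotation(self, season: str, mode: str) -> pd.DataFrame:
        return self.annotations[(season, mode)]

    def to_wkt(self) -> str:
        return shapely_wkt.dumps(self.polygon)


def compute_mcp(points: pd.DataFrame | np.ndarray) -> Polygon:
    """100% minimum convex polygon (convex hull) of planar locations.

    Returns a counter-clockwise polygon containing every input point.
    Raises on fewer than 3 points or a fully collinear set.
    """
    xy = _as_xy(points)
    if len(xy) < 3:
        raise ValueError("MCP needs at least 3 points")
    hull = MultiPoint([tuple(p) for p in xy]).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0:
        raise ValueError("degenerate geometry: points are collinear")
    return orient(hull, sign=1.0)


def buffer_polygon(polygon: Polygon, dist_km: float, quad_segs: int = 16) -> Polygon:
    """Minkowski dilation of a polygon by a disc of radius ``dist_km``.

    Arcs are approximated with ``quad_segs`` segments per quarter circle
    (64 per full circle by default).
    """
    if dist_km < 0:
        raise ValueError("buffer distance must be >= 0")
    if dist_km == 0:
        return polygon
    return orient(polygon.buffer(dist_km, quad_segs=quad_segs), sign=1.0)


def sample_background(polygon: Polygon, n: int, seed: int, label: str = "") -> pd.DataFrame:
    """Sample ``n`` points uniformly over a polygon by rejection from its bbox."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if polygon.area <= 0:
        raise ValueError("polygon has zero area")
    rng = substream(seed, "background", label)
    minx, miny, maxx, maxy = polygon.bounds
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    got = 0
    # acceptance rate = polygon area / bbox area; oversample accordingly
    rate = max(polygon.area / ((maxx - minx) * (maxy - miny)), 1e-3)
    while got < n:
        m = int((n - got) / rate * 1.2) + 16
        cx = rng.uniform(minx, maxx, m)
        cy = rng.uniform(miny, maxy, m)
        inside = contains_xy(polygon, cx, cy)
        xs.append(cx[inside])
        ys.append(cy[inside])
        got += int(inside.sum())
    x = np.concatenate(xs)[:n]
    y = np.concatenate(ys)[:n]
    return pd.DataFrame({"x_km": x, "y_km": y})


def _as_xy(points) -> np.ndarray:
    if isinstance(points, pd.DataFrame):
        return points[["x_km", "y_km"]].to_numpy(float)
    return np.asarray(points, float).reshape(-1, 2)


def _season_days(env: EnvironmentSet, season: str) -> pd.DatetimeIndex:
    months = SEASON_MONTHS[season]
    mask = env.time_index.month.isin(months)
    return env.time_index[mask]


def annotate(
    points: pd.DataFrame,
    env: EnvironmentSet,
    season: str,
    mode: str,
    seed: int = 0,
    label: str = "",
) -> pd.DataFrame:
    """Annotate planar points with environmental values for one season.

    climate mode: per variable, the mean of the season's two monthly climate
    layers at each point (pure lookup, identical on repetition).  weather
    mode: each point receives an independent random date, uniform over all
    days of the season's months across the tracked years, and is annotated
    with that day's weather layer; deterministic given the seed.
    """
    xy = _as_xy(points)
    inside = env.geometry.contains(xy[:, 0], xy[:, 1])
    if not inside.all():
        bad = np.flatnonzero(~inside)[0]
        raise ValueError(
            f"point ({xy[bad, 0]:.1f}, {xy[bad, 1]:.1f}) outside environment extent"
        )
    out = pd.DataFrame(index=pd.RangeIndex(len(xy)))
    if mode == "climate":
        months = SEASON_MONTHS[season]
        for var in VARIABLES:
            out[var] = env.season_climate_at(var, xy[:, 0], xy[:, 1], months)
    elif mode == "weather":
        rng = substream(seed, "annotate", season, label)
        days = _season_days(env, season)
        picks = rng.integers(len(days), size=len(xy))
        dates = days[picks]
        out["date"] = dates
        iy, ix = env.geometry.cell_index(xy[:, 0], xy[:, 1])
        offsets = env.time_index.get_indexer(dates)
        for var in VARIABLES:
            out[var] = env.weather[var][offsets, iy, ix]
    else:
        raise ValueError(f"mode must be 'climate' or 'weather', got {mode!r}")
    return out


def annotate_occurrences(
    points: pd.DataFrame, env: EnvironmentSet, season: str, mode: str
) -> pd.DataFrame:
    """Annotate occurrence (GPS) points at their own recorded dates.

    climate mode uses the season's monthly-mean layers exactly as for
    background points; weather mode uses the daily layer of each fix's own
    date (no randomization — the animal was really there on that day).
    """
    xy = _as_xy(points)
    out = pd.DataFrame(index=pd.RangeIndex(len(xy)))
    if mode == "climate":
        months = SEASON_MONTHS[season]
        for var in VARIABLES:
            out[var] = env.season_climate_at(var, xy[:, 0], xy[:, 1], months)
        return out
    if mode != "weather":
        raise ValueError(f"mode must be 'climate' or 'weather', got {mode!r}")
    dates = pd.DatetimeIndex(points["timestamp"]).normalize()
    offsets = env.time_index.get_indexer(dates)
    if (offsets < 0).any():
        bad = dates[offsets < 0][0]
        raise ValueError(f"fix date {bad.date()} outside environment time index")
    iy, ix = env.geometry.cell_index(xy[:, 0], xy[:, 1])
    for var in VARIABLES:
        out[var] = env.weather[var][offsets, iy, ix]
    return out


def build_background(
    flyway: str,
    flyway_points: pd.DataFrame,
    env: EnvironmentSet,
    n_background: int = 10_000,
    buffer_km: float = 300.0,
    seed: int = 0,
    seasons=None,
    modes=("climate", "weather"),
) -> BackgroundSample:
    """MCP -> buffer -> uniform sample -> per-season annotation, one flyway.

    The polygon is clipped to the environment extent before sampling so that
    every background point can be annotated.  ``seasons``/``modes`` restrict
    which annotation tables are built (default: all four seasons, both
    modes).
    """
    mcp = compute_mcp(flyway_points)
    poly = buffer_polygon(mcp, buffer_km)
    xmin, xmax, ymin, ymax = env.geometry.extent
    domain = Polygon([(xmin, ymin), (xmax, ymin), (xmax, ymax), (xmin, ymax)])
    clipped = poly.intersection(domain)
    pts = sample_background(clipped, n_background, seed, label=flyway)
    bg = BackgroundSample(flyway, clipped, pts)
    for season in (seasons if seasons is not None else SEASON_MONTHS):
        for mode in modes:
            bg.annotations[(season, mode)] = annotate(
                pts, env, season, mode, seed=seed, label=flyway
            )
    return bg
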