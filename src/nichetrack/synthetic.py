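"""Synthetic environment fields and movement tracks with known structure.

The generator plays the role of the field campaign: it produces gridded
daily "weather" layers (and their long-term monthly means, the "climate"
layers) for temperature, precipitation and NDVI on a planar km grid, and
individual movement tracks whose tendency to seek preferred environmental
conditions is controlled by a single bias parameter ``kappa``.  ``kappa = 0``
gives an environment-blind correlated random walk; large ``kappa`` gives
individuals that follow their preferred conditions through the seasons, i.e.
track their niche by construction.  Every downstream stage of the pipeline
can therefore be exercised against known ground truth.

Weather fields are built as (smooth spatial gradient) + (sinusoidal seasonal
cycle evaluated per calendar month, constant within a month) + (spatially
correlated daily noise).  Climate layers are computed as across-year monthly
means of the weather stack, so the climate/weather consistency invariant
holds by construction, and a zero-noise configuration makes every weather
day identical to its month's climate layer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ._rng import substream
from .seasons import SEASONS
from .tracks import FLYWAYS, Track

__all__ = [
    "VARIABLES",
    "GridGeometry",
    "EnvironmentSet",
    "SimulationConfig",
    "generate_environment",
    "generate_tracks",
    "write_environment",
    "read_environment",
]

VARIABLES = ("temperature", "precipitation", "ndvi")

# deterministic field parameters per variable:
#   mean, (gradient_x, gradient_y) per km, seasonal amplitude, peak month,
#   (clip_lo, clip_hi)
_FIELD_PARAMS = {
    "temperature": dict(mean=15.0, grad=(0.0, -0.02), amp=10.0, peak=7,
                        clip=(None, None)),          # degC, cooler northwards
    "precipitation": dict(mean=3.0, grad=(0.004, 0.0), amp=1.5, peak=1,
                          clip=(0.0, None)),         # mm/day, wetter eastwards
    "ndvi": dict(mean=0.45, grad=(0.0, 0.0004), amp=0.25, peak=8,
                 clip=(0.0, 1.0)),                   # unitless greenness
}

# scale used to make mismatches across variables comparable (roughly the
# within-season spatial spread of each field)
TARGET_SCALES = {"temperature": 2.0, "precipitation": 1.0, "ndvi": 0.1}


@dataclass(frozen=True)
class GridGeometry:
    """Planar raster geometry: origin (km), square cell size (km), shape."""

    origin: tuple[float, float]
    cell_km: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.cell_km <= 0 or self.nx <= 0 or self.ny <= 0:
            raise ValueError("grid dimensions and cell size must be positive")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) in km."""
        x0, y0 = self.origin
        return (x0, x0 + self.nx * self.cell_km, y0, y0 + self.ny * self.cell_km)

    def cell_index(self, x, y):
        """Nearest-cell (iy, ix) indices, clipped to the grid."""
        x0, y0 = self.origin
        ix = np.clip(((np.asarray(x) - x0) / self.cell_km).astype(int), 0, self.nx - 1)
        iy = np.clip(((np.asarray(y) - y0) / self.cell_km).astype(int), 0, self.ny - 1)
        return iy, ix

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.nx) + 0.5) * self.cell_km
        ys = y0 + (np.arange(self.ny) + 0.5) * self.cell_km
        return xs, ys

    def contains(self, x, y):
        xmin, xmax, ymin, ymax = self.extent
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)


@dataclass
class EnvironmentSet:
    """Daily weather stacks plus long-term monthly climate layers.

    ``weather[var]`` has shape (n_days, ny, nx) indexed by ``time_index``;
    ``climate[var]`` has shape (12, ny, nx) indexed by calendar month.
    All variables share one grid geometry and one time index.
    """

    geometry: GridGeometry
    time_index: pd.DatetimeIndex
    weather: dict[str, np.ndarray] = field(repr=False)
    climate: dict[str, np.ndarray] = field(repr=False)
    seed: int | None = None

    def __post_init__(self) -> None:
        shape = (len(self.time_index), self.geometry.ny, self.geometry.nx)
        for var in VARIABLES:
            if self.weather[var].shape != shape:
                raise ValueError(f"weather[{var}] shape {self.weather[var].shape} != {shape}")
            if self.climate[var].shape != (12, self.geometry.ny, self.geometry.nx):
                raise ValueError(f"climate[{var}] must hold 12 monthly layers")

    @property
    def years(self) -> list[int]:
        return sorted(set(self.time_index.year))

    def day_offset(self, date) -> int:
        loc = self.time_index.get_indexer([pd.Timestamp(date).normalize()])[0]
        if loc < 0:
            raise KeyError(f"date {date} outside environment time index")
        return int(loc)

    def weather_at(self, var: str, x, y, date) -> np.ndarray:
        """Daily weather value(s) at planar point(s), nearest-cell lookup."""
        iy, ix = self.geometry.cell_index(x, y)
        t = self.day_offset(date)
        return self.weather[var][t, iy, ix]

    def climate_at(self, var: str, x, y, month: int) -> np.ndarray:
        iy, ix = self.geometry.cell_index(x, y)
        return self.climate[var][month - 1, iy, ix]

    def season_climate_at(self, var: str, x, y, months: tuple[int, int]) -> np.ndarray:
        """Unweighted mean of a season's two monthly climate layers."""
        iy, ix = self.geometry.cell_index(x, y)
        m1, m2 = months
        return 0.5 * (self.climate[var][m1 - 1, iy, ix] + self.climate[var][m2 - 1, iy, ix])


def _default_targets() -> dict[str, dict[str, dict[str, float]]]:
    """Per-flyway, per-season preferred environmental values.

    Defaults keep each flyway's target constant across seasons (the niche-
    tracking scenario: individuals seek the same conditions year-round) and
    separate the two flyways so between-population contrasts exist.
    """
    base = {
        "eastern": {"temperature": 18.0, "precipitation": 3.5, "ndvi": 0.55},
        "western": {"temperature": 12.0, "precipitation": 2.5, "ndvi": 0.40},
    }
    return {fw: {s: dict(base[fw]) for s in SEASONS} for fw in FLYWAYS}


@dataclass
class SimulationConfig:
    """Tunable study conditions for the synthetic campaign.

    The defaults describe a deliberately compact campaign: two flyways of
    five individuals tracked for two years at 20-min fixes over a 600 km
    square domain — small enough to re-simulate freely while preserving the
    multi-individual, multi-year, two-population structure the analysis
    needs.
    """

    n_individuals: int = 5              # per flyway
    years: int = 2
    start_year: int = 2015
    fix_interval_min: int = 20
    step_km: float = 5.0                # displacement per fix interval
    kappa: float = 2.0                  # environment-bias weight, >= 0
    bias_field: str = "weather"         # which field the walker perceives
    extent_km: float = 600.0
    cell_km: float = 10.0
    origin: tuple[float, float] = (0.0, 0.0)
    noise_scales: dict[str, float] = field(
        default_factory=lambda: {"temperature": 2.0, "precipitation": 1.0, "ndvi": 0.05}
    )
    noise_corr_cells: float = 5.0       # correlation length of daily noise
    targets: dict = field(default_factory=_default_targets)
    individual_target_jitter: float = 0.0   # sd of per-individual target offsets,
                                            # in units of TARGET_SCALES per variable
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.extent_km <= 0 or self.cell_km <= 0:
            raise ValueError("extent and cell size must be positive")
        if self.bias_field not in ("weather", "climate"):
            raise ValueError("bias_field must be 'weather' or 'climate'")

    @property
    def geometry(self) -> GridGeometry:
        n = int(round(self.extent_km / self.cell_km))
        return GridGeometry(self.origin, self.cell_km, n, n)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# seasonal phase per calendar month: the two months of a season share their
# season's midpoint phase, so the deterministic part of the weather is
# constant within each season block (winter wraps around New Year)
_MONTH_PHASE = {1: 0.5, 2: 2.0, 3: 3.5, 4: 3.5, 5: 5.0, 6: 6.5, 7: 6.5,
                8: 8.0, 9: 9.5, 10: 9.5, 11: 11.0, 12: 0.5}


def _monthly_base(var: str, geom: GridGeometry) -> np.ndarray:
    """Deterministic (12, ny, nx) monthly base field for one variable."""
    p = _FIELD_PARAMS[var]
    xs, ys = geom.cell_centers()
    X, Y = np.meshgrid(xs, ys)
    spatial = p["mean"] + p["grad"][0] * (X - xs.mean()) + p["grad"][1] * (Y - ys.mean())
    phase = np.array([_MONTH_PHASE[m] for m in range(1, 13)])
    cycle = p["amp"] * np.cos(2 * np.pi * (phase - p["peak"]) / 12.0)
    return spatial[None, :, :] + cycle[:, None, None]


def _clip(var: str, arr: np.ndarray) -> np.ndarray:
    lo, hi = _FIELD_PARAMS[var]["clip"]
    if lo is not None or hi is not None:
        arr = np.clip(arr, lo, hi)
    return arr


def generate_environment(config: SimulationConfig) -> EnvironmentSet:
    """Simulate daily weather stacks and derive monthly climate layers.

    Deterministic for a given config (all randomness from ``config.seed``).
    """
    geom = config.geometry
    start = pd.Timestamp(year=config.start_year, month=1, day=1)
    end = pd.Timestamp(year=config.start_year + config.years - 1, month=12, day=31)
    tindex = pd.date_range(start, end, freq="D")
    months = tindex.month.to_numpy()

    weather: dict[str, np.ndarray] = {}
    climate: dict[str, np.ndarray] = {}
    for var in VARIABLES:
        rng = substream(config.seed, "environment", var)
        base = _monthly_base(var, geom)
        stack = base[months - 1].copy()
        scale = config.noise_scales.get(var, 0.0)
        if scale > 0:
            noise = rng.standard_normal((len(tindex), geom.ny, geom.nx))
            noise = gaussian_filter(
                noise, sigma=(0.0, config.noise_corr_cells, config.noise_corr_cells)
            )
            sd = noise.std()
            if sd > 0:
                noise *= scale / sd
            stack += noise
        stack = _clip(var, stack)
        weather[var] = stack
        # long-term monthly means across all simulated years
        clim = np.empty((12, geom.ny, geom.nx))
        for m in range(1, 13):
            clim[m - 1] = stack[months == m].mean(axis=0)
        climate[var] = clim

    return EnvironmentSet(geom, tindex, weather, climate, seed=config.seed)


def _individual_targets(config: SimulationConfig, flyway: str, ind_id: str) -> dict:
    """Season -> variable -> preferred value for one individual.

    Per-individual heterogeneity (``individual_target_jitter``) shifts each
    individual's targets by a fixed offset drawn once per individual, in
    units of the per-variable comparability scale, centred on the flyway
    target.
    """
    base = config.targets[flyway]
    if config.individual_target_jitter <= 0:
        return base
    rng = substream(config.seed, "targets", ind_id)
    offsets = {
        var: float(rng.normal(0.0, config.individual_target_jitter * TARGET_SCALES[var]))
        for var in VARIABLES
    }
    return {
        s: {var: base[s][var] + offsets[var] for var in VARIABLES} for s in SEASONS
    }


_MONTH_SEASON_FOR_TARGET = {
    1: "winter", 2: "winter", 3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer", 9: "autumn", 10: "autumn",
    11: "autumn", 12: "winter",
}


def _walk_one(
    config: SimulationConfig,
    env: EnvironmentSet,
    flyway: str,
    ind_id: str,
) -> Track:
    """Biased correlated random walk for one individual.

    Each step's direction is a unit vector of (kappa * descent direction of
    the environmental mismatch + standard-normal noise); the descent
    direction points towards the individual's preferred seasonal conditions.
    Positions reflect at the domain boundary.
    """
    geom = env.geometry
    xmin, xmax, ymin, ymax = geom.extent
    rng = substream(config.seed, "walk", ind_id)
    targets = _individual_targets(config, flyway, ind_id)

    steps_per_day = int(round(24 * 60 / config.fix_interval_min))
    n_days = len(env.time_index)
    n_steps = n_days * steps_per_day
    times = env.time_index[0] + pd.timedelta_range(
        start="0min", periods=n_steps, freq=f"{config.fix_interval_min}min"
    )

    x = float(rng.uniform(xmin, xmax))
    y = float(rng.uniform(ymin, ymax))
    xs = np.empty(n_steps)
    ys = np.empty(n_steps)
    cell = geom.cell_km
    scales = TARGET_SCALES
    months = env.time_index.month.to_numpy()
    noise = rng.standard_normal((n_steps, 2))

    for day in range(n_days):
        month = months[day]
        tgt = targets[_MONTH_SEASON_FOR_TARGET[month]]
        if config.bias_field == "weather":
            fields = [env.weather[v][day] for v in VARIABLES]
        else:
            fields = [env.climate[v][month - 1] for v in VARIABLES]
        for k in range(steps_per_day):
            i = day * steps_per_day + k
            xs[i], ys[i] = x, y
            if config.kappa > 0:
                iy, ix = geom.cell_index(x, y)
                ixm, ixp = max(ix - 1, 0), min(ix + 1, geom.nx - 1)
                iym, iyp = max(iy - 1, 0), min(iy + 1, geom.ny - 1)
                gx = gy = 0.0
                for fld, var in zip(fields, VARIABLES):
                    diff = fld[iy, ix] - tgt[var]
                    s2 = scales[var] ** 2
                    gx += diff * (fld[iy, ixp] - fld[iy, ixm]) / ((ixp - ixm) * cell) / s2
                    gy += diff * (fld[iyp, ix] - fld[iym, ix]) / ((iyp - iym) * cell) / s2
                gnorm = np.hypot(gx, gy)
                if gnorm > 1e-12:
                    dx = -config.kappa * gx / gnorm + noise[i, 0]
                    dy = -config.kappa * gy / gnorm + noise[i, 1]
                else:
                    dx, dy = noise[i]
            else:
                dx, dy = noise[i]
            norm = np.hypot(dx, dy)
            if norm < 1e-12:
                continue
            x += config.step_km * dx / norm
            y += config.step_km * dy / norm
            # reflect at the boundary
            if x < xmin:
                x = 2 * xmin - x
            elif x > xmax:
                x = 2 * xmax - x
            if y < ymin:
                y = 2 * ymin - y
            elif y > ymax:
                y = 2 * ymax - y

    fixes = pd.DataFrame({"timestamp": times, "x_km": xs, "y_km": ys})
    return Track(ind_id, flyway, fixes)


def generate_tracks(config: SimulationConfig, env: EnvironmentSet) -> list[Track]:
    """Simulate tracks for all individuals of both flyways.

    Individual ids are ``E01..`` / ``W01..``; each individual draws its own
    random substream (stable under reordering).
    """
    if config.kappa < 0:
        raise ValueError("kappa must be >= 0")
    tracks = []
    for flyway in FLYWAYS:
        prefix = flyway[0].upper()
        for j in range(config.n_individuals):
            ind_id = f"{prefix}{j + 1:02d}"
            tracks.append(_walk_one(config, env, flyway, ind_id))
    return tracks


def write_environment(env: EnvironmentSet, directory) -> None:
    """Persist an EnvironmentSet as an NPZ grid store plus a JSON manifest.

    One compressed NPZ holds the weather stacks and climate layers (arrays
    named ``weather_<var>`` / ``climate_<var>``); the manifest records grid
    geometry, time index bounds and seed.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for var in VARIABLES:
        arrays[f"weather_{var}"] = env.weather[var]
        arrays[f"climate_{var}"] = env.climate[var]
    np.savez_compressed(directory / "environment.npz", **arrays)
    manifest = {
        "origin": list(env.geometry.origin),
        "cell_km": env.geometry.cell_km,
        "nx": env.geometry.nx,
        "ny": env.geometry.ny,
        "time_start": str(env.time_index[0].date()),
        "time_end": str(env.time_index[-1].date()),
        "variables": list(VARIABLES),
        "seed": env.seed,
    }
    (directory / "environment.json").write_text(json.dumps(manifest, indent=2))


def read_environment(directory) -> EnvironmentSet:
    directory = Path(directory)
    manifest = json.loads((directory / "environment.json").read_text())
    geom = GridGeometry(
        tuple(manifest["origin"]), manifest["cell_km"], manifest["nx"], manifest["ny"]
    )
    tindex = pd.date_range(manifest["time_start"], manifest["time_end"], freq="D")
    with np.load(directory / "environment.npz") as data:
        weather = {var: data[f"weather_{var}"] for var in VARIABLES}
        climate = {var: data[f"climate_{var}"] for var in VARIABLES}
    return EnvironmentSet(geom, tindex, weather, climate, seed=manifest["seed"])
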