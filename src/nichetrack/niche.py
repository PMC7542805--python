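"""Environmental-niche densities and Schoener's D overlap.

The niche of an analysis unit (one individual-year-season or one
flyway-year-season) is the density of its occurrence points in environmental
space — 1-D (a single variable) or 3-D (temperature x precipitation x NDVI)
— estimated with a product-Gaussian kernel on a regular grid spanning the
background, then divided by the background density to correct for the
relative availability of environments, and renormalized.  Overlap between
two corrected occupancies z1, z2 is Schoener's

    D = 1 - 0.5 * sum_cells |z1 - z2|,

which is 0 for disjoint niches and 1 for identical ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import background as bg
from .seasons import season_pairs
from .synthetic import VARIABLES, EnvironmentSet

__all__ = [
    "GridDefinition",
    "NicheGrid",
    "build_grid",
    "silverman_bandwidth",
    "kernel_density",
    "occupancy",
    "schoener_d",
    "corrected_occupancy",
    "seasonal_overlaps",
    "InsufficientDataError",
]

logger = logging.getLogger(__name__)

MIN_POINTS = 5

VARIABLE_SETS: dict[str, tuple[str, ...]] = {
    "all": VARIABLES,
    "temperature": ("temperature",),
    "precipitation": ("precipitation",),
    "ndvi": ("ndvi",),
}


class InsufficientDataError(ValueError):
    """A unit has too few points to estimate a density."""


@dataclass(frozen=True)
class GridDefinition:
    """Binned environmental space: ordered axes with equal-width bin edges."""

    axes: tuple[str, ...]
    edges: tuple[np.ndarray, ...]

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(e) - 1 for e in self.edges)

    def midpoints(self, axis: int) -> np.ndarray:
        e = self.edges[axis]
        return 0.5 * (e[:-1] + e[1:])

    def clamp(self, values: np.ndarray) -> tuple[np.ndarray, int]:
        """Clip values into the grid range; return (clipped, n_clamped)."""
        values = np.asarray(values, float)
        lo = np.array([e[0] for e in self.edges])
        hi = np.array([e[-1] for e in self.edges])
        clipped = np.clip(values, lo, hi)
        n_clamped = int((values != clipped).any(axis=1).sum())
        return clipped, n_clamped


@dataclass
class NicheGrid:
    """Occurrence, background and corrected densities on one grid."""

    grid: GridDefinition
    z_occ: np.ndarray
    z_bkg: np.ndarray
    z: np.ndarray
    n_points: int
    n_clamped: int = 0
    n_unsupported_cells: int = 0


def build_grid(background_values: pd.DataFrame, axes, R: int) -> GridDefinition:
    """Equal-width bins per axis spanning the background's [min, max].

    Bins are half-open with the last bin closed, so a value exactly at the
    maximum falls in the last bin.
    """
    axes = tuple(axes)
    if R < 2:
        raise ValueError("R must be >= 2")
    edges = []
    for ax in axes:
        v = np.asarray(background_values[ax], float)
        lo, hi = v.min(), v.max()
        if not hi > lo:
            raise ValueError(f"degenerate background axis {ax!r}: constant values")
        edges.append(np.linspace(lo, hi, R + 1))
    return GridDefinition(axes, tuple(edges))


def silverman_bandwidth(values: np.ndarray, d: int) -> float:
    """Silverman's rule-of-thumb bandwidth for one axis of a d-dim kernel.

    h = sigma * (4 / (d + 2))^(1/(d+4)) * n^(-1/(d+4)) with sigma the robust
    spread min(sd, IQR/1.34).
    """
    values = np.asarray(values, float)
    n = len(values)
    sd = values.std(ddof=1) if n > 1 else 0.0
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    sigma = min(sd, iqr / 1.34) if iqr > 0 else sd
    if sigma <= 0:
        sigma = max(abs(values).max(), 1.0) * 1e-3  # degenerate spread guard
    return sigma * (4.0 / (d + 2)) ** (1.0 / (d + 4)) * n ** (-1.0 / (d + 4))


def kernel_density(values, grid: GridDefinition) -> np.ndarray:
    """Product-Gaussian KDE evaluated at cell midpoints, normalized to sum 1.

    Per-axis bandwidths follow Silverman's rule computed on the input values
    themselves.  Raises InsufficientDataError below MIN_POINTS points.
    """
    if isinstance(values, pd.DataFrame):
        values = values[list(grid.axes)].to_numpy(float)
    values = np.asarray(values, float).reshape(len(values), grid.ndim)
    n = len(values)
    if n < MIN_POINTS:
        raise InsufficientDataError(f"{n} points < minimum {MIN_POINTS}")
    # separable evaluation: per-axis kernel matrices K_a[p, i], combined with
    # an outer-product contraction over points
    kmats = []
    for a in range(grid.ndim):
        mids = grid.midpoints(a)
        # bandwidth never below half a bin width, or a tight cluster can
        # underflow between cell midpoints on a coarse grid
        h = max(
            silverman_bandwidth(values[:, a], grid.ndim),
            0.5 * (mids[1] - mids[0]) if len(mids) > 1 else 1e-12,
        )
        u = (mids[None, :] - values[:, a, None]) / h
        kmats.append(np.exp(-0.5 * u * u) / h)
    if grid.ndim == 1:
        dens = kmats[0].sum(axis=0)
    elif grid.ndim == 2:
        dens = np.einsum("pi,pj->ij", kmats[0], kmats[1])
    elif grid.ndim == 3:
        dens = np.einsum("pi,pj,pk->ijk", kmats[0], kmats[1], kmats[2])
    else:  # pragma: no cover - not used by any variable set
        dens = np.zeros(grid.shape)
        for p in range(n):
            term = kmats[0][p]
            for a in range(1, grid.ndim):
                term = np.multiply.outer(term, kmats[a][p])
            dens += term
    total = dens.sum()
    if total <= 0:
        raise InsufficientDataError("kernel density vanished on the grid")
    return dens / total


def occupancy(z_occ: np.ndarray, z_bkg: np.ndarray, floor: float | None = None):
    """Background-corrected occupancy: normalize z_occ / z_bkg over support.

    Cells where the background density is at or below ``floor`` are outside
    the available environment and contribute zero; the occurrence mass lost
    there is reported for diagnostics.  ``floor=None`` uses 1e-3 of the
    uniform cell mass (0.001/n_cells): the far Gaussian tails of the
    background estimate are not treated as available environment, which
    keeps the density ratio bounded when the occurrence bandwidth exceeds
    the background bandwidth.  Returns (z, n_unsupported_cells).
    """
    if z_occ.shape != z_bkg.shape:
        raise ValueError("misaligned grids")
    if floor is None:
        floor = 1e-3 / z_bkg.size
    support = z_bkg > floor
    z_raw = np.zeros_like(z_occ)
    z_raw[support] = z_occ[support] / z_bkg[support]
    total = z_raw.sum()
    if total <= 0:
        raise ValueError("empty niche: no occurrence mass on background support")
    n_unsupported = int(((~support) & (z_occ > 0)).sum())
    return z_raw / total, n_unsupported


def schoener_d(z1: np.ndarray, z2: np.ndarray) -> float:
    """Schoener's D = 1 - 0.5 * sum |z1 - z2| between normalized densities."""
    if z1.shape != z2.shape:
        raise ValueError("misaligned grids")
    d = 1.0 - 0.5 * float(np.abs(z1 - z2).sum())
    # clip floating-point excursions outside [0, 1]
    return min(max(d, 0.0), 1.0)


def corrected_occupancy(
    occ_values, bkg_values, grid: GridDefinition, floor: float | None = None
) -> NicheGrid:
    """Full chain for one unit: clamp -> KDE both densities -> correct."""
    if isinstance(occ_values, pd.DataFrame):
        occ_values = occ_values[list(grid.axes)].to_numpy(float)
    occ_values = np.asarray(occ_values, float).reshape(len(occ_values), grid.ndim)
    occ_values, n_clamped = grid.clamp(occ_values)
    if n_clamped:
        logger.info("clamped %d occurrence values into the background range", n_clamped)
    z_occ = kernel_density(occ_values, grid)
    z_bkg = kernel_density(bkg_values, grid)
    z, n_unsupported = occupancy(z_occ, z_bkg, floor=floor)
    return NicheGrid(grid, z_occ, z_bkg, z, len(occ_values), n_clamped, n_unsupported)


def _unit_groups(points: pd.DataFrame, level: str):
    """Yield (unit id, flyway, cycle_year, season, point frame) per unit."""
    if level == "individual":
        keys = ["individual_id", "flyway", "cycle_year", "season"]
        for (ind, fw, cy, season), grp in points.groupby(keys, sort=True):
            yield str(ind), str(fw), int(cy), str(season), grp
    elif level == "population":
        keys = ["flyway", "cycle_year", "season"]
        for (fw, cy, season), grp in points.groupby(keys, sort=True):
            yield str(fw), str(fw), int(cy), str(season), grp
    else:
        raise ValueError(f"level must be 'individual' or 'population', got {level!r}")


def seasonal_overlaps(
    points: pd.DataFrame,
    backgrounds: dict[str, "bg.BackgroundSample"],
    env: EnvironmentSet,
    levels=("individual", "population"),
    modes=("climate", "weather"),
    variable_sets=("all", "temperature", "precipitation", "ndvi"),
    R_1d: int = 100,
    R_3d: int = 50,
    pairing: str = "consecutive",
) -> pd.DataFrame:
    """Schoener's D for every unit pair of seasons, level, mode and axis set.

    ``points`` is the preprocessed seasonal point table (one row per retained
    fix).  For each analysis unit the occurrence points of the two seasons
    are annotated, gridded on axes spanning the pooled seasonal backgrounds
    of the unit's flyway, corrected by the season-specific background
    density, and compared.  Units that fail the minimum-point rule are
    skipped and logged.
    """
    rows = []
    for level in levels:
        for mode in modes:
            units: dict[tuple, dict] = {}
            for uid, fw, cy, season, grp in _unit_groups(points, level):
                units.setdefault((uid, fw), {})[(cy, season)] = grp
            for (uid, fw), seasons_points in sorted(units.items()):
                cycles = sorted({cy for cy, _ in seasons_points})
                for cy in cycles:
                    for s1, s2, off in season_pairs(pairing):
                        if (cy, s1) not in seasons_points:
                            continue
                        if (cy + off, s2) not in seasons_points:
                            continue
                        p1 = seasons_points[(cy, s1)]
                        p2 = seasons_points[(cy + off, s2)]
                        bkg = backgrounds[fw]
                        for vset in variable_sets:
                            axes = VARIABLE_SETS[vset]
                            R = R_1d if len(axes) == 1 else R_3d
                            try:
                                occ1 = bg.annotate_occurrences(p1, env, s1, mode)
                                occ2 = bg.annotate_occurrences(p2, env, s2, mode)
                                b1 = bkg.annotation(s1, mode)
                                b2 = bkg.annotation(s2, mode)
                                grid = build_grid(
                                    pd.concat([b1, b2], ignore_index=True), axes, R
                                )
                                g1 = corrected_occupancy(occ1, b1, grid)
                                g2 = corrected_occupancy(occ2, b2, grid)
                                D = schoener_d(g1.z, g2.z)
                            except InsufficientDataError as exc:
                                logger.info(
                                    "skipping %s %s %s %s-%s (%s): %s",
                                    level, uid, cy, s1, s2, vset, exc,
                                )
                                continue
                            rows.append(
                                dict(
                                    level=level, id=uid, flyway=fw, cycle_year=cy,
                                    season_pair=f"{s1}-{s2}", mode=mode,
                                    variable_set=vset, D=D,
                                    n1=len(p1), n2=len(p2), grid_R=R,
                                )
                            )
    return pd.DataFrame(
        rows,
        columns=["level", "id", "flyway", "cycle_year", "season_pair", "mode",
                 "variable_set", "D", "n1", "n2", "grid_R"],
    )
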