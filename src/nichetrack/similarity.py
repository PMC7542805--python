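"""Permutation-based niche similarity test ("niche tracking").

An analysis unit tracks its niche between two seasons if the observed
Schoener's D between the seasons' corrected occupancies is higher than
expected by chance given the available environment.  The null is built by
randomizing one season's occurrence environments within its background:
n_perm/2 randomizations keep season B observed and redraw season A's
environments uniformly from season A's background annotation (and vice
versa for the other half), each simulated density being divided by the
background density exactly as the observed one.  The unit is flagged as
tracking when D_obs strictly exceeds the empirical 95th percentile of the
pooled simulated D values (one-sided test; ties count as non-tracking).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import background as bg
from ._rng import substream
from .niche import (
    VARIABLE_SETS,
    GridDefinition,
    InsufficientDataError,
    build_grid,
    corrected_occupancy,
    kernel_density,
    occupancy,
    schoener_d,
)
from .seasons import season_pairs
from .synthetic import EnvironmentSet

__all__ = [
    "SimilarityResult",
    "permute_occurrences",
    "similarity_test",
    "tracking_proportion",
    "seasonal_tracking",
]

logger = logging.getLogger(__name__)


@dataclass
class SimilarityResult:
    D_obs: float
    sim_D: np.ndarray = field(repr=False)
    q95: float
    tracking: bool
    alpha: float
    n_perm: int
    seed: int
    exceedance_rank: int  # simulated values >= D_obs

    def summary(self) -> dict:
        return dict(
            D_obs=self.D_obs, q95_sim=self.q95, tracking=int(self.tracking),
            n_perm=self.n_perm, alpha=self.alpha, seed=self.seed,
        )


def permute_occurrences(
    n: int, background_annotation: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw n environmental vectors uniformly from the background annotation.

    Sampling is without replacement (a random n-subset of the available
    environments); if n exceeds the background size the draw falls back to
    sampling with replacement, with a log notice.
    """
    N = len(background_annotation)
    if n > N:
        logger.warning(
            "requested %d occurrence draws from %d background rows; "
            "falling back to sampling with replacement", n, N,
        )
        idx = rng.integers(N, size=n)
    else:
        idx = rng.choice(N, size=n, replace=False)
    return background_annotation.iloc[idx].reset_index(drop=True)


def similarity_test(
    occA: pd.DataFrame,
    occB: pd.DataFrame,
    bkgA: pd.DataFrame,
    bkgB: pd.DataFrame,
    axes,
    R: int,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    null: str = "resample",
    label: str = "",
) -> SimilarityResult:
    """Similarity test for one season pair of one analysis unit.

    ``occA``/``occB`` are the two seasons' occurrence environments;
    ``bkgA``/``bkgB`` the season-specific background annotations.  The grid
    spans the pooled backgrounds.  ``null='resample'`` redraws occurrence
    environments from the background (default); ``null='shift'`` instead
    translates the observed occurrence density by a random toroidal offset
    across the grid, for sensitivity analysis.
    """
    if n_perm < 20:
        logger.warning("n_perm=%d < 20: the 95%% quantile is unstable", n_perm)
    axes = tuple(axes)
    rng = substream(seed, "similarity", label)
    pooled = pd.concat(
        [bkgA[list(axes)], bkgB[list(axes)]], ignore_index=True
    )
    grid = build_grid(pooled, axes, R)
    z_bkgA = kernel_density(bkgA[list(axes)], grid)
    z_bkgB = kernel_density(bkgB[list(axes)], grid)

    gA = _corrected(occA, z_bkgA, grid)
    gB = _corrected(occB, z_bkgB, grid)
    D_obs = schoener_d(gA, gB)

    n_half = n_perm // 2
    sims = np.empty(n_perm)
    for i in range(n_perm):
        permute_A = i < n_perm - n_half  # first ceil(n/2) permute season A
        occ = occA if permute_A else occB
        bkg_ann = bkgA if permute_A else bkgB
        z_bkg = z_bkgA if permute_A else z_bkgB
        other = gB if permute_A else gA
        if null == "resample":
            draw = permute_occurrences(len(occ), bkg_ann, rng)
            z_sim = _corrected(draw, z_bkg, grid)
        elif null == "shift":
            z_sim = _shifted(occ, z_bkg, grid, rng)
        else:
            raise ValueError(f"unknown null mechanism {null!r}")
        sims[i] = schoener_d(z_sim, other)
    q95 = float(np.quantile(sims, 1.0 - alpha))
    tracking = bool(D_obs > q95)
    rank = int((sims >= D_obs).sum())
    return SimilarityResult(D_obs, sims, q95, tracking, alpha, n_perm, seed, rank)


def _corrected(occ_values, z_bkg: np.ndarray, grid: GridDefinition) -> np.ndarray:
    if isinstance(occ_values, pd.DataFrame):
        occ_values = occ_values[list(grid.axes)].to_numpy(float)
    occ_values, _ = grid.clamp(np.asarray(occ_values, float).reshape(-1, grid.ndim))
    z_occ = kernel_density(occ_values, grid)
    z, _ = occupancy(z_occ, z_bkg)
    return z


def _shifted(occ_values, z_bkg, grid, rng) -> np.ndarray:
    """Null by random toroidal translation of the observed occurrence density."""
    if isinstance(occ_values, pd.DataFrame):
        occ_values = occ_values[list(grid.axes)].to_numpy(float)
    occ_values, _ = grid.clamp(np.asarray(occ_values, float).reshape(-1, grid.ndim))
    z_occ = kernel_density(occ_values, grid)
    shifts = [int(rng.integers(s)) for s in z_occ.shape]
    z_occ = np.roll(z_occ, shifts, axis=tuple(range(z_occ.ndim)))
    z, _ = occupancy(z_occ, z_bkg)
    return z


def tracking_proportion(
    results: pd.DataFrame,
    level: str | None = None,
    mode: str | None = None,
    variable_set: str | None = None,
) -> float:
    """Percentage of unit-season-pairs flagged as tracking in a stratum."""
    sel = results
    for col, val in (("level", level), ("mode", mode), ("variable_set", variable_set)):
        if val is not None:
            sel = sel[sel[col] == val]
    if len(sel) == 0:
        return float("nan")
    return 100.0 * float(sel["tracking"].sum()) / len(sel)


def seasonal_tracking(
    points: pd.DataFrame,
    backgrounds: dict[str, "bg.BackgroundSample"],
    env: EnvironmentSet,
    levels=("individual", "population"),
    modes=("climate", "weather"),
    variable_sets=("all",),
    R_1d: int = 100,
    R_3d: int = 50,
    pairing: str = "consecutive",
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    null: str = "resample",
) -> pd.DataFrame:
    """Run the similarity test for every unit, season pair, level and mode.

    Returns a tidy table (level, id, flyway, cycle_year, season_pair, mode,
    variable_set, D_obs, q95_sim, tracking, n_perm, alpha, seed).  Per-test
    seeds are derived from the global seed and the unit identity, so results
    do not depend on iteration order.
    """
    from .niche import _unit_groups

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
                            label = f"{level}|{uid}|{cy}|{s1}-{s2}|{mode}|{vset}"
                            try:
                                res = similarity_test(
                                    bg.annotate_occurrences(p1, env, s1, mode),
                                    bg.annotate_occurrences(p2, env, s2, mode),
                                    bkg.annotation(s1, mode),
                                    bkg.annotation(s2, mode),
                                    axes, R, n_perm=n_perm, alpha=alpha,
                                    seed=seed, null=null, label=label,
                                )
                            except InsufficientDataError as exc:
                                logger.info("skipping %s: %s", label, exc)
                                continue
                            rows.append(
                                dict(
                                    level=level, id=uid, flyway=fw, cycle_year=cy,
                                    season_pair=f"{s1}-{s2}", mode=mode,
                                    variable_set=vset, **res.summary(),
                                )
                            )
    return pd.DataFrame(
        rows,
        columns=["level", "id", "flyway", "cycle_year", "season_pair", "mode",
                 "variable_set", "D_obs", "q95_sim", "tracking", "n_perm",
                 "alpha", "seed"],
    )
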