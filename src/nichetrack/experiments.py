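"""Calibration, power and scenario experiments on synthetic data.

These experiments give the pipeline known ground truth to be judged
against:

* ``null_calibration`` — both seasons' occurrence environments are
  independent uniform draws from the background annotation, so the
  similarity test should flag tracking at its nominal level (5%).
* ``power_experiment`` — simulated individuals with increasing
  environment-bias ``kappa``; the flagged-tracking rate should rise from
  near the nominal level (kappa = 0, environment-blind movement) to near 1
  (strong niche followers).
* ``scenario_weather_surfers`` — individuals that follow daily weather with
  heterogeneous preferred conditions centred per population: weather
  tracking should be at least as frequent as climate tracking at the
  individual level, and climate tracking at least as frequent at the
  population level as at the individual level.
"""

from __future__ import annotations

import dataclasses
import logging

import pandas as pd

from . import background as bgmod
from ._rng import substream
from .pipeline import RunConfig, preprocess_tracks
from .similarity import seasonal_tracking, similarity_test, tracking_proportion
from .synthetic import (
    VARIABLES,
    SimulationConfig,
    generate_environment,
    generate_tracks,
)

__all__ = [
    "null_calibration",
    "power_experiment",
    "scenario_weather_surfers",
    "tracking_rate_for_config",
]

logger = logging.getLogger(__name__)

_AXES3 = VARIABLES


def _synthetic_background(seed: int, n_background: int = 10_000):
    """Environment plus a full-extent background annotated for one season pair.

    Returns (summer annotation, autumn annotation) tables of the three
    environmental variables in weather mode.
    """
    cfg = SimulationConfig(years=2, extent_km=400, cell_km=10, seed=seed)
    env = generate_environment(cfg)
    xmin, xmax, ymin, ymax = env.geometry.extent
    rng = substream(seed, "calibration-points")
    pts = pd.DataFrame(
        {
            "x_km": rng.uniform(xmin, xmax, n_background),
            "y_km": rng.uniform(ymin, ymax, n_background),
        }
    )
    bkgA = bgmod.annotate(pts, env, "summer", "weather", seed=seed, label="calA")
    bkgB = bgmod.annotate(pts, env, "autumn", "weather", seed=seed, label="calB")
    return bkgA, bkgB


def null_calibration(
    n_replicates: int = 200,
    n_points: int = 150,
    n_perm: int = 200,
    R: int = 20,
    n_background: int = 10_000,
    seed: int = 0,
) -> float:
    """Tracking rate under the true null (occurrences = background draws).

    For each replicate, two independent sets of ``n_points`` occurrence
    environments are drawn uniformly from the background annotation and the
    3-D similarity test is run; returns the fraction of replicates flagged
    as tracking.  By exchangeability of observed and permuted draws this
    should approximate the nominal level (alpha = 0.05).
    """
    bkgA, bkgB = _synthetic_background(seed, n_background)
    rng = substream(seed, "calibration-draws")
    n_flagged = 0
    for rep in range(n_replicates):
        occA = bkgA.iloc[rng.choice(len(bkgA), n_points, replace=False)]
        occB = bkgB.iloc[rng.choice(len(bkgB), n_points, replace=False)]
        res = similarity_test(
            occA, occB, bkgA, bkgB, _AXES3, R, n_perm=n_perm,
            seed=seed, label=f"calibration-{rep}",
        )
        n_flagged += res.tracking
    return n_flagged / n_replicates


def tracking_rate_for_config(
    sim: SimulationConfig,
    n_replicates: int,
    seed: int,
    n_background: int = 3000,
    n_perm: int = 200,
    R: int = 20,
    season_pair: tuple[str, str] = ("summer", "autumn"),
) -> float:
    """Fraction of replicate individuals flagged as weather-niche tracking.

    Each replicate simulates one individual for one year under ``sim``
    (fresh movement randomness per replicate, shared environment), builds
    its own buffered-MCP background, and tests the given season pair in
    weather mode on the 3-D grid.
    """
    env = generate_environment(dataclasses.replace(sim, seed=seed))
    run_cfg = RunConfig(seed=seed)
    s1, s2 = season_pair
    n_flagged = 0
    n_done = 0
    for rep in range(n_replicates):
        rep_sim = dataclasses.replace(sim, n_individuals=1, seed=seed + 1 + rep)
        tracks = [t for t in generate_tracks(rep_sim, env) if t.flyway == "eastern"]
        points, _ = preprocess_tracks(tracks, run_cfg, origin=env.geometry.origin)
        sel = points[points["season"].isin(season_pair)]
        by_season = {s: g for s, g in sel.groupby("season")}
        if s1 not in by_season or s2 not in by_season:
            logger.info("replicate %d lacks season coverage; skipped", rep)
            continue
        bkg = bgmod.build_background(
            "eastern", points, env, n_background=n_background,
            seed=seed + 1 + rep, seasons=season_pair, modes=("weather",),
        )
        res = similarity_test(
            bgmod.annotate_occurrences(by_season[s1], env, s1, "weather"),
            bgmod.annotate_occurrences(by_season[s2], env, s2, "weather"),
            bkg.annotation(s1, "weather"),
            bkg.annotation(s2, "weather"),
            _AXES3, R, n_perm=n_perm, seed=seed, label=f"power-{rep}",
        )
        n_flagged += res.tracking
        n_done += 1
    if n_done == 0:
        raise RuntimeError("no replicate produced both seasons")
    return n_flagged / n_done


def power_experiment(
    kappas=(0.0, 2.0, 10.0),
    n_replicates: int = 20,
    seed: int = 0,
    **kwargs,
) -> dict[float, float]:
    """Tracking rate as a function of the movement bias ``kappa``.

    Rates should be non-decreasing in kappa: environment-blind walkers are
    flagged around the nominal level, strong niche followers almost always.
    """
    base = SimulationConfig(
        years=1, fix_interval_min=60, extent_km=400, cell_km=10, seed=seed
    )
    return {
        float(k): tracking_rate_for_config(
            dataclasses.replace(base, kappa=float(k)),
            n_replicates, seed=seed + int(1000 * k), **kwargs,
        )
        for k in kappas
    }


def scenario_weather_surfers(
    seed: int = 0,
    n_individuals: int = 3,
    n_background: int = 3000,
    n_perm: int = 100,
    R: int = 15,
) -> dict[str, float]:
    """Tracking percentages for populations of weather-following individuals.

    Individuals bias their movement on the daily weather field towards
    preferred conditions that differ between individuals but are centred on
    their population's target.  Returns tracking percentages keyed by
    ``<level>_<mode>``.
    """
    sim = SimulationConfig(
        n_individuals=n_individuals, years=1, fix_interval_min=60,
        extent_km=400, cell_km=10, kappa=6.0, bias_field="weather",
        individual_target_jitter=1.5, seed=seed,
    )
    env = generate_environment(sim)
    tracks = generate_tracks(sim, env)
    run_cfg = RunConfig(seed=seed)
    points, _ = preprocess_tracks(tracks, run_cfg, origin=env.geometry.origin)
    backgrounds = {
        str(fw): bgmod.build_background(
            str(fw), grp, env, n_background=n_background, seed=seed
        )
        for fw, grp in points.groupby("flyway")
    }
    results = seasonal_tracking(
        points, backgrounds, env, levels=("individual", "population"),
        modes=("climate", "weather"), variable_sets=("all",),
        R_3d=R, n_perm=n_perm, seed=seed,
    )
    return {
        f"{level}_{mode}": tracking_proportion(results, level=level, mode=mode)
        for level in ("individual", "population")
        for mode in ("climate", "weather")
    }
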