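"""End-to-end orchestration: simulate -> preprocess -> background ->
overlap -> tracking -> variance partitioning, from a single config.

Every stage writes its table to the run directory so each summary number is
recomputable from persisted intermediates, and all randomness flows from the
config's global seed through named substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import background as bgmod
from . import tracks as trmod
from .niche import seasonal_overlaps
from .similarity import seasonal_tracking, tracking_proportion
from .synthetic import (
    SimulationConfig,
    generate_environment,
    generate_tracks,
    write_environment,
)
from .variance import (
    MCMCConfig,
    fit_binary_varcomp,
    fit_gaussian_varcomp,
    standardize,
    welch_t,
)

__all__ = ["RunConfig", "run_all", "summarize", "preprocess_tracks"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one analysis run.

    Defaults: 100 locations/day subsampling, 1 km thinning cells, 300 km
    background buffer, 10 000 background points, 200 randomizations per
    similarity test at alpha = 0.05.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_per_day: int = 100
    thin_cell_km: float = 1.0
    buffer_km: float = 300.0
    n_background: int = 10_000
    grid_R_1d: int = 100
    grid_R_3d: int = 50
    n_perm: int = 200
    alpha: float = 0.05
    pairing: str = "consecutive"
    levels: tuple[str, ...] = ("individual", "population")
    modes: tuple[str, ...] = ("climate", "weather")
    variable_sets: tuple[str, ...] = ("all", "temperature", "precipitation", "ndvi")
    null: str = "resample"
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("levels", "modes", "variable_sets"):
            d[key] = list(d[key])
        d["simulation"]["origin"] = list(d["simulation"]["origin"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        if "origin" in sim:
            sim["origin"] = tuple(sim["origin"])
        mcmc = MCMCConfig(**d.pop("mcmc", {}))
        for key in ("levels", "modes", "variable_sets"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(simulation=SimulationConfig(**sim), mcmc=mcmc, **d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def preprocess_tracks(tracks, config: RunConfig, origin=(0.0, 0.0)):
    """Subsample daily -> full-year filter -> season assignment -> thinning.

    Returns (seasonal point table, drop log).
    """
    sub = [trmod.subsample_daily(t, config.n_per_day, config.seed) for t in tracks]
    kept, drop_log = trmod.filter_full_year(sub)
    frames = [trmod.assign_seasons(t) for t in kept]
    if not frames:
        return pd.DataFrame(
            columns=["individual_id", "flyway", "cycle_year", "season",
                     "x_km", "y_km", "timestamp"]
        ), drop_log
    pts = pd.concat(frames, ignore_index=True)
    thinned = []
    for (ind, cy, season), grp in pts.groupby(
        ["individual_id", "cycle_year", "season"], sort=True
    ):
        thinned.append(
            trmod.spatial_thin(
                grp, config.thin_cell_km, config.seed, origin=origin,
                label=f"{ind}|{cy}|{season}",
            )
        )
    return pd.concat(thinned, ignore_index=True), drop_log


def _variance_models(overlaps, tracking, config: RunConfig):
    """Fit Gaussian (overlap) and binary (tracking) models per level x mode."""
    summaries = []
    draw_frames = []
    for level, unit_col in (("individual", "id"), ("population", "flyway")):
        for mode in config.modes:
            ov = overlaps[
                (overlaps["level"] == level)
                & (overlaps["mode"] == mode)
                & (overlaps["variable_set"] == "all")
            ]
            tr = tracking[
                (tracking["level"] == level)
                & (tracking["mode"] == mode)
                & (tracking["variable_set"] == "all")
            ]
            for kind, df in (("gaussian", ov), ("binary", tr)):
                name = f"{level}_{mode}_{kind}"
                try:
                    if kind == "gaussian":
                        y = standardize(df["D"].to_numpy())
                        vc = fit_gaussian_varcomp(
                            y, df[unit_col], df["cycle_year"], df["flyway"],
                            mcmc=config.mcmc, seed=config.seed,
                        )
                    else:
                        vc = fit_binary_varcomp(
                            df["tracking"].to_numpy(int), df[unit_col],
                            df["cycle_year"], df["flyway"],
                            mcmc=config.mcmc, seed=config.seed,
                        )
                except ValueError as exc:
                    logger.warning("variance model %s skipped: %s", name, exc)
                    continue
                for w in vc.warnings:
                    logger.warning("variance model %s: %s", name, w)
                summ = vc.summary()
                summ.insert(0, "model", name)
                summaries.append(summ)
                dd = (
                    pd.DataFrame({p: d for p, d in vc.draws.items()})
                    .reset_index(names="draw")
                    .melt(id_vars="draw", var_name="parameter", value_name="value")
                )
                dd.insert(0, "model", name)
                draw_frames.append(dd)
    summary = pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    draws = pd.concat(draw_frames, ignore_index=True) if draw_frames else pd.DataFrame()
    return summary, draws


def run_all(config: RunConfig, outdir) -> Path:
    """Execute the full pipeline into a run directory; returns the path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    config.save(outdir / "config.yaml")

    sim = dataclasses.replace(config.simulation, seed=config.seed)
    logger.info("stage simulate: environment + %d individuals/flyway", sim.n_individuals)
    env = generate_environment(sim)
    write_environment(env, outdir / "environment")
    tracks = generate_tracks(sim, env)
    trmod.write_tracks_csv(tracks, outdir / "tracks.csv")

    logger.info("stage preprocess (%.1fs)", time.time() - t0)
    points, drop_log = preprocess_tracks(tracks, config, origin=env.geometry.origin)
    points.to_csv(outdir / "seasonal_points.csv", index=False)
    drop_log.to_csv(outdir / "dropped_individuals.csv", index=False)
    if len(points) == 0:
        raise RuntimeError("stage preprocess: no individuals survived filtering")

    logger.info("stage background (%.1fs)", time.time() - t0)
    backgrounds = {}
    for flyway, grp in points.groupby("flyway"):
        bg = bgmod.build_background(
            str(flyway), grp, env, n_background=config.n_background,
            buffer_km=config.buffer_km, seed=config.seed,
        )
        backgrounds[str(flyway)] = bg
        (outdir / f"background_{flyway}.wkt").write_text(bg.to_wkt())
        ann = []
        for (season, mode), table in bg.annotations.items():
            t = table.copy()
            t.insert(0, "point_id", np.arange(len(t)))
            t.insert(1, "x_km", bg.points["x_km"].to_numpy())
            t.insert(2, "y_km", bg.points["y_km"].to_numpy())
            t.insert(3, "season", season)
            t.insert(4, "mode", mode)
            ann.append(t)
        pd.concat(ann, ignore_index=True).to_csv(
            outdir / f"background_{flyway}_annotations.csv", index=False
        )

    logger.info("stage overlap (%.1fs)", time.time() - t0)
    overlaps = seasonal_overlaps(
        points, backgrounds, env, levels=config.levels, modes=config.modes,
        variable_sets=config.variable_sets, R_1d=config.grid_R_1d,
        R_3d=config.grid_R_3d, pairing=config.pairing,
    )
    overlaps.to_csv(outdir / "overlaps.csv", index=False)
    # re-read so every downstream number is exactly recomputable from the
    # persisted intermediates (CSV round-trip fixes the float precision)
    overlaps = pd.read_csv(outdir / "overlaps.csv")

    logger.info("stage tracking (%.1fs)", time.time() - t0)
    tracking = seasonal_tracking(
        points, backgrounds, env, levels=config.levels, modes=config.modes,
        variable_sets=config.variable_sets, R_1d=config.grid_R_1d,
        R_3d=config.grid_R_3d, pairing=config.pairing, n_perm=config.n_perm,
        alpha=config.alpha, seed=config.seed, null=config.null,
    )
    tracking.to_csv(outdir / "tracking.csv", index=False)
    tracking = pd.read_csv(outdir / "tracking.csv")

    logger.info("stage varpart (%.1fs)", time.time() - t0)
    vc_summary, vc_draws = _variance_models(overlaps, tracking, config)
    vc_summary.to_csv(outdir / "varcomp_summary.csv", index=False)
    vc_draws.to_csv(outdir / "varcomp_draws.csv", index=False)

    _write_summary(outdir, overlaps, tracking, vc_summary)
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "elapsed_s": round(time.time() - t0, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("run complete (%.1fs): %s", time.time() - t0, outdir)
    return outdir


def _write_summary(outdir, overlaps, tracking, vc_summary) -> None:
    rows = []
    for (level, mode, vset), grp in overlaps.groupby(
        ["level", "mode", "variable_set"], sort=True
    ):
        sel = tracking[
            (tracking["level"] == level)
            & (tracking["mode"] == mode)
            & (tracking["variable_set"] == vset)
        ]
        rows.append(
            dict(
                level=level, mode=mode, variable_set=vset,
                n_pairs=len(grp), mean_D=float(grp["D"].mean()),
                min_D=float(grp["D"].min()), max_D=float(grp["D"].max()),
                tracking_pct=tracking_proportion(sel) if len(sel) else float("nan"),
            )
        )
    pd.DataFrame(rows).to_csv(outdir / "summary.csv", index=False)

    welch_rows = []
    for level in overlaps["level"].unique():
        sel = overlaps[(overlaps["level"] == level) & (overlaps["variable_set"] == "all")]
        cl = sel[sel["mode"] == "climate"]["D"].to_numpy()
        we = sel[sel["mode"] == "weather"]["D"].to_numpy()
        if len(cl) >= 2 and len(we) >= 2:
            try:
                res = welch_t(cl, we)
            except ValueError:
                continue
            welch_rows.append(
                dict(contrast=f"{level}: climate vs weather", t=res.t,
                     df=res.df, p=res.p)
            )
    for mode in overlaps["mode"].unique():
        sel = overlaps[(overlaps["mode"] == mode) & (overlaps["variable_set"] == "all")]
        ind = sel[sel["level"] == "individual"]["D"].to_numpy()
        pop = sel[sel["level"] == "population"]["D"].to_numpy()
        if len(ind) >= 2 and len(pop) >= 2:
            try:
                res = welch_t(ind, pop)
            except ValueError:
                continue
            welch_rows.append(
                dict(contrast=f"{mode}: individual vs population", t=res.t,
                     df=res.df, p=res.p)
            )
    pd.DataFrame(welch_rows, columns=["contrast", "t", "df", "p"]).to_csv(
        outdir / "welch.csv", index=False
    )

    if len(vc_summary):
        rep = vc_summary[vc_summary["parameter"] == "R"].copy()
        rep.to_csv(outdir / "repeatability.csv", index=False)


def summarize(run_dir) -> dict[str, pd.DataFrame]:
    """Recompute the report tables from a completed run's persisted CSVs."""
    run_dir = Path(run_dir)
    needed = ["overlaps.csv", "tracking.csv", "varcomp_summary.csv"]
    for name in needed:
        if not (run_dir / name).exists():
            raise FileNotFoundError(f"missing stage output: {name}")
    overlaps = pd.read_csv(run_dir / "overlaps.csv")
    tracking = pd.read_csv(run_dir / "tracking.csv")
    vc_summary = pd.read_csv(run_dir / "varcomp_summary.csv")
    _write_summary(run_dir, overlaps, tracking, vc_summary)
    out = {
        "summary": pd.read_csv(run_dir / "summary.csv"),
        "welch": pd.read_csv(run_dir / "welch.csv"),
    }
    if (run_dir / "repeatability.csv").exists():
        out["repeatability"] = pd.read_csv(run_dir / "repeatability.csv")
    return out
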