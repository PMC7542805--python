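"""Track containers, Movebank-style CSV I/O and preprocessing.

Preprocessing mirrors the standard movement-niche workflow: random daily
subsampling to a fixed number of locations per day (controls temporal
autocorrelation and behaviour-driven over-representation), assignment of
fixes to two-month seasons with one-month gaps, exclusion of individuals not
tracked for a full annual cycle, and spatial thinning to one location per
grid cell (controls spatial autocorrelation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .seasons import SEASONS, cycle_year, season_of_month

__all__ = [
    "Track",
    "read_tracks_csv",
    "write_tracks_csv",
    "subsample_daily",
    "assign_seasons",
    "filter_full_year",
    "spatial_thin",
]

FLYWAYS = ("eastern", "western")


@dataclass
class Track:
    """Timestamped planar positions for one individual.

    Fixes are held in a DataFrame with columns ``timestamp`` (datetime64),
    ``x_km`` and ``y_km``; timestamps are strictly increasing.
    """

    individual_id: str
    flyway: str
    fixes: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.flyway not in FLYWAYS:
            raise ValueError(f"flyway must be one of {FLYWAYS}, got {self.flyway!r}")
        ts = self.fixes["timestamp"]
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ValueError(f"timestamps not increasing for {self.individual_id}")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def span_days(self) -> int:
        """Inclusive calendar-day span: a full Jan 1 - Dec 31 year counts 365."""
        if len(self.fixes) == 0:
            return 0
        ts = self.fixes["timestamp"]
        return (ts.iloc[-1].normalize() - ts.iloc[0].normalize()).days + 1


_DEFAULT_COLUMNS = {
    "individual_id": "individual_id",
    "timestamp": "timestamp",
    "x_km": "x_km",
    "y_km": "y_km",
    "flyway": "flyway",
}


def read_tracks_csv(path, column_map: dict[str, str] | None = None) -> list[Track]:
    """Read Movebank-style CSV into one Track per individual.

    ``column_map`` maps the canonical names (individual_id, timestamp, x_km,
    y_km, flyway) to the file's column names.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, parse_dates=[cols["timestamp"]])
    df = df.rename(columns={v: k for k, v in cols.items()})
    tracks = []
    for ind, grp in df.groupby("individual_id", sort=True):
        grp = grp.sort_values("timestamp").reset_index(drop=True)
        flyway = str(grp["flyway"].iloc[0])
        tracks.append(
            Track(str(ind), flyway, grp[["timestamp", "x_km", "y_km"]].copy())
        )
    return tracks


def write_tracks_csv(tracks: list[Track], path) -> None:
    frames = []
    for tr in tracks:
        df = tr.fixes[["timestamp", "x_km", "y_km"]].copy()
        df.insert(0, "individual_id", tr.individual_id)
        df["flyway"] = tr.flyway
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def subsample_daily(track: Track, n_per_day: int, seed: int) -> Track:
    """Randomly retain at most ``n_per_day`` fixes per calendar day.

    Days with fewer fixes are kept untouched; retained fixes stay in time
    order.  Deterministic for a given (seed, individual) pair.
    """
    if n_per_day < 1:
        raise ValueError("n_per_day must be >= 1")
    if len(track.fixes) == 0:
        return Track(track.individual_id, track.flyway, track.fixes.copy())
    rng = substream(seed, "subsample", track.individual_id)
    days = track.fixes["timestamp"].dt.normalize()
    keep = np.zeros(len(track.fixes), dtype=bool)
    for _, idx in track.fixes.groupby(days, sort=True).indices.items():
        if len(idx) <= n_per_day:
            keep[idx] = True
        else:
            keep[rng.choice(idx, size=n_per_day, replace=False)] = True
    fixes = track.fixes.loc[keep].reset_index(drop=True)
    return Track(track.individual_id, track.flyway, fixes)


def assign_seasons(track: Track) -> pd.DataFrame:
    """Assign fixes to two-month seasons; gap-month fixes are discarded.

    Returns a tidy frame with columns individual_id, flyway, cycle_year,
    season, x_km, y_km, timestamp.  Winter is anchored to the year of its
    December, so December and the following January form one unit.
    """
    ts = track.fixes["timestamp"]
    months = ts.dt.month.to_numpy()
    years = ts.dt.year.to_numpy()
    season = np.array([season_of_month(m) or "" for m in months], dtype=object)
    mask = season != ""
    cyc = np.array([cycle_year(y, m) for y, m in zip(years, months)])
    out = pd.DataFrame(
        {
            "individual_id": track.individual_id,
            "flyway": track.flyway,
            "cycle_year": cyc[mask],
            "season": season[mask],
            "x_km": track.fixes["x_km"].to_numpy()[mask],
            "y_km": track.fixes["y_km"].to_numpy()[mask],
            "timestamp": ts.to_numpy()[mask],
        }
    )
    return out


def filter_full_year(tracks: list[Track]) -> tuple[list[Track], pd.DataFrame]:
    """Keep individuals tracked >= 365 days with fixes in all four seasons.

    Returns (kept tracks, log frame of dropped individuals with reasons).
    """
    kept: list[Track] = []
    dropped: list[dict] = []
    for tr in tracks:
        if tr.span_days < 365:
            dropped.append(
                {"individual_id": tr.individual_id,
                 "reason": f"tracking span {tr.span_days} d < 365 d"}
            )
            continue
        present = set(assign_seasons(tr)["season"].unique())
        missing = [s for s in SEASONS if s not in present]
        if missing:
            dropped.append(
                {"individual_id": tr.individual_id,
                 "reason": "no fixes in season(s): " + ", ".join(missing)}
            )
            continue
        kept.append(tr)
    log = pd.DataFrame(dropped, columns=["individual_id", "reason"])
    return kept, log


def spatial_thin(
    points: pd.DataFrame,
    cell_km: float,
    seed: int,
    origin: tuple[float, float] = (0.0, 0.0),
    label: str = "",
) -> pd.DataFrame:
    """Keep one uniformly chosen point per occupied cell of a square grid.

    The grid is anchored at ``origin`` (the environment origin), not at the
    data, so the result is stable under point reordering.  Idempotent on its
    own output.
    """
    if cell_km <= 0:
        raise ValueError("cell_km must be > 0")
    if len(points) == 0:
        return points.copy()
    rng = substream(seed, "thin", label)
    x = points["x_km"].to_numpy()
    y = points["y_km"].to_numpy()
    ix = np.floor((x - origin[0]) / cell_km).astype(np.int64)
    iy = np.floor((y - origin[1]) / cell_km).astype(np.int64)
    cell = pd.Series(ix.astype(object) * (2**32) + iy.astype(object))
    keep_pos: list[int] = []
    for _, idx in sorted(cell.groupby(cell).indices.items()):
        # order within the cell by coordinates so the draw does not depend
        # on input row order
        order = np.lexsort((y[idx], x[idx]))
        keep_pos.append(int(idx[order[rng.integers(len(idx))]]))
    keep_pos.sort()
    return points.iloc[keep_pos].copy()
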