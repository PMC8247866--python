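"""Reading, projecting, subsampling and season-splitting GPS tracks.

Tracks are held as pandas DataFrames with columns ``individual_id``,
``timestamp`` (UTC), ``lon``, ``lat`` and, once projected, ``x``/``y`` in
metres. The non-breeding season of each individual is delimited by colony
departure (last detection within 10 km of the colony after the breeding
period) and colony arrival (first detection within 10 km before the next
breeding period). Seasons with transmission gaps longer than 21 days are
excluded, and individuals left with fewer than two seasons are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import ProjectionSpec, great_circle_km

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["individual_id", "timestamp", "lon", "lat"]

#: default inclusion-filter / season-splitting parameters
COLONY_RADIUS_KM = 10.0
MAX_GAP_DAYS = 21.0
ANCHOR_WINDOW = ((5, 1), (7, 15))  # breeding anchor: 1 May – 15 July
SUSTAINED_ABSENCE_DAYS = 7.0


@dataclass
class SeasonWindow:
    """One individual x one non-breeding season (colony-to-colony)."""

    individual_id: str
    season_label: str
    colony_departure: pd.Timestamp
    colony_arrival: pd.Timestamp
    fixes: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if not self.colony_departure < self.colony_arrival:
            raise ValueError("colony_departure must precede colony_arrival")


class ColumnError(ValueError):
    """A required column is missing from an input file."""


def read_tracks(path, column_map=None, sep=None):
    """Read a delimited track file into the canonical fix table.

    ``column_map`` maps file column names to the canonical names
    (individual_id, timestamp, lon, lat). Rows with unparseable timestamps
    or out-of-range coordinates are rejected and counted; duplicate
    (individual, timestamp) rows are reduced to one.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ColumnError(f"missing required columns: {missing}")
    df = df[TRACK_COLUMNS].copy()
    n_in = len(df)
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce", utc=True)
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    ok = (
        df["timestamp"].notna()
        & df["lon"].between(-180, 180)
        & df["lat"].between(-90, 90)
    )
    df = df[ok]
    df = df.drop_duplicates(subset=["individual_id", "timestamp"], keep="first")
    df = df.sort_values(["individual_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    n_rejected = n_in - len(df)
    if n_rejected:
        logger.info("read_tracks: rejected or de-duplicated %d of %d rows", n_rejected, n_in)
    df.attrs["n_rejected"] = n_rejected
    return df


def write_tracks(df, path):
    """Write the canonical fix table as CSV (ISO-8601 timestamps, UTC)."""
    out = df[TRACK_COLUMNS].copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def project(fixes, projection: ProjectionSpec):
    """Fill planar x/y (metres, equal-area) columns from lon/lat."""
    out = fixes.copy()
    x, y = projection.forward(out["lon"].to_numpy(), out["lat"].to_numpy())
    out["x"] = x
    out["y"] = y
    return out


def subsample(fixes, interval="12h"):
    """Thin a time-ordered fix table to at most one fix per interval bin.

    Bins are anchored at the first fix; within each bin the fix nearest the
    bin centre is kept. Empty bins (data holes) stay empty — no
    interpolation is performed, which keeps multi-day gaps visible to the
    downstream gap filters.
    """
    if len(fixes) == 0:
        return fixes.copy()
    dt = pd.to_timedelta(interval)
    t = fixes["timestamp"]
    rel = (t - t.iloc[0]).dt.total_seconds().to_numpy()
    bins = np.floor(rel / dt.total_seconds()).astype(np.int64)
    off = np.abs(rel - (bins + 0.5) * dt.total_seconds())
    order = np.lexsort((off, bins))
    first_in_bin = np.ones(len(fixes), dtype=bool)
    first_in_bin[1:] = bins[order][1:] != bins[order][:-1]
    keep = np.sort(order[first_in_bin])
    return fixes.iloc[keep].reset_index(drop=True)


def _season_label(departure):
    y = departure.year
    return f"{y}–{str(y + 1)[-2:]}"


def _anchor_presence_years(times, inside):
    """Calendar years in which the bird was detected at the colony during
    the breeding anchor window."""
    (m0, d0), (m1, d1) = ANCHOR_WINDOW
    years = sorted(times.dt.year.unique())
    present = []
    for y in years:
        a = pd.Timestamp(year=y, month=m0, day=d0, tz="UTC")
        b = pd.Timestamp(year=y, month=m1, day=d1, tz="UTC") + pd.Timedelta(days=1)
        if bool((inside & (times >= a) & (times < b)).any()):
            present.append(y)
    return present


def split_seasons(
    fixes,
    colony,
    radius_km=COLONY_RADIUS_KM,
    sustained_absence_days=SUSTAINED_ABSENCE_DAYS,
):
    """Split one individual's fixes into non-breeding SeasonWindows.

    For each pair of consecutive breeding years in which the individual was
    detected at the colony, the season is the longest sustained absence
    (>= ``sustained_absence_days``) from the 10-km colony radius between the
    two breeding anchor windows: departure is the last inside-radius fix
    before it, arrival the first inside-radius fix after it.

    Raises ``ResidentError`` if the bird never leaves the radius.
    """
    if len(fixes) < 2:
        return []
    lon_c, lat_c = colony
    times = fixes["timestamp"]
    dist = great_circle_km(fixes["lon"].to_numpy(), fixes["lat"].to_numpy(), lon_c, lat_c)
    inside = pd.Series(dist <= radius_km, index=fixes.index)
    if not bool((~inside).any()):
        raise ResidentError(
            f"{fixes['individual_id'].iloc[0]}: never beyond {radius_km} km of colony"
        )
    present_years = _anchor_presence_years(times, inside)
    in_idx = np.nonzero(inside.to_numpy())[0]
    if len(in_idx) < 2:
        return []
    t_naive = times.dt.tz_convert(None).to_numpy()
    t_in = t_naive[in_idx]
    gaps = (t_in[1:] - t_in[:-1]) / np.timedelta64(1, "D")
    (m0, d0), (m1, d1) = ANCHOR_WINDOW
    seasons = []
    for y0, y1 in zip(present_years[:-1], present_years[1:]):
        a_start = np.datetime64(pd.Timestamp(year=y0, month=m0, day=d0, tz="UTC").tz_convert(None))
        a_end = np.datetime64(
            (pd.Timestamp(year=y1, month=m1, day=d1, tz="UTC") + pd.Timedelta(days=1)).tz_convert(None)
        )
        cand = np.nonzero(
            (gaps >= sustained_absence_days)
            & (t_in[:-1] >= a_start)
            & (t_in[1:] <= a_end)
        )[0]
        if len(cand) == 0:
            continue
        k = cand[np.argmax(gaps[cand])]
        dep_i, arr_i = in_idx[k], in_idx[k + 1]
        dep_t, arr_t = times.iloc[dep_i], times.iloc[arr_i]
        window = fixes.iloc[dep_i : arr_i + 1].reset_index(drop=True)
        seasons.append(
            SeasonWindow(
                individual_id=str(fixes["individual_id"].iloc[0]),
                season_label=_season_label(dep_t),
                colony_departure=dep_t,
                colony_arrival=arr_t,
                fixes=window,
            )
        )
    return seasons


class ResidentError(ValueError):
    """Individual never leaves the colony radius — excluded from analysis."""


def max_gap_days(fixes):
    t = fixes["timestamp"].dt.tz_convert(None).to_numpy()
    if len(t) < 2:
        return 0.0
    return float(((t[1:] - t[:-1]) / np.timedelta64(1, "D")).max())


def apply_inclusion_filters(seasons, max_gap=MAX_GAP_DAYS, min_seasons=2):
    """Drop seasons with a >21-day transmission gap, then individuals left
    with fewer than two seasons. Returns (kept seasons, report DataFrame)."""
    report = []
    kept = []
    for s in seasons:
        g = max_gap_days(s.fixes)
        if g > max_gap:
            report.append(
                {"individual_id": s.individual_id, "season_label": s.season_label,
                 "reason": f"gap {g:.1f} d > {max_gap:g} d"}
            )
        else:
            kept.append(s)
    counts = {}
    for s in kept:
        counts[s.individual_id] = counts.get(s.individual_id, 0) + 1
    final = []
    for s in kept:
        if counts[s.individual_id] < min_seasons:
            report.append(
                {"individual_id": s.individual_id, "season_label": s.season_label,
                 "reason": f"individual has {counts[s.individual_id]} season(s) < {min_seasons}"}
            )
        else:
            final.append(s)
    return final, pd.DataFrame(report, columns=["individual_id", "season_label", "reason"])
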