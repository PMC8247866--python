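"""Core areas, wintering area, phenology dates and migration distance.

Core areas are the connected components of the 50% isopleth of the
seasonal UD — coarse regions where a bird wintered or staged for a
prolonged period. The wintering area is the core area with the greatest
dwell time between 1 December and 31 March (ties broken in favour of the
area farther from the colony); winter arrival/departure are the first and
last full-rate detections inside its polygon. Migration distance is the
great-circle distance from the colony to the winter-area centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from shapely.ops import unary_union

from .geo import ProjectionSpec, great_circle_km
from .space_use import GridUD, isopleth
from .track_io import SeasonWindow

DWELL_DAYS_PER_FIX = 0.5  # dwell counted in 12-h subsampled fixes
WINTER_WINDOW = ((12, 1), (3, 31))  # 1 Dec – 31 Mar, boundary inclusive
TRANSITION_GAP_FLAG_DAYS = 3.0


@dataclass
class CoreArea:
    polygon: object                    # shapely (Multi)Polygon, planar metres
    centroid_lonlat: tuple             # mass-weighted centroid of member cells
    role: str = "unassigned"           # winter | stopover | unassigned
    dwell_days: float = 0.0
    winter_dwell_days: float = 0.0     # Dec–Mar dwell
    cell_mask: np.ndarray = field(default=None, repr=False)
    ud: GridUD = field(default=None, repr=False)

    def contains_xy(self, x, y):
        """Boundary-inclusive membership via the UD cell lattice."""
        iy, ix = self.ud.cell_index(x, y)
        inside_grid = (
            (np.asarray(x) >= self.ud.origin[0])
            & (np.asarray(x) <= self.ud.origin[0] + self.ud.cell_size * self.ud.shape[1])
            & (np.asarray(y) >= self.ud.origin[1])
            & (np.asarray(y) <= self.ud.origin[1] + self.ud.cell_size * self.ud.shape[0])
        )
        return inside_grid & self.cell_mask[iy, ix]


@dataclass
class SeasonRecord:
    individual_id: str
    season_label: str
    colony_departure: Optional[pd.Timestamp]
    winter_arrival: Optional[pd.Timestamp]
    winter_departure: Optional[pd.Timestamp]
    colony_arrival: Optional[pd.Timestamp]
    migration_distance_km: float
    winter_area: CoreArea
    stopovers: list
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        dates = [self.colony_departure, self.winter_arrival,
                 self.winter_departure, self.colony_arrival]
        known = [d for d in dates if d is not None and not pd.isna(d)]
        for a, b in zip(known[:-1], known[1:]):
            if a > b:
                raise ValueError("season dates out of order")
        if self.migration_distance_km < 0:
            raise ValueError("negative migration distance")


def _mass_weighted_centroid(ud: GridUD, mask, projection: ProjectionSpec):
    iy, ix = np.nonzero(mask)
    w = ud.masses[iy, ix]
    if w.sum() <= 0:
        w = np.ones_like(w)
    cs = ud.cell_size
    xc = ud.origin[0] + cs * (ix + 0.5)
    yc = ud.origin[1] + cs * (iy + 0.5)
    x = float(np.average(xc, weights=w))
    y = float(np.average(yc, weights=w))
    lon, lat = projection.inverse(x, y)
    return (float(lon), float(lat)), (x, y)


def extract_core_areas(ud: GridUD, fixes_12h, projection: ProjectionSpec,
                       level=0.5) -> list:
    """One CoreArea per connected component of the ``level`` isopleth."""
    iso = isopleth(ud, level)
    areas = []
    iy, ix = ud.cell_index(fixes_12h["x"].to_numpy(), fixes_12h["y"].to_numpy())
    fix_labels = iso.labels[iy, ix]
    in_winter_window = _in_winter_window(fixes_12h["timestamp"])
    for comp in range(1, iso.n_components + 1):
        mask = iso.labels == comp
        centroid, _ = _mass_weighted_centroid(ud, mask, projection)
        inside = fix_labels == comp
        areas.append(
            CoreArea(
                polygon=iso.polygons[comp - 1],
                centroid_lonlat=centroid,
                dwell_days=float(inside.sum()) * DWELL_DAYS_PER_FIX,
                winter_dwell_days=float((inside & in_winter_window).sum()) * DWELL_DAYS_PER_FIX,
                cell_mask=mask,
                ud=ud,
            )
        )
    return areas


def _in_winter_window(timestamps):
    m = timestamps.dt.month.to_numpy()
    d = timestamps.dt.day.to_numpy()
    (m0, d0), (m1, d1) = WINTER_WINDOW
    after_start = (m > m0) | ((m == m0) & (d >= d0))
    before_end = (m < m1) | ((m == m1) & (d <= d1))
    return after_start | before_end  # window wraps the year boundary


def assign_winter(core_areas, colony) -> CoreArea:
    """Pick the wintering area: max Dec–Mar dwell, ties to the farther area.

    Remaining areas become stopovers. Raises if no area has any Dec–Mar
    dwell (no winter residence in the data).
    """
    if not core_areas:
        raise ValueError("no core areas")
    if all(a.winter_dwell_days == 0 for a in core_areas):
        raise ValueError("no winter residence: zero Dec-Mar dwell in all core areas")
    lon_c, lat_c = colony

    def key(a):
        return (a.winter_dwell_days,
                great_circle_km(a.centroid_lonlat[0], a.centroid_lonlat[1], lon_c, lat_c))

    winner = max(core_areas, key=key)
    for a in core_areas:
        a.role = "winter" if a is winner else "stopover"
    return winner


def merge_fragmented_winters(yearly_core_areas, projection: ProjectionSpec):
    """Group fragmented winter polygons into single wintering areas.

    If the winter polygon of one year intersects two or more 50% polygons
    of another year, those fragments are unioned into that year's winter
    area. The pass is repeated until stable, so the grouping is symmetric
    and idempotent. ``yearly_core_areas`` is a list (one entry per year) of
    CoreArea lists in which winter roles are already assigned; the lists
    are modified in place and returned.
    """
    changed = True
    while changed:
        changed = False
        for areas_a in yearly_core_areas:
            winter_a = next((a for a in areas_a if a.role == "winter"), None)
            if winter_a is None:
                continue
            for areas_b in yearly_core_areas:
                if areas_b is areas_a:
                    continue
                hits = [b for b in areas_b if b.polygon.intersects(winter_a.polygon)]
                if len(hits) >= 2:
                    merged = _merge_areas(hits, projection)
                    merged.role = "winter" if any(b.role == "winter" for b in hits) else "stopover"
                    for b in hits:
                        areas_b.remove(b)
                    areas_b.append(merged)
                    changed = True
    return yearly_core_areas


def _merge_areas(areas, projection):
    ud = areas[0].ud
    mask = np.zeros(ud.shape, dtype=bool)
    for a in areas:
        mask |= a.cell_mask
    centroid, _ = _mass_weighted_centroid(ud, mask, projection)
    return CoreArea(
        polygon=unary_union([a.polygon for a in areas]),
        centroid_lonlat=centroid,
        dwell_days=sum(a.dwell_days for a in areas),
        winter_dwell_days=sum(a.winter_dwell_days for a in areas),
        cell_mask=mask,
        ud=ud,
    )


def phenology(season: SeasonWindow, winter_area: CoreArea, colony,
              gap_flag_days=TRANSITION_GAP_FLAG_DAYS) -> SeasonRecord:
    """Fill the four phenology dates and migration distance for a season.

    Winter arrival/departure are the timestamps of the first and last
    full-rate fix inside the winter polygon (boundary inclusive). A
    transition spanned by a data gap longer than ``gap_flag_days`` is
    flagged and its date set missing, mirroring the exclusion of
    individuals whose gaps coincide with a migration transition.
    """
    fx = season.fixes
    if "x" not in fx.columns:
        raise ValueError("season fixes must be projected before phenology")
    inside = winter_area.contains_xy(fx["x"].to_numpy(), fx["y"].to_numpy())
    idx = np.nonzero(inside)[0]
    if len(idx) == 0:
        raise ValueError("no fix inside the winter polygon")
    first, last = idx[0], idx[-1]
    t = fx["timestamp"]
    flags = {}
    winter_arrival = t.iloc[first]
    winter_departure = t.iloc[last]
    if first > 0 and (winter_arrival - t.iloc[first - 1]) > pd.Timedelta(days=gap_flag_days):
        flags["winter_arrival"] = "gap spans transition"
        winter_arrival = pd.NaT
    if last < len(fx) - 1 and (t.iloc[last + 1] - winter_departure) > pd.Timedelta(days=gap_flag_days):
        flags["winter_departure"] = "gap spans transition"
        winter_departure = pd.NaT
    dist = migration_distance(colony, winter_area)
    return SeasonRecord(
        individual_id=season.individual_id,
        season_label=season.season_label,
        colony_departure=season.colony_departure,
        winter_arrival=winter_arrival,
        winter_departure=winter_departure,
        colony_arrival=season.colony_arrival,
        migration_distance_km=dist,
        winter_area=winter_area,
        stopovers=[],
        flags=flags,
    )


def migration_distance(colony, winter_area: CoreArea) -> float:
    """Great-circle km from colony to the winter-area centroid."""
    lon, lat = winter_area.centroid_lonlat
    return float(great_circle_km(colony[0], colony[1], lon, lat))


def detect_strategy_switch(yearly_winter_areas) -> tuple:
    """True if any pair of yearly winter polygons is disjoint.

    Returns (switched, list of disjoint year-index pairs). Switchers are
    excluded from distance regressions and individual-level repeatability
    but kept in population repeatability of timing.
    """
    disjoint = []
    for i in range(len(yearly_winter_areas)):
        for j in range(i + 1, len(yearly_winter_areas)):
            if not yearly_winter_areas[i].polygon.intersects(yearly_winter_areas[j].polygon):
                disjoint.append((i, j))
    return (len(disjoint) > 0), disjoint
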