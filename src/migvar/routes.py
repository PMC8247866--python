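"""Mean migration routes and the route-variation statistic.

A migration route is the GPS path between colony and wintering area, with
fixes inside core areas removed and each core-area visit replaced by a
single point at the area centroid, so routes consist of migratory flight
only. Routes with a >24-h gap outside core areas are discarded.

The mean route of an individual (per direction) is a sequence of 500
points that minimizes the distance to nearest-neighbour locations on the
individual's yearly routes: starting from the arc-length-uniform
resampling of the pointwise leg average, each mean point is repeatedly
replaced by the centroid of its nearest locations on each leg
(continuous point-to-polyline projection), with arc-length re-spacing
after each sweep, until the points stop moving. Route variation is the
square root of the mean (over the 500 points) of the variance of
nearest-neighbour locations around each mean point, in km.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

MAX_ROUTE_GAP_H = 24.0
N_ROUTE_POINTS = 500


@dataclass
class MigrationLeg:
    individual_id: str
    season_label: str
    direction: str                  # "autumn" | "spring"
    points: np.ndarray              # (n, 2) planar metres, time-ordered
    dropped_reason: Optional[str] = None

    @property
    def ok(self):
        return self.dropped_reason is None


@dataclass
class MeanRoute:
    direction: str
    points: np.ndarray              # (n_points, 2) planar metres
    per_point_variance_km2: np.ndarray
    route_variation_km: float
    route_variation_km2: float      # mean variance form of the same metric
    objective_history: list = field(default_factory=list)
    converged: bool = True


def extract_legs(window_fixes, record, core_areas, max_gap_h=MAX_ROUTE_GAP_H):
    """Autumn and spring migration legs for one season.

    Autumn runs from colony departure to winter arrival, spring from
    winter departure to colony arrival; contiguous core-area visits are
    collapsed to the area centroid. Returns a dict
    {"autumn": MigrationLeg, "spring": MigrationLeg}; legs failing the
    24-h outside-core-area gap rule carry a ``dropped_reason``.
    """
    legs = {}
    spans = {
        "autumn": (record.colony_departure, record.winter_arrival),
        "spring": (record.winter_departure, record.colony_arrival),
    }
    for direction, (t0, t1) in spans.items():
        if t0 is None or t1 is None or pd.isna(t0) or pd.isna(t1):
            legs[direction] = MigrationLeg(
                record.individual_id, record.season_label, direction,
                np.empty((0, 2)), dropped_reason="phenology date missing")
            continue
        sel = (window_fixes["timestamp"] >= t0) & (window_fixes["timestamp"] <= t1)
        fx = window_fixes[sel].reset_index(drop=True)
        legs[direction] = _collapse_core_visits(fx, record, direction,
                                                core_areas, max_gap_h)
    return legs


def _collapse_core_visits(fx, record, direction, core_areas, max_gap_h):
    x = fx["x"].to_numpy(dtype=float)
    y = fx["y"].to_numpy(dtype=float)
    t = fx["timestamp"].dt.tz_convert(None).to_numpy()
    area_of_fix = np.full(len(fx), -1)
    for k, area in enumerate(core_areas):
        m = area.contains_xy(x, y) & (area_of_fix < 0)
        area_of_fix[m] = k
    pts, times = [], []
    i = 0
    while i < len(fx):
        k = area_of_fix[i]
        if k < 0:
            pts.append((x[i], y[i]))
            times.append(t[i])
            i += 1
        else:
            # contiguous visit to one core area -> single centroid point
            j = i
            while j < len(fx) and area_of_fix[j] == k:
                j += 1
            cx, cy = _area_centroid_xy(core_areas[k])
            pts.append((cx, cy))
            times.append(None)  # centroid point: exempt from the gap rule
            i = j
    # 24-h gap rule applies between consecutive fixes outside core areas
    reason = None
    last_t = None
    for ti in times:
        if ti is None:
            last_t = None  # core-area visit resets the clock
            continue
        if last_t is not None:
            gap_h = (ti - last_t) / np.timedelta64(1, "h")
            if gap_h > max_gap_h:
                reason = f"gap {gap_h:.1f} h outside core areas > {max_gap_h:g} h"
                break
        last_t = ti
    points = np.asarray(pts, dtype=float).reshape(-1, 2)
    return MigrationLeg(record.individual_id, record.season_label, direction,
                        points, dropped_reason=reason)


def _area_centroid_xy(area):
    iy, ix = np.nonzero(area.cell_mask)
    w = area.ud.masses[iy, ix]
    if w.sum() <= 0:
        w = np.ones_like(w)
    cs = area.ud.cell_size
    return (float(np.average(area.ud.origin[0] + cs * (ix + 0.5), weights=w)),
            float(np.average(area.ud.origin[1] + cs * (iy + 0.5), weights=w)))


def _arclength_resample(points, n):
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        return np.repeat(points[:1], n, axis=0)
    target = np.linspace(0.0, s[-1], n)
    out = np.empty((n, 2))
    for d in range(2):
        out[:, d] = np.interp(target, s, points[:, d])
    return out


def _nearest_on_polyline(query, poly):
    """Continuous nearest points on a polyline for each query point.

    Returns (nearest points (m,2), squared distances (m,)).
    """
    a = poly[:-1]                       # (s, 2) segment starts
    b = poly[1:]                        # (s, 2) segment ends
    ab = b - a
    denom = (ab**2).sum(axis=1)
    denom = np.where(denom > 0, denom, 1.0)
    # project each query point onto each segment
    ap = query[:, None, :] - a[None, :, :]          # (m, s, 2)
    tpar = np.clip((ap * ab[None, :, :]).sum(-1) / denom[None, :], 0.0, 1.0)
    proj = a[None, :, :] + tpar[..., None] * ab[None, :, :]
    d2 = ((query[:, None, :] - proj) ** 2).sum(-1)
    best = np.argmin(d2, axis=1)
    m = np.arange(len(query))
    return proj[m, best], d2[m, best]


def _objective(mean_pts, legs):
    """Mean over mean-points of the mean squared nearest-neighbour
    distance to each leg (m^2)."""
    d2 = np.zeros(len(mean_pts))
    for leg in legs:
        _, di2 = _nearest_on_polyline(mean_pts, leg)
        d2 += di2
    return float(np.mean(d2 / len(legs)))


def mean_route(legs, n_points=N_ROUTE_POINTS, tol_m=1000.0, max_iter=200,
               direction=None):
    """Fit the mean route of >= 2 same-direction legs.

    ``legs`` may be MigrationLeg objects or raw (n, 2) arrays. Iterates
    nearest-neighbour averaging with arc-length re-spacing; a sweep that
    fails to decrease the objective is rejected and iteration stops, so
    the objective history is non-increasing.
    """
    arrs = [leg.points if isinstance(leg, MigrationLeg) else np.asarray(leg, float)
            for leg in legs]
    if direction is None and legs and isinstance(legs[0], MigrationLeg):
        direction = legs[0].direction
    if len(arrs) < 2:
        raise ValueError("mean route needs >= 2 legs (multi-year data)")
    for a in arrs:
        if len(a) < 2:
            raise ValueError("each leg needs >= 2 points")
    resampled = [_arclength_resample(a, n_points) for a in arrs]
    current = _arclength_resample(np.mean(resampled, axis=0), n_points)
    history = [_objective(current, arrs)]
    converged = False
    for _ in range(max_iter):
        nearest = np.zeros_like(current)
        for a in arrs:
            pts, _ = _nearest_on_polyline(current, a)
            nearest += pts
        updated = _arclength_resample(nearest / len(arrs), n_points)
        obj = _objective(updated, arrs)
        if obj > history[-1] + 1e-12:
            converged = True  # no accepted improvement possible
            break
        disp = np.linalg.norm(updated - current, axis=1).max()
        current = updated
        history.append(obj)
        if disp < tol_m:
            converged = True
            break
    var_km2 = _per_point_variance_km2(current, arrs)
    mean_var = float(np.mean(var_km2))
    return MeanRoute(
        direction=direction or "unknown",
        points=current,
        per_point_variance_km2=var_km2,
        route_variation_km=float(np.sqrt(mean_var)),
        route_variation_km2=mean_var,
        objective_history=history,
        converged=converged,
    )


def _per_point_variance_km2(mean_pts, arrs):
    d2 = np.zeros(len(mean_pts))
    for a in arrs:
        _, di2 = _nearest_on_polyline(mean_pts, a)
        d2 += di2
    return (d2 / len(arrs)) / 1e6  # m^2 -> km^2


def route_variation(mean_route_obj: MeanRoute, legs) -> float:
    """Route variation (km) of legs around an already-fitted mean route."""
    arrs = [leg.points if isinstance(leg, MigrationLeg) else np.asarray(leg, float)
            for leg in legs]
    var_km2 = _per_point_variance_km2(mean_route_obj.points, arrs)
    return float(np.sqrt(np.mean(var_km2)))


def mean_route_to_geojson(mr: MeanRoute, properties=None):
    """Mean route as a GeoJSON LineString (planar metres) with the
    per-point variance array attached as a property."""
    props = {"direction": mr.direction,
             "route_variation_km": mr.route_variation_km,
             "per_point_variance_km2": [float(v) for v in mr.per_point_variance_km2],
             "converged": mr.converged}
    if properties:
        props.update(properties)
    return {
        "type": "Feature",
        "geometry": {"type": "LineString",
                     "coordinates": [[float(x), float(y)] for x, y in mr.points]},
        "properties": props,
        "crs_note": "planar metres, Lambert azimuthal equal-area",
    }


def between_individual_route_variation(leg_a, leg_b, n_points=N_ROUTE_POINTS,
                                       **kwargs) -> float:
    """Route variation of a between-individual pair (one leg each).

    The mean route is fitted to the two individuals' legs exactly as for
    within-individual variation; symmetric in the pair order.
    """
    mr = mean_route([leg_a, leg_b], n_points=n_points, **kwargs)
    return mr.route_variation_km
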