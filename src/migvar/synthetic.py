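"""Synthetic multi-year GPS tracks with known ground truth.

The generator emulates the statistical structure of a multi-colony,
multi-year gull-tracking data set: hourly fixes; a breeding-colony
residence period; an outbound migration with optional prolonged stopovers;
a winter residence 50–4,600 km from the colony; a return migration; and
individual-specific mean timing, route and sites with separate
among-individual and within-individual (between-year) variance.

Movement model (deliberately minimal):

* residence periods are a bounded (AR(1)) random walk around the site
  centroid with stationary scale ``site_jitter_km``;
* migration legs follow the great circle from colony to winter site with a
  smooth lateral offset ``(individual offset + yearly jitter) * sin(pi f)``
  vanishing at both endpoints;
* within a migration leg the first and last ~250 km are flown at cruise
  speed, so radius crossings at the colony and polygon entry/exit at the
  winter area are sharp; any slack between flight time and the leg's
  window is spread as slow progress over the middle of the leg;
* timing: individual mean date ~ Normal(population mean, sigma_among),
  yearly date ~ Normal(individual mean, sigma_within), clipped only where
  needed to keep the cycle ordered and physically travellable. Two dates
  are travel-linked rather than independent draws: winter arrival of
  stopover-free individuals (departure + flight time) and colony arrival
  of everyone (winter departure + flight time) — direct migrants fly
  straight through, so their arrival variance is inherited from the
  departure trait and the per-trait repeatability contract still holds.
  Stopover use is an individual-level property (a bird either stages every
  year or never), which keeps within-individual timing variance governed
  by sigma_within alone.

The true repeatability of each timing trait is
sigma_among^2 / (sigma_among^2 + sigma_within^2); all truth (sites,
dates, distances) is exactly reconstructable from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .geo import destination, gc_interpolate, great_circle_km

KM_PER_DEG_LAT = 111.32

DEFAULT_COLONIES = [
    (4.72, 53.0),   # Wadden coast
    (3.18, 51.3),   # Belgian coast
    (1.58, 52.1),   # East Anglia
    (-3.18, 54.0),  # Irish Sea
]

TRAITS = ("colony_departure", "winter_arrival", "winter_departure", "colony_arrival")


@dataclass
class PopulationConfig:
    n_individuals: int = 20
    n_colonies: int = 4
    colony_coords: list = field(default_factory=lambda: list(DEFAULT_COLONIES))
    years_per_individual: tuple = (2, 4)
    start_year: int = 2014
    fix_interval_h: float = 1.0
    migration_distance_range_km: tuple = (50.0, 4600.0)
    bearing_sector_deg: tuple = (195.0, 220.0)
    p_stopover: float = 0.7
    # population mean dates as days since 1 Jan of the departure year
    timing_mu_days: dict = field(default_factory=lambda: {
        "colony_departure": 217.0,   # ~6 Aug
        "winter_arrival": 278.0,     # ~6 Oct
        "winter_departure": 434.0,   # ~10 Mar (next year)
        "colony_arrival": 465.0,     # ~10 Apr
    })
    sigma_among_days: float = 10.0
    sigma_within_days: float = 6.0
    route_offset_sigma_km: float = 60.0
    route_jitter_sigma_km: float = 25.0
    site_jitter_km: float = 3.0
    cruise_speed_kmh: float = 50.0
    fast_leg_km: float = 250.0
    min_stopover_days: float = 21.0
    min_winter_days: float = 60.0
    min_stopover_distance_km: float = 600.0
    gap_injection: list = field(default_factory=list)  # [(prob, (min_d, max_d)), ...]
    seed: int = 0

    def validate(self):
        if self.n_colonies < 1 or len(self.colony_coords) < self.n_colonies:
            raise ValueError("need >= 1 colony with coordinates")
        if self.fix_interval_h <= 0:
            raise ValueError("fix_interval must be positive")
        for name in ("sigma_among_days", "sigma_within_days",
                     "route_offset_sigma_km", "route_jitter_sigma_km",
                     "site_jitter_km"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        mu = [self.timing_mu_days[t] for t in TRAITS]
        if not all(a < b for a, b in zip(mu[:-1], mu[1:])):
            raise ValueError("population mean dates must be ordered "
                             "departure < winter arrival < winter departure < arrival")
        if not 0 <= self.p_stopover <= 1:
            raise ValueError("p_stopover must be a probability")


@dataclass
class GroundTruth:
    """Simulation-side truth: sites, dates and variance components."""

    individuals: pd.DataFrame
    seasons: pd.DataFrame
    r_true: dict
    sigma_among_days: float
    sigma_within_days: float

    def write(self, individuals_path, seasons_path):
        self.individuals.to_csv(individuals_path, index=False)
        out = self.seasons.copy()
        for t in TRAITS:
            out[t] = out[t].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
        out.to_csv(seasons_path, index=False)


def _ou_walk(n, sd, rng, rho=0.95):
    """Stationary AR(1) series of length n with marginal SD ``sd``."""
    if n <= 0:
        return np.empty(0)
    e = rng.standard_normal(n) * (sd * np.sqrt(1.0 - rho**2))
    e[0] = rng.standard_normal() * sd
    return lfilter([1.0], [1.0, -rho], e)


def _offset_lonlat(lon_c, lat_c, dx_km, dy_km):
    lat = lat_c + dy_km / KM_PER_DEG_LAT
    lon = lon_c + dx_km / (KM_PER_DEG_LAT * np.cos(np.radians(lat_c)))
    return lon, lat


def _progress_km(t_h, total_h, seg_km, cruise, fast_km):
    """Distance along a leg at hours ``t_h`` into a window of ``total_h``:
    fast start and end at cruise speed, slow drift in between."""
    t_h = np.asarray(t_h, dtype=float)
    a = min(fast_km, 0.4 * seg_km)
    t_fast = a / cruise
    t_mid = total_h - 2.0 * t_fast
    mid_km = seg_km - 2.0 * a
    if t_mid <= 0 or total_h * cruise <= seg_km:
        return np.clip(t_h / total_h, 0, 1) * seg_km
    p = np.where(
        t_h < t_fast,
        cruise * t_h,
        np.where(
            t_h < t_fast + t_mid,
            a + mid_km * (t_h - t_fast) / t_mid,
            a + mid_km + cruise * (t_h - t_fast - t_mid),
        ),
    )
    return np.clip(p, 0.0, seg_km)


class _Itinerary:
    """Phase list for one individual; renders hourly positions."""

    def __init__(self, cfg, rng):
        self.cfg = cfg
        self.rng = rng
        self.phases = []  # (t0_h, t1_h, kind, payload), half-open [t0, t1)

    def add(self, t0, t1, kind, **payload):
        if t1 > t0:
            self.phases.append((t0, t1, kind, payload))

    def render(self, start_ts):
        iv = self.cfg.fix_interval_h
        rows_t, rows_lon, rows_lat = [], [], []
        for t0, t1, kind, pl in self.phases:
            k0 = int(np.ceil(t0 / iv - 1e-9))
            k1 = int(np.ceil(t1 / iv - 1e-9))
            if k1 <= k0:
                continue
            th = np.arange(k0, k1) * iv
            if kind == "residence":
                dx = _ou_walk(len(th), pl["jitter_km"], self.rng)
                dy = _ou_walk(len(th), pl["jitter_km"], self.rng)
                r = np.hypot(dx, dy)
                cap = pl.get("cap_km")
                if cap:
                    scale = np.where(r > cap, cap / np.maximum(r, 1e-9), 1.0)
                    dx, dy = dx * scale, dy * scale
                lon, lat = _offset_lonlat(pl["lon"], pl["lat"], dx, dy)
            elif kind == "travel":
                p = _progress_km(th - t0, t1 - t0, pl["seg_km"],
                                 self.cfg.cruise_speed_kmh, self.cfg.fast_leg_km)
                f = pl["f0"] + (pl["f1"] - pl["f0"]) * p / max(pl["seg_km"], 1e-9)
                lateral = pl["amp_km"] * np.sin(np.pi * f)
                lon, lat = gc_interpolate(*pl["colony"], *pl["winter"], f, lateral)
            else:
                raise ValueError(kind)
            rows_t.append(th)
            rows_lon.append(np.atleast_1d(lon))
            rows_lat.append(np.atleast_1d(lat))
        th = np.concatenate(rows_t)
        ts = start_ts + pd.to_timedelta(th, unit="h")
        return ts, np.concatenate(rows_lon), np.concatenate(rows_lat)


def generate_population(config: PopulationConfig):
    """Generate hourly tracks for a population; returns (fixes, GroundTruth).

    The fix table has the canonical track_io columns; identical seeds give
    byte-identical output.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    iv = cfg.fix_interval_h
    lo, hi = cfg.migration_distance_range_km
    frames, ind_rows, season_rows = [], [], []
    for i in range(cfg.n_individuals):
        ind_id = f"g{i:03d}"
        colony_id = i % cfg.n_colonies
        colony = cfg.colony_coords[colony_id]
        dist = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        bearing = float(rng.uniform(*cfg.bearing_sector_deg))
        w_lon, w_lat = destination(colony[0], colony[1], bearing, dist)
        winter = (float(w_lon), float(w_lat))
        dist = float(great_circle_km(colony[0], colony[1], *winter))
        n_years = int(rng.integers(cfg.years_per_individual[0],
                                   cfg.years_per_individual[1] + 1))
        offset_km = float(rng.normal(0.0, cfg.route_offset_sigma_km))
        if dist >= cfg.min_stopover_distance_km and rng.random() < cfg.p_stopover:
            n_stop = int(rng.choice([1, 2], p=[0.7, 0.3]))
        else:
            n_stop = 0
        stop_fracs = {1: [0.55], 2: [0.4, 0.7]}.get(n_stop, [])
        mu = {t: cfg.timing_mu_days[t] + rng.normal(0.0, cfg.sigma_among_days)
              for t in TRAITS}
        travel_d_i = dist / cfg.cruise_speed_kmh / 24.0
        if n_stop == 0:
            mu["winter_arrival"] = mu["colony_departure"] + travel_d_i + 0.5
        mu["colony_arrival"] = mu["winter_departure"] + travel_d_i + 0.5
        start_ts = pd.Timestamp(year=cfg.start_year, month=5, day=1, tz="UTC")
        end_h = (pd.Timestamp(year=cfg.start_year + n_years, month=7, day=20, tz="UTC")
                 - start_ts) / pd.Timedelta(hours=1)
        itin = _Itinerary(cfg, rng)
        t_cursor = 0.0
        for k in range(n_years):
            yr0 = pd.Timestamp(year=cfg.start_year + k, month=1, day=1, tz="UTC")
            base_h = (yr0 - start_ts) / pd.Timedelta(hours=1)
            d = {t: mu[t] + rng.normal(0.0, cfg.sigma_within_days) for t in TRAITS}
            k_stop = n_stop
            travel_h = dist / cfg.cruise_speed_kmh
            travel_d = travel_h / 24.0
            if k_stop == 0:
                # direct migrants fly straight through: winter arrival is
                # departure-linked, not an independent draw
                d["winter_arrival"] = d["colony_departure"] + travel_d + 0.5
            else:
                need_out = travel_d + cfg.min_stopover_days * k_stop + 1.0
                d["winter_arrival"] = max(d["winter_arrival"],
                                          d["colony_departure"] + need_out)
            d["winter_departure"] = max(d["winter_departure"],
                                        d["winter_arrival"] + cfg.min_winter_days)
            # spring migration is direct for everyone
            d["colony_arrival"] = d["winter_departure"] + travel_d + 0.5
            ev = {t: round((base_h + d[t] * 24.0) / iv) * iv for t in TRAITS}
            amp = offset_km + rng.normal(0.0, cfg.route_jitter_sigma_km)
            itin.add(t_cursor, ev["colony_departure"], "residence",
                     lon=colony[0], lat=colony[1],
                     jitter_km=min(cfg.site_jitter_km, 3.0), cap_km=8.0)
            _plan_outbound(itin, cfg, ev, colony, winter, dist, amp, stop_fracs)
            itin.add(ev["winter_arrival"], ev["winter_departure"], "residence",
                     lon=winter[0], lat=winter[1], jitter_km=cfg.site_jitter_km)
            itin.add(ev["winter_departure"], ev["colony_arrival"], "travel",
                     colony=colony, winter=winter, f0=1.0, f1=0.0,
                     seg_km=dist, amp_km=amp)
            t_cursor = ev["colony_arrival"]
            season_rows.append({
                "individual_id": ind_id, "year": cfg.start_year + k,
                **{t: start_ts + pd.Timedelta(hours=ev[t]) for t in TRAITS},
                "n_stopovers": k_stop, "route_amp_km": amp,
            })
        itin.add(t_cursor, end_h, "residence", lon=colony[0], lat=colony[1],
                 jitter_km=min(cfg.site_jitter_km, 3.0), cap_km=8.0)
        ts, lon, lat = itin.render(start_ts)
        traj = pd.DataFrame({"individual_id": ind_id, "timestamp": ts,
                             "lon": lon, "lat": lat})
        if cfg.gap_injection:
            traj = inject_gaps(traj, cfg.gap_injection,
                               seed=int(rng.integers(2**31 - 1)))
        frames.append(traj)
        stop_lonlat = [
            gc_interpolate(*colony, *winter, np.array([f]),
                           np.array([offset_km * np.sin(np.pi * f)]))
            for f in stop_fracs
        ]
        ind_rows.append({
            "individual_id": ind_id, "colony_id": f"c{colony_id}",
            "colony_lon": colony[0], "colony_lat": colony[1],
            "winter_lon": winter[0], "winter_lat": winter[1],
            "migration_distance_km": dist, "bearing_deg": bearing,
            "route_offset_km": offset_km, "n_years": n_years,
            "n_stopover_sites": n_stop,
            "stopover_lons": ";".join(f"{p[0][0]:.6f}" for p in stop_lonlat),
            "stopover_lats": ";".join(f"{p[1][0]:.6f}" for p in stop_lonlat),
            **{f"mu_{t}_days": mu[t] for t in TRAITS},
        })
    fixes = pd.concat(frames, ignore_index=True)
    r = cfg.sigma_among_days**2 / (cfg.sigma_among_days**2 + cfg.sigma_within_days**2) \
        if (cfg.sigma_among_days or cfg.sigma_within_days) else 0.0
    truth = GroundTruth(
        individuals=pd.DataFrame(ind_rows),
        seasons=pd.DataFrame(season_rows),
        r_true={t: r for t in TRAITS},
        sigma_among_days=cfg.sigma_among_days,
        sigma_within_days=cfg.sigma_within_days,
    )
    return fixes, truth


def _plan_outbound(itin, cfg, ev, colony, winter, dist, amp, stop_fracs):
    """Outbound phases between colony departure and winter arrival."""
    t0, t1 = ev["colony_departure"], ev["winter_arrival"]
    if not stop_fracs:
        itin.add(t0, t1, "travel", colony=colony, winter=winter,
                 f0=0.0, f1=1.0, seg_km=dist, amp_km=amp)
        return
    fracs = [0.0] + list(stop_fracs) + [1.0]
    seg_kms = [dist * (b - a) for a, b in zip(fracs[:-1], fracs[1:])]
    travel_hs = [s / cfg.cruise_speed_kmh for s in seg_kms]
    dwell_total = (t1 - t0) - sum(travel_hs)
    dwell_each = dwell_total / len(stop_fracs)
    t = t0
    for j, (fa, fb) in enumerate(zip(fracs[:-1], fracs[1:])):
        itin.add(t, t + travel_hs[j], "travel", colony=colony, winter=winter,
                 f0=fa, f1=fb, seg_km=seg_kms[j], amp_km=amp)
        t += travel_hs[j]
        if fb < 1.0:
            s_lon, s_lat = gc_interpolate(*colony, *winter, np.array([fb]),
                                          np.array([amp * np.sin(np.pi * fb)]))
            itin.add(t, t + dwell_each, "residence",
                     lon=float(s_lon[0]), lat=float(s_lat[0]),
                     jitter_km=cfg.site_jitter_km)
            t += dwell_each


def inject_gaps(trajectory, gap_spec, seed=0):
    """Delete runs of fixes to emulate device outages.

    ``gap_spec`` is a list of (probability, (min_days, max_days)); each
    entry independently inserts at most one gap of uniform duration at a
    uniform start time. The input frame is not modified.
    """
    if not gap_spec:
        return trajectory.copy()
    rng = np.random.default_rng(seed)
    out = trajectory
    t0, t1 = trajectory["timestamp"].iloc[0], trajectory["timestamp"].iloc[-1]
    span_d = (t1 - t0) / pd.Timedelta(days=1)
    keep = np.ones(len(trajectory), dtype=bool)
    t = trajectory["timestamp"]
    for prob, (dmin, dmax) in gap_spec:
        if rng.random() >= prob:
            continue
        dur = float(rng.uniform(dmin, dmax))
        start_d = float(rng.uniform(0.0, max(span_d - dur, 0.0)))
        g0 = t0 + pd.Timedelta(days=start_d)
        g1 = g0 + pd.Timedelta(days=dur)
        keep &= ~((t >= g0) & (t < g1))
    return out[keep].reset_index(drop=True)


def force_gap(trajectory, start, duration_days):
    """Delete all fixes in [start, start + duration_days) — a deterministic
    gap for exercising the inclusion filters."""
    t = trajectory["timestamp"]
    g0 = pd.Timestamp(start)
    if g0.tzinfo is None:
        g0 = g0.tz_localize("UTC")
    g1 = g0 + pd.Timedelta(days=duration_days)
    return trajectory[~((t >= g0) & (t < g1))].reset_index(drop=True)
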