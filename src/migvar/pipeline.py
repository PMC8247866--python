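"""End-to-end orchestration: ingest -> seasons -> UDs -> phenology ->
routes -> overlaps -> statistics.

Every stage is a thin call into the library modules; the pipeline adds
bookkeeping (per-stage artifacts, a resolved-config manifest, seeds) and
is deterministic given (config, seeds). Distances are km, overlap is
Bhattacharyya affinity in [0, 0.95] under the 95%-truncation convention,
timing traits are days since 1 January of the season's starting year.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import routes as rt
from . import seasons as sn
from . import space_use as su
from . import stats as st
from . import synthetic as syn
from . import track_io as tio
from .geo import ProjectionSpec

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline parameters; defaults are the standard analysis values."""

    out_dir: str = "migvar_run"
    tracks_path: str = None
    colonies_path: str = None          # csv: individual_id, colony_id, lon, lat
    subsample_interval_h: float = 12.0
    grid_cell_km: float = 10.0
    bandwidth_km: float = 100.0
    ud_level: float = 0.95
    core_level: float = 0.50
    max_gap_days: float = 21.0
    colony_radius_km: float = 10.0
    pair_constraint_km: float = 250.0
    route_max_gap_h: float = 24.0
    n_route_points: int = 500
    winter_cell_m: float = 500.0
    n_permutations: int = 10_000
    n_bootstraps: int = 1_000
    seed: int = 0
    synthetic: dict = field(default_factory=dict)  # PopulationConfig overrides

    def to_manifest(self):
        return asdict(self)


def simulate_command(config: RunConfig):
    """Generate a synthetic population and write tracks + ground truth."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pc = syn.PopulationConfig(**{"seed": config.seed, **config.synthetic})
    pc.validate()
    fixes, truth = syn.generate_population(pc)
    tio.write_tracks(fixes, out / "tracks.csv")
    truth.individuals.to_csv(out / "truth_individuals.csv", index=False)
    tseasons = truth.seasons.copy()
    for t in syn.TRAITS:
        tseasons[t] = tseasons[t].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    tseasons.to_csv(out / "truth_seasons.csv", index=False)
    colonies = truth.individuals[["individual_id", "colony_id",
                                  "colony_lon", "colony_lat"]].rename(
        columns={"colony_lon": "lon", "colony_lat": "lat"})
    colonies.to_csv(out / "colonies.csv", index=False)
    return fixes, truth


def _write_table(df, path, note):
    """CSV with a '#' header comment declaring units / reference frame
    (read back with pandas via ``comment='#'``)."""
    with open(path, "w") as fh:
        fh.write(f"# {note}\n")
        df.to_csv(fh, index=False)


def _trait_days(ts, season_year):
    if ts is None or pd.isna(ts):
        return np.nan
    ref = pd.Timestamp(year=season_year, month=1, day=1, tz="UTC")
    return (ts - ref) / pd.Timedelta(days=1)


def run_pipeline(config: RunConfig, fixes=None, colonies=None):
    """Run all stages; returns a results dict and writes artifacts.

    ``fixes``/``colonies`` may be passed in-memory (e.g. straight from the
    generator); otherwise they are read from the configured paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fixes is None:
        fixes = tio.read_tracks(config.tracks_path)
    if colonies is None:
        colonies = pd.read_csv(config.colonies_path)
    colony_of = {r.individual_id: (r.lon, r.lat, str(r.colony_id))
                 for r in colonies.itertuples()}
    proj = ProjectionSpec(lon_0=float(colonies["lon"].mean()),
                          lat_0=float(colonies["lat"].mean()))

    # --- seasons + inclusion filters -------------------------------------
    all_seasons = []
    for ind, grp in fixes.groupby("individual_id", sort=True):
        lon_c, lat_c, _ = colony_of[str(ind)]
        try:
            wins = tio.split_seasons(grp.reset_index(drop=True), (lon_c, lat_c),
                                     radius_km=config.colony_radius_km)
        except tio.ResidentError as e:
            logger.info("excluded resident individual: %s", e)
            continue
        all_seasons.extend(wins)
    kept, drop_report = tio.apply_inclusion_filters(all_seasons,
                                                    max_gap=config.max_gap_days)
    _write_table(drop_report, out / "season_drops.csv",
                 "seasons/individuals removed by inclusion filters; gaps in days")

    # --- UDs, core areas, phenology --------------------------------------
    per_ind = {}
    for w in kept:
        per_ind.setdefault(w.individual_id, []).append(w)
    records, season_uds, winter_areas, season_windows = {}, {}, {}, {}
    core_sets = {}
    for ind, wins in per_ind.items():
        lon_c, lat_c, col_id = colony_of[ind]
        yearly_areas = []
        uds, sub12 = [], []
        for w in wins:
            fx = tio.project(w.fixes, proj)
            w.fixes = fx
            s12 = tio.subsample(fx, f"{config.subsample_interval_h:g}h")
            ud = su.kde_ud(s12, cell_size=config.grid_cell_km * 1000.0,
                           h=config.bandwidth_km * 1000.0)
            areas = sn.extract_core_areas(ud, s12, proj, level=config.core_level)
            try:
                sn.assign_winter(areas, (lon_c, lat_c))
            except ValueError as e:
                logger.info("%s %s: %s", ind, w.season_label, e)
                areas = []
            yearly_areas.append(areas)
            uds.append(ud)
            sub12.append(s12)
        sn.merge_fragmented_winters([a for a in yearly_areas if a], proj)
        for w, ud, areas in zip(wins, uds, yearly_areas):
            winter = next((a for a in areas if a.role == "winter"), None)
            if winter is None:
                continue
            try:
                rec = sn.phenology(w, winter, (lon_c, lat_c))
            except ValueError as e:
                logger.info("%s %s: %s", ind, w.season_label, e)
                continue
            rec.stopovers = [a for a in areas if a.role == "stopover"]
            key = (ind, w.season_label)
            records[key] = rec
            season_uds[key] = ud
            winter_areas[key] = winter
            season_windows[key] = w
            core_sets[key] = areas

    season_table = pd.DataFrame([
        {"individual_id": r.individual_id, "season_label": r.season_label,
         "colony_departure": r.colony_departure, "winter_arrival": r.winter_arrival,
         "winter_departure": r.winter_departure, "colony_arrival": r.colony_arrival,
         "migration_distance_km": r.migration_distance_km,
         "n_stopovers": len(r.stopovers)}
        for r in records.values()
    ])
    _write_table(season_table, out / "season_records.csv",
                 "dates UTC; migration_distance_km = great-circle colony to winter centroid")

    # --- switchers, per-individual summaries ------------------------------
    ind_ids = sorted({k[0] for k in records})
    switchers = set()
    ind_rows = []
    for ind in ind_ids:
        keys = sorted(k for k in records if k[0] == ind)
        if len(keys) < 2:
            continue
        wareas = [winter_areas[k] for k in keys]
        switched, _ = sn.detect_strategy_switch(wareas)
        if switched:
            switchers.add(ind)
        dists = [records[k].migration_distance_km for k in keys]
        lon_c, lat_c, col_id = colony_of[ind]
        wlon = float(np.mean([a.centroid_lonlat[0] for a in wareas]))
        wlat = float(np.mean([a.centroid_lonlat[1] for a in wareas]))
        ind_rows.append({
            "individual_id": ind, "colony_id": col_id,
            "colony_lon": lon_c, "colony_lat": lat_c,
            "winter_lon": wlon, "winter_lat": wlat,
            "median_distance_km": float(np.median(dists)),
            "n_seasons": len(keys), "switcher": ind in switchers,
            "seasons": [k[1] for k in keys],
        })
    individuals = pd.DataFrame(ind_rows)

    # --- within-individual overlap + winter site fidelity -----------------
    overlap_rows = []
    for row in ind_rows:
        ind = row["individual_id"]
        keys = [(ind, s) for s in row["seasons"]]
        mean_ba, _ = su.seasonal_overlap_matrix([season_uds[k] for k in keys],
                                                level=config.ud_level)
        fid = np.nan
        try:
            wuds = []
            for k in keys:
                rec, w = records[k], season_windows[k]
                if pd.isna(rec.winter_arrival) or pd.isna(rec.winter_departure):
                    raise ValueError("winter dates missing")
                sel = ((w.fixes["timestamp"] >= rec.winter_arrival)
                       & (w.fixes["timestamp"] <= rec.winter_departure))
                wuds.append(su.brb_ud(w.fixes[sel].reset_index(drop=True),
                                      cell_size=config.winter_cell_m))
            fid, _ = su.winter_site_fidelity(wuds, level=config.ud_level)
        except (ValueError, su.GridMismatchError) as e:
            logger.info("%s winter fidelity skipped: %s", ind, e)
        overlap_rows.append({"individual_id": ind, "overlap_ba": mean_ba,
                             "winter_fidelity_ba": fid,
                             "median_distance_km": row["median_distance_km"],
                             "switcher": row["switcher"]})
    overlap_table = pd.DataFrame(overlap_rows)
    _write_table(overlap_table, out / "within_individual_overlap.csv",
                 "Bhattacharyya affinity of 95% UDs (max 0.95); distances km")

    # --- routes ------------------------------------------------------------
    legs_by_ind = {"autumn": {}, "spring": {}}
    for key, rec in records.items():
        w = season_windows[key]
        legs = rt.extract_legs(w.fixes, rec, core_sets[key],
                               max_gap_h=config.route_max_gap_h)
        for direction, leg in legs.items():
            if leg.ok and len(leg.points) >= 2:
                legs_by_ind[direction].setdefault(key[0], []).append(leg)
    route_rows = []
    mean_routes = {}
    for direction in ("autumn", "spring"):
        for ind, legs in legs_by_ind[direction].items():
            if len(legs) < 2 or ind in switchers:
                continue
            mr = rt.mean_route(legs, n_points=config.n_route_points)
            mean_routes[(ind, direction)] = mr
            med = individuals.set_index("individual_id")["median_distance_km"]
            route_rows.append({"individual_id": ind, "direction": direction,
                               "n_legs": len(legs),
                               "route_variation_km": mr.route_variation_km,
                               "route_variation_km2": mr.route_variation_km2,
                               "median_distance_km": float(med[ind])})
    route_table = pd.DataFrame(route_rows, columns=[
        "individual_id", "direction", "n_legs", "route_variation_km",
        "route_variation_km2", "median_distance_km"])
    _write_table(route_table, out / "route_variation.csv",
                 "route variation in km (sqrt of mean nearest-neighbour variance); planar equal-area frame")

    # --- between-individual pairing + randomization ------------------------
    results = {"n_individuals": len(ind_rows), "n_seasons": len(records),
               "n_switchers": len(switchers)}
    nonswitch = individuals[~individuals["switcher"]] if len(individuals) else individuals
    pairset = st.build_pairs(nonswitch, constraint_km=config.pair_constraint_km,
                             seed=config.seed) if len(nonswitch) >= 2 else None
    between_rows = []
    if pairset is not None and len(pairset.pairs):
        for p in pairset.pairs.itertuples():
            ka, kb = (p.id_a, p.season_a), (p.id_b, p.season_b)
            if ka not in season_uds or kb not in season_uds:
                continue
            row = {"id_a": p.id_a, "id_b": p.id_b,
                   "pair_distance_km": p.pair_distance_km}
            aligned = su.common_grid([season_uds[ka], season_uds[kb]])
            row["overlap_ba"] = su.bhattacharyya(
                su.truncate_ud(aligned[0], config.ud_level),
                su.truncate_ud(aligned[1], config.ud_level))
            for direction in ("autumn", "spring"):
                la = legs_by_ind[direction].get(p.id_a, [])
                lb = legs_by_ind[direction].get(p.id_b, [])
                if la and lb:
                    row[f"route_variation_{direction}_km"] = (
                        rt.between_individual_route_variation(
                            la[0], lb[0], n_points=config.n_route_points))
            between_rows.append(row)
        _write_table(pairset.pairs, out / "pairs.csv",
                     "between-individual pairs under the 250-km colony/winter constraint; km")
    between_table = pd.DataFrame(between_rows)
    _write_table(between_table, out / "between_individual.csv",
                 "between-individual BA overlap and route variation (km)")

    rand_rows = []
    intra_ok = overlap_table[~overlap_table["switcher"]] if len(overlap_table) else overlap_table

    def _rand(name, within_vals, between_vals, larger_is_variable):
        w = np.asarray(within_vals, float)
        b = np.asarray(between_vals, float)
        w, b = w[np.isfinite(w)], b[np.isfinite(b)]
        if len(w) == 0 or len(b) == 0:
            return
        # overlap: low = variable, so the paper's one-sided direction flips
        if not larger_is_variable:
            w, b = -w, -b
        p, obs = st.randomization_test(w, b, n_perm=config.n_permutations,
                                       seed=config.seed)
        rand_rows.append({"metric": name, "p": p,
                          "observed_median_difference": obs if larger_is_variable else -obs})

    if len(between_table):
        _rand("overlap_ba", intra_ok["overlap_ba"],
              between_table.get("overlap_ba", []), larger_is_variable=False)
        for direction in ("autumn", "spring"):
            col = f"route_variation_{direction}_km"
            if col in between_table:
                _rand(col, route_table[route_table["direction"] == direction]
                      ["route_variation_km"], between_table[col],
                      larger_is_variable=True)
    rand_table = pd.DataFrame(rand_rows)
    _write_table(rand_table, out / "randomization_tests.csv",
                 "one-sided add-one permutation p-values; difference of medians")

    # --- repeatability of timing traits ------------------------------------
    rep_rows, ri_tables = [], {}
    timing = []
    ind_meta = individuals.set_index("individual_id") if len(individuals) else None
    for r in records.values():
        if ind_meta is None or r.individual_id not in ind_meta.index:
            continue
        y = int(r.season_label.split("–")[0])
        timing.append({
            "individual_id": r.individual_id,
            "colony_id": ind_meta.loc[r.individual_id, "colony_id"],
            "distance": ind_meta.loc[r.individual_id, "median_distance_km"],
            **{t: _trait_days(getattr(r, t), y) for t in syn.TRAITS},
        })
    timing = pd.DataFrame(timing)
    if len(timing):
        _write_table(timing, out / "timing_traits.csv",
                     "timing traits in days since 1 Jan of the season start year (UTC); distance km")
    for trait in syn.TRAITS:
        if not len(timing):
            break
        sub = timing.dropna(subset=[trait])
        try:
            res = st.fit_variance_components(
                sub[trait], sub["individual_id"], sub["colony_id"],
                sub["distance"], trait=trait,
                include_distance=(trait != "winter_arrival"))
            st.bootstrap_ci(res, n_boot=config.n_bootstraps, seed=config.seed)
            ri = st.individual_repeatability(res, exclude=switchers)
            ri_tables[trait] = ri
            rep_rows.append({"trait": trait, "R": res.R, "s_a2": res.s_a2,
                             "s_eps2": res.s_eps2, "s_colony2": res.s_colony2,
                             "ci_lo": res.ci95[0], "ci_hi": res.ci95[1],
                             "singular": res.singular})
        except Exception as e:
            logger.warning("repeatability %s failed: %s", trait, e)
    rep_table = pd.DataFrame(rep_rows)
    _write_table(rep_table, out / "repeatability.csv",
                 "variance components in trait units squared (days^2); R dimensionless")
    for trait, ri in ri_tables.items():
        _write_table(ri, out / f"individual_repeatability_{trait}.csv",
                     "per-individual residual variance (days^2) and R_i; distance km")

    # --- distance models ----------------------------------------------------
    model_rows = []

    def _model(name, values, dists):
        try:
            m = st.distance_model(values, dists, response=name)
            model_rows.append(vars(m))
            return m
        except ValueError as e:
            logger.info("distance model %s skipped: %s", name, e)
            return None

    if len(intra_ok) >= 3:
        m_overlap = _model("overlap_ba", intra_ok["overlap_ba"],
                           intra_ok["median_distance_km"])
        _model("winter_fidelity_ba", intra_ok["winter_fidelity_ba"],
               intra_ok["median_distance_km"])
        if len(between_table) >= 3 and m_overlap is not None:
            m_between = _model("between_overlap_ba", between_table["overlap_ba"],
                               between_table["pair_distance_km"])
            if m_between is not None:
                _, m_resid = st.residual_variation(
                    intra_ok["overlap_ba"], intra_ok["median_distance_km"], m_between)
                model_rows.append(vars(m_resid))
    for direction in ("autumn", "spring"):
        sub = route_table[route_table["direction"] == direction]
        if len(sub) >= 3:
            _model(f"route_variation_{direction}_km",
                   sub["route_variation_km"], sub["median_distance_km"])
    for trait, ri in ri_tables.items():
        sub = ri[ri["n_i"] >= 2]
        if len(sub) >= 3:
            _model(f"R_i_{trait}", sub["R_i"], sub["distance"])
    model_table = pd.DataFrame(model_rows)
    _write_table(model_table, out / "distance_models.csv",
                 "OLS fits of variation metrics on migration distance (km); F with (1, n-2) df")

    # --- summary ------------------------------------------------------------
    def _med_range(v):
        v = np.asarray(v, float)
        v = v[np.isfinite(v)]
        if len(v) == 0:
            return None
        return {"median": float(np.median(v)), "min": float(v.min()),
                "max": float(v.max()), "n": int(len(v))}

    results.update({
        "overlap_within": _med_range(intra_ok["overlap_ba"]) if len(intra_ok) else None,
        "overlap_between": _med_range(between_table["overlap_ba"]) if len(between_table) else None,
        "winter_fidelity": _med_range(intra_ok["winter_fidelity_ba"]) if len(intra_ok) else None,
        "route_variation": {
            d: _med_range(route_table[route_table["direction"] == d]["route_variation_km"])
            for d in ("autumn", "spring")} if len(route_table) else None,
        "repeatability": {r["trait"]: r["R"] for r in rep_rows},
        "randomization_p": {r["metric"]: r["p"] for r in rand_rows},
        "migration_distance": _med_range(individuals["median_distance_km"])
        if len(individuals) else None,
    })
    with open(out / "summary.json", "w") as fh:
        json.dump(results, fh, indent=2, default=str)
    with open(out / "manifest.json", "w") as fh:
        json.dump(config.to_manifest(), fh, indent=2)
    return results
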