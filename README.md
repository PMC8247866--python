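# migvar

Individual-level variation in migratory behaviour from multi-year GPS
tracking.

Many seabirds — lesser black-backed gulls are the motivating system — mix
radically different migration strategies within one breeding colony: some
individuals winter 50 km from the colony, others cross continents. With
multi-year GPS tracks, one can ask how repeatable each individual's
behaviour is across years, and whether long-distance migrants are more
"fixed" than short-distance ones. `migvar` implements that analysis for
anyone with tracking data of the form *(individual, timestamp, lon, lat)*:

* **Non-breeding distribution** — seasonal utilization distributions (UDs)
  from a bivariate normal kernel (10-km equal-area grid, fixed bandwidth
  *h* = 100 km) on 12-h subsampled fixes; within- and between-individual
  overlap via Bhattacharyya's affinity BA = Σ√(p·q). UDs are truncated at
  the 95% isopleth without renormalization, so the maximum attainable BA
  is 0.95.
* **Winter site fidelity** — fine-scale (500-m grid) winter UDs from a
  biased random bridge: kernel variance grows mid-step as
  σ²(p) = h²_min + 4DTp(1−p), with the diffusion coefficient D estimated
  from the data.
* **Migration routes** — a 500-point mean route per individual and
  direction that minimizes distance to nearest-neighbour locations on the
  yearly tracks; route variation is the square root of the mean
  nearest-neighbour variance along the route, in km.
* **Phenology and repeatability** — colony departure/arrival and winter
  arrival/departure dates per season; repeatability
  R = s²ₐ/(s²ₐ + s²ε) from a REML mixed model (distance fixed effect;
  colony and individual random intercepts), per-individual Rᵢ by
  substituting each bird's own residual variance, and parametric-bootstrap
  confidence intervals.
* **Inference** — one-sided randomization tests (10,000 label shuffles) of
  within- vs between-individual variation under a 250-km pairing
  constraint, OLS models of variation against migration distance, and a
  between-individual null-model correction for the spatial constraint on
  short-distance migrants.

A synthetic-track generator (`migvar.synthetic`) produces multi-year,
multi-colony populations with known ground truth — true sites, dates,
routes and variance components — so the entire pipeline is testable
without any field data.

## Worked example

```python
from migvar.pipeline import RunConfig, run_pipeline, simulate_command

cfg = RunConfig(out_dir="demo", seed=7,
                synthetic={"n_individuals": 8, "years_per_individual": (2, 2),
                           "migration_distance_range_km": (700, 1000),
                           "bearing_sector_deg": (203, 208)},
                n_permutations=500, n_bootstraps=10)
fixes, truth = simulate_command(cfg)
colonies = truth.individuals[["individual_id", "colony_id",
                              "colony_lon", "colony_lat"]].rename(
    columns={"colony_lon": "lon", "colony_lat": "lat"})
results = run_pipeline(cfg, fixes=fixes, colonies=colonies)
print(results["overlap_within"], results["overlap_between"])
print(results["randomization_p"])
```

prints (seed 7):

```
{'median': 0.9440651126492727, 'min': 0.9263827905472736, 'max': 0.9498719304272359, 'n': 8} {'median': 0.4629003449643631, 'min': 0.32203258906794496, 'max': 0.8640267791620118, 'n': 13}
{'overlap_ba': 0.001996007984031936, 'route_variation_autumn_km': 0.003992015968063872, 'route_variation_spring_km': 0.003992015968063872}
```

Read: each simulated bird overlaps with itself across years (median BA
0.944 of a possible 0.95) far more than with its distance-matched peers
(median 0.463 over 13 pairs), and the randomization tests reject
exchangeability of the within/between labels (p ≈ 0.002–0.004 at 500
permutations) — the synthetic
population behaves like a population of individually consistent migrants,
which is exactly what the generator encodes. The run directory also holds
per-season phenology (`season_records.csv`), repeatability with bootstrap
CIs (`repeatability.csv`), route variation (`route_variation.csv`), the
between-individual pair table and distance models, all as delimited text.

The same stages are scriptable from a shell:

```bash
migvar simulate --out demo --seed 7
migvar run --tracks demo/tracks.csv --colonies demo/colonies.csv --out demo
migvar all --out demo --seed 7         # both steps in one go
```

## Layout

| module | contents |
|---|---|
| `migvar.geo` | equal-area projection, great-circle helpers |
| `migvar.track_io` | reading, projecting, subsampling, season splitting, inclusion filters |
| `migvar.space_use` | kernel and biased-random-bridge UDs, isopleths, Bhattacharyya overlap |
| `migvar.seasons` | core areas, wintering-area assignment, phenology, migration distance |
| `migvar.routes` | migration legs, mean routes, route variation |
| `migvar.stats` | pairing, randomization tests, repeatability, distance models |
| `migvar.synthetic` | ground-truthed track generator |
| `migvar.pipeline`, `migvar.cli` | orchestration and the `migvar` command |

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
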