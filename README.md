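# vultrack

Movement-ecology pipeline for GPS-tagged juvenile Egyptian vultures
(*Neophron percnopterus*): from raw Movebank-dialect tracking tables to
life-stage timing, home ranges, apparent mortality and survival curves.

Juveniles tagged as nestlings in Iberian breeding nuclei pass through a
sequence of life stages — a **dependence period** around the natal nest,
a transit of Iberia, a Sahara crossing through the Strait of Gibraltar, a
one-to-two-year stay in the **Sahel**, and (for survivors) a spring
return — while a minority never migrate and live as year-round Iberian
residents alternating between two seasonal core areas. Because carcasses
are almost never recovered, mortality must be read off the transmitter
itself, and every death is an *apparent* death. This package implements
that full analysis chain for telemetry researchers, plus a
ground-truthed cohort simulator so the chain can be validated without
access-restricted tracking data.

## What it computes

- **QC and resampling** (`vultrack.io`): drop fixes with horizontal or
  vertical dilution of precision (HDOP/VDOP) above 5; standardise fix
  spacing to a 30-min grid by nearest-fix selection (never
  interpolation).
- **Stage segmentation** (`vultrack.segmentation`): displacement rules —
  nest departure at the first fix ≥ 200 m from the nest; natal departure
  at the last natal-territory fix followed by a long directed journey;
  a Strait-of-Gibraltar gate crossing; desert entry/Sahel arrival at the
  30°N and 22.5°N parallels; return onset from sustained northward
  displacement. Strategy is classified migrant / non-migrant /
  undetermined.
- **Home ranges** (`vultrack.homerange`): gridded Gaussian kernel
  utilization distributions on an equal-area plane; 95% isopleth areas
  (km²), pairwise percentage overlap, centroid distances, monthly KDEs
  and core-occupancy shares for residents.
- **Fate and survival** (`vultrack.survival`): transmitter-based fate
  rules (post-mortem stationarity with flat accelerometer activity;
  abrupt terminal silence with healthy battery; old-tag intermittency →
  censored alive), a stage × nucleus × sex apparent-mortality table with
  deaths/duration rates (truncated to two decimals, e.g. 5/28 → 0.17),
  the Kaplan–Meier product-limit estimator
  S(t) = Π<sub>t<sub>i</sub>≤t</sub>(1 − d<sub>i</sub>/n<sub>i</sub>),
  and the k-sample log-rank test.
- **Synthetic cohorts** (`vultrack.simulate`): stage-structured tracks
  (Ornstein–Uhlenbeck wandering + biased correlated random walks),
  per-stage daily hazards, and transmitter artifacts (DOP noise,
  missingness, mid-Sahel outages, post-death stationarity or silence,
  end-of-life intermittency) with a full ground-truth record per bird.
- **Orchestration** (`vultrack.pipeline`, `vultrack` CLI): one call runs
  QC → segmentation → home ranges → fate → survival and writes
  stages.csv, kde.csv + kde.geojson, overlaps.csv, fates.csv,
  mortality_table.csv, km_curves.csv, group_summary.csv and a
  sha256 manifest.

## Worked example

```python
import vultrack as vt

cfg = vt.SimulationConfig(seed=1)            # 32 juveniles, 3 nuclei
trajs, truth = vt.simulate_cohort(cfg)
result = vt.run_pipeline(vt.RunConfig(out_dir="results/demo"),
                         trajectories=trajs)

print({s: sum(1 for x in result.segmentations if x.strategy == s)
       for s in ("migrant", "non_migrant", "undetermined")})
cols = ["stage", "deaths_total", "duration_days", "mortality_rate"]
print(result.mortality_table[cols].to_string(index=False))
sahel = result.kde_table.query("stage == 'sahel_stay'")["area_km2"]
print(f"mean Sahel 95% KDE area: {sahel.mean():,.0f} km2 (n={len(sahel)})")
```

prints

```
{'migrant': 28, 'non_migrant': 3, 'undetermined': 1}
                        stage  deaths_total  duration_days  mortality_rate
                   Dependence             0      22.504557            0.00
                    Migration             5      45.292385            0.11
Stay in the Iberian Peninsula             1     190.668981            0.00
            Stay in the Sahel             9     502.891827            0.01
                        Total            15            NaN             NaN
mean Sahel 95% KDE area: 91,275 km2 (n=26)
```

Twenty-eight of the 32 simulated birds crossed to Africa, three stayed
resident, and one died too early to call. No bird died during
dependence; the per-day loss rate is an order of magnitude higher during
the short migration (0.11/day over ~45 days) than during the long Sahel
stay (0.01/day over ~500 days) — the characteristic pattern for this
system: most losses accumulate in the Sahel, but the riskiest days are
the migratory ones. Migrant Sahel ranges (~10⁵ km²) dwarf resident
ranges (~1.4×10⁴ km²).

The same steps are available from a shell:

```sh
vultrack simulate --seed 1 --out-dir data/
vultrack qc --in data/fixes.csv --deployments data/deployments.csv --out data/clean.csv
vultrack segment --in data/fixes.csv --deployments data/deployments.csv --out data/stages.csv
vultrack report --in data/fixes.csv --deployments data/deployments.csv --out-dir results/
```

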