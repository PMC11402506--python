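# Methods

This note documents the models and rules vultrack implements, the
parameter defaults and why they were chosen, what the synthetic-cohort
generator does and does not emulate, and the numerical choices that
affect results.

## Ingestion, QC and resampling

Tracking tables follow the Movebank column dialect. Rows with
unparseable or out-of-bounds coordinates/timestamps are dropped and
counted; duplicate (individual, timestamp) rows keep the first
occurrence, and fixes are sorted in time.

The QC rule removes fixes whose HDOP **or** VDOP exceeds 5 — strictly
greater, so a DOP of exactly 5 is kept. Fixes with *missing* DOP are
retained by default: several transmitter models report no DOP at all,
and the filter targets measured bad geometry, not absent metadata
(`--drop-missing-dop` switches to strict dropping).

Resampling standardises spacing to a 30-min grid anchored at the
individual's first retained fix. Each grid slot takes the nearest
original fix within half an interval; empty slots stay empty. Positions
are never interpolated — a fabricated position could cross the 200-m
nest-departure threshold or leak into a KDE — so every output timestamp
exists in the input, each input fix is used at most once, and QC +
resampling is idempotent. Transmission gaps are left as gaps; no
maximum-gap exclusion is applied.

## Geometry

All distances are great-circle on the mean-radius sphere
(R = 6371.0088 km); at continental scales the sub-0.5% departure from
ellipsoidal geodesics is immaterial and a single constant keeps path
lengths, thresholds and areas mutually consistent. Path length is the
sum over consecutive fixes (order-dependent by construction); daily
distance attributes each segment to the UTC day of its start fix, which
is deterministic and conserves the total across midnight. Home-range
work uses a spherical Lambert azimuthal equal-area projection about the
point cloud's geographic centroid; areas on the projected plane are true
spherical areas, and the inverse transform is sub-metre within the
scales used here.

## Stage segmentation

All boundaries are displacement rules evaluated on the QC-filtered,
resampled track, and every boundary snaps to an observed fix — no
sub-fix interpolation. Defaults, with rationale:

| parameter | default | rationale |
|---|---|---|
| nest departure | ≥ 200 m from nest (inclusive) | the field definition of leaving the nest |
| natal territory radius | 2 km | radius a dependent juvenile keeps returning inside |
| natal-departure confirmation | moves ≥ 50 km within 7 days | "stopped returning … long directed journeys" needs an operational form; drift does not qualify |
| Gibraltar gate | 36.0°N, lon −6.1…−5.2 | a lat/lon window covering the Strait avoids shipping coastline data |
| desert entry / Sahel arrival | 30.0°N / 22.5°N | 22.5°N is the observed upper bound of Sahel ranges; 30°N a conventional desert edge; both configurable |
| return onset | +100 km north over 3 days, confirmed by reaching 30°N | a directed latitudinal displacement, not a foray |

Natal departure is the *last* fix inside the natal radius never followed
by re-entry, confirmed by the displacement rule; the confirmation uses
the maximum displacement within the window (an endpoint can sit behind a
mean-reverting wander even after a genuine departure). If the track ends
before the window closes, the candidate is returned flagged
unconfirmed.

Return-onset detection needs three refinements beyond the window rule.
(1) Candidates are restricted to the 30 days before the final exit from
the Sahel band: a true departure connects to the band exit promptly,
whereas mid-winter northward forays inside the band can satisfy the
displacement rule months early. (2) The window rule necessarily fires
one–two days before the climb begins (the window already overlaps the
climb), so the reported instant is anchored to the onset of the
sustained northward run, found by walking back from the band exit while
the forward one-day gain stays above `return_net_km/return_window_days`.
(3) A directed climb cut short by transmitter loss — the bird at least
twice `return_net_km` north of its starting latitude at the final fix,
with no dip back — counts as a begun return; otherwise birds dying
mid-return would be attributed to the Sahel stay. A bird that reaches
North Africa and re-crosses the desert southward has still *started* a
return (the aborted-return phenotype).

Composition: migrants get dependence → iberia_premigration →
sahara_crossing (gate crossing to Sahel arrival) → sahel_stay
[→ return_migration [→ iberia_postreturn]]; confirmed residents get
dependence → residency. Undetermined birds' post-departure interval is
labelled iberia_premigration: their observed movement is a directed
departure, and an early death on such a track is a migration loss, not a
residency one. Strategy is migrant on any detected gate crossing,
non-migrant after ≥ 365 crossing-free days post-departure, otherwise
undetermined. Fixes before the tagging date are ignored.

## Home ranges

The utilization distribution is an isotropic Gaussian KDE evaluated on a
regular km grid (default 5-km cells): points are binned to cell centres
and smoothed with a separable Gaussian, which is equivalent to direct
kernel evaluation up to half-cell binning error and fast enough for
multi-year 30-min tracks. The default bandwidth is Silverman's 2-D
reference rule h = σ·n^(−1/6) on the projected coordinates, with σ the
root mean of the two marginal variances; a fixed km bandwidth can be
supplied instead. The grid extends 3 bandwidths beyond the data and the
density is renormalised to total mass exactly 1, so edge truncation
cannot violate mass conservation. The `level` isopleth is the smallest
set of cells whose mass reaches the level (the threshold cell is
included); its area is cells × cell², and the centroid is the
density-weighted mean of inside cells, inverse-projected to WGS84.

Overlap between two fitted ranges re-grids both onto one lattice centred
at the midpoint of their projection centres (bounding distortion
symmetrically), intersects the isopleth masks, and reports the symmetric
index — the mean of area(A∩B)/area(A) and area(A∩B)/area(B), × 100 —
alongside both directed values so any convention can be recovered.
Monthly KDEs for residents are independent fits per calendar month with
≥ 10 fixes (the union of monthly isopleths is *not* the pooled
isopleth), plus the monthly share of fixes inside user-supplied core
polygons.

## Fate, mortality rates, survival

Fate rules, in precedence order: (1) a tag older than 5 years whose
reception turns irregular (a gap above 3 days after that age) censors
the bird alive at its last regular fix; (2) a terminal run of fixes all
within 50 m spanning ≥ 3 days, with the run's median accelerometer
activity at most 10% of the pre-run median, is a death at the run's
start (without an activity channel the rule applies on positions alone
and is flagged lower-confidence); (3) terminal silence of ≥ 30 days
against the close of observation with a healthy last battery reading
(≥ 3.5 V) is assimilated to mortality at the last fix. Mid-track gaps
later bridged by the tag never count as death. These conflate true death
with unrecovered tag failure, so all downstream rates are *apparent*
mortality.

The stage-mortality table cross-tabulates deaths by reporting stage
(pre-migration Iberia, the desert crossing and the return all roll up to
"Migration") × nucleus × sex. A dead bird's segmentation is truncated at
its inferred death time first, so post-mortem transmitter activity is
not stage exposure. The stage duration is the mean total days spent in
the stage by the individuals that entered it, and the rate is
deaths/duration *truncated* (not rounded) to two decimals — the
convention that makes 5/28 report as 0.17.

Kaplan–Meier and the log-rank test are implemented in full (no
inferential dependencies): the product-limit estimator uses the standard
convention that individuals censored at a death time remain at risk for
it; the k-sample log-rank statistic uses the complete hypergeometric
variance–covariance of observed-minus-expected deaths with df = k − 1.
Both are verified against lifelines in the test suite; lifelines is
never on the computation path. The time axis is days since tagging.
Group comparisons beyond the log-rank test are deliberately
descriptive (mean ± SD, n, range per nucleus/sex/strategy): mixed-model
inference with year random effects is an off-the-shelf fit outside this
package's scope.

## The synthetic cohort generator

The generator emulates the study cohort — 32 nestlings (17/10/5 across
three nuclei, 16:16 sex ratio, exactly 3 residents, all from the largest
nucleus so the cohort marginal is 3/32) — with schematic geography: nest
points, a Gibraltar gate, latitude bands; no coastlines or landmasks.
Movement kernels are the simplest processes reproducing the stage
phenomenology:

- **Dependence**: Ornstein–Uhlenbeck wandering about the nest
  (reversion 0.2/day, scale 1.19 km/√day → ~10.3 km travelled per day at
  30-min sampling, stationary SD ≈ 1.9 km), with nightly roosting at the
  nest as dependent juveniles do; duration lognormal with mean 20 d,
  SD 12 d. The nightly roost is what makes "last fix near the nest" a
  sharp estimator of departure.
- **Migration legs**: biased correlated random walks whose heading mixes
  persistence (0.3) with the bearing to target plus von Mises noise
  (κ = 8). The Iberian leg draws its duration (lognormal, mean 15 d,
  SD 11.7 d, clipped 2–59 d) and sets speed accordingly; the desert leg
  runs at 76 km/day, which makes the pipeline-measured 30°N → 22.5°N
  span average ≈ 11 days. (The printed 11-day crossing corresponds to a
  much longer path; the simulator is calibrated so the *measured* span
  matches, since that is the quantity the pipeline reports.)
- **Sahel stay**: OU about a drawn destination (13.3–22.5°N band,
  reflecting boundaries), reversion 0.01/day, scale 16 km/√day →
  observed 95% KDE areas ≈ 10⁵ km². Returns start near Julian day
  100 ± 17 of the second year; the return leg runs at 110 km/day.
- **Residency**: a post-independence dispersal leg to the southern core,
  then seasonal alternation (south September–March, north April–August)
  between two OU cores ≈ 115 km apart with fast transits at season
  changes and a reflecting ±0.3° latitude bound per core; core SD
  ≈ 20 km gives ~1.4×10⁴ km² total ranges, an order below migrant
  ranges.
- **Hazards** (per-day): dependence 0 (no immediate post-fledging deaths
  were observed), migration 0.006 (≈ 5 deaths among 29 birds over ≈ 28
  exposure days), Sahel 0.0008, post-return 0.0003, residency 0.00005
  (the study's residents suffered no observed deaths).
- **Transmitter**: 5% missingness; 10% of fixes drawn with DOP above the
  QC threshold; 12 m positional jitter (3 m post-mortem); slow battery
  decay; on death, a coin flip between 30 days of stationary
  transmission and abrupt silence; a 10% chance of a 20–60-day mid-Sahel
  outage bridged before the return (so the fate rules must not read it
  as death); intermittent reception after a 5-year tag age.

One integer seed drives everything through per-individual substreams;
cohorts are byte-reproducible.

What the generator does **not** emulate: habitat, wind and thermal
soaring, conspecific attraction, Lévy-like movement, heterogeneous tag
schedules (5–30 min), Argos-quality error, or inter-annual variation in
phenology. Passing the recovery suites therefore shows the *rules are
implemented correctly and are robust to the modelled artifacts* — not
that the thresholds are optimal for real tracks, where the qualitative
definitions (natal departure above all) remain genuinely fuzzy.

## Problem sizes and numerical choices

The validation suites use a 110-bird cohort at 30-min fixes for
segmentation recovery and a 500-bird cohort at 120-min fixes for
hazard-rate recovery — the coarser interval for the large cohort is a
deliberate problem-size choice that leaves every detector's resolution
(1-day tolerances, 3-day windows) unchanged. KDE correctness is anchored
to the closed form for a smoothed Gaussian: the 95% region of
N(0, (σ²+h²)I) has area π·χ²₀.₉₅,₂·(σ²+h²), and the fitted area agrees
within 5% at n = 5000 (σ = 100 km, h = 20 km, 5-km cells; refinement to
2.5-km cells moves areas by < 3%). Ties in grid assignment resample to
the earlier fix; duplicate timestamps keep the first; empty inputs
return empty, flagged results rather than errors wherever the pipeline
can continue.

## Known limitations

- Apparent mortality conflates death with permanent tag failure; the
  rates carry that bias by construction, as the field method does.
- Stage boundaries for birds dying within ~2 days of a stage transition
  can be attributed to the neighbouring stage.
- A terminal silence shorter than 30 days at the close of observation is
  (correctly) not yet callable as death, so deaths in the last month of
  a study window are under-counted.
- The overlap index depends on the isopleth convention; both directed
  overlaps are reported so alternatives can be reconstructed.
- Natal-departure detection assumes the bird's nightly returns make the
  last in-radius fix a sharp anchor; for sparser schedules the detected
  instant can precede the true departure by up to the roost gap.
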