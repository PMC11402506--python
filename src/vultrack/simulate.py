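"""Stage-structured synthetic cohorts with known ground truth.

Generates Movebank-dialect tracking and deployment tables emulating a
cohort of GPS-tagged nestling vultures from three Iberian nuclei: a short
nestling phase at the nest, dependence-period wandering (mean-reverting
Ornstein–Uhlenbeck motion, ~10 km travelled per day at 30-min sampling),
a southward transit of Iberia through a Strait-of-Gibraltar gate (biased
correlated random walk), a Sahara crossing calibrated so the pipeline
measures ~11-day desert transits, a multi-month Sahel stay wandering over
~10⁵ km² within the 13.3°–22.5°N band, and a spring return in the second
year; a configurable minority never migrate and alternate seasonally
between two Iberian core areas (south September–March, north April–
August). Per-stage daily hazards kill birds; the transmitter layer then
thins fixes, adds DOP values (a configurable fraction above the QC
threshold), positional jitter, battery decay, mid-Sahel outages that are
later bridged, post-death stationarity or abrupt silence, and old-age
intermittency. Geography is schematic — nest points, a gate, latitude
bands — so no basemap data is required.

Every draw flows from one integer seed through per-individual
substreams, so a cohort is bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .io import Deployment, Trajectory, FIX_COLUMNS, write_movebank

KM_PER_DEG = 111.195


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _default_nuclei():
    return {"Arribes": 17, "Galicia": 10, "Segovia": 5}


def _default_nests():
    return {"Arribes": (-6.2, 41.2), "Galicia": (-7.6, 42.0), "Segovia": (-3.6, 41.3)}


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator (defaults emulate the study cohort)."""

    # cohort
    nucleus_counts: dict[str, int] = field(default_factory=_default_nuclei)
    nucleus_nests: dict[str, tuple[float, float]] = field(default_factory=_default_nests)
    sex_ratio_male: float = 0.5
    n_non_migrants: int = 3              # exactly this many residents ...
    resident_nucleus: str = "Arribes"    # ... all from this nucleus
    tag_year: int = 2021
    observed_days: float = 760.0
    fix_interval_min: float = 30.0

    # dependence period (OU about the nest; ~10.3 km/day at 30-min sampling;
    # nightly roosting at the nest, as dependent juveniles do)
    nestling_days_range: tuple[float, float] = (1.5, 4.0)
    dependence_mean_days: float = 20.0
    dependence_sd_days: float = 12.0
    dependence_reversion_per_day: float = 0.2
    dependence_scale_km: float = 1.19    # km/sqrt(day); stationary SD ≈ 1.9 km
    roost_radius_km: float = 0.03
    roost_hours: tuple[int, int] = (21, 5)   # UTC, wraps midnight

    # Iberian pre-migration transit
    premigration_mean_days: float = 15.0
    premigration_sd_days: float = 11.7
    gate_lon: float = -5.6
    gate_lat: float = 36.0
    crw_kappa: float = 8.0
    crw_persistence: float = 0.3

    # Sahara crossing (76 km/day ≈ 11-day 30°N→22.5°N spans)
    desert_speed_km_day: float = 76.0
    sahel_dest_lon_range: tuple[float, float] = (-14.0, -6.0)
    sahel_dest_lat_range: tuple[float, float] = (14.0, 17.0)

    # Sahel stay (OU; stationary SD ≈ 113 km → ~1e5 km² observed 95% ranges)
    sahel_reversion_per_day: float = 0.01
    sahel_scale_km: float = 16.0
    sahel_lat_band: tuple[float, float] = (13.3, 22.5)
    return_julian_mean: float = 100.0
    return_julian_sd: float = 17.0
    return_year_offset: int = 2
    return_speed_km_day: float = 110.0
    postreturn_reversion_per_day: float = 0.15
    postreturn_scale_km: float = 11.0

    # residency (two seasonal cores; SD ≈ 20 km each → ~1.5e4 km² total)
    resident_core_south: tuple[float, float] = (-6.0, 39.7)   # Caceres
    resident_core_north: tuple[float, float] = (-6.4, 40.6)   # Salamanca
    resident_south_months: tuple[int, ...] = (9, 10, 11, 12, 1, 2, 3)
    resident_reversion_per_day: float = 0.15
    resident_scale_km: float = 11.0
    resident_transit_speed_km_day: float = 100.0
    # reflecting latitude bound (deg) about each core / post-return centre;
    # keeps settled birds clear of the 2-km natal radius
    resident_lat_fold_deg: float = 0.3

    # per-stage daily hazards (apparent-mortality generators)
    hazard_dependence: float = 0.0
    hazard_migration: float = 0.006
    hazard_sahel: float = 0.0008
    hazard_postreturn: float = 0.0003
    # the study's residents suffered no observed deaths; keep a small but
    # non-zero background loss rate
    hazard_residency: float = 0.00005

    # transmitter artifacts
    missingness: float = 0.05
    dop_gt5_frac: float = 0.1            # fraction of fixes failing the DOP<=5 QC rule
    jitter_m: float = 12.0
    postdeath_jitter_m: float = 3.0
    postdeath_stationary_prob: float = 0.5
    postdeath_transmit_days: float = 30.0
    sahel_outage_prob: float = 0.1
    outage_days_range: tuple[float, float] = (20.0, 60.0)
    intermittency_age_years: float = 5.0
    intermittent_keep_prob: float = 0.03
    battery_start_v: float = 4.1
    battery_decay_v_per_day: float = 0.0002

    seed: int = 0

    def validate(self) -> None:
        for name in ("sex_ratio_male", "missingness", "dop_gt5_frac",
                     "postdeath_stationary_prob", "sahel_outage_prob",
                     "intermittent_keep_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        for name in ("observed_days", "fix_interval_min", "dependence_mean_days",
                     "desert_speed_km_day", "return_speed_km_day",
                     "dependence_scale_km", "sahel_scale_km"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("hazard_dependence", "hazard_migration", "hazard_sahel",
                     "hazard_postreturn", "hazard_residency"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sahel_lat_band[0] >= self.sahel_lat_band[1]:
            raise ValueError("sahel_lat_band must be ordered (south, north)")
        if self.resident_nucleus not in self.nucleus_counts:
            raise ValueError(f"resident_nucleus {self.resident_nucleus!r} not a nucleus")
        if self.n_non_migrants > self.nucleus_counts[self.resident_nucleus]:
            raise ValueError("n_non_migrants exceeds the resident nucleus count")


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated individual."""

    individual_id: str
    strategy: str                         # migrant | non_migrant
    nest_departure: pd.Timestamp | None = None
    natal_departure: pd.Timestamp | None = None
    gibraltar_crossing: pd.Timestamp | None = None
    desert_entry: pd.Timestamp | None = None
    sahel_arrival: pd.Timestamp | None = None
    return_start: pd.Timestamp | None = None
    iberia_return: pd.Timestamp | None = None
    death_time: pd.Timestamp | None = None
    death_stage: str | None = None        # dependence|migration|sahel_stay|postreturn|residency
    post_death_mode: str | None = None    # stationary | silent
    outage: tuple[pd.Timestamp, pd.Timestamp] | None = None
    intermittency_onset: pd.Timestamp | None = None

    def to_dict(self) -> dict:
        def iso(v):
            if v is None:
                return None
            if isinstance(v, tuple):
                return [iso(x) for x in v]
            if isinstance(v, pd.Timestamp):
                return v.isoformat()
            return v
        return {k: iso(v) for k, v in asdict(self).items()}


# ---------------------------------------------------------------------------
# movement kernels
# ---------------------------------------------------------------------------

def ou_step(x: float, y: float, cx: float, cy: float, reversion: float,
            scale: float, dt: float, rng: np.random.Generator):
    """One exact-discretisation Ornstein–Uhlenbeck step in plane km.

    Mean-reverting toward (cx, cy) with rate ``reversion`` (1/day) and
    noise intensity ``scale`` (km/√day); the stationary per-axis SD is
    scale/√(2·reversion). reversion = 0 degenerates to Brownian motion;
    scale = 0 to deterministic decay toward the centre.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = math.exp(-reversion * dt)
    if reversion > 0:
        sig = scale * math.sqrt((1.0 - a * a) / (2.0 * reversion))
    else:
        sig = scale * math.sqrt(dt)
    nx = cx + a * (x - cx) + (sig * rng.standard_normal() if sig > 0 else 0.0)
    ny = cy + a * (y - cy) + (sig * rng.standard_normal() if sig > 0 else 0.0)
    return nx, ny


def ou_path(n: int, x0: float, y0: float, cx: float, cy: float, reversion: float,
            scale: float, dt: float, rng: np.random.Generator):
    """Vectorised n-step OU path (same discretisation as :func:`ou_step`)."""
    a = math.exp(-reversion * dt)
    if reversion > 0:
        sig = scale * math.sqrt((1.0 - a * a) / (2.0 * reversion))
    else:
        sig = scale * math.sqrt(dt)
    w = rng.normal(0.0, sig, size=(n, 2)) if sig > 0 else np.zeros((n, 2))
    decay = a ** np.arange(1, n + 1)
    x = cx + (x0 - cx) * decay + lfilter([1.0], [1.0, -a], w[:, 0])
    y = cy + (y0 - cy) * decay + lfilter([1.0], [1.0, -a], w[:, 1])
    return x, y


def _mix_heading(prev: float, bearing: float, kappa: float, persistence: float,
                 rng: np.random.Generator | None) -> float:
    """Heading update of the biased correlated walk: the mean direction is
    the vector mixture of the previous heading (weight = persistence) and
    the bearing to target, with von Mises noise of the given concentration."""
    vx = persistence * math.cos(prev) + (1.0 - persistence) * math.cos(bearing)
    vy = persistence * math.sin(prev) + (1.0 - persistence) * math.sin(bearing)
    mu = math.atan2(vy, vx)
    if rng is None or kappa >= 1e6:
        return mu
    return float(rng.vonmises(mu, kappa))


def biased_crw_step(x: float, y: float, heading: float, tx: float, ty: float,
                    speed: float, kappa: float, dt: float,
                    rng: np.random.Generator | None,
                    persistence: float = 0.3):
    """One biased correlated-random-walk step in plane km.

    Returns ``((x, y), heading)``. speed is km/day; concentration → ∞ (or
    rng None) removes the angular noise; persistence 0 heads straight at
    the target; speed 0 is stationary.
    """
    if speed < 0:
        raise ValueError("speed must be non-negative")
    bearing = math.atan2(ty - y, tx - x)
    h = _mix_heading(heading, bearing, kappa, persistence, rng)
    s = speed * dt
    return (x + s * math.cos(h), y + s * math.sin(h)), h


def _crw_lonlat(lon0, lat0, heading, target, speed, kappa, persistence, dt, rng,
                max_steps, stop):
    """Run a biased CRW in lon/lat (local-scale km steps) until ``stop(lon,
    lat)`` or max_steps; returns (lons, lats, final_heading)."""
    lons, lats = [], []
    lon, lat, h = float(lon0), float(lat0), float(heading)
    for _ in range(max_steps):
        de = (target[0] - lon) * KM_PER_DEG * math.cos(math.radians(lat))
        dn = (target[1] - lat) * KM_PER_DEG
        bearing = math.atan2(dn, de)
        h = _mix_heading(h, bearing, kappa, persistence, rng)
        s = speed * dt
        lat += s * math.sin(h) / KM_PER_DEG
        lon += s * math.cos(h) / (KM_PER_DEG * math.cos(math.radians(lat)))
        lons.append(lon)
        lats.append(lat)
        if stop(lon, lat):
            break
    return np.asarray(lons), np.asarray(lats), h


def _offsets_to_lonlat(center, x_km, y_km):
    lon0, lat0 = center
    lat = lat0 + np.asarray(y_km) / KM_PER_DEG
    lon = lon0 + np.asarray(x_km) / (KM_PER_DEG * math.cos(math.radians(lat0)))
    return lon, lat


def _fold(v, lo, hi):
    """Reflect values into [lo, hi] (triangular fold)."""
    span = hi - lo
    w = np.mod(np.asarray(v) - lo, 2.0 * span)
    return lo + np.where(w <= span, w, 2.0 * span - w)


def _lognormal(rng, mean, sd, lo, hi):
    s2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - s2 / 2.0
    return float(np.clip(rng.lognormal(mu, math.sqrt(s2)), lo, hi))


def _planar_dist_km(lon1, lat1, lon2, lat2):
    de = (lon2 - lon1) * KM_PER_DEG * math.cos(math.radians(0.5 * (lat1 + lat2)))
    dn = (lat2 - lat1) * KM_PER_DEG
    return math.hypot(de, dn)


# ---------------------------------------------------------------------------
# per-individual simulation
# ---------------------------------------------------------------------------

@dataclass
class _IdealPath:
    times: np.ndarray          # datetime64[s] grid
    lon: np.ndarray
    lat: np.ndarray
    valid: np.ndarray          # transmitting (alive or post-death stationary)
    dead: np.ndarray           # post-death stationary portion
    truth: SyntheticTruth


def _simulate_individual(dep: Deployment, strategy: str, cfg: SimulationConfig,
                         rng: np.random.Generator) -> _IdealPath:
    dt = cfg.fix_interval_min / 1440.0
    n = int(round(cfg.observed_days / dt))
    step = np.timedelta64(int(round(cfg.fix_interval_min * 60)), "s")
    t0 = np.datetime64(dep.tagging_date, "s") + np.timedelta64(12 * 3600, "s")
    times = t0 + step * np.arange(n)
    lon = np.full(n, np.nan)
    lat = np.full(n, np.nan)
    truth = SyntheticTruth(dep.individual_id, strategy)
    nest = (dep.nest_lon, dep.nest_lat)

    # nestling phase: within ~20 m of the nest
    i = min(int(round(rng.uniform(*cfg.nestling_days_range) / dt)), n)
    offs = rng.normal(0.0, 0.02, size=(i, 2))
    lon[:i], lat[:i] = _offsets_to_lonlat(nest, offs[:, 0], offs[:, 1])

    # dependence: OU about the nest
    dur = _lognormal(rng, cfg.dependence_mean_days, cfg.dependence_sd_days, 5.0, 70.0)
    n_dep = min(int(round(dur / dt)), n - i)
    if n_dep > 0:
        x, y = ou_path(n_dep, 0.0, 0.0, 0.0, 0.0, cfg.dependence_reversion_per_day,
                       cfg.dependence_scale_km, dt, rng)
        # nightly roost at the nest: dependent juveniles return to sleep
        hours = pd.DatetimeIndex(times[i:i + n_dep]).hour.to_numpy()
        h0, h1 = cfg.roost_hours
        night = (hours >= h0) | (hours < h1) if h0 > h1 else (h0 <= hours) & (hours < h1)
        roost = rng.normal(0.0, cfg.roost_radius_km, size=(n_dep, 2))
        x = np.where(night, roost[:, 0], x)
        y = np.where(night, roost[:, 1], y)
        lon[i:i + n_dep], lat[i:i + n_dep] = _offsets_to_lonlat(nest, x, y)
        i += n_dep
    if i < n:
        truth.natal_departure = pd.Timestamp(times[i])

    heading = -math.pi / 2.0   # due south
    if strategy == "migrant" and i < n:
        # Iberia transit toward the Gibraltar gate
        gate = (cfg.gate_lon + rng.uniform(-0.15, 0.15), cfg.gate_lat)
        d_gate = _planar_dist_km(lon[i - 1], lat[i - 1], gate[0], gate[1])
        dur_pre = _lognormal(rng, cfg.premigration_mean_days, cfg.premigration_sd_days,
                             2.0, 59.0)
        speed = max(d_gate / dur_pre, 40.0)
        ls, bs, heading = _crw_lonlat(lon[i - 1], lat[i - 1], heading, gate, speed,
                                      cfg.crw_kappa, cfg.crw_persistence, dt, rng,
                                      n - i, lambda lo_, la_: la_ <= cfg.gate_lat)
        m = ls.size
        lon[i:i + m], lat[i:i + m] = ls, bs
        i += m
        if i < n or (m and bs[-1] <= cfg.gate_lat):
            truth.gibraltar_crossing = pd.Timestamp(times[i - 1])

        # Sahara crossing toward a Sahel destination
        if truth.gibraltar_crossing is not None and i < n:
            dest = (rng.uniform(*cfg.sahel_dest_lon_range),
                    rng.uniform(*cfg.sahel_dest_lat_range))
            ls, bs, heading = _crw_lonlat(
                lon[i - 1], lat[i - 1], heading, dest, cfg.desert_speed_km_day,
                cfg.crw_kappa, cfg.crw_persistence, dt, rng, n - i,
                lambda lo_, la_: _planar_dist_km(lo_, la_, dest[0], dest[1]) < 30.0)
            m = ls.size
            lon[i:i + m], lat[i:i + m] = ls, bs
            i += m

            # Sahel stay: OU about the destination until the return date
            if i < n:
                jday = rng.normal(cfg.return_julian_mean, cfg.return_julian_sd)
                t_ret = (np.datetime64(f"{cfg.tag_year + cfg.return_year_offset}-01-01", "s")
                         + np.timedelta64(int(round((jday - 1) * 86400)), "s"))
                i_ret = int(np.searchsorted(times, max(t_ret, times[i])))
                n_sah = min(i_ret, n) - i
                if n_sah > 0:
                    x, y = ou_path(n_sah, 0.0, 0.0, 0.0, 0.0,
                                   cfg.sahel_reversion_per_day, cfg.sahel_scale_km,
                                   dt, rng)
                    slon, slat = _offsets_to_lonlat(dest, x, y)
                    slat = _fold(slat, cfg.sahel_lat_band[0] + 0.1,
                                 cfg.sahel_lat_band[1] - 0.3)
                    lon[i:i + n_sah], lat[i:i + n_sah] = slon, slat
                    i += n_sah
                # northward return through the gate, then home
                if i < n and i_ret < n:
                    truth.return_start = pd.Timestamp(times[i])
                    gate2 = (cfg.gate_lon + rng.uniform(-0.15, 0.15), cfg.gate_lat)
                    ls, bs, heading = _crw_lonlat(
                        lon[i - 1], lat[i - 1], math.pi / 2.0, gate2,
                        cfg.return_speed_km_day, cfg.crw_kappa, cfg.crw_persistence,
                        dt, rng, n - i, lambda lo_, la_: la_ >= cfg.gate_lat)
                    m = ls.size
                    lon[i:i + m], lat[i:i + m] = ls, bs
                    i += m
                    # settle 45-90 km south of the natal territory
                    home = (nest[0] + rng.uniform(-0.4, 0.4),
                            nest[1] + rng.uniform(-0.8, -0.4))
                    ls, bs, heading = _crw_lonlat(
                        lon[i - 1], lat[i - 1], heading, home, 150.0,
                        cfg.crw_kappa, cfg.crw_persistence, dt, rng, n - i,
                        lambda lo_, la_: _planar_dist_km(lo_, la_, home[0], home[1]) < 30.0)
                    m = ls.size
                    lon[i:i + m], lat[i:i + m] = ls, bs
                    i += m
                    if i < n:
                        x, y = ou_path(n - i, 0.0, 0.0, 0.0, 0.0,
                                       cfg.postreturn_reversion_per_day,
                                       cfg.postreturn_scale_km, dt, rng)
                        plon, plat = _offsets_to_lonlat(home, x, y)
                        plat = _fold(plat, home[1] - cfg.resident_lat_fold_deg,
                                     home[1] + cfg.resident_lat_fold_deg)
                        lon[i:], lat[i:] = plon, plat
                        i = n
    elif strategy == "non_migrant" and i < n:
        i = _residency(cfg, rng, times, lon, lat, i, n, dt)

    lon, lat = lon[:i], lat[:i]
    times_used = times[:i]

    # --- post-hoc truth from the ideal path (same rules the pipeline uses)
    d_nest_km = np.hypot((lon - nest[0]) * KM_PER_DEG * math.cos(math.radians(nest[1])),
                         (lat - nest[1]) * KM_PER_DEG)
    idx = np.flatnonzero(d_nest_km >= 0.2)
    if idx.size:
        truth.nest_departure = pd.Timestamp(times_used[idx[0]])
    if truth.gibraltar_crossing is not None:
        after = times_used >= np.datetime64(truth.gibraltar_crossing)
        la = lat[after]
        ta = times_used[after]
        arr = np.flatnonzero(la <= cfg.sahel_lat_band[1])
        if arr.size:
            j = int(arr[0])
            truth.sahel_arrival = pd.Timestamp(ta[j])
            ent = np.flatnonzero(la[:j] >= 30.0)
            if ent.size:
                truth.desert_entry = pd.Timestamp(ta[int(ent[-1])])
    if truth.return_start is not None:
        after = times_used > np.datetime64(truth.return_start)
        back = np.flatnonzero(after & (lat >= cfg.gate_lat))
        if back.size:
            truth.iberia_return = pd.Timestamp(times_used[int(back[0])])

    # --- mortality draw over the truth stage schedule
    _draw_death(cfg, rng, truth, pd.Timestamp(times_used[0]),
                pd.Timestamp(times_used[-1]))
    if truth.death_time is not None:
        # boundaries the bird did not live to reach never happened
        for name in ("nest_departure", "natal_departure", "gibraltar_crossing",
                     "desert_entry", "sahel_arrival", "return_start",
                     "iberia_return"):
            v = getattr(truth, name)
            if v is not None and v > truth.death_time:
                setattr(truth, name, None)

    valid = np.ones(lon.size, dtype=bool)
    dead = np.zeros(lon.size, dtype=bool)
    if truth.death_time is not None:
        t_d = np.datetime64(truth.death_time)
        after = times_used >= t_d
        truth.post_death_mode = ("stationary"
                                 if rng.random() < cfg.postdeath_stationary_prob
                                 else "silent")
        valid[after] = False
        if truth.post_death_mode == "stationary":
            idx_d = int(np.searchsorted(times_used, t_d))
            end = t_d + np.timedelta64(int(cfg.postdeath_transmit_days * 86400), "s")
            window = after & (times_used < end)
            k = int(window.sum())
            if idx_d > 0 and k > 0:
                jit = rng.normal(0.0, 0.003, size=(k, 2))
                dlon, dlat = _offsets_to_lonlat((lon[idx_d - 1], lat[idx_d - 1]),
                                                jit[:, 0], jit[:, 1])
                lon[window], lat[window] = dlon, dlat
                valid[window] = True
                dead[window] = True

    return _IdealPath(times_used, lon, lat, valid, dead, truth)


def _residency(cfg, rng, times, lon, lat, i, n, dt):
    """Fill the residency phase: a post-independence dispersal leg to the
    southern (autumn) core, then seasonal alternation between the two core
    areas with fast transit legs at season changes."""
    months = pd.DatetimeIndex(times).month.to_numpy()
    south = np.isin(months, cfg.resident_south_months)
    cur = (lon[i - 1], lat[i - 1])
    # dispersal: a long directed journey away from the natal territory
    target = (cfg.resident_core_south[0] + rng.uniform(-0.2, 0.2),
              cfg.resident_core_south[1] + rng.uniform(-0.2, 0.2))
    ls, bs, _ = _crw_lonlat(
        cur[0], cur[1], -math.pi / 2.0, target, 60.0, cfg.crw_kappa,
        cfg.crw_persistence, dt, rng, n - i,
        lambda lo_, la_: _planar_dist_km(lo_, la_, target[0], target[1]) < 25.0)
    m = ls.size
    lon[i:i + m], lat[i:i + m] = ls, bs
    i += m
    if m:
        cur = (ls[-1], bs[-1])
    while i < n:
        want_south = south[i]
        core = cfg.resident_core_south if want_south else cfg.resident_core_north
        # end of this seasonal block
        j = i
        while j < n and south[j] == want_south:
            j += 1
        # transit leg toward the active core
        if _planar_dist_km(cur[0], cur[1], core[0], core[1]) > 25.0:
            ls, bs, _ = _crw_lonlat(
                cur[0], cur[1], 0.0, core, cfg.resident_transit_speed_km_day,
                cfg.crw_kappa, cfg.crw_persistence, dt, rng, j - i,
                lambda lo_, la_: _planar_dist_km(lo_, la_, core[0], core[1]) < 20.0)
            m = ls.size
            lon[i:i + m], lat[i:i + m] = ls, bs
            i += m
            if m:
                cur = (ls[-1], bs[-1])
        if i < j:
            x0 = (cur[0] - core[0]) * KM_PER_DEG * math.cos(math.radians(core[1]))
            y0 = (cur[1] - core[1]) * KM_PER_DEG
            x, y = ou_path(j - i, x0, y0, 0.0, 0.0, cfg.resident_reversion_per_day,
                           cfg.resident_scale_km, dt, rng)
            rlon, rlat = _offsets_to_lonlat(core, x, y)
            rlat = _fold(rlat, core[1] - cfg.resident_lat_fold_deg,
                         core[1] + cfg.resident_lat_fold_deg)
            lon[i:j], lat[i:j] = rlon, rlat
            cur = (rlon[-1], rlat[-1])
            i = j
    return i


def _draw_death(cfg, rng, truth: SyntheticTruth, t_start, t_end) -> None:
    """Walk the truth stage schedule in order, drawing an exponential death
    time against each stage's daily hazard."""
    spans = []
    nd = truth.natal_departure or t_end
    spans.append((t_start, nd, "dependence", cfg.hazard_dependence))
    if truth.strategy == "migrant":
        sa = truth.sahel_arrival
        rs = truth.return_start
        ir = truth.iberia_return
        spans.append((nd, sa or t_end, "migration", cfg.hazard_migration))
        if sa is not None:
            spans.append((sa, rs or t_end, "sahel_stay", cfg.hazard_sahel))
        if rs is not None:
            spans.append((rs, ir or t_end, "migration", cfg.hazard_migration))
        if ir is not None:
            spans.append((ir, t_end, "postreturn", cfg.hazard_postreturn))
    else:
        spans.append((nd, t_end, "residency", cfg.hazard_residency))

    for start, end, label, h in spans:
        span_days = (end - start).total_seconds() / 86400.0
        if span_days <= 0:
            continue
        if h > 0:
            t_d = rng.exponential(1.0 / h)
            if t_d < span_days:
                truth.death_time = start + pd.Timedelta(days=t_d)
                truth.death_stage = label
                return


# ---------------------------------------------------------------------------
# transmitter layer
# ---------------------------------------------------------------------------

def apply_transmitter(ideal: _IdealPath, cfg: SimulationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Turn an ideal path into observed fixes: missingness, DOP draws,
    positional jitter, battery decay, activity channel, optional mid-Sahel
    outage (bridged later) and old-age intermittency. Annotates the truth
    record with the artifacts it injected."""
    n = ideal.times.size
    truth = ideal.truth
    keep = ideal.valid & (rng.random(n) >= cfg.missingness)
    if n:
        keep[0] = ideal.valid[0]   # the tagging fix always transmits

    # mid-Sahel outage on a live bird, bridged before the stay ends
    if (truth.strategy == "migrant" and truth.sahel_arrival is not None
            and truth.death_time is None and truth.return_start is not None
            and rng.random() < cfg.sahel_outage_prob):
        stay_days = (truth.return_start - truth.sahel_arrival).total_seconds() / 86400.0
        length = rng.uniform(*cfg.outage_days_range)
        if stay_days > length + 90.0:
            off = rng.uniform(0.2, 0.5) * stay_days
            o_start = truth.sahel_arrival + pd.Timedelta(days=off)
            o_end = o_start + pd.Timedelta(days=length)
            window = (ideal.times >= np.datetime64(o_start)) & (ideal.times < np.datetime64(o_end))
            keep[window] = False
            truth.outage = (o_start, o_end)

    # old-age intermittency
    onset64 = (np.datetime64(ideal.times[0], "s")
               + np.timedelta64(int(cfg.intermittency_age_years * 365.25 * 86400), "s"))
    late = ideal.times > onset64
    if late.any():
        keep[late] &= rng.random(n)[late] < cfg.intermittent_keep_prob
        truth.intermittency_onset = pd.Timestamp(onset64)

    idx = np.flatnonzero(keep)
    m = idx.size
    dead = ideal.dead[idx]
    sigma_km = np.where(dead, cfg.postdeath_jitter_m, cfg.jitter_m) / 1000.0
    jit = rng.normal(0.0, 1.0, size=(m, 2)) * sigma_km[:, None]
    lat_obs = ideal.lat[idx] + jit[:, 1] / KM_PER_DEG
    lon_obs = ideal.lon[idx] + jit[:, 0] / (KM_PER_DEG * np.cos(np.radians(ideal.lat[idx])))

    bad = rng.random(m) < cfg.dop_gt5_frac       # fails the DOP<=5 QC rule
    hdop = np.where(bad, rng.uniform(5.1, 12.0, m), rng.uniform(0.6, 4.8, m))
    vdop = np.where(bad, rng.uniform(2.0, 12.0, m), rng.uniform(0.6, 4.8, m))

    age_days = (ideal.times[idx] - ideal.times[0]) / np.timedelta64(1, "D")
    battery = (cfg.battery_start_v - cfg.battery_decay_v_per_day * age_days
               + rng.normal(0.0, 0.01, m)).clip(3.7, None)
    activity = np.where(dead, np.abs(rng.normal(0.0, 0.002, m)),
                        np.abs(rng.normal(1.0, 0.3, m)))

    return pd.DataFrame({
        "timestamp": pd.DatetimeIndex(ideal.times[idx]).astype("datetime64[ns]"),
        "lon": np.round(lon_obs, 6), "lat": np.round(lat_obs, 6),
        "hdop": np.round(hdop, 2), "vdop": np.round(vdop, 2),
        "battery_v": np.round(battery, 3), "activity": np.round(activity, 4),
    })[FIX_COLUMNS]


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig | None = None):
    """Simulate a full cohort.

    Returns ``(trajectories, truths)`` — one :class:`Trajectory` per
    deployment (ingestion-ready) and a dict of :class:`SyntheticTruth`
    keyed by individual id. Fully reproducible from ``config.seed``.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    n_total = sum(cfg.nucleus_counts.values())
    children = ss.spawn(n_total + 1)
    rng0 = np.random.default_rng(children[0])

    # deployments: ids ordered by nucleus; sexes exactly at the configured ratio
    nuclei = []
    for nucleus, count in cfg.nucleus_counts.items():
        nuclei.extend([nucleus] * count)
    n_m = int(round(n_total * cfg.sex_ratio_male))
    sexes = np.array(["M"] * n_m + ["F"] * (n_total - n_m))
    rng0.shuffle(sexes)
    resident_idx = set()
    if cfg.n_non_migrants > 0:
        pool = [k for k, nuc in enumerate(nuclei) if nuc == cfg.resident_nucleus]
        resident_idx = set(rng0.choice(pool, size=cfg.n_non_migrants, replace=False))

    trajectories: list[Trajectory] = []
    truths: dict[str, SyntheticTruth] = {}
    width = max(2, len(str(n_total)))
    for k in range(n_total):
        rng = np.random.default_rng(children[k + 1])
        nucleus = nuclei[k]
        clon, clat = cfg.nucleus_nests[nucleus]
        dep = Deployment(
            individual_id=f"EV{k + 1:0{width}d}",
            sex=str(sexes[k]),
            nucleus=nucleus,
            nest_lon=round(clon + rng.uniform(-0.15, 0.15), 5),
            nest_lat=round(clat + rng.uniform(-0.15, 0.15), 5),
            tagging_date=pd.Timestamp(cfg.tag_year, 7, 10) + pd.Timedelta(days=int(rng.integers(-5, 6))),
            transmitter_model="OrniTrack-30" if rng.random() < 0.8 else "E-Obs-48",
        )
        strategy = "non_migrant" if k in resident_idx else "migrant"
        ideal = _simulate_individual(dep, strategy, cfg, rng)
        fixes = apply_transmitter(ideal, cfg, rng)
        trajectories.append(Trajectory(dep, fixes))
        truths[dep.individual_id] = ideal.truth
    return trajectories, truths


def write_cohort(trajectories, truths, out_dir: str | Path):
    """Emit fixes.csv, deployments.csv and truth.json (byte-reproducible)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_movebank(trajectories, out / "fixes.csv", out / "deployments.csv")
    payload = {k: v.to_dict() for k, v in sorted(truths.items())}
    (out / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    return out / "fixes.csv", out / "deployments.csv", out / "truth.json"
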