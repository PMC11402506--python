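"""Fate classification from transmitter behaviour, stage mortality, survival.

Without carcass recovery, death must be read off the tag: a transmitter
that keeps emitting from one spot with flat accelerometer activity marks a
dead bird; a tag that falls abruptly silent while battery and reception
were healthy is assimilated to mortality; an old tag (>5 years) that
merely turns intermittent censors the bird alive at its last regular fix.
These are *apparent* mortality rules — true death and unrecovered tag
failure are confounded, and every downstream rate inherits that caveat.

The survival machinery (product-limit estimator, k-group log-rank test)
is implemented here in full so the pipeline has no inferential
dependencies; standard survival packages serve only as cross-checks in
the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .geometry import haversine_km
from .io import Deployment, Trajectory
from .segmentation import STAGE_ROLLUP, StageSegmentation

logger = logging.getLogger(__name__)

DEATH_STATUSES = ("presumed_dead_stationary", "presumed_dead_signal_loss")


@dataclass(frozen=True)
class FateParams:
    stationary_radius_m: float = 50.0
    stationary_min_days: float = 3.0
    # "accelerometers stabilized": terminal-run median activity at most this
    # fraction of the median while the bird was demonstrably moving
    activity_flat_ratio: float = 0.1
    intermittency_age_years: float = 5.0
    intermittent_gap_days: float = 3.0     # a gap this long after old age marks intermittency
    gap_death_days: float = 30.0
    battery_healthy_v: float = 3.5

    def __post_init__(self) -> None:
        for name in ("stationary_radius_m", "stationary_min_days",
                     "intermittency_age_years", "gap_death_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FateRecord:
    individual_id: str
    status: str                       # alive_transmitting | presumed_dead_stationary |
                                      # presumed_dead_signal_loss | censored_alive
    event_time: pd.Timestamp
    age_days_at_event: float
    stage_at_event: str | None = None
    low_confidence: bool = False      # stationary rule applied without activity channel

    @property
    def is_death(self) -> bool:
        return self.status in DEATH_STATUSES


def infer_fate(traj: Trajectory, params: FateParams = FateParams(),
               study_end: pd.Timestamp | None = None) -> FateRecord:
    """Classify an individual's fate from its transmitter record.

    ``study_end`` is the close of observation (e.g. the cohort's download
    date); terminal silence is measured against it. Precedence: old-age
    intermittency (censoring) is checked first, then post-mortem
    stationarity, then abrupt terminal silence. Mid-track gaps that the
    tag later bridges never count as death.
    """
    f = traj.fixes
    dep = traj.deployment
    if len(f) == 0:
        raise ValueError(f"{dep.individual_id}: cannot infer fate from an empty track")
    ts = f["timestamp"].to_numpy()
    t_tag = np.datetime64(dep.tagging_date) if dep.tagging_date is not None else ts[0]

    def age_days(t) -> float:
        return float((np.datetime64(t) - t_tag) / np.timedelta64(1, "s")) / 86400.0

    # --- old-age intermittency -> censored alive at last regular fix
    t_old = t_tag + np.timedelta64(int(params.intermittency_age_years * 365.25 * 86400), "s")
    if ts[-1] > t_old and len(f) >= 2:
        gaps = np.diff(ts) / np.timedelta64(1, "D")
        late = np.flatnonzero((ts[1:] > t_old) & (gaps > params.intermittent_gap_days))
        if late.size:
            i = int(late[0])   # fix *before* the first long late gap
            t_ev = pd.Timestamp(ts[i])
            return FateRecord(dep.individual_id, "censored_alive", t_ev, age_days(t_ev))

    # --- post-mortem stationarity: terminal run within radius, activity flat
    lon = f["lon"].to_numpy(dtype=float)
    lat = f["lat"].to_numpy(dtype=float)
    d_to_last_m = haversine_km(lon, lat, lon[-1], lat[-1]) * 1000.0
    outside = np.flatnonzero(d_to_last_m > params.stationary_radius_m)
    run_start = int(outside[-1]) + 1 if outside.size else 0
    run_days = (ts[-1] - ts[run_start]) / np.timedelta64(1, "D")
    if run_days >= params.stationary_min_days and run_start > 0:
        activity = f["activity"].to_numpy(dtype=float)
        pre = activity[:run_start]
        pre = pre[np.isfinite(pre)]
        run_act = activity[run_start:]
        run_act = run_act[np.isfinite(run_act)]
        have_activity = pre.size > 0 and run_act.size > 0
        if have_activity:
            flat = float(np.median(run_act)) <= params.activity_flat_ratio \
                * max(float(np.median(pre)), 1e-12)
        else:
            flat = True
        if flat:
            t_ev = pd.Timestamp(ts[run_start])
            return FateRecord(dep.individual_id, "presumed_dead_stationary", t_ev,
                              age_days(t_ev), low_confidence=not have_activity)

    # --- abrupt terminal silence with healthy battery -> assimilated to death
    if study_end is not None:
        silent_days = (np.datetime64(study_end) - ts[-1]) / np.timedelta64(1, "D")
        if silent_days >= params.gap_death_days:
            battery = f["battery_v"].to_numpy(dtype=float)
            finite_b = battery[np.isfinite(battery)]
            healthy = finite_b.size == 0 or finite_b[-1] >= params.battery_healthy_v
            if healthy:
                t_ev = pd.Timestamp(ts[-1])
                return FateRecord(dep.individual_id, "presumed_dead_signal_loss",
                                  t_ev, age_days(t_ev))

    t_ev = pd.Timestamp(ts[-1])
    return FateRecord(dep.individual_id, "alive_transmitting", t_ev, age_days(t_ev))


def assign_loss_stage(fate: FateRecord, seg: StageSegmentation) -> str:
    """Reporting stage containing the fate's event time (pre-migration
    Iberia, the desert crossing and the return all roll up to
    "Migration"); "unsegmented" with a warning if no interval contains it."""
    stage = seg.stage_at(fate.event_time)
    if stage is None:
        logger.warning("%s: event time %s outside all segmented intervals",
                       fate.individual_id, fate.event_time)
        fate.stage_at_event = "unsegmented"
        return "unsegmented"
    rolled = STAGE_ROLLUP[stage]
    fate.stage_at_event = rolled
    return rolled


def mortality_rate(deaths: float, duration_days: float) -> float:
    """Apparent mortality rate deaths/duration, truncated (not rounded) to
    two decimals for reporting — e.g. 5 deaths over 28 days → 0.17."""
    if duration_days <= 0:
        raise ValueError("duration must be positive")
    return math.floor((deaths / duration_days) * 100.0) / 100.0


REPORT_STAGES = ["Dependence", "Migration", "Stay in the Iberian Peninsula",
                 "Stay in the Sahel"]


def stage_mortality_table(fates: list[FateRecord], segs: list[StageSegmentation],
                          deployments: list[Deployment]) -> pd.DataFrame:
    """Deaths by stage × nucleus × sex with per-stage apparent mortality rates.

    Duration per reporting stage is the mean of the total days individuals
    that entered the stage spent in it; the rate is deaths/duration under
    the two-decimal truncation convention. A stage nobody entered is
    omitted (with a log note). A final row carries per-nucleus
    "lost/tagged (pct)" totals.
    """
    seg_by_id = {s.individual_id: s for s in segs}
    dep_by_id = {d.individual_id: d for d in deployments}
    nuclei = sorted({d.nucleus for d in deployments})

    durations: dict[str, list[float]] = {s: [] for s in REPORT_STAGES}
    for seg in segs:
        per: dict[str, float] = {}
        for iv in seg.intervals:
            rolled = STAGE_ROLLUP[iv.stage]
            per[rolled] = per.get(rolled, 0.0) + iv.duration_days
        for stage, days in per.items():
            durations[stage].append(days)

    deaths: dict[str, dict[tuple[str, str], int]] = {s: {} for s in REPORT_STAGES + ["unsegmented"]}
    lost_by_nucleus: dict[str, int] = {n: 0 for n in nuclei}
    for fate in fates:
        dep = dep_by_id[fate.individual_id]
        if not fate.is_death:
            continue
        lost_by_nucleus[dep.nucleus] += 1
        stage = fate.stage_at_event or assign_loss_stage(fate, seg_by_id[fate.individual_id])
        cell = (dep.nucleus, dep.sex)
        deaths.setdefault(stage, {})[cell] = deaths.setdefault(stage, {}).get(cell, 0) + 1

    rows = []
    for stage in REPORT_STAGES:
        entrants = durations[stage]
        if not entrants:
            logger.info("stage %r never entered by any individual; row omitted", stage)
            continue
        row: dict[str, object] = {"stage": stage}
        total = 0
        for nucleus in nuclei:
            for sex in ("M", "F"):
                n = deaths[stage].get((nucleus, sex), 0)
                row[f"{nucleus}_{sex}"] = n
                total += n
        total += sum(v for (nuc, sex), v in deaths[stage].items() if sex not in ("M", "F"))
        dur = float(np.mean(entrants))
        row.update(deaths_total=total, duration_days=dur,
                   mortality_rate=mortality_rate(total, dur))
        rows.append(row)

    totals: dict[str, object] = {"stage": "Total"}
    tagged = {n: sum(1 for d in deployments if d.nucleus == n) for n in nuclei}
    for nucleus in nuclei:
        lost, n = lost_by_nucleus[nucleus], tagged[nucleus]
        totals[f"{nucleus}_M"] = f"{lost}/{n} ({100.0 * lost / n:.0f}%)" if n else "0/0"
    totals["deaths_total"] = sum(lost_by_nucleus.values())
    rows.append(totals)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Product-limit estimation and the log-rank test
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Kaplan–Meier product-limit estimate.

    ``times`` are the distinct event (death) times; ``survival[i]`` is
    S(t) for t in [times[i], times[i+1]). S(0) = 1 and S is
    non-increasing. Individuals censored at a death time remain at risk
    for that death (the standard convention).
    """

    times: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t) -> float | np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        s = np.where(idx < 0, 1.0, np.concatenate([[1.0], self.survival])[idx + 1])
        return float(s) if s.ndim == 0 else s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "at_risk": self.at_risk,
                             "deaths": self.deaths, "survival": self.survival})


def kaplan_meier(times, events) -> SurvivalCurve:
    """Product-limit survival estimate S(t) = Π_{t_i ≤ t} (1 − d_i/n_i).

    ``times`` are days ≥ 0 since tagging; ``events`` is 1 for a death and
    0 for censoring. With no censoring this reduces to the empirical
    survivor fraction; with no deaths S ≡ 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one subject")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")

    order = np.argsort(times, kind="mergesort")
    times_s, events_s = times[order], events[order]
    death_times = np.unique(times_s[events_s == 1])
    n = times.size
    at_risk, deaths, surv = [], [], []
    s = 1.0
    for t in death_times:
        n_i = int(np.sum(times_s >= t))
        d_i = int(np.sum((times_s == t) & (events_s == 1)))
        s *= 1.0 - d_i / n_i
        at_risk.append(n_i)
        deaths.append(d_i)
        surv.append(s)
    return SurvivalCurve(times=death_times, at_risk=np.asarray(at_risk),
                         deaths=np.asarray(deaths), survival=np.asarray(surv),
                         censor_times=np.sort(times_s[events_s == 0]))


def log_rank(groups: list[tuple[np.ndarray, np.ndarray]]):
    """k-sample log-rank test on (times, events) per group.

    Uses the full hypergeometric variance–covariance of observed-minus-
    expected deaths (the statistic standard survival software reports),
    with df = k − 1. Returns ``(chi_square, df, p)``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = []
    for gi, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {gi} has no subjects")
        arrs.append((t, e))
    k = len(arrs)
    all_deaths = np.unique(np.concatenate([t[e == 1] for t, e in arrs])
                           if any((e == 1).any() for _, e in arrs) else np.array([]))
    if all_deaths.size == 0:
        return 0.0, k - 1, 1.0

    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for td in all_deaths:
        n_g = np.array([np.sum(t >= td) for t, _ in arrs], dtype=float)
        d_g = np.array([np.sum((t == td) & (e == 1)) for t, e in arrs], dtype=float)
        n_tot, d_tot = n_g.sum(), d_g.sum()
        if n_tot <= 0 or d_tot == 0:
            continue
        p_g = n_g / n_tot
        O += d_g
        E += d_tot * p_g
        if n_tot > 1:
            c = d_tot * (n_tot - d_tot) / (n_tot - 1.0)
            V += c * (np.diag(p_g) - np.outer(p_g, p_g))
    z = (O - E)[:-1]
    v = V[:-1, :-1]
    try:
        stat = float(z @ np.linalg.solve(v, z))
    except np.linalg.LinAlgError:
        stat = float(z @ np.linalg.pinv(v) @ z)
    stat = max(stat, 0.0)
    df = k - 1
    return stat, df, float(chi2.sf(stat, df))
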