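"""Life-stage segmentation of juvenile vulture tracks.

A juvenile's first years decompose into: a dependence period around the
natal nest, a pre-migration transit of Iberia, a Sahara crossing, a
multi-month (often multi-year) stay in the Sahel, and — for survivors —
a northward return; a minority never cross to Africa and live as
year-round Iberian residents. All boundaries here are displacement
rules on the QC-filtered, resampled track: distance-from-nest thresholds
for nest and natal departure, a Strait-of-Gibraltar gate for the Africa
crossing, and latitude bands for desert entry and Sahel arrival. Every
boundary snaps to an observed fix timestamp — no sub-fix interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import GeoPoint, haversine_km
from .io import Trajectory

KM_PER_DEG_LAT = 111.195  # great-circle km per degree of latitude (mean sphere)

STAGES = ["dependence", "iberia_premigration", "sahara_crossing", "sahel_stay",
          "return_migration", "iberia_postreturn", "residency"]

#: roll-up used for stage-mortality reporting (Table-style stages)
STAGE_ROLLUP = {
    "dependence": "Dependence",
    "iberia_premigration": "Migration",
    "sahara_crossing": "Migration",
    "sahel_stay": "Stay in the Sahel",
    "return_migration": "Migration",
    "iberia_postreturn": "Stay in the Iberian Peninsula",
    "residency": "Stay in the Iberian Peninsula",
}


class SegmentationError(RuntimeError):
    """Detector outputs contradict each other (e.g. Sahel arrival precedes
    the Gibraltar crossing)."""


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds for the displacement rules.

    The 200 m nest-departure displacement and the 22.5°N upper bound of the
    Sahel band are taken from the study system; the remaining values are
    declared operational defaults (the field definitions are qualitative)
    and are all configurable.
    """

    nest_departure_m: float = 200.0
    natal_radius_km: float = 2.0
    natal_confirm_days: float = 7.0
    natal_confirm_km: float = 50.0
    gibraltar_lat: float = 36.0
    gibraltar_lon_window: tuple[float, float] = (-6.1, -5.2)
    desert_north_lat: float = 30.0
    sahel_north_lat: float = 22.5
    return_net_km: float = 100.0
    return_window_days: float = 3.0
    return_dip_slack_km: float = 25.0
    return_climb_max_days: float = 30.0
    nonmigrant_min_days: float = 365.0

    def __post_init__(self) -> None:
        for name in ("nest_departure_m", "natal_radius_km", "natal_confirm_days",
                     "natal_confirm_km", "return_net_km", "return_window_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.sahel_north_lat < self.desert_north_lat < self.gibraltar_lat):
            raise ValueError("require sahel_north_lat < desert_north_lat < gibraltar_lat")


@dataclass
class StageInterval:
    stage: str
    start: pd.Timestamp
    end: pd.Timestamp

    @property
    def duration_days(self) -> float:
        return (self.end - self.start).total_seconds() / 86400.0


@dataclass
class StageSegmentation:
    """Ordered, non-overlapping labelled intervals covering the observed span."""

    individual_id: str
    intervals: list[StageInterval] = field(default_factory=list)
    strategy: str = "undetermined"      # migrant | non_migrant | undetermined
    natal_departure_confirmed: bool = True

    def stage_at(self, t: pd.Timestamp) -> str | None:
        for iv in self.intervals:
            if iv.start <= t <= iv.end:
                return iv.stage
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"individual": self.individual_id, "stage": iv.stage, "start": iv.start,
              "end": iv.end, "duration_days": iv.duration_days, "strategy": self.strategy}
             for iv in self.intervals])


def _arrays(traj: Trajectory):
    f = traj.fixes
    return (f["timestamp"].to_numpy(), f["lon"].to_numpy(dtype=float),
            f["lat"].to_numpy(dtype=float))


def detect_nest_departure(traj: Trajectory, nest: GeoPoint,
                          params: SegmentationParams = SegmentationParams()):
    """Timestamp of the first fix at ≥ ``nest_departure_m`` from the nest
    (inclusive threshold), or None if the bird never moves that far."""
    if len(traj) == 0:
        return None
    ts, lon, lat = _arrays(traj)
    d_km = haversine_km(lon, lat, nest.lon, nest.lat)
    idx = np.flatnonzero(d_km * 1000.0 >= params.nest_departure_m)
    return pd.Timestamp(ts[idx[0]]) if idx.size else None


def detect_natal_departure(traj: Trajectory, nest: GeoPoint,
                           params: SegmentationParams = SegmentationParams()):
    """Definitive departure from the natal territory.

    Returns ``(timestamp, confirmed)`` — the last fix within
    ``natal_radius_km`` of the nest after which the bird never re-enters
    that radius, provided it moves at least ``natal_confirm_km`` from
    there within the next ``natal_confirm_days`` (a long, directed
    journey rather than drift). ``(None, True)`` if the track ends inside
    the radius or the confirmation fails; ``(timestamp, False)`` when the
    track is too short after the candidate to confirm.
    """
    if len(traj) == 0:
        return None, True
    ts, lon, lat = _arrays(traj)
    d_km = haversine_km(lon, lat, nest.lon, nest.lat)
    inside = np.flatnonzero(d_km <= params.natal_radius_km)
    if inside.size == 0:
        # never seen inside the natal radius: departure is the first fix
        cand = 0
    else:
        cand = int(inside[-1])
        if cand == len(ts) - 1:
            return None, True  # track ends inside the natal territory
    t_cand = ts[cand]
    horizon = t_cand + np.timedelta64(int(params.natal_confirm_days * 86400), "s")
    in_window = np.flatnonzero((ts > t_cand) & (ts <= horizon))
    track_covers_window = ts[-1] >= horizon
    if in_window.size == 0:
        return pd.Timestamp(t_cand), False
    net_km = float(np.max(haversine_km(lon[cand], lat[cand],
                                       lon[in_window], lat[in_window])))
    if net_km >= params.natal_confirm_km:
        return pd.Timestamp(t_cand), True
    if not track_covers_window:
        return pd.Timestamp(t_cand), False   # candidate, unconfirmable
    return None, True


def detect_gibraltar_crossing(traj: Trajectory,
                              params: SegmentationParams = SegmentationParams(),
                              after: pd.Timestamp | None = None):
    """First southbound crossing of the Gibraltar gate, or None.

    The gate is the ``gibraltar_lat`` parallel restricted to
    ``gibraltar_lon_window``. A consecutive fix pair crosses when the first
    fix is north of the parallel and the second at/ south of it, and either
    both longitudes lie in the window or the linearly interpolated crossing
    longitude does. The crossing time is the second fix's timestamp.
    """
    if len(traj) < 2:
        return None
    ts, lon, lat = _arrays(traj)
    if after is not None:
        keep = ts >= np.datetime64(after)
        ts, lon, lat = ts[keep], lon[keep], lat[keep]
        if ts.size < 2:
            return None
    lo, hi = params.gibraltar_lon_window
    g = params.gibraltar_lat
    south = (lat[:-1] > g) & (lat[1:] <= g)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(lat[:-1] != lat[1:], (lat[:-1] - g) / (lat[:-1] - lat[1:]), 0.0)
    lon_cross = lon[:-1] + frac * (lon[1:] - lon[:-1])
    in_window = ((lon[:-1] >= lo) & (lon[:-1] <= hi) & (lon[1:] >= lo) & (lon[1:] <= hi)) \
        | ((lon_cross >= lo) & (lon_cross <= hi))
    idx = np.flatnonzero(south & in_window)
    return pd.Timestamp(ts[idx[0] + 1]) if idx.size else None


def detect_sahara_span(traj: Trajectory,
                       params: SegmentationParams = SegmentationParams(),
                       after: pd.Timestamp | None = None):
    """(desert entry, Sahel arrival) for the successful desert transit.

    Sahel arrival is the first fix at/below ``sahel_north_lat`` (after
    ``after``, normally the Gibraltar crossing); desert entry is the last
    fix at/above ``desert_north_lat`` before it. None when the bird never
    reaches the Sahel band (lost in the desert or turned back).
    """
    if len(traj) == 0:
        return None
    ts, lon, lat = _arrays(traj)
    if after is not None:
        keep = ts >= np.datetime64(after)
        ts, lon, lat = ts[keep], lon[keep], lat[keep]
    arr = np.flatnonzero(lat <= params.sahel_north_lat)
    if arr.size == 0:
        return None
    j = int(arr[0])
    before = np.flatnonzero(lat[:j] >= params.desert_north_lat)
    if before.size == 0:
        return None
    return pd.Timestamp(ts[int(before[-1])]), pd.Timestamp(ts[j])


def detect_return_start(traj: Trajectory,
                        params: SegmentationParams = SegmentationParams(),
                        sahel_arrival: pd.Timestamp | None = None):
    """Start of the northward return from the Sahel, or None.

    The return start is the first fix after Sahel arrival from which
    (a) net northward displacement over ``return_window_days`` reaches
    ``return_net_km``, (b) latitude never drops more than
    ``return_dip_slack_km`` below the starting fix before the bird reaches
    ``desert_north_lat``, and (c) the bird does reach ``desert_north_lat``
    without re-entering the Sahel band in between — or, if the track ends
    first, the final fix lies at least twice ``return_net_km`` north of
    the start with no dip back (a directed climb cut short by transmitter
    loss is a begun return). Clause (b) rejects transient in-band
    northward forays that wander back south; a bird that reaches North
    Africa and later re-crosses the desert southward still counts as
    having started a return.
    """
    if len(traj) < 2:
        return None
    ts, lon, lat = _arrays(traj)
    if sahel_arrival is not None:
        keep = ts >= np.datetime64(sahel_arrival)
        ts, lon, lat = ts[keep], lon[keep], lat[keep]
        if ts.size < 2:
            return None
    desert = np.flatnonzero(lat >= params.desert_north_lat)
    desert_reached = desert.size > 0
    j_ref = int(desert[0]) if desert_reached else lat.size - 1
    # last fix inside the Sahel band before the reference fix: the climb out
    # of the band must start at or before it (no re-entry clause)
    in_band = np.flatnonzero(lat[:j_ref + 1] <= params.sahel_north_lat)
    i_exit = int(in_band[-1]) if in_band.size else 0

    # a true return connects to the band exit promptly; candidates further
    # back than the climb window are wandering, not departure
    t_lo = ts[i_exit] - np.timedelta64(int(params.return_climb_max_days * 86400), "s")
    i_lo = int(np.searchsorted(ts, t_lo, side="left"))
    cand = np.arange(i_lo, i_exit + 1)
    horizon = ts[cand] + np.timedelta64(int(params.return_window_days * 86400), "s")
    k = np.searchsorted(ts, horizon, side="right") - 1
    gain_km = (lat[k] - lat[cand]) * KM_PER_DEG_LAT
    # suffix minimum of latitude up to the reference fix, for the dip clause
    suffmin = np.minimum.accumulate(lat[:j_ref + 1][::-1])[::-1]
    dip_ok = (suffmin[np.minimum(cand + 1, j_ref)]
              >= lat[cand] - params.return_dip_slack_km / KM_PER_DEG_LAT)
    ok = (gain_km >= params.return_net_km) & dip_ok
    if not desert_reached:
        # truncated-climb clause: track must end well north of the start
        end_gain = (lat[j_ref] - lat[cand]) * KM_PER_DEG_LAT
        ok &= end_gain >= 2.0 * params.return_net_km
    idx = np.flatnonzero(ok)
    if not idx.size:
        return None
    trigger = int(cand[idx[0]])
    # The window rule necessarily fires a little before the climb begins.
    # Anchor the reported instant to the onset of the sustained northward
    # run: walking back from the band exit, keep indices whose forward
    # one-day latitude gain stays at the minimum climb rate.
    rate_deg = params.return_net_km / params.return_window_days / KM_PER_DEG_LAT
    onset = i_exit
    j = i_exit - 1
    day = np.timedelta64(86400, "s")
    while j >= trigger:
        k = min(int(np.searchsorted(ts, ts[j] + day, side="right")) - 1, j_ref)
        if lat[k] - lat[j] < rate_deg:
            break
        onset = j
        j -= 1
    if onset == i_exit and trigger < i_exit:
        # no sustained run found behind the exit (e.g. the track ends in a
        # post-mortem standstill); keep the window-rule instant
        return pd.Timestamp(ts[trigger])
    return pd.Timestamp(ts[onset])


def classify_strategy(traj: Trajectory, params: SegmentationParams = SegmentationParams(),
                      natal_departure: pd.Timestamp | None = None) -> str:
    """migrant / non_migrant / undetermined.

    Migrant on any detected Gibraltar crossing; non-migrant when at least
    ``nonmigrant_min_days`` (default a full year) of post-departure
    observation contain no crossing; otherwise undetermined.
    """
    crossing = detect_gibraltar_crossing(traj, params, after=natal_departure)
    if crossing is not None:
        return "migrant"
    if len(traj) == 0 or natal_departure is None:
        return "undetermined"
    span_days = (traj.fixes["timestamp"].iloc[-1] - natal_departure).total_seconds() / 86400.0
    return "non_migrant" if span_days >= params.nonmigrant_min_days else "undetermined"


def segment(traj: Trajectory, nest: GeoPoint | None = None,
            params: SegmentationParams = SegmentationParams()) -> StageSegmentation:
    """Compose the detectors into a contiguous labelled segmentation.

    Migrants: dependence → iberia_premigration → sahara_crossing →
    sahel_stay [→ return_migration [→ iberia_postreturn]]; residents:
    dependence → residency. Fixes before the deployment's tagging date are
    ignored. The final interval is truncated at the last fix.
    """
    dep = traj.deployment
    if nest is None:
        nest = GeoPoint(dep.nest_lon, dep.nest_lat)
    fixes = traj.fixes
    if dep.tagging_date is not None and len(fixes):
        fixes = fixes[fixes["timestamp"] >= dep.tagging_date].reset_index(drop=True)
        traj = Trajectory(dep, fixes)
    if len(fixes) == 0:
        return StageSegmentation(dep.individual_id, [], "undetermined")

    t_first = fixes["timestamp"].iloc[0]
    t_last = fixes["timestamp"].iloc[-1]
    natal_dep, confirmed = detect_natal_departure(traj, nest, params)
    if natal_dep is None:
        return StageSegmentation(dep.individual_id,
                                 [StageInterval("dependence", t_first, t_last)],
                                 "undetermined", confirmed)

    intervals = [StageInterval("dependence", t_first, natal_dep)]
    strategy = classify_strategy(traj, params, natal_dep)
    crossing = detect_gibraltar_crossing(traj, params, after=natal_dep)

    if crossing is None:
        # confirmed residents settle; an undetermined bird's post-departure
        # directed movement is treated as pre-migration transit
        label = "residency" if strategy == "non_migrant" else "iberia_premigration"
        intervals.append(StageInterval(label, natal_dep, t_last))
        return StageSegmentation(dep.individual_id, intervals, strategy, confirmed)

    if crossing < natal_dep:
        raise SegmentationError(
            f"{dep.individual_id}: Gibraltar crossing {crossing} precedes "
            f"natal departure {natal_dep}")
    intervals.append(StageInterval("iberia_premigration", natal_dep, crossing))

    span = detect_sahara_span(traj, params, after=crossing)
    if span is None:
        intervals.append(StageInterval("sahara_crossing", crossing, t_last))
        return StageSegmentation(dep.individual_id, intervals, strategy, confirmed)
    desert_entry, sahel_arrival = span
    if sahel_arrival < crossing:
        raise SegmentationError(
            f"{dep.individual_id}: Sahel arrival {sahel_arrival} precedes "
            f"Gibraltar crossing {crossing}")
    intervals.append(StageInterval("sahara_crossing", crossing, sahel_arrival))

    ret = detect_return_start(traj, params, sahel_arrival=sahel_arrival)
    if ret is None:
        intervals.append(StageInterval("sahel_stay", sahel_arrival, t_last))
        return StageSegmentation(dep.individual_id, intervals, strategy, confirmed)
    intervals.append(StageInterval("sahel_stay", sahel_arrival, ret))

    ts, lon, lat = _arrays(traj)
    north = np.flatnonzero((ts > np.datetime64(ret)) & (lat >= params.gibraltar_lat))
    if north.size:
        t_north = pd.Timestamp(ts[int(north[0])])
        intervals.append(StageInterval("return_migration", ret, t_north))
        intervals.append(StageInterval("iberia_postreturn", t_north, t_last))
    else:
        intervals.append(StageInterval("return_migration", ret, t_last))
    return StageSegmentation(dep.individual_id, intervals, strategy, confirmed)


def truncate_segmentation(seg: StageSegmentation, t: pd.Timestamp) -> StageSegmentation:
    """Clip a segmentation at an instant (e.g. an inferred death time):
    intervals starting after ``t`` are dropped, the containing interval is
    shortened. Post-mortem transmitter activity is not life-stage exposure."""
    out = []
    for iv in seg.intervals:
        if iv.start >= t:
            break
        out.append(StageInterval(iv.stage, iv.start, min(iv.end, t)))
    return StageSegmentation(seg.individual_id, out, seg.strategy,
                             seg.natal_departure_confirmed)


def stage_durations_days(seg: StageSegmentation) -> dict[str, float]:
    """Total fractional days per stage label (summed over intervals)."""
    out: dict[str, float] = {}
    for iv in seg.intervals:
        out[iv.stage] = out.get(iv.stage, 0.0) + iv.duration_days
    return out
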