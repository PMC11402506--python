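"""Movebank-dialect tracking tables: ingestion, QC filtering, resampling.

The on-disk dialect follows Movebank column naming (``timestamp``,
``location-long``, ``location-lat``, ``individual-local-identifier``,
``gps:hdop``, ``gps:vdop``, ...). In memory a track is a
:class:`Trajectory`: a deployment record plus a time-sorted DataFrame of
fixes with plain column names (``timestamp, lon, lat, hdop, vdop,
battery_v, activity``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FIX_COLUMNS = ["timestamp", "lon", "lat", "hdop", "vdop", "battery_v", "activity"]

_TRACK_REQUIRED = ["timestamp", "location-long", "location-lat", "individual-local-identifier"]
_DEPLOY_REQUIRED = ["individual-local-identifier", "sex", "nucleus", "nest-long", "nest-lat",
                    "tagging-date", "transmitter-model"]

_TRACK_RENAME = {
    "location-long": "lon",
    "location-lat": "lat",
    "gps:hdop": "hdop",
    "gps:vdop": "vdop",
    "tag-voltage": "battery_v",
    "activity": "activity",
    "acceleration-raw-x": "activity",
}


class FormatError(ValueError):
    """A required column is missing or a file is structurally malformed."""


class ConsistencyError(ValueError):
    """Fixes reference an individual absent from the deployment metadata."""


@dataclass(frozen=True)
class Deployment:
    individual_id: str
    sex: str = "unknown"              # M, F or unknown
    nucleus: str = ""
    nest_lon: float = float("nan")
    nest_lat: float = float("nan")
    tagging_date: pd.Timestamp | None = None
    transmitter_model: str = ""
    sibling_group: str | None = None


@dataclass
class Trajectory:
    """One individual's ordered fixes plus its deployment metadata."""

    deployment: Deployment
    fixes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=FIX_COLUMNS))

    @property
    def individual_id(self) -> str:
        return self.deployment.individual_id

    def __len__(self) -> int:
        return len(self.fixes)


def _require(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing required column(s): {', '.join(missing)}")


def read_deployments(path: str | Path) -> dict[str, Deployment]:
    """Read the deployment-metadata CSV into a dict keyed by individual id."""
    df = pd.read_csv(path, dtype={"individual-local-identifier": str})
    _require(df, _DEPLOY_REQUIRED, "deployment table")
    out: dict[str, Deployment] = {}
    for _, row in df.iterrows():
        sex = str(row["sex"]).strip() if pd.notna(row["sex"]) else "unknown"
        sib = row.get("sibling-group")
        out[str(row["individual-local-identifier"])] = Deployment(
            individual_id=str(row["individual-local-identifier"]),
            sex=sex if sex in ("M", "F") else "unknown",
            nucleus=str(row["nucleus"]),
            nest_lon=float(row["nest-long"]),
            nest_lat=float(row["nest-lat"]),
            tagging_date=pd.to_datetime(row["tagging-date"]),
            transmitter_model=str(row["transmitter-model"]),
            sibling_group=str(sib) if pd.notna(sib) else None,
        )
    return out


def read_movebank(path: str | Path, deployments_path: str | Path) -> list[Trajectory]:
    """Read a Movebank-dialect tracking CSV into one Trajectory per individual.

    Rows with unparseable coordinates or timestamps, or with coordinates
    outside valid lon/lat bounds, are dropped and counted in a log record.
    Duplicate (individual, timestamp) rows keep the first occurrence. Fixes
    come out strictly time-ordered regardless of row order on disk.

    Raises :class:`FormatError` when a required column is absent and
    :class:`ConsistencyError` when a fix references an individual missing
    from the deployment table.
    """
    deployments = read_deployments(deployments_path)
    df = pd.read_csv(path, dtype={"individual-local-identifier": str})
    _require(df, _TRACK_REQUIRED, "tracking table")

    n_raw = len(df)
    df = df.rename(columns=_TRACK_RENAME)
    df["timestamp"] = pd.to_datetime(df["timestamp"], errors="coerce", utc=True).dt.tz_localize(None)
    for col in ("lon", "lat", "hdop", "vdop", "battery_v", "activity"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        else:
            df[col] = np.nan

    ok = (df["timestamp"].notna() & df["lon"].notna() & df["lat"].notna()
          & df["lon"].between(-180, 180) & df["lat"].between(-90, 90))
    dropped = int(n_raw - ok.sum())
    if dropped:
        logger.info("read_movebank: dropped %d of %d rows (bad coordinates/timestamps)",
                    dropped, n_raw)
    df = df[ok]

    ids_seen = set(df["individual-local-identifier"].unique())
    unknown = ids_seen - set(deployments)
    if unknown:
        raise ConsistencyError(
            f"fixes reference individual(s) absent from deployment metadata: {sorted(unknown)}")

    trajectories = []
    for ind_id, dep in deployments.items():
        sub = df[df["individual-local-identifier"] == ind_id]
        sub = (sub.sort_values("timestamp", kind="mergesort")
                  .drop_duplicates(subset="timestamp", keep="first"))
        fixes = sub[FIX_COLUMNS].reset_index(drop=True)
        trajectories.append(Trajectory(deployment=dep, fixes=fixes))
    return trajectories


def write_movebank(trajectories: list[Trajectory], path: str | Path,
                   deployments_path: str | Path | None = None) -> None:
    """Write trajectories back to the Movebank dialect (lossless for finite
    fields; missing optional channels stay empty)."""
    frames = []
    for traj in trajectories:
        df = traj.fixes.copy()
        df["individual-local-identifier"] = traj.individual_id
        frames.append(df)
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=FIX_COLUMNS + ["individual-local-identifier"])
    out = out.rename(columns={"lon": "location-long", "lat": "location-lat",
                              "hdop": "gps:hdop", "vdop": "gps:vdop",
                              "battery_v": "tag-voltage"})
    cols = ["timestamp", "location-long", "location-lat", "individual-local-identifier",
            "gps:hdop", "gps:vdop", "tag-voltage", "activity"]
    out[cols].to_csv(path, index=False, date_format="%Y-%m-%d %H:%M:%S",
                     float_format="%.10g")

    if deployments_path is not None:
        rows = []
        for traj in trajectories:
            d = traj.deployment
            rows.append({
                "individual-local-identifier": d.individual_id, "sex": d.sex,
                "nucleus": d.nucleus, "nest-long": d.nest_lon, "nest-lat": d.nest_lat,
                "tagging-date": None if d.tagging_date is None else d.tagging_date.date(),
                "transmitter-model": d.transmitter_model,
                "sibling-group": d.sibling_group,
            })
        pd.DataFrame(rows).to_csv(deployments_path, index=False)


def qc_filter(traj: Trajectory, max_dop: float = 5.0,
              drop_missing_dop: bool = False) -> Trajectory:
    """Remove fixes whose horizontal or vertical dilution of precision
    exceeds ``max_dop`` (strictly greater; a DOP of exactly 5 is kept).

    Fixes with *missing* DOP are retained by default — several transmitter
    models report no DOP at all, and the filter targets measured bad
    geometry, not absent metadata. ``drop_missing_dop=True`` switches to
    strict dropping.
    """
    f = traj.fixes
    bad_h = f["hdop"] > max_dop
    bad_v = f["vdop"] > max_dop
    if drop_missing_dop:
        bad_h = bad_h | f["hdop"].isna()
        bad_v = bad_v | f["vdop"].isna()
    keep = ~(bad_h | bad_v)
    return Trajectory(traj.deployment, f[keep].reset_index(drop=True))


def resample(traj: Trajectory, interval: pd.Timedelta | str = "30min",
             tolerance: pd.Timedelta | str | None = None) -> Trajectory:
    """Standardise fix spacing to a regular grid without interpolation.

    The grid is anchored at the trajectory's first fix. Each grid slot takes
    the nearest original fix within ``tolerance`` (default: half the
    interval); slots with no fix nearby stay empty — no positions are ever
    fabricated, so every output timestamp exists in the input and each input
    fix is used at most once. Applying QC + resample twice equals once.
    """
    interval = pd.Timedelta(interval)
    if interval <= pd.Timedelta(0):
        raise ValueError("resample interval must be positive")
    tolerance = interval / 2 if tolerance is None else pd.Timedelta(tolerance)

    f = traj.fixes
    if len(f) < 2:
        return Trajectory(traj.deployment, f.copy())

    t0 = f["timestamp"].iloc[0]
    offset = (f["timestamp"] - t0).dt.total_seconds().to_numpy()
    step = interval.total_seconds()
    slot = np.rint(offset / step).astype(np.int64)
    resid = np.abs(offset - slot * step)
    ok = resid <= tolerance.total_seconds()

    cand = pd.DataFrame({"slot": slot[ok], "resid": resid[ok],
                         "idx": np.flatnonzero(ok)})
    # per slot keep the nearest fix; earliest wins ties (stable sort)
    cand = cand.sort_values(["slot", "resid"], kind="mergesort")
    winners = cand.drop_duplicates(subset="slot", keep="first")["idx"].to_numpy()
    winners.sort()
    return Trajectory(traj.deployment, f.iloc[winners].reset_index(drop=True))
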