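"""End-to-end orchestration: QC → segmentation → home ranges → fate →
survival, emitting a bundle of report tables.

Every number in the bundle is recomputable from the input files plus the
run configuration alone; a sha256 manifest of the outputs is emitted so a
rerun can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import homerange
from .geometry import GeoPoint, daily_distance_km, max_displacement_km, path_length_km
from .io import Trajectory, qc_filter, read_movebank, resample
from .segmentation import (SegmentationParams, StageSegmentation, segment,
                           truncate_segmentation)
from .survival import (FateParams, FateRecord, assign_loss_stage, infer_fate,
                       kaplan_meier, log_rank, stage_mortality_table)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    fixes_path: str | Path = "fixes.csv"
    deployments_path: str | Path = "deployments.csv"
    out_dir: str | Path = "results"
    max_dop: float = 5.0
    resample_interval: str = "30min"
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    fate: FateParams = field(default_factory=FateParams)
    kde_bandwidth: float | str = "reference"
    kde_cell_km: float = 5.0
    kde_level: float = 0.95
    compute_overlaps: bool = True
    group_vars: tuple[str, ...] = ("nucleus", "sex", "strategy")
    study_end: pd.Timestamp | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        seg = SegmentationParams(**raw.pop("segmentation", {}))
        fate = FateParams(**raw.pop("fate", {}))
        if "study_end" in raw and raw["study_end"] is not None:
            raw["study_end"] = pd.Timestamp(raw["study_end"])
        if "group_vars" in raw:
            raw["group_vars"] = tuple(raw["group_vars"])
        return cls(segmentation=seg, fate=fate, **raw)


def group_summary(values, groups) -> pd.DataFrame:
    """Per-group descriptive summary: mean, sample SD (n−1), n, min, max.

    Singleton groups report SD as missing; empty groups are omitted with a
    log note.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": list(groups)})
    df = df[np.isfinite(df["value"])]
    rows = []
    for g, sub in df.groupby("group", sort=True):
        v = sub["value"].to_numpy()
        rows.append({"group": g, "n": v.size, "mean": float(v.mean()),
                     "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
                     "min": float(v.min()), "max": float(v.max())})
    if not rows:
        logger.info("group_summary: no non-empty groups")
    return pd.DataFrame(rows)


@dataclass
class RunResult:
    out_dir: Path
    trajectories: list[Trajectory]
    segmentations: list[StageSegmentation]
    fates: list[FateRecord]
    kde_table: pd.DataFrame
    overlap_table: pd.DataFrame
    mortality_table: pd.DataFrame
    km_table: pd.DataFrame
    logrank: dict
    group_table: pd.DataFrame


def run_pipeline(config: RunConfig,
                 trajectories: list[Trajectory] | None = None) -> RunResult:
    """Run the full analysis and write the report bundle.

    Outputs under ``config.out_dir``: stages.csv, kde.csv, kde.geojson,
    fates.csv, mortality_table.csv, km_curves.csv, group_summary.csv, plus
    overlaps.csv, run_log.txt and manifest.json. Any stage failure aborts
    with a stage-named diagnostic; outputs written so far are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.6f")
        written.append(path)

    stage = "ingestion"
    try:
        if trajectories is None:
            trajectories = read_movebank(config.fixes_path, config.deployments_path)

        stage = "qc"
        clean = [resample(qc_filter(t, config.max_dop), config.resample_interval)
                 for t in trajectories]

        stage = "segmentation"
        segs = [segment(t, params=config.segmentation) for t in clean]
        stages_df = (pd.concat([s.to_frame() for s in segs if s.intervals],
                               ignore_index=True)
                     if any(s.intervals for s in segs) else
                     pd.DataFrame(columns=["individual", "stage", "start", "end",
                                           "duration_days", "strategy"]))
        emit("stages.csv", stages_df)

        stage = "homerange"
        kde_rows, features, estimates = [], [], {}
        for traj, seg_ in zip(clean, segs):
            if seg_.strategy == "migrant":
                label = "sahel_stay"
            elif seg_.strategy == "non_migrant":
                label = "residency"
            else:
                continue
            spans = [iv for iv in seg_.intervals if iv.stage == label]
            if not spans:
                continue
            mask = np.zeros(len(traj.fixes), dtype=bool)
            ts = traj.fixes["timestamp"]
            for iv in spans:
                mask |= ((ts >= iv.start) & (ts <= iv.end)).to_numpy()
            sub = traj.fixes[mask]
            if len(sub) < 10:
                continue
            est = homerange.fit_kde(sub["lon"], sub["lat"],
                                    bandwidth=config.kde_bandwidth,
                                    cell_km=config.kde_cell_km,
                                    level=config.kde_level)
            estimates[traj.individual_id] = (est, label)
            kde_rows.append({"individual": traj.individual_id, "stage": label,
                             "n_fixes": len(sub), "bandwidth_km": est.bandwidth_km,
                             "area_km2": est.area_km2,
                             "centroid_lon": est.centroid.lon,
                             "centroid_lat": est.centroid.lat})
            geom = est.isopleth_polygons()
            features.append({"type": "Feature",
                             "properties": {"individual": traj.individual_id,
                                            "stage": label,
                                            "level": config.kde_level,
                                            "area_km2": round(est.area_km2, 1)},
                             "geometry": geom.__geo_interface__})
        emit("kde.csv", pd.DataFrame(
            kde_rows, columns=["individual", "stage", "n_fixes", "bandwidth_km",
                               "area_km2", "centroid_lon", "centroid_lat"]))
        geo_path = out / "kde.geojson"
        geo_path.write_text(json.dumps(
            {"type": "FeatureCollection", "features": features}, default=float))
        written.append(geo_path)

        stage = "overlap"
        dep_by_id = {t.individual_id: t.deployment for t in trajectories}
        ov_rows = []
        if config.compute_overlaps:
            sahel_ids = [i for i, (_, lbl) in estimates.items() if lbl == "sahel_stay"]
            for a_i in range(len(sahel_ids)):
                for b_i in range(a_i + 1, len(sahel_ids)):
                    ida, idb = sahel_ids[a_i], sahel_ids[b_i]
                    res = homerange.pairwise_overlap(
                        estimates[ida][0], estimates[idb][0], ida, idb,
                        same_nucleus=dep_by_id[ida].nucleus == dep_by_id[idb].nucleus)
                    ov_rows.append(asdict(res))
        ov_df = pd.DataFrame(ov_rows, columns=["id_a", "id_b", "overlap_pct",
                                               "directed_a_pct", "directed_b_pct",
                                               "centroid_distance_km", "same_nucleus"])
        emit("overlaps.csv", ov_df)

        stage = "fate"
        study_end = config.study_end
        if study_end is None:
            ends = [t.fixes["timestamp"].iloc[-1] for t in clean if len(t)]
            study_end = max(ends) if ends else None
        fates = []
        seg_by_id = {s.individual_id: s for s in segs}
        for traj in clean:
            if len(traj) == 0:
                continue
            fate = infer_fate(traj, config.fate, study_end=study_end)
            assign_loss_stage(fate, seg_by_id[traj.individual_id])
            fates.append(fate)
        emit("fates.csv", pd.DataFrame(
            [{"individual": f.individual_id, "status": f.status,
              "event_time": f.event_time, "age_days_at_event": f.age_days_at_event,
              "stage_at_event": f.stage_at_event, "is_death": f.is_death,
              "low_confidence": f.low_confidence} for f in fates]))

        stage = "mortality_table"
        deployments = [t.deployment for t in trajectories]
        # clip dead birds' segmentations at the inferred death time so
        # post-mortem transmitter activity is not counted as stage exposure
        fate_by_id = {f.individual_id: f for f in fates}
        segs_rates = [truncate_segmentation(s, fate_by_id[s.individual_id].event_time)
                      if s.individual_id in fate_by_id
                      and fate_by_id[s.individual_id].is_death else s
                      for s in segs]
        mort = stage_mortality_table(fates, segs_rates, deployments)
        emit("mortality_table.csv", mort)

        stage = "survival"
        fate_df = pd.DataFrame(
            {"individual": [f.individual_id for f in fates],
             "time": [f.age_days_at_event for f in fates],
             "event": [int(f.is_death) for f in fates]})
        meta = pd.DataFrame(
            {"individual": [d.individual_id for d in deployments],
             "nucleus": [d.nucleus for d in deployments],
             "sex": [d.sex for d in deployments]})
        meta["strategy"] = meta["individual"].map(
            {s.individual_id: s.strategy for s in segs})
        fate_df = fate_df.merge(meta, on="individual")

        km_rows, logrank_res = [], {}
        for var in ("overall",) + tuple(config.group_vars):
            grouping = (pd.Series("all", index=fate_df.index) if var == "overall"
                        else fate_df[var])
            groups = []
            for gname, sub in fate_df.groupby(grouping, sort=True):
                curve = kaplan_meier(sub["time"], sub["event"])
                groups.append((sub["time"].to_numpy(), sub["event"].to_numpy()))
                for t, r, d, s in zip(curve.times, curve.at_risk, curve.deaths,
                                      curve.survival):
                    km_rows.append({"group_var": var, "group": gname, "time": t,
                                    "at_risk": r, "deaths": d, "survival": s})
            if var != "overall" and len(groups) >= 2:
                chi2_, df_, p_ = log_rank(groups)
                logrank_res[var] = {"chi_square": chi2_, "df": df_, "p": p_}
        emit("km_curves.csv", pd.DataFrame(
            km_rows, columns=["group_var", "group", "time", "at_risk", "deaths",
                              "survival"]))

        stage = "group_summary"
        metrics = _individual_metrics(clean, segs, kde_rows)
        grp_rows = []
        for var in ("nucleus", "sex", "strategy"):
            lookup = meta.set_index("individual")[var]
            for metric in [c for c in metrics.columns if c != "individual"]:
                gs = group_summary(metrics[metric],
                                   metrics["individual"].map(lookup))
                gs.insert(0, "metric", metric)
                gs.insert(0, "group_var", var)
                grp_rows.append(gs)
        grp_df = (pd.concat(grp_rows, ignore_index=True) if grp_rows
                  else pd.DataFrame())
        emit("group_summary.csv", grp_df)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    log_path = out / "run_log.txt"
    log_path.write_text(_run_log(config, trajectories, segs, fates, logrank_res))
    written.append(log_path)

    # manifest covers the data products; the run log carries host paths
    manifest = {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(written) if p.name != "run_log.txt"}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return RunResult(out, clean, segs, fates, pd.DataFrame(kde_rows), ov_df, mort,
                     pd.DataFrame(km_rows), logrank_res, grp_df)


def _individual_metrics(clean, segs, kde_rows) -> pd.DataFrame:
    """Per-individual descriptive metrics feeding the group summaries."""
    area = {r["individual"]: r["area_km2"] for r in kde_rows}
    rows = []
    for traj, seg_ in zip(clean, segs):
        row = {"individual": traj.individual_id}
        by_stage = {}
        for iv in seg_.intervals:
            by_stage.setdefault(iv.stage, []).append(iv)
        for name, label in (("dependence_days", "dependence"),
                            ("premigration_days", "iberia_premigration"),
                            ("sahara_days", "sahara_crossing"),
                            ("sahel_days", "sahel_stay")):
            ivs = by_stage.get(label)
            row[name] = sum(iv.duration_days for iv in ivs) if ivs else np.nan
        f = traj.fixes
        nest = GeoPoint(traj.deployment.nest_lon, traj.deployment.nest_lat)
        dep_ivs = by_stage.get("dependence")
        if dep_ivs and len(f):
            m = ((f["timestamp"] >= dep_ivs[0].start)
                 & (f["timestamp"] <= dep_ivs[-1].end))
            sub = f[m]
            if len(sub) >= 2:
                row["dependence_daily_km"] = float(
                    daily_distance_km(sub["timestamp"], sub["lon"], sub["lat"]).mean())
                row["dependence_max_km"] = max_displacement_km(sub["lon"], sub["lat"], nest)
        pre_ivs = by_stage.get("iberia_premigration")
        if pre_ivs and len(f):
            m = ((f["timestamp"] >= pre_ivs[0].start)
                 & (f["timestamp"] <= pre_ivs[-1].end))
            sub = f[m]
            if len(sub) >= 2:
                row["premigration_path_km"] = path_length_km(sub["lon"], sub["lat"])
        row["range_area_km2"] = area.get(traj.individual_id, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def _run_log(config, trajectories, segs, fates, logrank_res) -> str:
    lines = ["vultrack pipeline run", "", "parameters:"]
    cfg = asdict(config)
    cfg["segmentation"] = asdict(config.segmentation)
    cfg["fate"] = asdict(config.fate)
    for k, v in cfg.items():
        lines.append(f"  {k}: {v}")
    lines += ["", f"individuals: {len(trajectories)}",
              f"migrants: {sum(1 for s in segs if s.strategy == 'migrant')}",
              f"non-migrants: {sum(1 for s in segs if s.strategy == 'non_migrant')}",
              f"undetermined: {sum(1 for s in segs if s.strategy == 'undetermined')}",
              f"apparent deaths: {sum(1 for f in fates if f.is_death)}", "",
              "log-rank tests (apparent survival):"]
    for var, res in logrank_res.items():
        lines.append(f"  {var}: chi2={res['chi_square']:.4f} df={res['df']} "
                     f"p={res['p']:.4f}")
    return "\n".join(lines) + "\n"
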