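"""End-to-end pipeline: synthetic cohort (or files on disk) to report.

Stages: read + project tracks, 1 Hz spline interpolation and speed
threshold, trip segmentation and stage mixed models, dive detection
with drift correction and bout structure, outbound-route NNA clustering
with AU support, colony bearings and KS stage comparisons, chlorophyll
sampling with ROI tests and bootstrap enrichment, and Turchin
step-length fits per stage and reorientation scale.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import dives as dv
from . import environment as env
from . import routes as rt
from . import simulate as sim
from . import steps as st
from . import tracks as tk
from . import trips as tp

log = logging.getLogger(__name__)


def load_cohort(root: str | Path, colony: tuple[float, float]) -> dict:
    """Read a file-backed cohort (gps/, tdr/, chl.nc, truth.json)."""
    import json
    root = Path(root)
    truth = json.loads((root / "truth.json").read_text())
    birds = {}
    for gp in sorted((root / "gps").glob("*.csv")):
        bird_id = gp.stem
        g = tk.read_gps(gp)
        g = tk.project(g, colony)
        g["t_s"] = (g["t"] - sim.EPOCH).dt.total_seconds()
        t = tk.read_tdr(root / "tdr" / f"{bird_id}.csv")
        t["t_s"] = (t["t"] - sim.EPOCH).dt.total_seconds()
        meta = truth["birds"][bird_id]
        birds[bird_id] = {"gps_xy": g, "tdr": t,
                          "stage": meta["stage"], "year": meta["year"]}
    raster = xr.open_dataset(root / "chl.nc")
    from .geo import LocalProjection
    return {"birds": birds, "raster": raster, "truth": truth,
            "projection": LocalProjection(*colony)}


def run_pipeline(data: dict, config: sim.SimConfig | None = None,
                 n_boot_au: int = 1000, n_boot_roi: int = 1000,
                 seed: int = 0) -> dict:
    """Run every analysis stage on a cohort dict and return a report.

    ``data`` is the in-memory structure produced by
    :func:`alcatrack.simulate.gen_cohort` or :func:`load_cohort`.
    """
    config = config or sim.SimConfig()
    proj = data["projection"]
    raster = data["raster"]
    roi = config.roi

    all_trips, outbound_by_stage, dive_rows = [], {"incubation": [], "chick_rearing": []}, []
    raw_by_stage = {"incubation": [], "chick_rearing": []}
    speeds_pool, all_intervals = [], []
    bearing_pool = {("dive", "incubation"): [], ("dive", "chick_rearing"): [],
                    ("flight", "incubation"): [], ("flight", "chick_rearing")
                    : []}

    # first pass: interpolate everything to pick one global speed threshold
    interp_cache = {}
    for bird_id, d in data["birds"].items():
        g = d["gps_xy"]
        interp = tk.interpolate_1hz(g)
        interp_cache[bird_id] = interp
        speeds_pool.append(interp["speed"].to_numpy())
    try:
        speed_thr = tk.select_speed_threshold(
            np.random.default_rng(seed).choice(np.concatenate(speeds_pool),
                                               size=50_000, replace=False))
    except ValueError:
        speed_thr = None
        log.warning("speed density not bimodal; no flight/surface threshold")

    for bird_id, d in data["birds"].items():
        stage = d["stage"]
        g = d["gps_xy"]
        interp = interp_cache[bird_id]

        # dives: drift-correct, detect, bout structure, locate
        depth = d["tdr"]["depth_m"].to_numpy()
        corrected = dv.zero_offset_correct(depth)
        t0 = float(d["tdr"]["t_s"].iloc[0]) if "t_s" in d["tdr"] else 0.0
        recs = dv.detect_dives(corrected, t0=t0)
        all_intervals.append(dv.inter_dive_intervals(recs))
        located = dv.locate_dives(recs, interp, projection=proj)
        for r in located:
            dive_rows.append({"bird_id": bird_id, "stage": stage,
                              "t_start": r.t_start, "t_end": r.t_end,
                              "duration_s": r.duration, "max_depth_m": r.max_depth,
                              "lon": r.lon, "lat": r.lat, "located": r.located})

        # trips and outbound paths
        trips = tp.segment_trips(g, radius_km=config.colony_radius_km,
                                 bird_id=bird_id, stage=stage, year=d["year"])
        all_trips.extend(trips)
        for trip in trips:
            ob = tp.outbound_path(trip)
            outbound_by_stage[stage].append(ob)
            raw_by_stage[stage].append(trip.fixes)

        # bearings at dives and at flight fixes
        for r in located:
            if r.located:
                bearing_pool[("dive", stage)].append(
                    env.bearing(config.colony, r.lon, r.lat))
        if speed_thr is not None:
            fl = st.flight_fixes(g, speed_thr)
            if len(fl):
                lon, lat = proj.inverse(fl["x"].to_numpy(), fl["y"].to_numpy())
                th = env.bearing(config.colony, lon, lat)
                bearing_pool[("flight", stage)].extend(np.atleast_1d(th))

    table = tp.trip_table(all_trips)
    report = {"n_birds": len(data["birds"]), "n_trips": len(table),
              "speed_threshold_m_s": speed_thr,
              "trip_duration_h_mean": float(table["duration_h"].mean()),
              "trip_duration_h_sd": float(table["duration_h"].std()),
              "max_range_km_mean": float(table["max_range_km"].mean()),
              "max_range_km_sd": float(table["max_range_km"].std())}

    for resp in ("duration_h", "max_range_km"):
        try:
            report[f"stage_effect_{resp}"] = tp.stage_effect_aic(table, resp)
        except ValueError as e:
            report[f"stage_effect_{resp}"] = {"error": str(e)}

    # dives + bouts
    dive_df = pd.DataFrame(dive_rows)
    report["n_dives"] = len(dive_df)
    intervals = np.concatenate(all_intervals) if all_intervals else np.empty(0)
    if intervals.size >= 50:
        bout = dv.bout_ending_criterion(intervals)
        report["bout_t_bec_s"] = bout.t_bec
        report["bout_degenerate"] = bout.degenerate
    else:
        report["bout_t_bec_s"] = None

    # route similarity on outbound paths (resting fixes excluded upstream
    # of NNA by the flight-speed filter when a threshold exists)
    paths, labels, stages = [], [], []
    for stage, obs in outbound_by_stage.items():
        for i, ob in enumerate(obs):
            pf = st.flight_fixes(ob, speed_thr) if speed_thr is not None else ob
            paths.append(pf[["x", "y"]].to_numpy())
            labels.append(f"{stage[:3]}_{i}")
            stages.append(stage)
    kept = [(p, l, s) for p, l, s in zip(paths, labels, stages) if len(p) >= 10]
    report["n_outbound_retained"] = len(kept)
    if len(kept) >= 4:
        paths, labels, stages = map(list, zip(*kept))
        lbl, D = rt.nna_matrix(paths, labels)
        tree = rt.cluster_tree(D, lbl)
        rt.au_support(D, n_boot=n_boot_au, seed=seed, tree=tree)
        rec = rt.group_recovery(tree, np.array(stages), k=2)
        report["group_recovery"] = {k: float(v) for k, v in rec.items()}
        # AU of the best-matching node for each stage's member set
        au_by_stage = {}
        for stage in set(stages):
            want = frozenset(i for i, s in enumerate(stages) if s == stage)
            best = max(((len(s & want) / len(s | want), tree.au.get(nid, 0.0))
                        for nid, s in tree.nodes.items() if len(s) > 1),
                       default=(0, 0.0))
            au_by_stage[stage] = {"jaccard": best[0], "au": best[1]}
        report["stage_node_au"] = au_by_stage

    # bearings: KS by stage, per activity
    for act in ("dive", "flight"):
        a = np.asarray(bearing_pool[(act, "incubation")], float)
        b = np.asarray(bearing_pool[(act, "chick_rearing")], float)
        if a.size > 5 and b.size > 5:
            report[f"ks_bearings_{act}"] = env.ks_compare(a, b)

    # productivity at dive locations
    if len(dive_df):
        pp = env.pp_sample_table(raster, dive_df, roi)
        report["pp_tests"] = env.stage_roi_tests(pp).to_dict("records")
        boot = env.bootstrap_roi_enrichment(raster, roi, n_boot=n_boot_roi, seed=seed)
        report["roi_bootstrap"] = {"observed": boot["observed"], "p": boot["p"]}
        report["pp_mean_in_roi"] = float(pp.loc[pp["in_roi"], "chl"].mean())
        report["pp_mean_out_roi"] = float(pp.loc[~pp["in_roi"], "chl"].mean())

    # step-length fits per stage and scale
    fits = st.stage_scale_comparison(raw_by_stage, speed_threshold=speed_thr)
    report["step_fits"] = fits.to_dict("records")
    return report
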