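"""Synthetic GPS / TDR / chlorophyll data with known ground truth.

Every downstream stage of the pipeline (trip segmentation, dive
detection, route clustering, step-length fitting, productivity
sampling) is exercised against data produced here, so each generated
record carries a traceable truth entry.

The generated cohort emulates a central-place-foraging seabird study:
birds commute from a colony to a foraging destination, perform
area-restricted search (ARS) whose displacement lengths follow either a
truncated power law (Levy-like) or a shifted exponential, dive in bouts
while searching, and return.  Chick-rearing birds head for a chlorophyll
hotspot inside a region of interest (ROI) west of the colony; incubating
birds disperse more widely.  GPS fixes are taken at a nominal 5-min
interval with isotropic Gaussian noise; the depth trace is 1 Hz with
surface noise and optional linear sensor drift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .geo import LocalProjection

#: reference epoch for all synthetic timestamps (UTC)
EPOCH = pd.Timestamp("2012-06-01T00:00:00Z")

#: hard cap on power-law step draws inside trips, metres
LEVY_TRUNCATION_M = 100_000.0


@dataclass
class ROIBox:
    """Closed lon/lat bounding box (degrees)."""

    lon_min: float = -5.73
    lon_max: float = -5.30
    lat_min: float = 51.65
    lat_max: float = 51.82

    def __post_init__(self):
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError("ROI must satisfy min < max on both axes")


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults follow the emulated study design: 5-min GPS sampling,
    ~14 m/s commuting flight, power-law ARS displacements with scaling
    exponent ``mu_true`` and minimum step ``l_min``, 18 birds with a
    mean of ~3.1 trips each, and consumer-GPS noise of 15 m (1 SD per
    axis).
    """

    seed: int = 0
    colony: tuple[float, float] = (-5.30, 51.74)  # lon, lat
    n_birds: int = 18
    trips_per_bird: float = 3.1          # mean; per-bird counts jittered
    trips_per_bird_sd: float = 1.8
    stage: str | None = None             # None = mixed cohort
    fix_interval: float = 300.0          # s
    flight_speed: float = 14.0           # m/s
    search_kernel: str = "powerlaw"      # or "exponential"
    mu_true: float = 2.0                 # power-law scaling exponent
    exp_rate: float = 1.0 / 300.0        # 1/m, exponential kernel
    l_min: float = 1000.0                # m
    gps_noise_sd: float = 15.0           # m, per planar axis
    dive_depth_range: tuple[float, float] = (2.0, 20.0)  # m
    roi: ROIBox = field(default_factory=ROIBox)
    ars_steps: int = 25                  # mean ARS displacements per trip
    drift_speed: float = 0.3             # m/s while resting on water
    surface_noise_sd: float = 0.02       # m, TDR surface noise
    tdr_drift_rate: float = 1e-5         # m/s, sensor drift
    colony_radius_km: float = 1.0

    def __post_init__(self):
        if self.fix_interval <= 0:
            raise ValueError("fix_interval must be > 0")
        if self.l_min <= 0:
            raise ValueError("l_min must be > 0")
        if self.search_kernel == "powerlaw" and self.mu_true <= 1:
            raise ValueError("mu_true must exceed 1 for a power-law kernel")
        if self.search_kernel not in ("powerlaw", "exponential"):
            raise ValueError(f"unknown search_kernel {self.search_kernel!r}")
        if self.stage not in (None, "incubation", "chick_rearing"):
            raise ValueError(f"unknown stage {self.stage!r}")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# step-length kernels
# ---------------------------------------------------------------------------

def gen_levy_steps(n: int, mu: float, l_min: float, seed) -> np.ndarray:
    """Draw ``n`` i.i.d. power-law (Pareto) step lengths.

    The step-length density is (mu - 1) * l_min**(mu - 1) * l**(-mu) on
    [l_min, inf), sampled by inversion: l = l_min * u**(1 / (1 - mu)).
    """
    if mu <= 1:
        raise ValueError("power-law exponent mu must exceed 1")
    if l_min <= 0:
        raise ValueError("l_min must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    u = _rng(seed).uniform(size=n)
    return l_min * u ** (1.0 / (1.0 - mu))


def gen_exponential_steps(n: int, rate: float, l_min: float, seed) -> np.ndarray:
    """Draw ``n`` i.i.d. shifted-exponential step lengths l_min + Exp(rate)."""
    if rate <= 0:
        raise ValueError("exponential rate must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    return l_min + _rng(seed).exponential(scale=1.0 / rate, size=n)


def _draw_kernel_steps(n: int, config: SimConfig, rng) -> np.ndarray:
    if config.search_kernel == "powerlaw":
        return gen_levy_steps(n, config.mu_true, config.l_min, rng)
    return gen_exponential_steps(n, config.exp_rate, config.l_min, rng)


# ---------------------------------------------------------------------------
# single trips
# ---------------------------------------------------------------------------

def _segment_point_distance(a, b, p) -> float:
    """Distance from point ``p`` to the segment ``a``-``b``."""
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(a + t * ab - p))


def _ars_waypoints(start_xy, heading, lengths, rng,
                   keepout_xy=(0.0, 0.0), keepout_radius=2000.0,
                   tether_xy=None, tether_radius=None):
    """Build ARS waypoints from step lengths with uniform turning angles.

    Headings that would carry the bird inside the colony keep-out disc
    (or outside an optional tether disc around the destination) are
    resampled; step lengths are never altered except when no heading can
    satisfy the tether, in which case the step is clipped to the disc and
    flagged.  Returns (xy array, turn angles, realized lengths, clipped flags).
    """
    pos = np.asarray(start_xy, float).copy()
    keepout = np.asarray(keepout_xy, float)
    tether = None if tether_xy is None else np.asarray(tether_xy, float)
    pts, turns, realized, clipped = [], [], [], []
    for l in lengths:
        l_try = float(l)
        was_clipped = False
        if tether is not None and tether_radius is not None:
            # longest chord from pos inside the tether disc
            reach = np.linalg.norm(pos - tether) + tether_radius
            if l_try > reach:
                l_try = max(0.5 * tether_radius, reach * 0.9)
                was_clipped = True
        for _ in range(60):
            turn = rng.uniform(-np.pi, np.pi)
            h = heading + turn
            cand = pos + l_try * np.array([np.sin(h), np.cos(h)])
            # the whole hop, not just its endpoint, must avoid the colony
            ok = _segment_point_distance(pos, cand, keepout) > keepout_radius
            if ok and tether is not None and tether_radius is not None:
                ok = np.linalg.norm(cand - tether) <= tether_radius
            if ok:
                break
        else:  # pragma: no cover - essentially unreachable
            cand = pos + l_try * np.array([np.sin(heading), np.cos(heading)])
            turn = 0.0
        heading = heading + turn
        pos = cand
        pts.append(pos.copy())
        turns.append(turn)
        realized.append(l_try)
        clipped.append(was_clipped)
    return np.array(pts), np.array(turns), np.array(realized), np.array(clipped)


def gen_central_place_trip(config: SimConfig, destination_bearing: float, seed,
                           distal_distance: float | None = None,
                           n_ars_steps: int | None = None,
                           n_rests: int = 1,
                           ars_tether_radius: float | None = None,
                           start_s: float = 0.0):
    """Generate one foraging trip as GPS fixes plus ground truth.

    Three phases: an outbound commute at ``flight_speed`` along
    ``destination_bearing`` (degrees clockwise from north), ARS whose
    displacement lengths come from the configured kernel (power-law
    draws truncated at 100 km, recorded in the truth) and whose headings
    turn by uniform random angles, and an inbound commute.  ``n_rests``
    surface-drift rest bouts are inserted at ARS waypoints.  The
    continuous trajectory is sampled every ``fix_interval`` seconds
    (plus the exact trip end and the maximum-range waypoint) and
    isotropic Gaussian GPS noise of ``gps_noise_sd`` is added; the first
    and last fixes are at the colony.

    Returns ``(fixes, truth)`` where ``fixes`` is a DataFrame with
    columns ``t_s, x, y`` (planar metres, colony at the origin) and
    ``truth`` records the radius-crossing times, commanded geometry, and
    the true ARS step sequence.
    """
    rng = _rng(seed)
    if distal_distance is None:
        distal_distance = rng.normal(25_000.0, 5_000.0)
    distal_distance = float(max(distal_distance, 3_000.0))
    if distal_distance <= config.colony_radius_km * 1000.0:
        raise ValueError("destination must lie beyond the colony radius")
    if n_ars_steps is None:
        n_ars_steps = max(3, int(round(rng.normal(config.ars_steps, config.ars_steps / 4))))

    b = np.radians(destination_bearing)
    dest = distal_distance * np.array([np.sin(b), np.cos(b)])

    lengths = _draw_kernel_steps(n_ars_steps, config, rng)
    truncated = lengths > LEVY_TRUNCATION_M
    lengths = np.minimum(lengths, LEVY_TRUNCATION_M)

    ars_xy, turns, realized, clipped = _ars_waypoints(
        dest, b, lengths, rng,
        keepout_radius=2 * config.colony_radius_km * 1000.0,
        tether_xy=dest if ars_tether_radius else None,
        tether_radius=ars_tether_radius)

    # waypoints: (t, x, y); continuous motion at flight_speed, rests inserted
    way = [(0.0, 0.0, 0.0), (distal_distance / config.flight_speed, *dest)]
    t = way[-1][0]
    rest_at = set(rng.choice(n_ars_steps, size=min(n_rests, n_ars_steps), replace=False)
                  ) if n_rests > 0 else set()
    rest_windows = []
    prev = dest
    for i, p in enumerate(ars_xy):
        hop = np.linalg.norm(p - prev)
        t += hop / config.flight_speed
        way.append((t, p[0], p[1]))
        if i in rest_at:
            dur = rng.uniform(600.0, 1800.0)
            drift_h = rng.uniform(-np.pi, np.pi)
            q = p + config.drift_speed * dur * np.array([np.sin(drift_h), np.cos(drift_h)])
            rest_windows.append((start_s + t, start_s + t + dur))
            t += dur
            way.append((t, q[0], q[1]))
            p = q
        prev = p
    # inbound commute
    t += np.linalg.norm(prev) / config.flight_speed
    way.append((t, 0.0, 0.0))
    way = np.array(way)
    t_end = float(way[-1, 0])

    # sample times: regular grid plus trip end and the max-range waypoint
    ranges = np.hypot(way[:, 1], way[:, 2])
    t_peak = float(way[np.argmax(ranges), 0])
    times = np.arange(0.0, t_end, config.fix_interval)
    times = np.unique(np.concatenate([times, [t_peak, t_end]]))
    x = np.interp(times, way[:, 0], way[:, 1])
    y = np.interp(times, way[:, 0], way[:, 2])
    if config.gps_noise_sd > 0:
        x = x + rng.normal(0.0, config.gps_noise_sd, size=times.size)
        y = y + rng.normal(0.0, config.gps_noise_sd, size=times.size)
    # first and last fixes are at the colony
    x[0] = y[0] = x[-1] = y[-1] = 0.0

    r_m = config.colony_radius_km * 1000.0
    truth = {
        "t_start_s": start_s + r_m / config.flight_speed,
        "t_end_s": start_s + t_end - np.linalg.norm(prev) / config.flight_speed
        + (np.linalg.norm(prev) - r_m) / config.flight_speed,
        "depart_s": start_s,
        "return_s": start_s + t_end,
        "destination_bearing_deg": float(destination_bearing),
        "distal_distance_m": distal_distance,
        "max_range_m": float(ranges.max()),
        "kernel": config.search_kernel,
        "mu_true": config.mu_true if config.search_kernel == "powerlaw" else None,
        "step_lengths_m": [float(v) for v in realized],
        "turn_angles_rad": [float(v) for v in turns],
        "steps_truncated": [bool(v) for v in truncated],
        "steps_clipped": [bool(v) for v in clipped],
        "rest_windows_s": [(float(a), float(b)) for a, b in rest_windows],
        "ars_window_s": (start_s + distal_distance / config.flight_speed,
                         start_s + float(way[-2, 0])),
    }
    fixes = pd.DataFrame({"t_s": start_s + times, "x": x, "y": y})
    return fixes, truth


# ---------------------------------------------------------------------------
# route families
# ---------------------------------------------------------------------------

def gen_route_families(k_families: int, n_per_family: int | list[int], jitter_m: float,
                       seed, separation_m: float = 10_000.0, n_points: int = 40,
                       route_length_m: float = 30_000.0):
    """Jittered copies of per-family template routes, with labels.

    Family templates are gently curved outbound paths from the origin,
    laterally separated by ``separation_m``; each member adds isotropic
    Gaussian jitter of ``jitter_m`` to every template point.  Returns
    ``(paths, labels)`` where each path is an (n_points, 2) planar array.
    """
    rng = _rng(seed)
    counts = ([n_per_family] * k_families if np.isscalar(n_per_family)
              else list(n_per_family))
    if len(counts) != k_families:
        raise ValueError("n_per_family list must have k_families entries")
    s = np.linspace(0.0, route_length_m, n_points)
    paths, labels = [], []
    for f in range(k_families):
        offset = f * separation_m
        wiggle = 0.05 * route_length_m * np.sin(2 * np.pi * s / route_length_m + f)
        template = np.column_stack([offset + wiggle, s])
        for _ in range(counts[f]):
            noise = rng.normal(0.0, jitter_m, size=template.shape) if jitter_m > 0 else 0.0
            paths.append(template + noise)
            labels.append(f)
    return paths, np.array(labels)


# ---------------------------------------------------------------------------
# TDR traces
# ---------------------------------------------------------------------------

def gen_tdr_trace(dive_plan, duration_s: float, surface_noise_sd: float = 0.02,
                  drift_rate: float = 0.0, seed=0) -> pd.DataFrame:
    """1 Hz depth series: U-shaped dives over surface noise plus linear drift.

    ``dive_plan`` is a list of (start_s, duration_s, max_depth_m); dives
    must not overlap.  Depth is positive down; the surface reads 0 plus
    noise plus ``drift_rate * t``.
    """
    plan = sorted((float(a), float(d), float(m)) for a, d, m in dive_plan)
    for (a0, d0, _), (a1, _, _) in zip(plan, plan[1:]):
        if a0 + d0 > a1:
            raise ValueError("dive plan contains overlapping dives")
    rng = _rng(seed)
    n = int(round(duration_s))
    t = np.arange(n, dtype=float)
    depth = drift_rate * t
    if surface_noise_sd > 0:
        depth = depth + rng.normal(0.0, surface_noise_sd, size=n)
    for start, dur, max_d in plan:
        i0, i1 = int(np.ceil(start)), min(n, int(np.floor(start + dur)))
        if i1 <= i0:
            continue
        tt = t[i0:i1] - start
        ramp = min(max_d / 1.5, 0.4 * dur)  # s of descent/ascent at ~1.5 m/s
        profile = np.minimum.reduce([tt / ramp * max_d if ramp > 0 else np.full_like(tt, max_d),
                                     (dur - tt) / ramp * max_d if ramp > 0 else np.full_like(tt, max_d),
                                     np.full_like(tt, max_d)])
        depth[i0:i1] += np.clip(profile, 0.0, None)
    return pd.DataFrame({"t_s": t, "depth_m": depth})


def gen_dive_plan(windows, depth_range, rng,
                  fast_mean_s: float = 20.0, slow_mean_s: float = 600.0,
                  p_fast: float = 0.7, dive_dur_range=(20.0, 60.0)):
    """Bout-structured dive plan inside the given (start, end) windows.

    Surface intervals between consecutive dives are drawn from the
    two-process exponential mixture p_fast * Exp(1/fast_mean) +
    (1 - p_fast) * Exp(1/slow_mean), producing dive bouts separated by
    longer gaps — the structure the bout-ending criterion recovers.
    """
    plan = []
    for w0, w1 in windows:
        t = w0 + rng.exponential(slow_mean_s / 2)
        while True:
            dur = rng.uniform(*dive_dur_range)
            if t + dur > w1:
                break
            plan.append((t, dur, rng.uniform(*depth_range)))
            mean = fast_mean_s if rng.uniform() < p_fast else slow_mean_s
            t += dur + rng.exponential(mean)
    return plan


# ---------------------------------------------------------------------------
# chlorophyll raster
# ---------------------------------------------------------------------------

def gen_pp_raster(lons, lats, times, background_mean: float = 5.0,
                  noise_sd: float = 1.0, hotspot_box: ROIBox | None = None,
                  hotspot_delta: float = 0.0, seed=0) -> xr.Dataset:
    """Gridded chlorophyll-a field (mg/m3) with an optional hotspot.

    Cells inside ``hotspot_box`` are elevated by ``hotspot_delta`` on
    top of Gaussian noise around ``background_mean``; values are clipped
    at 0.  Dimensions are (time, lat, lon) with monotone coordinates.
    """
    lons = np.sort(np.asarray(lons, float))
    lats = np.sort(np.asarray(lats, float))
    rng = _rng(seed)
    shape = (len(times), len(lats), len(lons))
    chl = background_mean + rng.normal(0.0, noise_sd, size=shape)
    if hotspot_box is not None and hotspot_delta != 0.0:
        in_lon = (lons >= hotspot_box.lon_min) & (lons <= hotspot_box.lon_max)
        in_lat = (lats >= hotspot_box.lat_min) & (lats <= hotspot_box.lat_max)
        chl[:, np.ix_(in_lat, in_lon)[0], np.ix_(in_lat, in_lon)[1]] += hotspot_delta
    chl = np.clip(chl, 0.0, None)
    ds = xr.Dataset(
        {"chl": (("time", "lat", "lon"), chl)},
        coords={"time": np.asarray(times), "lat": lats, "lon": lons},
        attrs={"description": "synthetic chlorophyll-a (mg m-3)"},
    )
    if hotspot_box is not None:
        ds.attrs["hotspot"] = json.dumps(asdict(hotspot_box))
        ds.attrs["hotspot_delta"] = hotspot_delta
    return ds


# ---------------------------------------------------------------------------
# whole-cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortPaths:
    root: Path
    gps: dict          # bird_id -> csv path
    tdr: dict          # bird_id -> csv path
    raster: Path
    truth: Path


def _bird_stage(i: int, n_birds: int, forced: str | None) -> str:
    if forced is not None:
        return forced
    return "incubation" if i < n_birds // 2 else "chick_rearing"


def gen_cohort(config: SimConfig, outdir: str | Path | None = None):
    """Generate a full synthetic study: tracks, TDR traces, raster, truth.

    Deterministic given ``config.seed``.  Chick-rearing birds are sent
    to a chlorophyll hotspot inside the ROI (ARS tethered near the
    destination); incubating birds disperse over bearings 90-160 deg
    with larger ranges.  If ``outdir`` is given, writes one GPS CSV and
    one TDR CSV per bird, a netCDF raster, and a JSON truth table, and
    returns ``(CohortPaths, data)``; otherwise returns ``(None, data)``
    with everything in memory.
    """
    rng = np.random.default_rng(config.seed)
    proj = LocalProjection(*config.colony)
    roi = config.roi
    hotspot_lon = 0.5 * (roi.lon_min + roi.lon_max)
    hotspot_lat = 0.5 * (roi.lat_min + roi.lat_max)
    hx, hy = proj.forward(hotspot_lon, hotspot_lat)

    birds, truth_trips, truth_dives = {}, [], {}
    for i in range(config.n_birds):
        bird_id = f"bird_{i:02d}"
        stage = _bird_stage(i, config.n_birds, config.stage)
        year = 2011 + int(rng.integers(0, 3))
        n_trips = int(np.clip(round(rng.normal(config.trips_per_bird,
                                               config.trips_per_bird_sd)), 1, 7))
        t_cursor = float(rng.uniform(0, 6 * 3600))
        fixes_parts, windows = [], []
        for j in range(n_trips):
            if stage == "chick_rearing":
                dx, dy = rng.normal(hx, 1500.0), rng.normal(hy, 1500.0)
                bearing = np.degrees(np.arctan2(dx, dy))
                distal = float(np.hypot(dx, dy))
                tether = 12_000.0
            else:
                # dispersed foraging: any bearing, larger and more variable range
                bearing = float(rng.uniform(-180.0, 180.0))
                distal = float(np.clip(rng.normal(34_000.0, 9_000.0), 15_000.0, 55_000.0))
                tether = 25_000.0
            trip_fixes, tr = gen_central_place_trip(
                config, bearing, rng, distal_distance=distal,
                ars_tether_radius=tether, start_s=t_cursor)
            tr.update({"bird_id": bird_id, "stage": stage, "year": year, "trip": j})
            truth_trips.append(tr)
            windows.append(tr["ars_window_s"])
            fixes_parts.append(trip_fixes)
            t_cursor = tr["return_s"] + float(rng.uniform(3600.0, 3 * 3600.0))
            # colony dwell fixes between trips (drifting near the nest)
            if j < n_trips - 1:
                dwell_t = np.arange(tr["return_s"] + config.fix_interval,
                                    t_cursor, config.fix_interval)
                if dwell_t.size:
                    fixes_parts.append(pd.DataFrame({
                        "t_s": dwell_t,
                        "x": rng.normal(0.0, 20.0, dwell_t.size),
                        "y": rng.normal(0.0, 20.0, dwell_t.size)}))
        fixes = pd.concat(fixes_parts, ignore_index=True).sort_values("t_s")
        fixes = fixes[~fixes["t_s"].duplicated()].reset_index(drop=True)
        lon, lat = proj.inverse(fixes["x"].to_numpy(), fixes["y"].to_numpy())
        span = float(fixes["t_s"].iloc[-1]) + 1.0
        plan = gen_dive_plan(windows, config.dive_depth_range, rng)
        tdr = gen_tdr_trace(plan, span, config.surface_noise_sd,
                            config.tdr_drift_rate, rng)
        truth_dives[bird_id] = [(float(a), float(d), float(m)) for a, d, m in plan]
        birds[bird_id] = {
            "stage": stage, "year": year,
            "gps": pd.DataFrame({"t_s": fixes["t_s"], "lon": lon, "lat": lat}),
            "gps_xy": fixes, "tdr": tdr,
        }

    # raster covering colony surroundings, hotspot inside the ROI
    pad = 0.45
    lons = np.arange(roi.lon_min - pad, roi.lon_max + pad, 0.0075)  # ~500 m
    lats = np.arange(roi.lat_min - pad, roi.lat_max + pad, 0.0045)
    raster_times = np.arange(0.0, 6 * 86400.0, 43200.0)  # seconds, 12-h slices
    raster = gen_pp_raster(lons, lats, raster_times, background_mean=5.0,
                           noise_sd=1.0, hotspot_box=roi, hotspot_delta=5.0,
                           seed=rng)

    truth = {
        "config": {**{k: v for k, v in asdict(config).items() if k != "roi"},
                   "roi": asdict(config.roi)},
        "trips": truth_trips,
        "dives": truth_dives,
        "birds": {b: {"stage": d["stage"], "year": d["year"]} for b, d in birds.items()},
        "raster": {"hotspot": asdict(roi), "hotspot_delta": 5.0,
                   "background_mean": 5.0, "noise_sd": 1.0},
    }
    data = {"birds": birds, "raster": raster, "truth": truth, "projection": proj}
    if outdir is None:
        return None, data

    outdir = Path(outdir)
    (outdir / "gps").mkdir(parents=True, exist_ok=True)
    (outdir / "tdr").mkdir(parents=True, exist_ok=True)
    gps_paths, tdr_paths = {}, {}
    for bird_id, d in birds.items():
        g = d["gps"].copy()
        g["timestamp"] = (EPOCH + pd.to_timedelta(g.pop("t_s").round().astype(int), unit="s")
                          ).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
        gp = outdir / "gps" / f"{bird_id}.csv"
        g[["timestamp", "lat", "lon"]].to_csv(gp, index=False, float_format="%.6f",
                                              lineterminator="\n")
        gps_paths[bird_id] = gp
        td = d["tdr"].copy()
        td["timestamp"] = (EPOCH + pd.to_timedelta(td.pop("t_s").astype(int), unit="s")
                           ).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
        td["temp_C"] = 12.0
        tp = outdir / "tdr" / f"{bird_id}.csv"
        td[["timestamp", "depth_m", "temp_C"]].to_csv(tp, index=False, float_format="%.4f",
                                                      lineterminator="\n")
        tdr_paths[bird_id] = tp
    raster_path = outdir / "chl.nc"
    raster.to_netcdf(raster_path, engine="scipy")
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return CohortPaths(outdir, gps_paths, tdr_paths, raster_path, truth_path), data
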