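"""GPS/TDR ingestion, projection, 1 Hz spline interpolation, activity labels."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.stats import gaussian_kde

from .geo import LocalProjection

log = logging.getLogger(__name__)


class InputError(ValueError):
    """Raised for unreadable or malformed input files."""


def read_gps(path: str | Path) -> pd.DataFrame:
    """Read a GPS CSV (columns timestamp, lat, lon) into a sorted fix table.

    Timestamps are parsed as UTC; rows are sorted by time and duplicate
    timestamps dropped keeping the first occurrence (with a warning).
    Unparseable rows raise :class:`InputError` listing the offending lines.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as e:
        raise InputError(f"{path}: {e}") from e
    required = {"timestamp", "lat", "lon"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if df.empty:
        raise InputError(f"{path}: no data rows")
    t = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601", errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    bad = t.isna() | lat.isna() | lon.isna() | (lat.abs() > 90) | (lon.abs() > 180)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise InputError(f"{path}: unparseable or out-of-range rows at lines {lines}")
    out = pd.DataFrame({"t": t, "lat": lat, "lon": lon}).sort_values("t", kind="stable")
    dup = out["t"].duplicated()
    if dup.any():
        log.warning("%s: dropped %d duplicate timestamps", path, int(dup.sum()))
        out = out[~dup]
    return out.reset_index(drop=True)


def read_tdr(path: str | Path, max_gap_s: float = 5.0) -> pd.DataFrame:
    """Read a TDR CSV (timestamp, depth_m[, temp_C]); flags spacing gaps."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as e:
        raise InputError(f"{path}: {e}") from e
    if not {"timestamp", "depth_m"}.issubset(df.columns):
        raise InputError(f"{path}: needs columns timestamp, depth_m")
    t = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601", errors="coerce")
    if t.isna().any():
        raise InputError(f"{path}: unparseable timestamps")
    out = pd.DataFrame({"t": t, "depth_m": pd.to_numeric(df["depth_m"], errors="coerce")})
    if "temp_C" in df.columns:
        out["temp_C"] = pd.to_numeric(df["temp_C"], errors="coerce")
    out = out.sort_values("t", kind="stable").reset_index(drop=True)
    dt = out["t"].diff().dt.total_seconds().to_numpy()[1:]
    n_gaps = int((dt > max_gap_s).sum())
    if n_gaps:
        log.warning("%s: %d gaps longer than %.0f s in the 1 Hz series", path, n_gaps, max_gap_s)
    out.attrs["n_gaps"] = n_gaps
    return out


def project(track: pd.DataFrame, reference_lonlat: tuple[float, float],
            max_extent_m: float = 500_000.0) -> pd.DataFrame:
    """Add planar x/y (metres) about a reference point; inverse-exact."""
    proj = LocalProjection(*reference_lonlat)
    x, y = proj.forward(track["lon"].to_numpy(), track["lat"].to_numpy())
    if np.hypot(x, y).max(initial=0.0) > max_extent_m:
        log.warning("fixes further than %.0f km from the projection centre",
                    max_extent_m / 1000)
    out = track.copy()
    out["x"], out["y"] = x, y
    out.attrs["projection"] = proj
    return out


def _seconds(t: pd.Series) -> np.ndarray:
    if np.issubdtype(t.dtype, np.datetime64) or isinstance(t.dtype, pd.DatetimeTZDtype):
        return (t - t.iloc[0]).dt.total_seconds().to_numpy()
    return t.to_numpy(dtype=float)


def interpolate_1hz(track: pd.DataFrame, max_gap_s: float = 1800.0) -> pd.DataFrame:
    """Natural cubic spline through (t, x) and (t, y), evaluated each second.

    Speed is the magnitude of the spline's planar derivative.  The track
    is split at gaps longer than ``max_gap_s`` and each piece splined
    separately (pieces with fewer than 4 fixes fall back to linear
    interpolation); no extrapolation beyond the first/last fix.
    Returns a DataFrame with ``t_s`` (seconds from the first fix), x, y,
    speed, and a ``segment`` id.
    """
    if len(track) < 4:
        raise ValueError("cubic spline interpolation requires at least 4 fixes")
    ts = _seconds(track["t_s"] if "t_s" in track else track["t"])
    x = track["x"].to_numpy(dtype=float)
    y = track["y"].to_numpy(dtype=float)
    if np.any(np.diff(ts) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    breaks = np.flatnonzero(np.diff(ts) > max_gap_s)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [len(ts)]])
    parts = []
    for seg, (i0, i1) in enumerate(zip(starts, ends)):
        if i1 - i0 < 2:
            continue
        tt = ts[i0:i1]
        grid = np.arange(np.ceil(tt[0]), np.floor(tt[-1]) + 1.0)
        grid = np.union1d(grid, tt)  # keep exact fix times
        if i1 - i0 >= 4:
            sx = CubicSpline(tt, x[i0:i1], bc_type="natural")
            sy = CubicSpline(tt, y[i0:i1], bc_type="natural")
            gx, gy = sx(grid), sy(grid)
            vx, vy = sx(grid, 1), sy(grid, 1)
        else:
            gx = np.interp(grid, tt, x[i0:i1])
            gy = np.interp(grid, tt, y[i0:i1])
            vx = np.gradient(gx, grid)
            vy = np.gradient(gy, grid)
        parts.append(pd.DataFrame({"t_s": grid, "x": gx, "y": gy,
                                   "speed": np.hypot(vx, vy), "segment": seg}))
    out = pd.concat(parts, ignore_index=True)
    out.attrs["t0"] = (track["t"].iloc[0] if "t" in track else None)
    return out


def select_speed_threshold(speeds, grid_size: int = 1024, bw_method=None) -> float:
    """Kernel-density valley between the two largest speed modes (m/s).

    The speed distribution of a commuting diving bird is bimodal —
    drifting/surface speeds near zero and flight speeds an order of
    magnitude higher; the threshold is the density minimum between the
    two highest modes.  A unimodal density raises ValueError (set a
    manual threshold in that case).
    """
    v = np.asarray(speeds, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 10:
        raise ValueError("need at least 10 speed values")
    kde = gaussian_kde(v, bw_method=bw_method)
    grid = np.linspace(v.min(), v.max(), grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    if grid.size and dens[0] > dens[1]:
        peaks = np.concatenate([[0], peaks])
    if dens[-1] > dens[-2]:
        peaks = np.concatenate([peaks, [grid.size - 1]])
    # ignore negligible wiggles; a genuine mode carries real mass
    peaks = peaks[dens[peaks] >= 0.05 * dens.max()]
    if len(peaks) < 2:
        raise ValueError("speed density is unimodal; supply a manual threshold")
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    valley = lo + int(np.argmin(dens[lo:hi + 1]))
    if dens[valley] > 0.8 * dens[top2].min():
        raise ValueError("speed density is effectively unimodal; "
                         "supply a manual threshold")
    thr = float(grid[valley])
    log.info("speed threshold %.2f m/s (modes at %.2f and %.2f m/s)",
             thr, grid[lo], grid[hi])
    return thr


def classify_activity(interp: pd.DataFrame, threshold: float,
                      dive_intervals=()) -> pd.DataFrame:
    """Per-second activity labels: dive > flight > surface.

    A second covered by a detected dive interval is labelled ``dive``
    regardless of speed (pressure is a direct observation); otherwise
    ``flight`` if speed exceeds the threshold, else ``surface``.
    """
    t = interp["t_s"].to_numpy()
    label = np.where(interp["speed"].to_numpy() > threshold, "flight", "surface")
    label = label.astype(object)
    for a, b in dive_intervals:
        label[(t >= a) & (t <= b)] = "dive"
    out = interp[["t_s", "speed"]].copy()
    out["activity"] = label
    return out
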