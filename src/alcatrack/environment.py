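"""Colony bearings, ROI membership, chlorophyll sampling and stage tests.

Bearings theta are measured at the colony, clockwise from true north,
in (-180, 180] (configurable convention: an ``origin_offset`` rotates
the zero direction).  Stage comparisons of bearing distributions use
the two-sample Kolmogorov-Smirnov test on the linear angle scale; a
circular alternative (Kuiper-style) is available but off by default.
Primary productivity (chlorophyll-a) is sampled at dive locations from
a gridded lon x lat x time raster by nearest cell and nearest time
slice, and compared inside vs outside the ROI per breeding stage with
Welch t-tests under a Bonferroni correction for the three comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .geo import initial_bearing
from .simulate import ROIBox

log = logging.getLogger(__name__)

ROI = ROIBox  # canonical ROI type lives with the generator config


def bearing(colony: tuple[float, float], lon, lat,
            origin_offset: float = 0.0):
    """Bearing(s) from the colony to point(s), degrees in (-180, 180].

    Initial great-circle bearing clockwise from north; due south maps
    to +180, never -180.  ``origin_offset`` rotates the zero direction
    (degrees clockwise from north) for alternative conventions.  A
    point coincident with the colony has no bearing and yields NaN.
    """
    theta = initial_bearing(colony[0], colony[1], lon, lat)
    if origin_offset:
        theta = np.asarray(theta) - origin_offset
        theta = (theta + 180.0) % 360.0 - 180.0
        theta = np.where(np.isclose(theta, -180.0), 180.0, theta)
        if np.ndim(lon) == 0:
            theta = float(theta)
    return theta


def ks_compare(sample_a, sample_b) -> dict:
    """Two-sample KS: D = sup |ECDF_a - ECDF_b| with asymptotic p."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    res = stats.ks_2samp(a[np.isfinite(a)], b[np.isfinite(b)], method="asymp")
    return {"D": float(res.statistic), "p": float(res.pvalue)}


def kuiper_compare(sample_a, sample_b) -> dict:
    """Kuiper two-sample statistic V (circular-aware alternative to KS)."""
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / a.size
    fb = np.searchsorted(b, grid, side="right") / b.size
    diff = fa - fb
    return {"V": float(diff.max() - diff.min())}


def in_roi(lon, lat, roi: ROIBox) -> np.ndarray | bool:
    """Closed-box membership test (boundary points are inside)."""
    res = ((np.asarray(lon) >= roi.lon_min) & (np.asarray(lon) <= roi.lon_max)
           & (np.asarray(lat) >= roi.lat_min) & (np.asarray(lat) <= roi.lat_max))
    return bool(res) if np.ndim(lon) == 0 and np.ndim(lat) == 0 else res


def sample_pp(raster: xr.Dataset, time, lon, lat,
              max_time_offset: float = 86400.0, var: str = "chl"):
    """Chlorophyll value of the nearest grid cell and time slice, or NaN.

    Queries outside the grid's lon/lat extent (beyond half a cell of
    the edge), or with no time slice within ``max_time_offset``, return
    NaN and are counted by the caller.
    """
    da = raster[var]
    lons = da["lon"].to_numpy()
    lats = da["lat"].to_numpy()
    times = da["time"].to_numpy()
    half_lon = 0.5 * np.median(np.diff(lons)) if lons.size > 1 else np.inf
    half_lat = 0.5 * np.median(np.diff(lats)) if lats.size > 1 else np.inf
    scalar = np.ndim(lon) == 0
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    time = np.atleast_1d(np.asarray(time, dtype=float))
    out = np.full(lon.shape, np.nan)
    i_lon = np.clip(np.searchsorted(lons, lon), 1, lons.size - 1)
    i_lon = np.where(np.abs(lons[i_lon - 1] - lon) <= np.abs(lons[i_lon] - lon),
                     i_lon - 1, i_lon)
    i_lat = np.clip(np.searchsorted(lats, lat), 1, lats.size - 1)
    i_lat = np.where(np.abs(lats[i_lat - 1] - lat) <= np.abs(lats[i_lat] - lat),
                     i_lat - 1, i_lat)
    i_t = np.clip(np.searchsorted(times, time), 1, times.size - 1)
    i_t = np.where(np.abs(times[i_t - 1] - time) <= np.abs(times[i_t] - time),
                   i_t - 1, i_t)
    ok = ((np.abs(lons[i_lon] - lon) <= half_lon + 1e-12)
          & (np.abs(lats[i_lat] - lat) <= half_lat + 1e-12)
          & (np.abs(times[i_t] - time) <= max_time_offset))
    vals = da.to_numpy()[i_t, i_lat, i_lon]
    out[ok] = vals[ok]
    return float(out[0]) if scalar else out


def pp_sample_table(raster: xr.Dataset, dives: pd.DataFrame, roi: ROIBox,
                    max_time_offset: float = 86400.0) -> pd.DataFrame:
    """PP at each located dive: chl value, stage, in_roi; NaN = missing."""
    located = dives[dives["located"]].copy() if "located" in dives else dives.copy()
    located["chl"] = sample_pp(raster, located["t_start"].to_numpy(),
                               located["lon"].to_numpy(), located["lat"].to_numpy(),
                               max_time_offset=max_time_offset)
    located["in_roi"] = in_roi(located["lon"].to_numpy(), located["lat"].to_numpy(), roi)
    n_missing = int(located["chl"].isna().sum())
    if n_missing:
        log.info("%d of %d dives had no raster coverage", n_missing, len(located))
    return located


def stage_roi_tests(pp: pd.DataFrame, m_tests: int = 3) -> pd.DataFrame:
    """Three Welch t-tests on PP with Bonferroni-adjusted p-values.

    (1) inside vs outside the ROI during incubation, (2) inside vs
    outside during chick rearing, (3) inside-ROI incubation vs
    inside-ROI chick rearing.  Two-tailed Welch t (unequal variances);
    p_adj = min(1, m * p).
    """
    def grp(stage, roi_flag):
        sel = pp[(pp["stage"] == stage) & (pp["in_roi"] == roi_flag)]["chl"].dropna()
        return sel.to_numpy()

    comparisons = [
        ("incubation_in_vs_out", grp("incubation", True), grp("incubation", False)),
        ("chick_rearing_in_vs_out", grp("chick_rearing", True), grp("chick_rearing", False)),
        ("in_roi_incubation_vs_chick", grp("incubation", True), grp("chick_rearing", True)),
    ]
    rows = []
    for name, a, b in comparisons:
        if a.size < 2 or b.size < 2:
            rows.append({"comparison": name, "t": np.nan, "df": np.nan,
                         "p": np.nan, "p_adj": np.nan,
                         "n_a": a.size, "n_b": b.size})
            continue
        res = stats.ttest_ind(a, b, equal_var=False)
        p = float(res.pvalue)
        rows.append({"comparison": name, "t": float(res.statistic),
                     "df": float(res.df), "p": p,
                     "p_adj": min(1.0, m_tests * p), "n_a": a.size, "n_b": b.size})
    return pd.DataFrame(rows)


def bootstrap_roi_enrichment(raster: xr.Dataset, roi: ROIBox, n_boot: int = 1000,
                             seed=0, var: str = "chl") -> dict:
    """Is mean chlorophyll inside the ROI higher than in random boxes?

    The observed statistic is the time-mean chl averaged over ROI
    cells; the null distribution is the same statistic for ``n_boot``
    ROI-sized boxes placed uniformly over the raster extent, rejecting
    placements that overlap the ROI.  p = fraction of null >= observed.
    """
    da = raster[var]
    lons = da["lon"].to_numpy()
    lats = da["lat"].to_numpy()
    field = da.mean("time").to_numpy()  # (lat, lon)
    w = roi.lon_max - roi.lon_min
    h = roi.lat_max - roi.lat_min
    if w >= lons.max() - lons.min() or h >= lats.max() - lats.min():
        raise ValueError("raster extent smaller than the ROI")

    def box_mean(lon0, lat0):
        sel = field[np.ix_((lats >= lat0) & (lats <= lat0 + h),
                           (lons >= lon0) & (lons <= lon0 + w))]
        return float(sel.mean()) if sel.size else np.nan

    observed = box_mean(roi.lon_min, roi.lat_min)
    rng = np.random.default_rng(seed)
    null = np.empty(n_boot)
    i = 0
    attempts = 0
    while i < n_boot:
        attempts += 1
        if attempts > 100 * n_boot:
            raise RuntimeError("could not place non-overlapping null boxes")
        lon0 = rng.uniform(lons.min(), lons.max() - w)
        lat0 = rng.uniform(lats.min(), lats.max() - h)
        overlaps = not (lon0 + w < roi.lon_min or lon0 > roi.lon_max
                        or lat0 + h < roi.lat_min or lat0 > roi.lat_max)
        if overlaps:
            continue
        m = box_mean(lon0, lat0)
        if np.isnan(m):
            continue
        null[i] = m
        i += 1
    p = float((null >= observed).mean())
    return {"observed": observed, "null": null, "p": p}
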