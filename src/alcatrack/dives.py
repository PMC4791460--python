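"""Depth-trace processing: drift correction, dive detection, bout structure.

Dives are submergences deeper than 1 m (shallower excursions are
typically bathing).  The pressure sensor drifts slowly, so a running
surface baseline — a low quantile of depth in a sliding window — is
subtracted first (zero-offset correction).  Bout structure of the
inter-dive surface intervals is modelled as a two-process exponential
mixture fitted by maximum likelihood (EM); the bout-ending criterion
t_bec is the interval length at which the fast (within-bout) and slow
(between-bout) process densities, weighted by their mixture
proportions, are equal:

    t_bec = ln((p_f * lam_f) / (p_s * lam_s)) / (lam_f - lam_s)

Intervals shorter than t_bec are within-bout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import percentile_filter

log = logging.getLogger(__name__)


@dataclass
class DiveRecord:
    t_start: float       # s
    t_end: float         # s
    max_depth: float     # m
    duration: float      # s
    lon: float | None = None
    lat: float | None = None
    located: bool = False


@dataclass
class BoutModel:
    lambda_fast: float   # 1/s
    lambda_slow: float   # 1/s
    p_fast: float        # mixture weight of the fast process
    p_slow: float
    t_bec: float | None  # s; None when the fit is degenerate
    degenerate: bool
    loglik: float


def zero_offset_correct(depth: np.ndarray, window_s: int = 600,
                        surface_quantile: float = 0.10,
                        submergence_margin: float = 0.5) -> np.ndarray:
    """Subtract a running surface baseline from a 1 Hz depth series.

    Two stages: a sliding-window low quantile (``surface_quantile``
    within ``window_s``) gives a rough surface level that is robust to
    dives occupying most of a window; samples more than
    ``submergence_margin`` below that rough surface are treated as
    submerged and masked, and the baseline is the running median of the
    remaining surface samples (interpolated across masked spans).  A
    low quantile alone would under-shoot a drifting surface by about
    0.4 * drift_rate * window; the masked median tracks it exactly.
    Negative corrected depths are clipped to 0.
    """
    depth = np.asarray(depth, dtype=float)
    if window_s > depth.size:
        raise ValueError("ZOC window longer than the series")
    rough = percentile_filter(depth, percentile=100 * surface_quantile,
                              size=window_s, mode="nearest")
    surface = np.where(depth <= rough + submergence_margin, depth, np.nan)
    # odd-reflection padding preserves linear trends at the edges, so a
    # drifting surface is tracked without boundary lag
    w = int(window_s)
    first = surface[np.isfinite(surface)][0] if np.isfinite(surface).any() else 0.0
    last = surface[np.isfinite(surface)][-1] if np.isfinite(surface).any() else 0.0
    left = 2 * first - surface[w:0:-1]
    right = 2 * last - surface[-2:-w - 2:-1]
    padded = np.concatenate([left, surface, right])
    baseline = (pd.Series(padded)
                .rolling(w, center=True, min_periods=max(3, w // 20))
                .median().ffill().bfill().to_numpy())[w:w + depth.size]
    baseline = np.where(np.isfinite(baseline), baseline, rough)
    return np.clip(depth - baseline, 0.0, None)


def detect_dives(depth: np.ndarray, min_depth: float = 1.0,
                 surface_band: float = 0.1, t0: float = 0.0) -> list[DiveRecord]:
    """Maximal submergence intervals exceeding ``min_depth``.

    A dive is a maximal run of samples deeper than the surface band
    (0.1 m by default — exact-zero crossings are unstable under sensor
    noise) whose maximum depth exceeds ``min_depth``.  Returns disjoint,
    time-ordered records; times are sample indices plus ``t0``.
    """
    depth = np.asarray(depth, dtype=float)
    wet = depth > surface_band
    if not wet.any():
        return []
    edges = np.diff(wet.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1  # exclusive
    if wet[0]:
        starts = np.concatenate([[0], starts])
    if wet[-1]:
        ends = np.concatenate([ends, [wet.size]])
    out = []
    for i0, i1 in zip(starts, ends):
        m = float(depth[i0:i1].max())
        if m > min_depth:
            out.append(DiveRecord(t_start=t0 + float(i0), t_end=t0 + float(i1 - 1),
                                  max_depth=m, duration=float(i1 - i0)))
    return out


def inter_dive_intervals(dives) -> np.ndarray:
    """Surface intervals (s) between consecutive detected dives."""
    if len(dives) < 2:
        return np.empty(0)
    starts = np.array([d.t_start for d in dives])
    ends = np.array([d.t_end for d in dives])
    return starts[1:] - ends[:-1]


def bout_ending_criterion(intervals, max_iter: int = 500, tol: float = 1e-10,
                          min_rate_ratio: float = 1.5) -> BoutModel:
    """ML fit of a two-process exponential mixture to surface intervals.

    EM on raw intervals (statistically efficient, unlike log-survivorship
    regression).  The fit is flagged degenerate — and t_bec withheld —
    when one process vanishes (weight < 1e-3) or the two rates are
    closer than ``min_rate_ratio``.  Fewer than ~50 intervals makes the
    fit unstable; a warning is logged below that.
    """
    x = np.asarray(intervals, dtype=float)
    x = x[x > 0]
    if x.size < 5:
        raise ValueError("need at least 5 positive intervals")
    if x.size < 50:
        log.warning("only %d intervals; bout fit may be unstable", x.size)
    med = np.median(x)
    lam_f = 1.0 / max(np.mean(x[x <= med]), 1e-9)
    lam_s = 1.0 / max(np.mean(x[x > med]), np.mean(x))
    if lam_s >= lam_f:
        lam_s = lam_f / 10.0
    p = 0.5
    ll_old = -np.inf
    for _ in range(max_iter):
        log_f = np.log(p) + np.log(lam_f) - lam_f * x
        log_s = np.log1p(-p) + np.log(lam_s) - lam_s * x
        m = np.maximum(log_f, log_s)
        denom = m + np.log(np.exp(log_f - m) + np.exp(log_s - m))
        w = np.exp(log_f - denom)
        ll = float(denom.sum())
        p = float(np.clip(w.mean(), 1e-12, 1 - 1e-12))
        lam_f = float(w.sum() / max((w * x).sum(), 1e-300))
        lam_s = float((1 - w).sum() / max(((1 - w) * x).sum(), 1e-300))
        if lam_f < lam_s:  # keep the fast process first
            lam_f, lam_s, p = lam_s, lam_f, 1 - p
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    degenerate = (p < 1e-3 or p > 1 - 1e-3 or lam_f / lam_s < min_rate_ratio)
    t_bec = None
    if not degenerate:
        t_bec = float(np.log((p * lam_f) / ((1 - p) * lam_s)) / (lam_f - lam_s))
        if t_bec <= 0:
            degenerate, t_bec = True, None
    if degenerate:
        log.warning("bout fit degenerate (p=%.3g, rate ratio=%.2f); no t_bec",
                    p, lam_f / lam_s)
    return BoutModel(lambda_fast=lam_f, lambda_slow=lam_s, p_fast=p, p_slow=1 - p,
                     t_bec=t_bec, degenerate=degenerate, loglik=ll)


def bec_closed_form(p_fast: float, lambda_fast: float, lambda_slow: float) -> float:
    """t_bec from known mixture parameters (reference for recovery checks)."""
    return float(np.log((p_fast * lambda_fast) / ((1 - p_fast) * lambda_slow))
                 / (lambda_fast - lambda_slow))


def locate_dives(dives, interp: pd.DataFrame, projection=None) -> list[DiveRecord]:
    """Attach the interpolated track position at each dive's midpoint time.

    Dives whose midpoint falls outside the track's time span (or inside
    an interpolation gap) are left unlocated and flagged.
    """
    t = interp["t_s"].to_numpy()
    x = interp["x"].to_numpy()
    y = interp["y"].to_numpy()
    out = []
    for d in dives:
        mid = 0.5 * (d.t_start + d.t_end)
        rec = DiveRecord(d.t_start, d.t_end, d.max_depth, d.duration)
        if t[0] <= mid <= t[-1]:
            i = int(np.searchsorted(t, mid))
            i = min(max(i, 0), t.size - 1)
            if i > 0 and abs(t[i - 1] - mid) < abs(t[i] - mid):
                i -= 1
            if abs(t[i] - mid) <= 1.5:  # within the 1 Hz grid (gaps excluded)
                if projection is not None:
                    lon, lat = projection.inverse(x[i], y[i])
                    rec.lon, rec.lat = float(lon), float(lat)
                else:
                    rec.lon, rec.lat = float(x[i]), float(y[i])
                rec.located = True
        if not rec.located:
            log.warning("dive at t=%.0f s outside the interpolated track; not located",
                        mid)
        out.append(rec)
    return out


def dive_table(dives) -> pd.DataFrame:
    """DiveRecord list as a DataFrame (CSV-ready)."""
    return pd.DataFrame([{
        "t_start": d.t_start, "t_end": d.t_end, "duration_s": d.duration,
        "max_depth_m": d.max_depth, "lon": d.lon, "lat": d.lat, "located": d.located,
    } for d in dives])
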