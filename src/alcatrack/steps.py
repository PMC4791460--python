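"""Turchin reorientation steps and CCDF fits of the step-length law.

A reorientation occurs wherever the turning angle between consecutive
raw-fix displacements reaches a threshold (mild pi/4 or radical 7pi/8);
a step spans consecutive reorientations, its length being the
straight-line distance between its endpoints.  Steps containing an
inter-fix gap longer than 8 min are discarded (such gaps are typically
GPS dropouts).  Power-law and exponential models are then fitted by
least squares to the complementary cumulative distribution (CCDF) of
step lengths normalised by the minimum observed length l_min:

    power law:    P(L > l) = (l / l_min)^(1 - mu)
    exponential:  P(L > l) = exp(-rate * (l - l_min))

Scaling exponents 1 < mu <= 3 indicate heavy-tailed (Levy-like)
movement; mu > 3 is the signature of exponential motion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

log = logging.getLogger(__name__)

ALPHA_MILD = np.pi / 4        # 45 deg
ALPHA_RADICAL = 7 * np.pi / 8  # 157.5 deg


@dataclass
class StepFit:
    model: str                 # "powerlaw" or "exponential"
    alpha_threshold: float     # radians
    mu_hat: float | None       # power-law scaling exponent
    rate_hat: float | None     # exponential rate, 1/m
    sd: float                  # SE of the fitted parameter
    l_min: float               # m, minimum observed step length
    n_steps: int
    r_squared: float
    label: str                 # heavy_tail / exponential_motion / undefined


def turning_angle(p1, p2, p3) -> float:
    """Absolute angle (radians, [0, pi]) between displacements p1->p2, p2->p3.

    Zero-length displacements leave the angle undefined (NaN); callers
    skip such fixes.
    """
    v1 = np.asarray(p2, float) - np.asarray(p1, float)
    v2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1, n2 = np.hypot(*v1), np.hypot(*v2)
    if n1 == 0 or n2 == 0:
        return float("nan")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.arccos(c))


def _turning_angles(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorised turning angles at interior fixes; NaN where degenerate."""
    dx, dy = np.diff(x), np.diff(y)
    n = np.hypot(dx, dy)
    dot = dx[:-1] * dx[1:] + dy[:-1] * dy[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where((n[:-1] > 0) & (n[1:] > 0), dot / (n[:-1] * n[1:]), np.nan)
    return np.arccos(np.clip(c, -1.0, 1.0))


def extract_steps(fixes: pd.DataFrame, alpha_threshold: float,
                  max_gap_s: float = 480.0) -> pd.DataFrame:
    """Turchin discretisation of a raw (pre-interpolation) fix sequence.

    Interior fixes whose turning angle reaches ``alpha_threshold`` are
    reorientations; the track start and end also delimit steps.  Each
    step's length is the straight-line distance between its endpoint
    fixes.  Inter-fix intervals longer than ``max_gap_s`` (default
    8 min, typically GPS dropouts) split the track first, so no step
    ever spans a gap.  Fixes with zero-length displacements are skipped
    with a warning.  Fewer than 3 fixes yield no steps.
    """
    empty = pd.DataFrame(columns=["i_start", "i_end", "length_m", "elapsed_s"])
    if len(fixes) < 3:
        return empty
    x = fixes["x"].to_numpy(dtype=float)
    y = fixes["y"].to_numpy(dtype=float)
    t = (fixes["t_s"].to_numpy(dtype=float) if "t_s" in fixes
         else np.arange(len(fixes), dtype=float))
    # collapse zero-displacement fixes (undefined turning angle)
    keep = np.concatenate([[True], (np.diff(x) != 0) | (np.diff(y) != 0)])
    if not keep.all():
        log.warning("skipped %d stationary fixes (zero displacement)",
                    int((~keep).sum()))
        x, y, t = x[keep], y[keep], t[keep]
    if x.size < 2:
        return empty
    rows = []
    gap_breaks = np.flatnonzero(np.diff(t) > max_gap_s)
    seg_starts = np.concatenate([[0], gap_breaks + 1])
    seg_ends = np.concatenate([gap_breaks, [x.size - 1]])  # inclusive
    for s0, s1 in zip(seg_starts, seg_ends):
        if s1 - s0 < 1:
            continue
        xs, ys = x[s0:s1 + 1], y[s0:s1 + 1]
        if xs.size >= 3:
            ang = _turning_angles(xs, ys)
            reorient = np.flatnonzero(ang >= alpha_threshold) + 1
        else:
            reorient = np.empty(0, dtype=int)
        bounds = np.unique(np.concatenate([[0], reorient, [xs.size - 1]]))
        for i0, i1 in zip(bounds[:-1], bounds[1:]):
            rows.append({"i_start": int(s0 + i0), "i_end": int(s0 + i1),
                         "length_m": float(np.hypot(xs[i1] - xs[i0], ys[i1] - ys[i0])),
                         "elapsed_s": float(t[s0 + i1] - t[s0 + i0])})
    out = pd.DataFrame(rows, columns=["i_start", "i_end", "length_m", "elapsed_s"])
    return out[out["length_m"] > 0].reset_index(drop=True)


def _ccdf(lengths: np.ndarray):
    """Empirical CCDF P(L > l) at each unique observed length."""
    uniq, counts = np.unique(lengths, return_counts=True)
    n = lengths.size
    exceed = n - np.cumsum(counts)  # strictly greater
    return uniq, exceed / n


def fit_ccdf(lengths, model: str = "powerlaw", alpha_threshold: float = np.nan,
             min_steps: int = 30) -> StepFit:
    """Least-squares fit of a step-length model to the empirical CCDF.

    l_min is set empirically to the minimum observed length; lengths
    are normalised by l_min and the model CCDF fitted in linear space
    by nonlinear least squares.  The parameter SE comes from the fit
    covariance.  Requires at least ``min_steps`` steps.
    """
    l = np.asarray(lengths, dtype=float)
    if hasattr(lengths, "columns") and "length_m" in getattr(lengths, "columns", ()):
        l = lengths["length_m"].to_numpy(dtype=float)
    l = l[np.isfinite(l) & (l > 0)]
    if l.size < min_steps:
        raise ValueError(
            f"only {l.size} steps; need >= {min_steps} — pool more tracks or "
            "lower the reorientation threshold")
    l_min = float(l.min())
    uniq, ccdf = _ccdf(l / l_min)

    if model == "powerlaw":
        def f(xx, mu):
            return xx ** (1.0 - mu)
        p0, bounds = [2.0], ([1.0 + 1e-9], [60.0])
    elif model == "exponential":
        def f(xx, rate):
            return np.exp(-rate * (xx - 1.0))
        p0, bounds = [1.0 / max(np.mean(uniq) - 1.0, 1e-9)], ([1e-12], [np.inf])
    else:
        raise ValueError(f"unknown model {model!r}")

    try:
        popt, pcov = curve_fit(f, uniq, ccdf, p0=p0, bounds=bounds, maxfev=10000)
    except RuntimeError as e:
        raise RuntimeError(
            f"CCDF fit failed to converge for model={model}, n={l.size}, "
            f"l_min={l_min:.3g}: {e}") from e
    param = float(popt[0])
    sd = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
    resid = ccdf - f(uniq, param)
    ss_tot = float(((ccdf - ccdf.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else np.nan

    if model == "powerlaw":
        mu_hat, rate_hat = param, None
        # exponential rate is per normalised length; report per metre
    else:
        mu_hat, rate_hat = None, param / l_min
    label = classify_motion(mu_hat) if mu_hat is not None else "n/a"
    return StepFit(model=model, alpha_threshold=float(alpha_threshold),
                   mu_hat=mu_hat, rate_hat=rate_hat, sd=sd, l_min=l_min,
                   n_steps=int(l.size), r_squared=r2, label=label)


def classify_motion(mu_hat: float) -> str:
    """heavy_tail for 1 < mu <= 3, exponential_motion for mu > 3.

    Values at or below 1 do not correspond to a normalisable power law
    and are flagged undefined.
    """
    if mu_hat is None or not np.isfinite(mu_hat) or mu_hat <= 1:
        log.warning("scaling exponent %.3g outside the defined range", mu_hat)
        return "undefined"
    return "heavy_tail" if mu_hat <= 3 else "exponential_motion"


def flight_fixes(fixes: pd.DataFrame, speed_threshold: float | None) -> pd.DataFrame:
    """Raw fixes whose fix-to-fix speed indicates flight.

    Per-fix speed is the displacement to the next fix over the elapsed
    time (assigned to the leading fix); fixes at or below the threshold
    are dropped before step extraction (reorientation analysis concerns
    flight, and drifting fixes would masquerade as tight turns).
    """
    if speed_threshold is None:
        return fixes
    x = fixes["x"].to_numpy(dtype=float)
    y = fixes["y"].to_numpy(dtype=float)
    t = fixes["t_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    v = np.hypot(np.diff(x), np.diff(y)) / np.where(dt > 0, dt, np.inf)
    keep = np.concatenate([v > speed_threshold, [False]])
    return fixes.iloc[keep].reset_index(drop=True)


def stage_scale_comparison(tracks_by_stage: dict, speed_threshold: float | None = None,
                           thresholds=(ALPHA_MILD, ALPHA_RADICAL),
                           max_gap_s: float = 480.0, model: str = "powerlaw",
                           min_steps: int = 30) -> pd.DataFrame:
    """Power-law CCDF fit per (breeding stage x reorientation threshold).

    ``tracks_by_stage`` maps stage name to a list of raw projected fix
    DataFrames; steps are pooled across tracks within a stage before
    fitting.  Returns one row per stage/threshold with mu_hat +- sd,
    step counts and the motion label.
    """
    rows = []
    for stage, tracks in tracks_by_stage.items():
        flights = [flight_fixes(tr, speed_threshold) for tr in tracks]
        for alpha in thresholds:
            pooled = [extract_steps(tr, alpha, max_gap_s) for tr in flights]
            lengths = np.concatenate([p["length_m"].to_numpy() for p in pooled]
                                     ) if pooled else np.empty(0)
            try:
                fit = fit_ccdf(lengths, model=model, alpha_threshold=alpha,
                               min_steps=min_steps)
                rows.append({"stage": stage, "alpha_deg": np.degrees(alpha),
                             "mu_hat": fit.mu_hat, "sd": fit.sd,
                             "l_min_m": fit.l_min, "n_steps": fit.n_steps,
                             "r_squared": fit.r_squared, "label": fit.label})
            except ValueError as e:
                log.warning("stage %s alpha %.1f deg: %s", stage, np.degrees(alpha), e)
                rows.append({"stage": stage, "alpha_deg": np.degrees(alpha),
                             "mu_hat": np.nan, "sd": np.nan, "l_min_m": np.nan,
                             "n_steps": int(lengths.size), "r_squared": np.nan,
                             "label": "insufficient_steps"})
    return pd.DataFrame(rows)
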