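"""Non-compartmental analysis of concentration-time profiles.

Model-free PK summary of a single extravascular profile: Cmax/Tmax read off
the observations, AUC by numerical integration anchored at zero
concentration at the dose time, terminal elimination rate constant (lambda_z)
by log-linear regression over an adjusted-R^2-selected terminal window, and
the extrapolated quantities AUC0-inf, t1/2 = ln2/lambda_z and
MRT0-inf = AUMC0-inf / AUC0-inf.

AUC variants
------------
``linear``
    Linear trapezoid on the (midpoint-assigned) samples. Default for point
    samples.
``linlog``
    Linear up / log down: log-trapezoid on strictly decreasing positive
    segments, linear elsewhere.
``interval``
    Exact window sums for interval-averaged dialysate samples: each
    observation is the average concentration over its collection window, so
    mean x width recovers the integral over the covered span exactly. Used
    automatically (``auto``) when the series declares an ``interval`` width —
    the correct estimator for microdialysis data, where the 20-min
    collection windows tile the sampling horizon.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .series import SampleSeries

__all__ = ["NcaResult", "auc_trapezoid", "terminal_slope", "nca_full",
           "nca_table"]


@dataclass(frozen=True)
class NcaResult:
    """NCA parameter set for one profile. Extrapolated quantities are NaN
    when the terminal slope is undefined (``lambda_z_defined`` False)."""

    analyte: str
    subject: str
    cmax: float          # ng/mL
    tmax: float          # min
    auc_0_t: float       # ng*min/mL
    auc_0_inf: float     # ng*min/mL
    lambda_z: float      # 1/min
    t_half: float        # min
    mrt_0_inf: float     # min
    lambda_z_points: int
    lambda_z_adj_r2: float
    lambda_z_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte, "subject": self.subject,
            "cmax_ng_ml": self.cmax, "tmax_min": self.tmax,
            "auc_0_t": self.auc_0_t, "auc_0_inf": self.auc_0_inf,
            "lambda_z_per_min": self.lambda_z, "t_half_min": self.t_half,
            "mrt_0_inf_min": self.mrt_0_inf,
            "lambda_z_points": self.lambda_z_points,
            "lambda_z_adj_r2": self.lambda_z_adj_r2,
        }


def _anchored(series: SampleSeries) -> tuple[np.ndarray, np.ndarray]:
    """Post-dose times/concs with a zero anchor at the dose time."""
    s = series.post_dose()
    t, c = s.times, s.concentrations
    if t.size and t[0] > series.dose_time:
        t = np.concatenate([[series.dose_time], t])
        c = np.concatenate([[0.0], c])
    return t, c


def _trap_linear(t: np.ndarray, c: np.ndarray) -> float:
    return float(np.trapezoid(c, t))


def _trap_linlog(t: np.ndarray, c: np.ndarray) -> float:
    total = 0.0
    for i in range(t.size - 1):
        c0, c1, dt = c[i], c[i + 1], t[i + 1] - t[i]
        if c0 > c1 > 0:
            total += dt * (c0 - c1) / math.log(c0 / c1)
        else:
            total += dt * (c0 + c1) / 2.0
    return float(total)


def auc_trapezoid(series: SampleSeries, method: str = "auto",
                  t_start: float | None = None,
                  t_end: float | None = None) -> float:
    """AUC from the dose time to the last observation (``auc_0_t``).

    ``t_start``/``t_end`` restrict the integration span (concentrations at
    interior bounds are linearly interpolated), making partial AUCs exactly
    additive.
    """
    s = series.post_dose()
    if len(s) < 2:
        raise InsufficientDataError("AUC needs >=2 post-dose samples")
    if method == "auto":
        method = "interval" if series.interval else "linear"

    if method == "interval":
        if not series.interval:
            raise ValueError("interval AUC needs series.interval set")
        half = series.interval / 2.0
        lo = np.clip(s.times - half, t_start, t_end) if (t_start is not None or t_end is not None) \
            else s.times - half
        hi = np.clip(s.times + half, t_start, t_end) if (t_start is not None or t_end is not None) \
            else s.times + half
        widths = np.maximum(hi - lo, 0.0)
        return float(np.sum(s.concentrations * widths))

    t, c = _anchored(series)
    if t_start is not None or t_end is not None:
        lo = t[0] if t_start is None else max(t_start, t[0])
        hi = t[-1] if t_end is None else min(t_end, t[-1])
        grid = np.unique(np.concatenate([[lo, hi], t[(t > lo) & (t < hi)]]))
        c = np.interp(grid, t, c)
        t = grid
    if method == "linear":
        return _trap_linear(t, c)
    if method == "linlog":
        return _trap_linlog(t, c)
    raise ValueError(f"unknown AUC method {method!r}")


def _aumc(series: SampleSeries, method: str) -> float:
    """Area under the first-moment curve t*C(t) to the last observation."""
    if method == "interval" and series.interval:
        s = series.post_dose()
        # midpoint x window-average is second-order accurate for t*C
        return float(np.sum(s.times * s.concentrations * series.interval))
    t, c = _anchored(series)
    return _trap_linear(t, t * c)


def terminal_slope(series: SampleSeries, *, min_points: int = 3
                   ) -> tuple[float, float, int, float]:
    """Terminal elimination rate by log-linear regression.

    Candidate windows are every contiguous run of the last k >= 3 positive
    post-Tmax concentrations (Cmax itself excluded); the window maximising
    adjusted R^2 wins, ties going to the longer window. Returns
    ``(lambda_z, t_half, points_used, adj_r2)``; ``lambda_z`` is NaN when no
    window yields a negative slope.
    """
    s = series.post_dose()
    if len(s) == 0 or np.all(s.concentrations <= 0):
        return math.nan, math.nan, 0, math.nan
    i_max = int(np.argmax(s.concentrations))
    t = s.times[i_max + 1:]
    c = s.concentrations[i_max + 1:]
    keep = c > 0  # below-LOQ (zero) samples are excluded from the regression
    t, c = t[keep], c[keep]
    if t.size < min_points:
        return math.nan, math.nan, 0, math.nan

    best = None  # (adj_r2, n_points, lambda_z)
    logc = np.log(c)
    for start in range(t.size - min_points + 1):
        x, y = t[start:], logc[start:]
        n = x.size
        sxx = np.sum((x - x.mean()) ** 2)
        if sxx == 0:
            continue
        slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
        if slope >= 0:
            continue
        resid = y - (y.mean() + slope * (x - x.mean()))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
        key = (round(adj, 12), n)
        if best is None or key > (round(best[0], 12), best[1]):
            best = (adj, n, -slope)
    if best is None:
        return math.nan, math.nan, 0, math.nan
    adj, n, lam = best
    return lam, math.log(2.0) / lam, n, adj


def nca_full(series: SampleSeries, auc_method: str = "auto") -> NcaResult:
    """Full NCA parameter set for one profile."""
    s = series.post_dose()
    if len(s) < 2:
        raise InsufficientDataError("NCA needs >=2 post-dose samples")
    c, t = s.concentrations, s.times
    i_max = int(np.argmax(c))  # argmax returns the earliest maximum on ties
    cmax, tmax = float(c[i_max]), float(t[i_max])

    if np.all(c <= 0):
        return NcaResult(series.analyte, series.subject, 0.0, tmax, 0.0,
                         math.nan, math.nan, math.nan, math.nan, 0, math.nan,
                         lambda_z_defined=False)

    auc_t = auc_trapezoid(series, method=auc_method)
    lam, t_half, n_pts, adj_r2 = terminal_slope(series)

    if math.isnan(lam):
        return NcaResult(series.analyte, series.subject, cmax, tmax, auc_t,
                         math.nan, math.nan, math.nan, math.nan, 0, math.nan,
                         lambda_z_defined=False)

    pos = c > 0
    c_last = float(c[pos][-1])
    t_last = float(t[pos][-1])
    auc_inf = auc_t + c_last / lam
    aumc_t = _aumc(series, "interval" if (auc_method in ("auto", "interval")
                                          and series.interval) else "linear")
    aumc_inf = aumc_t + c_last * t_last / lam + c_last / lam ** 2
    mrt = aumc_inf / auc_inf
    return NcaResult(series.analyte, series.subject, cmax, tmax, auc_t,
                     float(auc_inf), lam, t_half, float(mrt), n_pts, adj_r2)


def nca_table(df: pd.DataFrame, *, dose_time: float = 0.0,
              interval: float | None = None,
              auc_method: str = "auto") -> pd.DataFrame:
    """Run NCA per (analyte, group, subject) over a tidy table; one row per
    profile, mirroring a per-subject PK parameter table."""
    from .series import series_from_frame
    rows = []
    keys = [k for k in ("analyte", "group", "subject") if k in df.columns]
    for key, grp in df.groupby(keys):
        key = key if isinstance(key, tuple) else (key,)
        s = series_from_frame(grp.assign(), dose_time=dose_time,
                              interval=interval)
        res = nca_full(s, auc_method=auc_method)
        rows.append({**dict(zip(keys, key)),
                     **{k: v for k, v in res.to_dict().items()
                        if k not in ("analyte", "subject")}})
    return pd.DataFrame(rows)
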