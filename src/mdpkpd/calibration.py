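"""LC-MS/MS method-validation arithmetic: dual-range linear calibration,
detection limits, QC precision/accuracy and matrix effect.

Bioanalytical calibration for dialysate work commonly uses two overlapping
linear ranges per analyte (a dense low range bracketing the LOQ and a wide
high range). Each range is an ordinary least-squares line

    peak_area = slope * concentration + intercept

fit with concentration as the abscissa. Detection limits follow the
signal-to-noise convention: LOD at S/N >= 3, LOQ at S/N >= 10.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CalibrationUnderdeterminedError,
    DegenerateDesignError,
    InvalidReferenceError,
    InvalidSlopeError,
    UndefinedRsdError,
)

__all__ = [
    "CalibrationPoint", "CalibrationRange", "CalibrationCurve",
    "InvertedConcentration", "fit_calibration", "invert_calibration",
    "detection_limits", "qc_levels", "precision_accuracy", "matrix_effect",
    "qc_report",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration standard: nominal concentration vs detector response."""

    nominal_conc: float  # ng/mL, > 0
    peak_area: float     # arbitrary units
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if not self.nominal_conc > 0:
            raise ValueError("nominal_conc must be positive")
        if not np.isfinite(self.peak_area):
            raise ValueError("peak_area must be finite")


@dataclass(frozen=True)
class CalibrationRange:
    conc_low: float
    conc_high: float
    slope: float
    intercept: float
    r_squared: float

    def contains(self, conc: float) -> bool:
        return self.conc_low <= conc <= self.conc_high

    def predict_area(self, conc) -> np.ndarray:
        return self.slope * np.asarray(conc, dtype=float) + self.intercept


@dataclass(frozen=True)
class CalibrationCurve:
    """Piecewise (low/high range) signal-to-concentration map with LOD/LOQ."""

    analyte: str
    ranges: tuple[CalibrationRange, ...]
    lod: float = 0.0
    loq: float = 0.0

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValueError("calibration curve needs at least one range")
        for r in self.ranges:
            if not r.conc_low < r.conc_high:
                raise ValueError("each range needs conc_low < conc_high")
            if not r.slope > 0:
                raise ValueError("calibration slope must be positive")
        if self.lod < 0 or self.loq < self.lod:
            raise ValueError("need 0 <= lod <= loq")

    @property
    def lloq(self) -> float:
        """Lower limit of quantification: bottom of the lowest range."""
        return self.ranges[0].conc_low

    @property
    def uloq(self) -> float:
        """Upper limit of quantification: top of the highest range."""
        return self.ranges[-1].conc_high


@dataclass(frozen=True)
class InvertedConcentration:
    """Back-calculated concentration with quality flags."""

    value: float
    range_index: int
    below_loq: bool = False
    clamped: bool = False
    overlap: bool = False


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Unweighted OLS of y on x; returns slope, intercept, R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise DegenerateDesignError("zero concentration variance in range")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    ss_res = float(np.sum((y - slope * x - intercept) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, intercept, r2


def fit_calibration(points: list[CalibrationPoint],
                    range_breaks: list[tuple[float, float]] | None = None,
                    *, analyte: str = "", lod: float = 0.0,
                    loq: float = 0.0,
                    weighting: str = "none") -> CalibrationCurve:
    """Fit one OLS line per concentration range.

    Parameters
    ----------
    points
        Calibration standards across all ranges.
    range_breaks
        List of (low, high) concentration intervals, one per range. ``None``
        fits a single range spanning the data.
    weighting
        ``"none"`` (default) or ``"1/x2"`` for 1/concentration^2 weights.

    Raises
    ------
    CalibrationUnderdeterminedError
        If any range holds fewer than three distinct concentrations.
    DegenerateDesignError
        If a range has zero concentration variance.
    """
    if not points:
        raise CalibrationUnderdeterminedError("no calibration points")
    conc = np.array([p.nominal_conc for p in points])
    area = np.array([p.peak_area for p in points])
    if range_breaks is None:
        range_breaks = [(float(conc.min()), float(conc.max()))]
    ranges = []
    for lo, hi in sorted(range_breaks):
        mask = (conc >= lo) & (conc <= hi)
        x, y = conc[mask], area[mask]
        if np.unique(x).size < 3:
            raise CalibrationUnderdeterminedError(
                f"range ({lo}, {hi}): need >=3 distinct concentrations, "
                f"got {np.unique(x).size}")
        if weighting == "1/x2":
            w = 1.0 / x ** 2
            # weighted least squares via sqrt-weight transform
            sw = np.sqrt(w)
            xm = np.sum(w * x) / np.sum(w)
            ym = np.sum(w * y) / np.sum(w)
            sxx = np.sum(w * (x - xm) ** 2)
            if sxx == 0:
                raise DegenerateDesignError("zero concentration variance in range")
            slope = float(np.sum(w * (x - xm) * (y - ym)) / sxx)
            intercept = float(ym - slope * xm)
            ss_res = float(np.sum(w * (y - slope * x - intercept) ** 2))
            ss_tot = float(np.sum(w * (y - ym) ** 2))
            r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        else:
            slope, intercept, r2 = _ols_line(x, y)
        ranges.append(CalibrationRange(float(lo), float(hi), slope, intercept, r2))
    return CalibrationCurve(analyte=analyte, ranges=tuple(ranges),
                            lod=lod, loq=loq)


def invert_calibration(curve: CalibrationCurve, peak_area: float,
                       hint_range: int | None = None) -> InvertedConcentration:
    """Back-calculate concentration from a detector response.

    Range selection: the unique range whose concentration interval contains
    the back-calculated value; when both overlapping ranges contain it the
    lower range wins (its low-end calibration is denser) and an overlap flag
    is set. Values below the LOQ are retained but flagged; negative values
    are clamped to zero and flagged.
    """
    if hint_range is not None:
        candidates = [(hint_range, curve.ranges[hint_range])]
        overlap = False
    else:
        back = [(i, r, (peak_area - r.intercept) / r.slope)
                for i, r in enumerate(curve.ranges)]
        containing = [(i, r) for i, r, v in back if r.contains(v)]
        overlap = len(containing) > 1
        if containing:
            candidates = [min(containing, key=lambda ir: ir[1].conc_low)]
        else:
            # fall back to whichever range's back-calculated value is least
            # out of range (extrapolation); lowest range on ties
            def dist(item):
                _, r, v = item
                return max(r.conc_low - v, v - r.conc_high, 0.0)
            i, r, _ = min(back, key=dist)
            candidates = [(i, r)]
    idx, rng = candidates[0]
    value = (peak_area - rng.intercept) / rng.slope
    clamped = value < 0
    if clamped:
        value = 0.0
    below_loq = value < curve.loq if curve.loq > 0 else value <= 0
    return InvertedConcentration(value=float(value), range_index=idx,
                                 below_loq=bool(below_loq),
                                 clamped=bool(clamped), overlap=bool(overlap))


def detection_limits(slope: float, noise_sd: float,
                     k_lod: float = 3.0, k_loq: float = 10.0) -> tuple[float, float]:
    """LOD and LOQ from the S/N >= 3 and S/N >= 10 conventions.

    The concentration whose signal equals k times the baseline noise SD is
    ``k * noise_sd / slope``.
    """
    if slope <= 0:
        raise InvalidSlopeError(f"slope must be positive, got {slope}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    return k_lod * noise_sd / slope, k_loq * noise_sd / slope


def qc_levels(lloq: float, uloq: float) -> tuple[tuple[float, float, float], bool]:
    """Low/medium/high QC concentrations: 3x LLOQ, 40% ULOQ, 80% ULOQ.

    Returns the triple and an overlap flag set when the low level is not
    below the medium level (possible for narrow calibration ranges).
    """
    if not 0 < lloq < uloq:
        raise ValueError("need 0 < lloq < uloq")
    levels = (3.0 * lloq, 0.4 * uloq, 0.8 * uloq)
    return levels, levels[0] >= levels[1]


def precision_accuracy(measured, nominal: float) -> tuple[float, float]:
    """Replicate precision (RSD%) and accuracy (RE%) against nominal.

    RSD uses the n-1 sample standard deviation, the bioanalytical convention
    for small replicate counts.
    """
    m = np.asarray(measured, dtype=float)
    if m.size < 3:
        raise UndefinedRsdError("need >=3 replicate measurements")
    if nominal <= 0:
        raise ValueError("nominal must be positive")
    mean = m.mean()
    if mean == 0:
        raise UndefinedRsdError("mean of measurements is zero; RSD undefined")
    rsd = 100.0 * m.std(ddof=1) / mean
    re = 100.0 * (mean - nominal) / nominal
    return float(rsd), float(re)


def matrix_effect(area_in_matrix, area_in_reference) -> tuple[float, float]:
    """Matrix effect as percent: mean matrix response over mean reference
    response, with SD propagated from paired replicate ratios."""
    m = np.asarray(area_in_matrix, dtype=float)
    r = np.asarray(area_in_reference, dtype=float)
    if m.size < 3 or r.size < 3:
        raise ValueError("need >=3 replicates in both matrix and reference")
    if r.mean() <= 0:
        raise InvalidReferenceError("reference mean must be positive")
    me = 100.0 * m.mean() / r.mean()
    k = min(m.size, r.size)
    ratios = 100.0 * m[:k] / r[:k]
    sd = float(ratios.std(ddof=1))
    return float(me), sd


def qc_report(df: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a QC table into per (analyte, level, day) RSD%/RE% rows.

    Expects columns ``analyte, level, day, nominal_conc_ng_ml,
    measured_conc_ng_ml`` (one row per replicate).
    """
    rows = []
    for (analyte, level, day), grp in df.groupby(["analyte", "level", "day"]):
        rsd, re = precision_accuracy(grp["measured_conc_ng_ml"].to_numpy(),
                                     float(grp["nominal_conc_ng_ml"].iloc[0]))
        rows.append({"analyte": analyte, "level": level, "day": day,
                     "rsd_percent": rsd, "re_percent": re,
                     "n_replicates": len(grp)})
    return pd.DataFrame(rows)
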