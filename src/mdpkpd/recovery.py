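"""In-vitro microdialysis probe recovery.

Relative (gain-mode) recovery is the fraction of the surrounding medium's
concentration that appears in the dialysate when the probe is immersed in a
standard solution: R = C_dialysate / C_medium. Recovery falls with perfusion
rate; the operating flow rate is chosen to maximise mean recovery across
analytes. Measured dialysate concentrations are corrected to tissue
concentrations by dividing by R.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (ImplausibleRecoveryError, InvalidRecoveryError,
                     NoDataError)

__all__ = ["RecoveryMeasurement", "RecoveryTable", "compute_recovery",
           "select_flow_rate", "correct_concentration"]

#: per-replicate recovery above this is treated as a unit mismatch
_IMPLAUSIBLE = 1.2


@dataclass(frozen=True)
class RecoveryMeasurement:
    analyte: str
    flow_rate: float      # µL/min
    nominal_conc: float   # ng/mL of the immersion standard
    dialysate_conc: float  # ng/mL measured in the dialysate
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.flow_rate <= 0:
            raise ValueError("flow_rate must be positive")
        if self.nominal_conc <= 0:
            raise InvalidRecoveryError("nominal_conc must be positive")
        if self.dialysate_conc < 0:
            raise ValueError("dialysate_conc must be non-negative")

    @property
    def recovery(self) -> float:
        return self.dialysate_conc / self.nominal_conc


@dataclass(frozen=True)
class RecoveryTable:
    """Aggregated recovery: per (analyte, flow_rate) and per concentration.

    ``by_flow`` has columns analyte, flow_rate, mean_recovery, sd, n;
    ``by_conc`` additionally resolves nominal_conc. ``trend_warnings`` lists
    (analyte, flow_rate) cells where recovery drifts with concentration by
    more than the configured relative threshold, flagging a violation of the
    concentration-independence assumption.
    """

    by_flow: pd.DataFrame
    by_conc: pd.DataFrame
    trend_warnings: tuple[tuple[str, float], ...] = ()

    def mean_recovery(self, analyte: str, flow_rate: float) -> float:
        sub = self.by_flow[(self.by_flow["analyte"] == analyte)
                           & (self.by_flow["flow_rate"] == flow_rate)]
        if sub.empty:
            raise NoDataError(f"no recovery for {analyte} at {flow_rate}")
        return float(sub["mean_recovery"].iloc[0])


def compute_recovery(measurements: list[RecoveryMeasurement], *,
                     min_replicates: int = 3,
                     trend_threshold: float = 0.20) -> RecoveryTable:
    """Aggregate replicate immersion measurements into a recovery table.

    Per-replicate recovery is dialysate/nominal; each
    (analyte, flow_rate, nominal_conc) cell needs ``min_replicates``
    replicates. A linear trend of recovery across the nominal-concentration
    grid exceeding ``trend_threshold`` (relative to the mean) raises a
    trend warning for that (analyte, flow_rate).
    """
    if not measurements:
        raise NoDataError("no recovery measurements")
    for m in measurements:
        if m.recovery > _IMPLAUSIBLE:
            raise ImplausibleRecoveryError(
                f"{m.analyte} at {m.flow_rate} µL/min: replicate recovery "
                f"{m.recovery:.2f} > {_IMPLAUSIBLE} (unit mismatch?)")
    df = pd.DataFrame([{
        "analyte": m.analyte, "flow_rate": m.flow_rate,
        "nominal_conc": m.nominal_conc, "recovery": m.recovery,
    } for m in measurements])

    counts = df.groupby(["analyte", "flow_rate", "nominal_conc"]).size()
    short = counts[counts < min_replicates]
    if not short.empty:
        cell = short.index[0]
        raise NoDataError(
            f"cell {cell}: {short.iloc[0]} replicates < {min_replicates}")

    by_conc = (df.groupby(["analyte", "flow_rate", "nominal_conc"])["recovery"]
               .agg(mean_recovery="mean", sd=lambda s: s.std(ddof=1), n="size")
               .reset_index())
    by_flow = (df.groupby(["analyte", "flow_rate"])["recovery"]
               .agg(mean_recovery="mean", sd=lambda s: s.std(ddof=1), n="size")
               .reset_index())

    warnings = []
    for (analyte, flow), grp in by_conc.groupby(["analyte", "flow_rate"]):
        if grp["nominal_conc"].nunique() >= 2:
            slope = np.polyfit(grp["nominal_conc"], grp["mean_recovery"], 1)[0]
            span = grp["nominal_conc"].max() - grp["nominal_conc"].min()
            drift = abs(slope) * span / grp["mean_recovery"].mean()
            if drift > trend_threshold:
                warnings.append((str(analyte), float(flow)))
    return RecoveryTable(by_flow=by_flow, by_conc=by_conc,
                         trend_warnings=tuple(warnings))


def select_flow_rate(table: RecoveryTable) -> float:
    """Flow rate maximising mean recovery averaged over analytes.

    Ties break toward the lower flow rate (gentler perfusion, higher
    temporal resolution per unit volume).
    """
    if table.by_flow.empty:
        raise NoDataError("empty recovery table")
    per_flow = table.by_flow.groupby("flow_rate")["mean_recovery"].mean()
    best = per_flow.max()
    candidates = per_flow[per_flow >= best].index
    return float(min(candidates))


def correct_concentration(measured: float | np.ndarray,
                          recovery: float) -> float | np.ndarray:
    """Back-correct a dialysate concentration to the surrounding medium:
    C_true = C_measured / R, valid for R in (0, 1]."""
    if not 0 < recovery <= 1:
        raise InvalidRecoveryError(f"recovery must be in (0, 1], got {recovery}")
    return measured / recovery


def recovery_from_frame(df: pd.DataFrame) -> list[RecoveryMeasurement]:
    """Parse the recovery CSV schema (analyte, flow_rate_ul_min,
    nominal_conc_ng_ml, dialysate_conc_ng_ml, replicate)."""
    return [RecoveryMeasurement(
        analyte=str(r.analyte), flow_rate=float(r.flow_rate_ul_min),
        nominal_conc=float(r.nominal_conc_ng_ml),
        dialysate_conc=float(r.dialysate_conc_ng_ml),
        replicate_id=int(getattr(r, "replicate", 0)),
    ) for r in df.itertuples()]
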