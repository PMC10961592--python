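"""Time-series containers for interval-sampled dialysate data.

Microdialysis does not sample instantaneous concentrations: each observation
is the average of the extracellular concentration over a collection window
(20 min in the default design). :class:`SampleSeries` therefore carries the
collection-interval width alongside the (midpoint-assigned) time grid, and
downstream analyses may exploit the interval-average structure.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

#: canonical tidy-CSV column names used across the pipeline
TIDY_COLUMNS = ["analyte", "group", "subject", "t_min", "conc_ng_ml"]


@dataclass(frozen=True)
class SampleSeries:
    """One analyte's concentration-time profile for one subject (or a group
    mean), in ng/mL versus minutes.

    Parameters
    ----------
    analyte : str
        Analyte name (lignan or neurotransmitter).
    times : array of float
        Sample times in minutes, strictly increasing. For interval-collected
        dialysate these are window midpoints (a 0-20 min sample sits at 10).
    concentrations : array of float
        Non-negative concentrations, ng/mL.
    subject : str
        Subject or group identifier.
    dose_time : float
        Time of extravascular dosing, minutes; must not exceed the first
        post-dose sample time.
    baseline_window : tuple (t_start, t_end) or None
        Pre-dose window whose samples define the basal level.
    interval : float or None
        Collection-window width in minutes if the samples are interval
        averages; ``None`` for instantaneous (point) samples.
    """

    analyte: str
    times: np.ndarray
    concentrations: np.ndarray
    subject: str = "mean"
    group: str = ""
    dose_time: float = 0.0
    baseline_window: tuple[float, float] | None = None
    interval: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or c.shape != t.shape:
            raise SchemaError("times and concentrations must be 1-D and equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise SchemaError("times must be strictly increasing")
        if np.any(c < 0):
            raise SchemaError("concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    def __len__(self) -> int:
        return self.times.size

    def post_dose(self) -> "SampleSeries":
        """Restrict to samples at or after the dose time."""
        mask = self.times >= self.dose_time
        return replace(self, times=self.times[mask],
                       concentrations=self.concentrations[mask])

    def scaled(self, factor: float) -> "SampleSeries":
        return replace(self, concentrations=self.concentrations * factor)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "analyte": self.analyte, "group": self.group,
            "subject": self.subject, "t_min": self.times,
            "conc_ng_ml": self.concentrations,
        })


def series_from_frame(df: pd.DataFrame, analyte: str | None = None,
                      subject: str | None = None, *,
                      dose_time: float = 0.0,
                      baseline_window: tuple[float, float] | None = None,
                      interval: float | None = None) -> SampleSeries:
    """Build a :class:`SampleSeries` from a tidy long-format table.

    The table must carry the columns ``analyte, group, subject, t_min,
    conc_ng_ml`` (missing ``group``/``subject`` default to placeholders).
    """
    required = {"analyte", "t_min", "conc_ng_ml"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(sorted(missing))}")
    sub = df
    if analyte is not None:
        sub = sub[sub["analyte"] == analyte]
    if subject is not None and "subject" in sub.columns:
        sub = sub[sub["subject"].astype(str) == str(subject)]
    if sub.empty:
        raise SchemaError(f"no rows for analyte={analyte!r}, subject={subject!r}")
    sub = sub.sort_values("t_min")
    name = analyte if analyte is not None else str(sub["analyte"].iloc[0])
    return SampleSeries(
        analyte=name,
        times=sub["t_min"].to_numpy(dtype=float),
        concentrations=sub["conc_ng_ml"].to_numpy(dtype=float),
        subject=str(sub["subject"].iloc[0]) if "subject" in sub.columns else "mean",
        group=str(sub["group"].iloc[0]) if "group" in sub.columns else "",
        dose_time=dose_time, baseline_window=baseline_window, interval=interval,
    )


def group_mean_series(df: pd.DataFrame, analyte: str, group: str, *,
                      dose_time: float = 0.0,
                      baseline_window: tuple[float, float] | None = None,
                      interval: float | None = None) -> SampleSeries:
    """Average the per-subject profiles of one group onto the shared grid."""
    sub = df[(df["analyte"] == analyte) & (df["group"] == group)]
    if sub.empty:
        raise SchemaError(f"no rows for analyte={analyte!r}, group={group!r}")
    mean = sub.groupby("t_min", sort=True)["conc_ng_ml"].mean()
    return SampleSeries(analyte=analyte, times=mean.index.to_numpy(dtype=float),
                        concentrations=mean.to_numpy(dtype=float),
                        subject="mean", group=group, dose_time=dose_time,
                        baseline_window=baseline_window, interval=interval)


@dataclass(frozen=True)
class EffectSeries:
    """Baseline-normalised neurotransmitter response, percent of basal.

    The first basal (pre-dose) sample is pinned to exactly 100 by
    construction; ``baseline_raw`` keeps the raw basal concentration (ng/mL)
    so the normalisation is invertible.
    """

    neurotransmitter: str
    times: np.ndarray
    effect: np.ndarray
    baseline_raw: float
    group: str = ""
    subject: str = "mean"
    dose_time: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.effect, dtype=float)
        if t.shape != e.shape:
            raise SchemaError("times and effect must have equal length")
        if np.any(e < 0):
            raise SchemaError("effect percentages must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "effect", e)

    def post_dose(self) -> "EffectSeries":
        mask = self.times >= self.dose_time
        return EffectSeries(self.neurotransmitter, self.times[mask],
                            self.effect[mask], self.baseline_raw,
                            self.group, self.subject, self.dose_time)


def write_tidy_csv(frames: Sequence[pd.DataFrame] | pd.DataFrame, path) -> None:
    """Write tidy tables with 9-significant-digit floats for stable diffs."""
    df = pd.concat(frames, ignore_index=True) if isinstance(frames, (list, tuple)) else frames
    df.to_csv(path, index=False, float_format="%.9g")


def read_tidy_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"analyte", "t_min", "conc_ng_ml"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s): "
                          f"{', '.join(sorted(missing))}")
    return df
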