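"""Sigmoid-Emax / Sigmoid-Imax pharmacodynamic response models.

Neurotransmitter dialysate levels are first normalised to percent of the
pre-dose basal sample (the first basal sample maps to exactly 100%), then
related to the driving concentration C through a Hill-type model:

stimulation (Tau-, Ach-like responses)::

    E(C) = E0 + Emax * C**n / (EC50**n + C**n)

inhibition (Asp-, Glu-like responses), multiplicative so the effect stays
non-negative and Imax is a scale-free fraction in (0, 1]::

    E(C) = E0 * (1 - Imax * C**n / (IC50**n + C**n))

The Hill coefficient n is estimated within [0.1, 10] to prevent
step-function degeneracy.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .compartmental import ModelSelectionScores
from .errors import (FitFailedError, InsufficientDataError,
                     NormalizationError, UnidentifiableError)
from .series import EffectSeries, SampleSeries

__all__ = ["PdParams", "PdFit", "SigmoidEmaxModel", "normalize_effect",
           "pd_predict", "fit_pd"]

HILL_BOUNDS = (0.1, 10.0)


@dataclass(frozen=True)
class PdParams:
    """Hill-model parameters; ``emax_or_imax`` is the maximal stimulation in
    percent (stimulation) or the fractional maximal inhibition in (0, 1]
    (inhibition)."""

    e0: float
    emax_or_imax: float
    c50: float          # EC50 or IC50, ng/mL
    hill_n: float
    mode: str           # "stimulation" | "inhibition"

    def __post_init__(self) -> None:
        if self.mode not in ("stimulation", "inhibition"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.c50 <= 0 or self.hill_n <= 0 or self.e0 <= 0:
            raise ValueError("e0, c50 and hill_n must be positive")
        if self.mode == "inhibition" and not 0 < self.emax_or_imax <= 1:
            raise ValueError("imax must lie in (0, 1]")
        if self.mode == "stimulation" and self.emax_or_imax <= 0:
            raise ValueError("emax must be positive")

    def as_dict(self) -> dict:
        key = "emax" if self.mode == "stimulation" else "imax"
        c50_key = "ec50" if self.mode == "stimulation" else "ic50"
        return {"e0": self.e0, key: self.emax_or_imax,
                c50_key: self.c50, "hill_n": self.hill_n, "mode": self.mode}


def pd_predict(params: PdParams, conc) -> np.ndarray:
    """Model effect (percent of baseline) at the given concentrations."""
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    cn = np.power(c, params.hill_n)
    frac = cn / (params.c50 ** params.hill_n + cn)
    if params.mode == "stimulation":
        return params.e0 + params.emax_or_imax * frac
    return params.e0 * (1.0 - params.emax_or_imax * frac)


def normalize_effect(raw: SampleSeries,
                     baseline_window: tuple[float, float] | None = None,
                     rule: str = "first") -> EffectSeries:
    """Convert a raw neurotransmitter series to percent-of-baseline.

    ``rule="first"`` (default) divides by the first pre-dose sample inside
    the baseline window, pinning that sample to exactly 100;
    ``rule="mean"`` divides by the window mean instead.
    """
    window = baseline_window or raw.baseline_window
    if window is None:
        window = (-math.inf, raw.dose_time)
    mask = (raw.times >= window[0]) & (raw.times <= window[1]) \
        & (raw.times <= raw.dose_time)
    if not np.any(mask):
        raise NormalizationError("no pre-dose sample inside baseline window")
    basal_values = raw.concentrations[mask]
    basal = float(basal_values[0]) if rule == "first" else float(basal_values.mean())
    if basal <= 0:
        raise NormalizationError("baseline must be positive")
    return EffectSeries(
        neurotransmitter=raw.analyte, times=raw.times,
        effect=100.0 * raw.concentrations / basal, baseline_raw=basal,
        group=raw.group, subject=raw.subject, dose_time=raw.dose_time)


@dataclass(frozen=True)
class PdFit:
    params: PdParams
    scores: ModelSelectionScores
    predicted: np.ndarray
    seed: int

    def summary(self) -> str:
        lines = [f"Sigmoid-{'Emax' if self.params.mode == 'stimulation' else 'Imax'}"
                 f" fit  n_obs={self.scores.n_obs}  SSR={self.scores.ssr:.6g}"
                 f"  AIC={self.scores.aic:.3f}",
                 f"  {'param':>8}  {'estimate':>12}  {'CV%':>8}"]
        for name, val in self.params.as_dict().items():
            if name == "mode":
                continue
            cv = self.scores.cv_percent.get(name, math.nan)
            lines.append(f"  {name:>8}  {val:12.6g}  {cv:8.3g}")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {"params": self.params.as_dict(), "aic": self.scores.aic,
                "bic": self.scores.bic, "cv_percent": self.scores.cv_percent,
                "ssr": self.scores.ssr, "n_obs": self.scores.n_obs,
                "seed": self.seed}


class SigmoidEmaxModel:
    """Hill-model WLS fit of paired (concentration, effect) observations.

    Free parameters are transformed — log E0, log Emax (or logit Imax),
    log C50, log n (bounded) — so positivity and the Imax fraction are
    structural, then fit by multi-start least squares.
    """

    def __init__(self, effect, conc, mode: str = "stimulation",
                 weights=None):
        e = np.asarray(getattr(effect, "effect", effect), dtype=float)
        c = np.asarray(conc, dtype=float)
        if e.shape != c.shape:
            raise ValueError("effect and concentration lengths differ")
        if e.size < 5:
            raise InsufficientDataError("need >=5 paired (conc, effect) points")
        if np.ptp(c) <= 0:
            raise UnidentifiableError("degenerate concentration range")
        self.effect = e
        self.conc = c
        self.mode = mode
        self._sqrt_w = np.ones_like(e) if weights is None else np.sqrt(weights)

    def _params_from_x(self, x: np.ndarray) -> PdParams:
        e0 = math.exp(x[0])
        if self.mode == "stimulation":
            mag = math.exp(x[1])
        else:
            mag = 1.0 / (1.0 + math.exp(-x[1]))  # logit^-1 -> (0, 1)
        c50 = math.exp(x[2])
        hill = math.exp(x[3])
        return PdParams(e0=e0, emax_or_imax=mag, c50=c50, hill_n=hill,
                        mode=self.mode)

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        try:
            pred = pd_predict(self._params_from_x(x), self.conc)
        except (ValueError, OverflowError):
            return np.full(self.effect.size, 1e6)
        return self._sqrt_w * (pred - self.effect)

    def _starts(self, rng: np.random.Generator, n_restarts: int):
        e = self.effect
        c = self.conc
        e0 = max(float(e[np.argmin(np.abs(c - c.min()))]), 1e-6)
        c50 = float(np.median(c[c > 0])) if np.any(c > 0) else 1.0
        if self.mode == "stimulation":
            mag = max(float(e.max() - e0), 1e-3)
            x0 = np.array([math.log(e0), math.log(mag), math.log(c50), 0.0])
        else:
            e0 = max(float(e.max()), 1e-6)
            frac = min(max(1.0 - float(e.min()) / e0, 0.05), 0.95)
            x0 = np.array([math.log(e0), math.log(frac / (1 - frac)),
                           math.log(c50), 0.0])
        starts = [x0]
        for _ in range(n_restarts):
            starts.append(x0 + rng.normal(0.0, 0.5, size=4))
        return starts

    def fit(self, seed: int = 0, n_restarts: int = 8) -> PdFit:
        rng = np.random.default_rng(seed)
        lb = np.array([-np.inf, -np.inf, -np.inf, math.log(HILL_BOUNDS[0])])
        ub = np.array([np.inf, np.inf, np.inf, math.log(HILL_BOUNDS[1])])
        best = None
        for x0 in self._starts(rng, n_restarts):
            x0c = np.clip(x0, lb + 1e-9, ub - 1e-9)
            try:
                sol = least_squares(self._residuals, x0c, bounds=(lb, ub),
                                    method="trf", max_nfev=3000)
            except Exception:
                continue
            ssr = float(2.0 * sol.cost)
            if not np.isfinite(ssr) or ssr >= 1e11:
                continue
            if best is None or ssr < best[0]:
                best = (ssr, sol)
        if best is None:
            raise FitFailedError("PD optimizer failed from every start")
        ssr, sol = best
        params = self._params_from_x(sol.x)
        n, p = self.effect.size, 4
        aic = n * math.log(max(ssr, 1e-300) / n) + 2 * p
        bic = n * math.log(max(ssr, 1e-300) / n) + p * math.log(n)
        cv = self._cv_percent(sol, ssr, n, p, params)
        return PdFit(params, ModelSelectionScores(aic, bic, cv, ssr, n, p),
                     pd_predict(params, self.conc), seed)

    def _cv_percent(self, sol, ssr, n, p, params) -> dict[str, float]:
        names = [k for k in params.as_dict() if k != "mode"]
        vals0 = np.array([v for k, v in params.as_dict().items() if k != "mode"])
        try:
            s2 = ssr / max(n - p, 1)
            cov_x = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        except np.linalg.LinAlgError:
            return {k: math.nan for k in names}
        h = 1e-6
        Jp = np.zeros((vals0.size, sol.x.size))
        for j in range(sol.x.size):
            xp = sol.x.copy()
            xp[j] += h
            vp = np.array([v for k, v in
                           self._params_from_x(xp).as_dict().items()
                           if k != "mode"])
            Jp[:, j] = (vp - vals0) / h
        var = np.clip(np.diag(Jp @ cov_x @ Jp.T), 0.0, None)
        return {name: (float(100.0 * sd / abs(v)) if v != 0 else math.nan)
                for name, v, sd in zip(names, vals0, np.sqrt(var))}


def fit_pd(effect, conc_at_effect, mode: str = "stimulation", *,
           seed: int = 0, n_restarts: int = 8, weights=None) -> PdFit:
    """Fit a Sigmoid-Emax (stimulation) or Sigmoid-Imax (inhibition) model
    to paired effect/concentration observations."""
    return SigmoidEmaxModel(effect, conc_at_effect, mode=mode,
                            weights=weights).fit(seed=seed,
                                                 n_restarts=n_restarts)
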