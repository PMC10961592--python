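"""Compartmental PK models for oral (extravascular) absorption.

One-compartment model (Bateman function)::

    C(t) = dose*ka / (v_f*(ka - ke)) * (exp(-ke*tau) - exp(-ka*tau)),
    tau = max(t - tlag, 0)

Two-compartment model in macro-coefficient form::

    C(t) = A*exp(-alpha*tau) + B*exp(-beta*tau) - (A + B)*exp(-ka*tau)

Only the apparent volume v_f = V/F is identifiable without an intravenous
reference, so dose is carried as a known constant. Both models are fit by
weighted least squares in log-parameter space (positivity enforced by the
transform, alpha > beta by construction), starting from curve-stripping
estimates plus log-jittered restarts. Model selection uses the Gaussian
concentrated-likelihood AIC, n*ln(SSR/n) + 2p, with BIC and per-parameter
CV% as secondary diagnostics.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import (DegenerateRateError, FitFailedError,
                     InsufficientDataError)
from .nca import terminal_slope
from .series import SampleSeries

__all__ = [
    "Pk1CParams", "Pk2CParams", "ModelSelectionScores", "PkFit",
    "OneCompartmentModel", "TwoCompartmentModel", "predict_conc",
    "interval_average_conc", "exponential_terms", "fit_pk", "select_model",
]


@dataclass(frozen=True)
class Pk1CParams:
    """One-compartment first-order absorption parameters."""

    ka: float    # 1/min
    ke: float    # 1/min
    v_f: float   # apparent volume V/F, mL per dose unit
    tlag: float = 0.0

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.ke <= 0 or self.v_f <= 0 or self.tlag < 0:
            raise ValueError("ka, ke, v_f must be > 0 and tlag >= 0")
        if self.ka == self.ke:
            raise DegenerateRateError("ka == ke; reparameterize")

    def as_dict(self) -> dict[str, float]:
        return {"ka": self.ka, "ke": self.ke, "v_f": self.v_f,
                "tlag": self.tlag}


@dataclass(frozen=True)
class Pk2CParams:
    """Two-compartment oral model, macro-coefficient (A/alpha, B/beta) form."""

    ka: float
    alpha: float
    beta: float
    a_coef: float  # ng/mL
    b_coef: float  # ng/mL
    tlag: float = 0.0

    def __post_init__(self) -> None:
        if not (self.alpha > self.beta > 0):
            raise ValueError("need alpha > beta > 0")
        if self.ka <= 0 or self.a_coef <= 0 or self.b_coef <= 0 or self.tlag < 0:
            raise ValueError("ka, a_coef, b_coef must be > 0 and tlag >= 0")

    def as_dict(self) -> dict[str, float]:
        return {"ka": self.ka, "alpha": self.alpha, "beta": self.beta,
                "a_coef": self.a_coef, "b_coef": self.b_coef,
                "tlag": self.tlag}


@dataclass(frozen=True)
class ModelSelectionScores:
    aic: float
    bic: float
    cv_percent: dict[str, float]
    ssr: float
    n_obs: int
    n_params: int


def exponential_terms(params: Pk1CParams | Pk2CParams,
                      dose: float = 1.0) -> list[tuple[float, float]]:
    """Represent C(tau) as sum of coef * exp(-rate * tau) terms.

    The coefficients sum to zero (C(tlag) = 0 for extravascular input),
    which downstream closed forms (interval averages, effect-compartment
    convolution) rely on.
    """
    if isinstance(params, Pk1CParams):
        if abs(params.ka - params.ke) < 1e-12 * params.ka:
            raise DegenerateRateError("ka == ke; macro form undefined")
        a = dose * params.ka / (params.v_f * (params.ka - params.ke))
        return [(a, params.ke), (-a, params.ka)]
    return [(params.a_coef, params.alpha), (params.b_coef, params.beta),
            (-(params.a_coef + params.b_coef), params.ka)]


def predict_conc(params: Pk1CParams | Pk2CParams, times,
                 dose: float = 1.0) -> np.ndarray:
    """Model concentration at the given times (minutes)."""
    t = np.asarray(times, dtype=float)
    tau = np.maximum(t - params.tlag, 0.0)
    out = np.zeros_like(tau)
    for coef, rate in exponential_terms(params, dose):
        out += coef * np.exp(-rate * tau)
    return np.maximum(out, 0.0)


def interval_average_conc(params: Pk1CParams | Pk2CParams, t0, t1,
                          dose: float = 1.0) -> np.ndarray:
    """Exact average of the model curve over collection windows [t0, t1].

    Microdialysis observations are window averages; this is the analytic
    integral of the exponential terms divided by the window width.
    """
    t0 = np.asarray(t0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    width = t1 - t0
    if np.any(width <= 0):
        raise ValueError("need t1 > t0 for every window")
    lo = np.maximum(t0 - params.tlag, 0.0)
    hi = np.maximum(t1 - params.tlag, 0.0)
    total = np.zeros_like(lo)
    for coef, rate in exponential_terms(params, dose):
        total += coef / rate * (np.exp(-rate * lo) - np.exp(-rate * hi))
    return np.maximum(total / width, 0.0)


@dataclass(frozen=True)
class PkFit:
    """Results of a compartmental fit: estimates, diagnostics, predictions."""

    model_id: str  # "1C" or "2C"
    params: Pk1CParams | Pk2CParams
    scores: ModelSelectionScores
    predicted: SampleSeries
    dose: float
    weighting: str
    seed: int
    n_starts: int

    def summary(self) -> str:
        lines = [f"Compartmental PK fit ({self.model_id}), "
                 f"weighting={self.weighting}",
                 f"  n_obs={self.scores.n_obs}  n_params={self.scores.n_params}"
                 f"  SSR={self.scores.ssr:.6g}",
                 f"  AIC={self.scores.aic:.3f}  BIC={self.scores.bic:.3f}",
                 f"  {'param':>8}  {'estimate':>12}  {'CV%':>8}"]
        for name, val in self.params.as_dict().items():
            cv = self.scores.cv_percent.get(name, math.nan)
            lines.append(f"  {name:>8}  {val:12.6g}  {cv:8.3g}")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {"model_id": self.model_id, "params": self.params.as_dict(),
                "aic": self.scores.aic, "bic": self.scores.bic,
                "cv_percent": self.scores.cv_percent,
                "ssr": self.scores.ssr, "n_obs": self.scores.n_obs,
                "n_params": self.scores.n_params, "dose": self.dose,
                "weighting": self.weighting, "seed": self.seed}


class _CompartmentalModel:
    """Shared WLS machinery for the 1C and 2C models (statsmodels-style:
    construct from data, call :meth:`fit`)."""

    model_id: str = ""
    param_names: tuple[str, ...] = ()

    def __init__(self, series: SampleSeries, dose: float = 1.0,
                 weighting: str = "uniform", fit_tlag: bool = False):
        if weighting not in ("uniform", "1/C", "1/C2"):
            raise ValueError(f"unknown weighting {weighting!r}")
        self.series = series.post_dose()
        self.full_series = series
        self.dose = float(dose)
        self.weighting = weighting
        self.fit_tlag = fit_tlag
        self.n_params = len(self.param_names) + (1 if fit_tlag else 0)
        obs = self.series.concentrations
        if len(self.series) < self.n_params + 1:
            raise InsufficientDataError(
                f"{self.model_id}: need > {self.n_params} observations")
        if not np.any(obs > 0):
            raise FitFailedError("all concentrations are zero")
        w = np.ones_like(obs)
        floor = max(obs[obs > 0].min(), 1e-12)
        if self.weighting == "1/C":
            w = 1.0 / np.maximum(obs, floor)
        elif self.weighting == "1/C2":
            w = 1.0 / np.maximum(obs, floor) ** 2
        self._sqrt_w = np.sqrt(w)

    @classmethod
    def from_dataframe(cls, df, analyte: str, subject: str | None = None,
                       **kwargs) -> "_CompartmentalModel":
        from .series import series_from_frame
        interval = kwargs.pop("interval", None)
        dose_time = kwargs.pop("dose_time", 0.0)
        s = series_from_frame(df, analyte, subject, dose_time=dose_time,
                              interval=interval)
        return cls(s, **kwargs)

    # transform x (free vector) <-> natural parameter object
    def _params_from_x(self, x: np.ndarray):
        raise NotImplementedError

    def _initial_points(self, rng: np.random.Generator,
                        n_restarts: int) -> list[np.ndarray]:
        raise NotImplementedError

    def _predict(self, params) -> np.ndarray:
        s = self.series
        if s.interval:
            half = s.interval / 2.0
            return interval_average_conc(params, s.times - half,
                                         s.times + half, self.dose)
        return predict_conc(params, s.times, self.dose)

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        # clip the free vector so exp() stays finite during restarts
        x = np.clip(x, -50.0, 50.0)
        try:
            params = self._params_from_x(x)
            pred = self._predict(params)
        except (DegenerateRateError, ValueError, OverflowError):
            return np.full(len(self.series), 1e6)
        if not np.all(np.isfinite(pred)):
            return np.full(len(self.series), 1e6)
        return self._sqrt_w * (pred - self.series.concentrations)

    def fit(self, seed: int = 0, n_restarts: int = 8,
            jitter_sd: float = 0.5) -> PkFit:
        """Weighted least squares from curve-stripping starts plus
        ``n_restarts`` log-jittered restarts; returns the best-SSR fit."""
        rng = np.random.default_rng(seed)
        starts = self._initial_points(rng, n_restarts)
        best = None
        failures = []
        for x0 in starts:
            try:
                sol = least_squares(self._residuals, x0, method="lm",
                                    max_nfev=2000)
            except Exception as exc:  # pragma: no cover - scipy internal
                failures.append(str(exc))
                continue
            ssr = float(2.0 * sol.cost)
            if not np.isfinite(ssr) or ssr >= 1e11:
                failures.append("diverged")
                continue
            if best is None or ssr < best[0]:
                best = (ssr, sol)
        if best is None:
            raise FitFailedError("optimizer failed from every start",
                                 {"n_starts": len(starts),
                                  "failures": failures})
        ssr, sol = best
        sol.x = np.clip(sol.x, -50.0, 50.0)  # same domain as the residuals
        params = self._params_from_x(sol.x)
        n, p = len(self.series), self.n_params
        aic = n * math.log(max(ssr, 1e-300) / n) + 2 * p
        bic = n * math.log(max(ssr, 1e-300) / n) + p * math.log(n)
        cv = self._cv_percent(sol, ssr, n, p, params)
        pred = replace(self.series, concentrations=self._predict(params))
        return PkFit(self.model_id, params,
                     ModelSelectionScores(aic, bic, cv, ssr, n, p),
                     pred, self.dose, self.weighting, seed, len(starts))

    def _cv_percent(self, sol, ssr: float, n: int, p: int,
                    params) -> dict[str, float]:
        """Asymptotic CV% per natural parameter via the delta method on the
        free-parameter covariance. NaN when the Jacobian is singular."""
        names = list(params.as_dict().keys())
        try:
            J = sol.jac
            s2 = ssr / max(n - p, 1)
            cov_x = s2 * np.linalg.inv(J.T @ J)
        except np.linalg.LinAlgError:
            return {k: math.nan for k in names}
        # numerical jacobian of natural params wrt free vector
        x = sol.x
        vals0 = np.array(list(params.as_dict().values()))
        Jp = np.zeros((vals0.size, x.size))
        h = 1e-6
        for j in range(x.size):
            xp = x.copy()
            xp[j] += h
            try:
                vp = np.array(list(self._params_from_x(xp).as_dict().values()))
            except (ValueError, DegenerateRateError):
                xp[j] -= 2 * h
                vp = np.array(list(self._params_from_x(xp).as_dict().values()))
                Jp[:, j] = (vals0 - vp) / h
                continue
            Jp[:, j] = (vp - vals0) / h
        var = np.clip(np.diag(Jp @ cov_x @ Jp.T), 0.0, None)
        out = {}
        for name, v, sd in zip(names, vals0, np.sqrt(var)):
            out[name] = float(100.0 * sd / abs(v)) if v != 0 else math.nan
        return out


class OneCompartmentModel(_CompartmentalModel):
    """Bateman one-compartment oral model; parameters (ka, ke, v_f[, tlag])."""

    model_id = "1C"
    param_names = ("ka", "ke", "v_f")

    def _params_from_x(self, x: np.ndarray) -> Pk1CParams:
        ka, ke, v_f = np.exp(x[:3])
        tlag = x[3] ** 2 if self.fit_tlag else 0.0
        return Pk1CParams(ka=ka, ke=ke, v_f=v_f, tlag=tlag)

    def _strip(self) -> np.ndarray:
        """Curve-stripping start: ke from the terminal log-linear slope,
        ka a few-fold faster (absorption faster than elimination for a
        post-peak maximum inside the horizon), v_f from matching Cmax."""
        s = self.series
        lam, _, npts, _ = terminal_slope(self.full_series)
        ke0 = lam if np.isfinite(lam) and lam > 0 else 1.0 / max(s.times[-1], 1.0)
        ka0 = 5.0 * ke0
        cmax = float(s.concentrations.max())
        t_at = float(s.times[np.argmax(s.concentrations)])
        try:
            trial = Pk1CParams(ka=ka0, ke=ke0, v_f=1.0)
            scale = float(predict_conc(trial, [t_at], self.dose)[0])
            v0 = max(scale / max(cmax, 1e-12), 1e-9)
        except DegenerateRateError:
            v0 = 1.0
        x = [math.log(ka0), math.log(ke0), math.log(v0)]
        if self.fit_tlag:
            x.append(0.0)
        return np.array(x)

    def _initial_points(self, rng, n_restarts):
        x0 = self._strip()
        starts = [x0]
        for _ in range(n_restarts):
            starts.append(x0 + rng.normal(0.0, 0.5, size=x0.size))
        return starts


class TwoCompartmentModel(_CompartmentalModel):
    """Two-compartment oral model; parameters
    (ka, alpha, beta, a_coef, b_coef[, tlag]), alpha > beta enforced."""

    model_id = "2C"
    param_names = ("ka", "alpha", "beta", "a_coef", "b_coef")

    def _params_from_x(self, x: np.ndarray) -> Pk2CParams:
        ka = math.exp(x[0])
        beta = math.exp(x[1])
        alpha = beta + math.exp(x[2])
        a_coef = math.exp(x[3])
        b_coef = math.exp(x[4])
        tlag = x[5] ** 2 if self.fit_tlag else 0.0
        return Pk2CParams(ka=ka, alpha=alpha, beta=beta, a_coef=a_coef,
                          b_coef=b_coef, tlag=tlag)

    def _strip(self) -> np.ndarray:
        s = self.series
        lam, _, _, _ = terminal_slope(self.full_series)
        beta0 = lam if np.isfinite(lam) and lam > 0 else 1.0 / max(s.times[-1], 1.0)
        alpha0 = 10.0 * beta0
        ka0 = 3.0 * alpha0
        cmax = float(s.concentrations.max())
        b0 = max(cmax, 1e-9)
        a0 = max(0.5 * cmax, 1e-9)
        x = [math.log(ka0), math.log(beta0), math.log(alpha0 - beta0),
             math.log(a0), math.log(b0)]
        if self.fit_tlag:
            x.append(0.0)
        return np.array(x)

    def _initial_points(self, rng, n_restarts):
        x0 = self._strip()
        starts = [x0]
        for _ in range(n_restarts):
            starts.append(x0 + rng.normal(0.0, 0.5, size=x0.size))
        return starts


_MODELS = {"1C": OneCompartmentModel, "2C": TwoCompartmentModel}


def fit_pk(series: SampleSeries, model_id: str = "1C",
           weighting: str = "uniform", *, dose: float = 1.0,
           seed: int = 0, n_restarts: int = 8) -> PkFit:
    """Fit a compartmental model to one concentration-time profile."""
    try:
        cls = _MODELS[model_id]
    except KeyError:
        raise ValueError(f"unknown model_id {model_id!r}") from None
    return cls(series, dose=dose, weighting=weighting).fit(
        seed=seed, n_restarts=n_restarts)


def select_model(fits: list[PkFit]) -> PkFit:
    """Choose the minimal-AIC fit; within a 2-unit AIC band prefer the
    model with fewer parameters (parsimony)."""
    if not fits:
        raise FitFailedError("no fits to select among")
    best_aic = min(f.scores.aic for f in fits)
    band = [f for f in fits if f.scores.aic - best_aic < 2.0]
    return min(band, key=lambda f: (f.scores.n_params, f.scores.aic))
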