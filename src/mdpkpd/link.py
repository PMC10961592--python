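"""Effect-compartment PK-PD link and concentration-effect hysteresis.

A delay between the concentration peak and the effect peak is modelled by a
hypothetical effect compartment equilibrating with the sampled fluid at
first-order rate ke0::

    dCe/dt = ke0 * (Cp(t) - Ce(t)),   Ce(0) = 0

For Cp given as a sum of exponentials (any compartmental oral model), Ce has
the closed form: each term A*exp(-lam*tau) contributes
``A*ke0*(exp(-lam*tau) - exp(-ke0*tau)) / (ke0 - lam)``, with the lam == ke0
limit ``A*ke0*tau*exp(-ke0*tau)``.

The loop traced by plotting effect against concentration in time order
quantifies the delay: with concentration on x and effect on y,
counterclockwise (positive shoelace area) means the effect lags a
stimulatory relationship, clockwise a suppressive one, and the loop
collapses as ke0 grows (instantaneous equilibration).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .compartmental import (ModelSelectionScores, Pk1CParams, Pk2CParams,
                            PkFit, exponential_terms)
from .errors import (FitFailedError, InsufficientDataError,
                     UnidentifiableError)
from .pdmodels import HILL_BOUNDS, PdParams, SigmoidEmaxModel, pd_predict
from .series import EffectSeries, SampleSeries

__all__ = ["LinkParams", "LinkFit", "HysteresisResult",
           "EffectCompartmentLink", "effect_compartment_conc", "fit_link",
           "hysteresis_loop", "classify_relationship"]

#: |normalized_area| below this is indistinguishable from no loop
AREA_TOLERANCE = 0.01


@dataclass(frozen=True)
class LinkParams:
    ke0: float          # 1/min
    pd: PdParams

    def __post_init__(self) -> None:
        if self.ke0 <= 0:
            raise ValueError("ke0 must be positive")

    def as_dict(self) -> dict:
        return {"ke0": self.ke0, **self.pd.as_dict()}


def effect_compartment_conc(pk_params: Pk1CParams | Pk2CParams, ke0: float,
                            times, dose: float = 1.0) -> np.ndarray:
    """Analytic effect-site concentration Ce(t) for a compartmental Cp."""
    if ke0 <= 0:
        raise ValueError("ke0 must be positive")
    t = np.asarray(times, dtype=float)
    tau = np.maximum(t - pk_params.tlag, 0.0)
    ce = np.zeros_like(tau)
    e_ke0 = np.exp(-ke0 * tau)
    for coef, lam in exponential_terms(pk_params, dose):
        if abs(lam - ke0) <= 1e-9 * ke0:
            ce += coef * ke0 * tau * e_ke0
        else:
            ce += coef * ke0 * (np.exp(-lam * tau) - e_ke0) / (ke0 - lam)
    return np.maximum(ce, 0.0)


@dataclass(frozen=True)
class HysteresisResult:
    """Signed loop area of a time-ordered concentration-effect trajectory.

    ``signed_area`` is the shoelace area of the polygon closed last-to-first
    ((ng/mL)*percent); ``normalized_area`` divides by the bounding-box area
    range(conc)*range(effect), so it lies in [-1, 1]. Direction is
    counterclockwise (positive, effect lags a stimulatory relation),
    clockwise (negative, suppressive), or none within tolerance.
    ``open_loop`` flags a closure chord longer than 20% of the bounding-box
    diagonal (start and end effects differ appreciably).
    """

    signed_area: float
    normalized_area: float
    direction: str  # "clockwise" | "counterclockwise" | "none"
    n_points: int
    open_loop: bool = False


def hysteresis_loop(conc, effect, times=None, *,
                    tolerance: float = AREA_TOLERANCE) -> HysteresisResult:
    """Shoelace analysis of a paired concentration-effect trajectory.

    Points are taken in time order (sorted by ``times`` when given), the
    polygon is closed by connecting the last point back to the first, and
    the signed area follows the x = concentration, y = effect convention:
    counterclockwise traversal is positive.
    """
    x = np.asarray(conc, dtype=float)
    y = np.asarray(effect, dtype=float)
    if x.shape != y.shape:
        raise ValueError("conc and effect lengths differ")
    if x.size < 4:
        raise InsufficientDataError("hysteresis loop needs >=4 points")
    if times is not None:
        order = np.argsort(np.asarray(times, dtype=float), kind="stable")
        x, y = x[order], y[order]
    rx, ry = float(np.ptp(x)), float(np.ptp(y))
    area = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    if rx == 0 or ry == 0:
        return HysteresisResult(area, 0.0, "none", x.size)
    norm = area / (rx * ry)
    if norm > tolerance:
        direction = "counterclockwise"
    elif norm < -tolerance:
        direction = "clockwise"
    else:
        direction = "none"
    chord = math.hypot((x[-1] - x[0]) / rx, (y[-1] - y[0]) / ry)
    open_loop = chord > 0.2 * math.sqrt(2.0)
    return HysteresisResult(float(area), float(norm), direction, x.size,
                            open_loop)


def classify_relationship(result: HysteresisResult, mode: str) -> str:
    """Map loop direction plus PD mode to the qualitative interpretation:
    a clockwise loop under inhibition is delayed suppression (the
    excitatory-neurotransmitter pattern), a counterclockwise loop under
    stimulation is delayed enhancement; anything else is atypical."""
    if result.direction == "clockwise" and mode == "inhibition":
        return "delayed suppression (Asp/Glu pattern)"
    if result.direction == "counterclockwise" and mode == "stimulation":
        return "delayed enhancement (Tau/Ach pattern)"
    return "atypical"


@dataclass(frozen=True)
class LinkFit:
    params: LinkParams
    scores: ModelSelectionScores
    predicted_effect: np.ndarray
    ce: np.ndarray
    times: np.ndarray
    seed: int

    def summary(self) -> str:
        lines = [f"Effect-compartment link fit  n_obs={self.scores.n_obs}"
                 f"  SSR={self.scores.ssr:.6g}  AIC={self.scores.aic:.3f}",
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


class EffectCompartmentLink:
    """Sequential (fixed-PK) link model: the compartmental PK fit is frozen
    and (ke0, PD parameters) are estimated by least squares on the observed
    effect series against ``pd_predict(Ce(t; ke0))``."""

    #: log-spaced ke0 multi-start grid, 1/min
    KE0_GRID = (0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0)

    def __init__(self, effect: EffectSeries, pk_fit: PkFit,
                 mode: str = "stimulation", weighting: str = "uniform"):
        # keep pre-dose samples: the effect compartment is empty there
        # (Ce = 0), so they anchor the baseline parameter e0
        if effect.times.size < 6:
            raise InsufficientDataError("link fit needs >=6 effect samples")
        if np.ptp(effect.effect) <= 0:
            raise UnidentifiableError("flat effect series")
        self.effect = effect
        self.pk_fit = pk_fit
        self.mode = mode
        if weighting not in ("uniform", "1/E", "1/E2"):
            raise ValueError(f"unknown weighting {weighting!r}")
        e = effect.effect
        floor = max(e[e > 0].min(), 1e-9)
        if weighting == "1/E":
            w = 1.0 / np.maximum(e, floor)
        elif weighting == "1/E2":
            w = 1.0 / np.maximum(e, floor) ** 2
        else:
            w = np.ones_like(e)
        self._sqrt_w = np.sqrt(w)

    def _params_from_x(self, x: np.ndarray) -> LinkParams:
        ke0 = math.exp(x[0])
        if self.mode == "stimulation":
            mag = math.exp(x[2])
        else:
            mag = 1.0 / (1.0 + math.exp(-x[2]))
        pd = PdParams(e0=math.exp(x[1]), emax_or_imax=mag,
                      c50=math.exp(x[3]), hill_n=math.exp(x[4]),
                      mode=self.mode)
        return LinkParams(ke0=ke0, pd=pd)

    def _predict(self, lp: LinkParams) -> np.ndarray:
        ce = effect_compartment_conc(self.pk_fit.params, lp.ke0,
                                     self.effect.times, self.pk_fit.dose)
        return pd_predict(lp.pd, ce)

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        try:
            pred = self._predict(self._params_from_x(x))
        except (ValueError, OverflowError):
            return np.full(self.effect.times.size, 1e6)
        return self._sqrt_w * (pred - self.effect.effect)

    def fit(self, seed: int = 0, n_restarts: int = 2) -> LinkFit:
        rng = np.random.default_rng(seed)
        e = self.effect.effect
        e0_guess = max(float(e[0]), 1e-6)
        lb = np.array([-np.inf] * 4 + [math.log(HILL_BOUNDS[0])])
        ub = np.array([np.inf] * 4 + [math.log(HILL_BOUNDS[1])])
        best = None
        for ke0 in self.KE0_GRID:
            # scale the C50 guess to the Ce range this ke0 implies
            ce = effect_compartment_conc(self.pk_fit.params, ke0,
                                         self.effect.times, self.pk_fit.dose)
            c50_guess = max(float(np.median(ce[ce > 0])) if np.any(ce > 0)
                            else 1.0, 1e-9)
            if self.mode == "stimulation":
                mag0 = math.log(max(float(e.max()) - e0_guess, 1e-3))
            else:
                frac = min(max(1.0 - float(e.min()) / max(float(e.max()), 1e-9),
                               0.05), 0.95)
                mag0 = math.log(frac / (1 - frac))
                e0_guess = max(float(e.max()), 1e-6)
            x0 = np.array([math.log(ke0), math.log(e0_guess), mag0,
                           math.log(c50_guess), 0.0])
            for trial in range(n_restarts + 1):
                xs = x0 if trial == 0 else x0 + rng.normal(0, 0.4, size=5)
                xs = np.clip(xs, lb + 1e-9, ub - 1e-9)
                try:
                    sol = least_squares(self._residuals, xs, bounds=(lb, ub),
                                        method="trf", max_nfev=3000)
                except Exception:
                    continue
                ssr = float(2.0 * sol.cost)
                if not np.isfinite(ssr) or ssr >= 1e11:
                    continue
                if best is None or ssr < best[0]:
                    best = (ssr, sol)
        if best is None:
            raise FitFailedError("link optimizer failed from every start")
        ssr, sol = best
        lp = self._params_from_x(sol.x)
        n, p = e.size, 5
        aic = n * math.log(max(ssr, 1e-300) / n) + 2 * p
        bic = n * math.log(max(ssr, 1e-300) / n) + p * math.log(n)
        cv = self._cv_percent(sol, ssr, n, p, lp)
        ce = effect_compartment_conc(self.pk_fit.params, lp.ke0,
                                     self.effect.times, self.pk_fit.dose)
        return LinkFit(lp, ModelSelectionScores(aic, bic, cv, ssr, n, p),
                       self._predict(lp), ce, self.effect.times, seed)

    def _cv_percent(self, sol, ssr, n, p, lp: LinkParams) -> dict[str, float]:
        names = [k for k in lp.as_dict() if k != "mode"]
        vals0 = np.array([v for k, v in lp.as_dict().items() if k != "mode"])
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


def fit_link(series: SampleSeries, effect: EffectSeries, pk_fit: PkFit,
             mode: str = "stimulation", *, weighting: str = "uniform",
             seed: int = 0) -> LinkFit:
    """Sequential link estimation: PK frozen from ``pk_fit``, then
    (ke0, PD parameters) fit to the effect series. ``series`` documents the
    concentration observations the PK fit came from (kept for provenance;
    the link itself drives PD through the fitted PK curve)."""
    return EffectCompartmentLink(effect, pk_fit, mode=mode,
                                 weighting=weighting).fit(seed=seed)
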