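"""In-silico microdialysis experiments with known ground truth.

The generator emulates the study design the analysis modules target: rats
in three groups (healthy controls BLA, disease model ADM, treated SCH) are
dosed orally at t = 0; a probe in the hippocampus collects dialysate in
20-min windows over 480 min after one pre-dose blank window. Each observed
lignan concentration is the interval average of a compartmental oral
profile, attenuated by probe recovery (per-analyte fractions inside the
empirically typical 0.19-0.31 band) and corrupted by proportional plus
additive-floor noise. Neurotransmitter responses are driven by the
effect-site concentration of an index lignan through Sigmoid-Emax
(stimulation: Tau, Ach) or Sigmoid-Imax (inhibition: Asp, Glu) models, and
are emitted as raw dialysate concentrations whose baseline differs by group
(excitatory transmitters elevated and inhibitory-pathway ones depressed in
the disease model).

Determinism: one RNG stream per (subject, analyte), keyed from the config
seed, so regenerating with the same seed is byte-identical and adding an
analyte never perturbs existing series.
"""
from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .compartmental import (Pk1CParams, Pk2CParams, interval_average_conc,
                            predict_conc)
from .errors import ConfigError
from .link import LinkParams, effect_compartment_conc
from .pdmodels import PdParams, pd_predict
from .series import write_tidy_csv

__all__ = ["PkTruth", "PdTruth", "SimulationConfig", "SyntheticExperiment",
           "simulate_pk_sample", "simulate_effect_sample",
           "generate_experiment", "default_config", "load_config",
           "DETECTED_LIGNANS", "NEUROTRANSMITTERS"]

#: the eight lignans detectable in hippocampal dialysate
DETECTED_LIGNANS = (
    "schisandrol A", "schisandrol B", "angeloylgomisin H",
    "angeloylgomisin Q", "gomisin K", "schisantherin A",
    "schisantherin B", "schisanhenol",
)

NEUROTRANSMITTERS = ("Asp", "Glu", "Tau", "Ach")

#: dialysate flow rates tested in vitro, µL/min
FLOW_RATES = (1.0, 2.0, 3.0)
#: immersion-standard concentrations for the recovery protocol, ng/mL
RECOVERY_CONCS = (100.0, 500.0, 1000.0)


def v_f_for_cmax(ka: float, ke: float, dose: float, cmax: float) -> float:
    """Apparent volume giving the requested peak concentration for a
    one-compartment oral profile."""
    tmax = math.log(ka / ke) / (ka - ke)
    shape = (math.exp(-ke * tmax) - math.exp(-ka * tmax)) * ka / (ka - ke)
    return dose * shape / cmax


@dataclass(frozen=True)
class PkTruth:
    model_id: str
    params: Pk1CParams | Pk2CParams


@dataclass(frozen=True)
class PdTruth:
    mode: str           # "stimulation" | "inhibition"
    e0: float           # percent, 100 by normalisation
    magnitude: float    # emax (percent) or imax (fraction)
    c50: float          # ng/mL at the effect site
    hill_n: float
    ke0: float          # 1/min
    baseline_ng_ml: float  # raw basal tissue concentration

    def pd_params(self) -> PdParams:
        return PdParams(e0=self.e0, emax_or_imax=self.magnitude,
                        c50=self.c50, hill_n=self.hill_n, mode=self.mode)


@dataclass
class SimulationConfig:
    """Complete ground truth for one in-silico experiment."""

    seed: int = 0
    n_subjects: int = 8
    groups: tuple[str, ...] = ("BLA", "ADM", "SCH")
    interval: float = 20.0       # collection-window width, min
    horizon: float = 480.0       # post-dose sampling horizon, min
    n_baseline: int = 1          # pre-dose blank windows
    dose: float = 100.0          # oral dose, arbitrary dose units
    lignan_pk: dict[str, PkTruth] = field(default_factory=dict)
    nt_pd: dict[str, PdTruth] = field(default_factory=dict)
    recovery: dict[str, float] = field(default_factory=dict)
    group_exposure: dict[str, float] = field(
        default_factory=lambda: {"BLA": 1.0, "ADM": 1.8, "SCH": 1.3})
    group_nt_baseline: dict[str, dict[str, float]] = field(default_factory=dict)
    index_lignan: str = "schisandrol A"
    noise_cv: float = 0.10       # proportional noise
    noise_floor: float = 0.02    # additive noise SD, ng/mL
    calibration_noise_cv: float = 0.01   # response noise of standards
    recovery_noise_cv: float = 0.04      # replicate scatter of recovery assay
    apply_recovery: bool = True

    def validate(self) -> None:
        bad = []
        if self.interval <= 0 or self.horizon <= 0:
            bad.append("interval/horizon")
        elif abs(self.horizon / self.interval - round(self.horizon / self.interval)) > 1e-9:
            bad.append("interval (must divide horizon)")
        if self.n_subjects < 1:
            bad.append("n_subjects")
        for name, r in self.recovery.items():
            if not 0 < r <= 1:
                bad.append(f"recovery[{name}]")
        if self.noise_cv < 0 or self.noise_floor < 0:
            bad.append("noise_cv/noise_floor")
        if self.index_lignan not in self.lignan_pk:
            bad.append("index_lignan")
        for g in self.groups:
            if g not in self.group_exposure:
                bad.append(f"group_exposure[{g}]")
        if bad:
            raise ConfigError("invalid simulation config", bad)

    # -- sampling grid -----------------------------------------------------

    def windows(self) -> list[tuple[float, float]]:
        """All collection windows (pre-dose blanks then post-dose), as
        (start, end) in minutes; dose at t = 0."""
        n_post = int(round(self.horizon / self.interval))
        pre = [(-(i + 1) * self.interval, -i * self.interval)
               for i in reversed(range(self.n_baseline))]
        post = [(i * self.interval, (i + 1) * self.interval)
                for i in range(n_post)]
        return pre + post

    def midpoints(self) -> np.ndarray:
        return np.array([(a + b) / 2 for a, b in self.windows()])


def _stream(seed: int, subject: int, analyte: str) -> np.random.Generator:
    """Independent, reproducible stream per (subject, analyte)."""
    key = zlib.crc32(analyte.encode())
    return np.random.default_rng(np.random.SeedSequence([seed, subject, key]))


def default_config(seed: int = 0, *, noise_cv: float = 0.10,
                   n_subjects: int = 8,
                   apply_recovery: bool = True) -> SimulationConfig:
    """Study-design defaults: 20-min windows over 480 min, one pre-dose
    blank, eight detectable lignans with one-compartment truth, four
    neurotransmitters with effect-compartment Hill truth, per-analyte
    recoveries inside the 0.19-0.31 band."""
    cfg = SimulationConfig(seed=seed, noise_cv=noise_cv,
                           n_subjects=n_subjects,
                           apply_recovery=apply_recovery)
    if noise_cv == 0:  # a noise-free experiment is noise-free throughout
        cfg.noise_floor = 0.0
        cfg.calibration_noise_cv = 0.0
        cfg.recovery_noise_cv = 0.0
    # per-lignan 1C truth: absorption 0.018-0.032 /min, elimination
    # 0.005-0.009 /min, peak tissue concentrations 20-80 ng/mL
    base = [(0.025, 0.0060, 60.0), (0.020, 0.0075, 45.0),
            (0.030, 0.0055, 30.0), (0.022, 0.0085, 25.0),
            (0.028, 0.0065, 70.0), (0.018, 0.0050, 40.0),
            (0.032, 0.0090, 35.0), (0.024, 0.0070, 50.0)]
    recoveries = [0.27, 0.23, 0.20, 0.30, 0.25, 0.19, 0.29, 0.22]
    for name, (ka, ke, cmax), rec in zip(DETECTED_LIGNANS, base, recoveries):
        vf = v_f_for_cmax(ka, ke, cfg.dose, cmax)
        cfg.lignan_pk[name] = PkTruth("1C", Pk1CParams(ka=ka, ke=ke, v_f=vf))
        cfg.recovery[name] = rec
    # neurotransmitter truth; c50 on the effect-site (tissue) scale
    cfg.nt_pd = {
        "Asp": PdTruth("inhibition", 100.0, 0.40, 30.0, 1.5, 0.020, 50.0),
        "Glu": PdTruth("inhibition", 100.0, 0.35, 25.0, 1.3, 0.015, 80.0),
        "Tau": PdTruth("stimulation", 100.0, 60.0, 25.0, 1.5, 0.020, 60.0),
        "Ach": PdTruth("stimulation", 100.0, 80.0, 30.0, 1.2, 0.025, 5.0),
    }
    for nt in NEUROTRANSMITTERS:
        cfg.recovery[nt] = {"Asp": 0.253, "Glu": 0.278,
                            "Tau": 0.255, "Ach": 0.286}[nt]
    # disease model: excitatory transmitters elevated, the others depressed
    cfg.group_nt_baseline = {
        "BLA": {"Asp": 1.0, "Glu": 1.0, "Tau": 1.0, "Ach": 1.0},
        "ADM": {"Asp": 1.5, "Glu": 1.4, "Tau": 0.6, "Ach": 0.55},
        "SCH": {"Asp": 1.15, "Glu": 1.1, "Tau": 0.85, "Ach": 0.8},
    }
    return cfg


def simulate_pk_sample(params: Pk1CParams | Pk2CParams, dose: float,
                       window: tuple[float, float], recovery: float,
                       noise: tuple[float, float],
                       rng: np.random.Generator) -> float:
    """One dialysate observation: interval average of the model curve over
    the collection window, attenuated by probe recovery, then noised
    (proportional CV plus additive floor), truncated at zero."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have t1 > t0")
    if t1 <= 0:  # entirely pre-dose: blank
        value = 0.0
    else:
        value = float(interval_average_conc(params, max(t0, 0.0), t1, dose))
        value *= (t1 - max(t0, 0.0)) / (t1 - t0)  # pre-dose part of window is blank
    value *= recovery
    cv, floor = noise
    value = value * (1.0 + cv * rng.standard_normal()) \
        + floor * rng.standard_normal()
    return max(value, 0.0)


def simulate_effect_sample(link: LinkParams,
                           pk_params: Pk1CParams | Pk2CParams, dose: float,
                           window: tuple[float, float],
                           noise: tuple[float, float],
                           rng: np.random.Generator) -> float:
    """One effect observation (percent of baseline) at the window midpoint:
    pre-dose windows return e0-centred noise, post-dose windows the Hill
    response to the effect-site concentration."""
    t0, t1 = window
    mid = (t0 + t1) / 2.0
    if mid < 0:
        value = link.pd.e0
    else:
        ce = float(effect_compartment_conc(pk_params, link.ke0, [mid], dose)[0])
        value = float(pd_predict(link.pd, [ce])[0])
    cv, _ = noise
    return max(value * (1.0 + cv * rng.standard_normal()), 0.0)


@dataclass
class SyntheticExperiment:
    """Generated tables plus the full truth used to make them."""

    truth: SimulationConfig
    lignans: pd.DataFrame           # tidy: analyte, group, subject, t_min, conc_ng_ml
    neurotransmitters: pd.DataFrame
    calibration: pd.DataFrame       # analyte, nominal_conc_ng_ml, peak_area, replicate
    recovery: pd.DataFrame          # analyte, flow_rate_ul_min, nominal..., dialysate...

    def write(self, outdir) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [("lignans", self.lignans),
                         ("neurotransmitters", self.neurotransmitters),
                         ("calibration", self.calibration),
                         ("recovery", self.recovery)]:
            p = outdir / f"{name}.csv"
            write_tidy_csv(df, p)
            paths[name] = str(p)
        manifest = outdir / "truth.json"
        manifest.write_text(json.dumps(_truth_dict(self.truth), indent=2,
                                       sort_keys=True))
        paths["truth"] = str(manifest)
        return paths


def _truth_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["lignan_pk"] = {k: {"model_id": v.model_id, **v.params.as_dict()}
                      for k, v in cfg.lignan_pk.items()}
    d["nt_pd"] = {k: asdict(v) for k, v in cfg.nt_pd.items()}
    d["groups"] = list(cfg.groups)
    return d


def generate_experiment(config: SimulationConfig) -> SyntheticExperiment:
    """Simulate the full experiment for every group, subject and analyte."""
    config.validate()
    windows = config.windows()
    noise = (config.noise_cv, config.noise_floor)
    lig_rows, nt_rows = [], []
    for gi, group in enumerate(config.groups):
        expo = config.group_exposure[group]
        for subj in range(config.n_subjects):
            subject = f"{group}{subj + 1:02d}"
            subj_key = gi * 1000 + subj
            for name, truth in config.lignan_pk.items():
                rng = _stream(config.seed, subj_key, name)
                rec = config.recovery.get(name, 1.0) if config.apply_recovery else 1.0
                for (t0, t1) in windows:
                    val = simulate_pk_sample(truth.params, config.dose * expo,
                                             (t0, t1), rec, noise, rng)
                    lig_rows.append((name, group, subject, (t0 + t1) / 2, val))
            driver = config.lignan_pk[config.index_lignan].params
            for nt, pdt in config.nt_pd.items():
                rng = _stream(config.seed, subj_key, nt)
                basal_mult = config.group_nt_baseline.get(group, {}).get(nt, 1.0)
                rec = config.recovery.get(nt, 1.0) if config.apply_recovery else 1.0
                basal_raw = pdt.baseline_ng_ml * basal_mult * rec
                link = LinkParams(ke0=pdt.ke0, pd=pdt.pd_params())
                for (t0, t1) in windows:
                    eff = simulate_effect_sample(link, driver,
                                                 config.dose * expo,
                                                 (t0, t1), noise, rng)
                    nt_rows.append((nt, group, subject, (t0 + t1) / 2,
                                    basal_raw * eff / 100.0))
    cols = ["analyte", "group", "subject", "t_min", "conc_ng_ml"]
    lignans = pd.DataFrame(lig_rows, columns=cols)
    nts = pd.DataFrame(nt_rows, columns=cols)
    calibration = _calibration_table(config)
    recovery = _recovery_table(config)
    return SyntheticExperiment(config, lignans, nts, calibration, recovery)


def _calibration_table(config: SimulationConfig) -> pd.DataFrame:
    """Dual-range calibration standards per analyte (triplicate), with a
    1% proportional response noise."""
    rows = []
    low_grid = [1.0, 2.0, 5.0, 10.0, 25.0, 50.0, 100.0]
    high_grid = [10.0, 50.0, 100.0, 250.0, 500.0, 750.0, 1000.0]
    analytes = list(config.lignan_pk) + list(config.nt_pd)
    for ai, name in enumerate(analytes):
        rng = _stream(config.seed, 10_000 + ai, "calibration")
        slope = 30.0 + 10.0 * (ai % 5)      # response units per ng/mL
        intercept = 5.0 * ((ai % 3) - 1)
        for rng_name, grid in [("low", low_grid), ("high", high_grid)]:
            for conc in grid:
                for rep in range(3):
                    area = (slope * conc + intercept) \
                        * (1.0 + config.calibration_noise_cv
                           * rng.standard_normal())
                    rows.append((name, rng_name, conc, area, rep + 1))
    return pd.DataFrame(rows, columns=["analyte", "range", "nominal_conc_ng_ml",
                                       "peak_area", "replicate"])


def _recovery_table(config: SimulationConfig) -> pd.DataFrame:
    """In-vitro immersion protocol: three flow rates x three standard
    concentrations x triplicate, recovery peaking at 2.0 µL/min."""
    # relative recovery vs flow rate, peaking at the middle rate
    flow_shape = {1.0: 0.78, 2.0: 1.0, 3.0: 0.60}
    rows = []
    analytes = list(config.lignan_pk) + list(config.nt_pd)
    for ai, name in enumerate(analytes):
        rng = _stream(config.seed, 20_000 + ai, "recovery")
        r2 = config.recovery.get(name, 0.25)
        for flow in FLOW_RATES:
            r = r2 * flow_shape[flow]
            for conc in RECOVERY_CONCS:
                for rep in range(3):
                    dialysate = conc * r * (1.0 + config.recovery_noise_cv
                                            * rng.standard_normal())
                    rows.append((name, flow, conc, max(dialysate, 0.0), rep + 1))
    return pd.DataFrame(rows, columns=["analyte", "flow_rate_ul_min",
                                       "nominal_conc_ng_ml",
                                       "dialysate_conc_ng_ml", "replicate"])


def load_config(path) -> SimulationConfig:
    """Read a simulation config from TOML, overriding the defaults.

    Recognised top-level keys: seed, n_subjects, groups, interval, horizon,
    n_baseline, dose, index_lignan, noise_cv, noise_floor, apply_recovery,
    plus [recovery], [group_exposure] and per-analyte [lignan_pk.<name>]
    / [nt_pd.<name>] tables.
    """
    import tomllib
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = default_config(seed=int(raw.get("seed", 0)))
    for key in ("n_subjects", "interval", "horizon", "n_baseline", "dose",
                "index_lignan", "noise_cv", "noise_floor", "apply_recovery"):
        if key in raw:
            setattr(cfg, key, raw[key])
    if "groups" in raw:
        cfg.groups = tuple(raw["groups"])
    cfg.recovery.update(raw.get("recovery", {}))
    cfg.group_exposure.update(raw.get("group_exposure", {}))
    for name, spec in raw.get("lignan_pk", {}).items():
        params = Pk1CParams(ka=spec["ka"], ke=spec["ke"], v_f=spec["v_f"],
                            tlag=spec.get("tlag", 0.0))
        cfg.lignan_pk[name] = PkTruth(spec.get("model_id", "1C"), params)
    for name, spec in raw.get("nt_pd", {}).items():
        cfg.nt_pd[name] = PdTruth(
            mode=spec["mode"], e0=spec.get("e0", 100.0),
            magnitude=spec["magnitude"], c50=spec["c50"],
            hill_n=spec.get("hill_n", 1.0), ke0=spec["ke0"],
            baseline_ng_ml=spec.get("baseline_ng_ml", 50.0))
    cfg.validate()
    return cfg
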