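# mdpkpd

Microdialysis PK-PD analysis for awake-animal neuropharmacology studies:
from LC-MS/MS method-validation arithmetic to effect-compartment
hysteresis. The package targets the common design in which a probe in the
brain (e.g. rat hippocampus) collects dialysate in fixed 20-min windows for
8 h after an oral dose, and both the drug's active components (here:
*Schisandra chinensis* lignans) and endogenous response markers
(neurotransmitters Asp, Glu, Tau, Ach) are quantified from the same
samples. It is written for pharmacometricians and analytical chemists who
want a scriptable, fully reproducible alternative to point-and-click NCA /
PK-PD tools for this kind of data.

## What it computes

- **Calibration & QC** (`mdpkpd.calibration`) — dual-range linear
  calibration curves (peak area = slope·C + intercept per range), LOD/LOQ
  from the S/N ≥ 3 and S/N ≥ 10 conventions, QC levels (3×LLOQ, 40% ULOQ,
  80% ULOQ), replicate precision RSD% and accuracy RE%, matrix effect.
- **Probe recovery** (`mdpkpd.recovery`) — gain-mode relative recovery
  R = C_dialysate / C_medium from in-vitro immersion tests across perfusion
  rates; flow-rate selection by maximal mean recovery; correction
  C_tissue = C_dialysate / R.
- **NCA** (`mdpkpd.nca`) — Cmax, Tmax, AUC0-t, AUC0-∞, λz (adjusted-R²
  window search), t½ = ln 2/λz, MRT0-∞ = AUMC/AUC. Because microdialysis
  samples are interval averages, a declared collection-window width makes
  the AUC an exact window sum rather than a midpoint trapezoid.
- **Compartmental PK** (`mdpkpd.compartmental`) — one-compartment
  (Bateman) and two-compartment oral models,

      C(t) = (D·ka)/(V/F·(ka−ke)) · (e^(−ke·t) − e^(−ka·t))            [1C]
      C(t) = A·e^(−αt) + B·e^(−βt) − (A+B)·e^(−ka·t)                    [2C]

  fit by multi-start weighted least squares in log-parameter space, scored
  by AIC = n·ln(SSR/n) + 2p, BIC, and per-parameter CV%; model selection by
  minimal AIC with a 2-unit parsimony band.
- **Pharmacodynamics** (`mdpkpd.pdmodels`) — baseline normalisation to
  percent of the first basal sample (pinned to exactly 100%), then Hill
  models: stimulation E = E0 + Emax·Cⁿ/(EC50ⁿ + Cⁿ), inhibition
  E = E0·(1 − Imax·Cⁿ/(IC50ⁿ + Cⁿ)).
- **PK-PD link & hysteresis** (`mdpkpd.link`) — effect compartment
  dCe/dt = ke0·(Cp − Ce) solved in closed form for any sum-of-exponentials
  PK; sequential (fixed-PK) estimation of (ke0, Hill parameters); shoelace
  signed area of the concentration-effect trajectory, with
  counterclockwise = delayed enhancement and clockwise = delayed
  suppression.
- **Synthetic experiments** (`mdpkpd.simulate`) — complete in-silico
  studies with known ground truth (three animal groups, interval-averaged
  sampling, probe-recovery attenuation, proportional + floor noise), used
  throughout the test suite to validate the estimators.

## Worked example

```python
import mdpkpd as m
from mdpkpd.pipeline import analyze_experiment

cfg = m.default_config(seed=7, noise_cv=0.05, n_subjects=4)
exp = m.generate_experiment(cfg)                  # tidy CSV-shaped tables
res = analyze_experiment(exp.lignans, exp.neurotransmitters, exp.recovery,
                         index_lignan="schisandrol A", dose=cfg.dose, seed=0)

print(res.flow_rate, res.analyte_recovery["schisandrol A"])
print(res.pk_fits[("schisandrol A", "ADM")].summary())
print(res.link_fits[("Tau", "ADM")].summary())
```

Output (abridged):

```
chosen flow rate: 2.0 µL/min; recovery(schisandrol A) = 0.266
NCA (ADM): Cmax 109.4 ng/mL, Tmax 70 min, AUC0-t 26529 ng*min/mL, t1/2 110 min
Compartmental PK fit (1C), weighting=uniform
  n_obs=24  n_params=3  SSR=32.3561
  AIC=13.170  BIC=16.704
     param      estimate       CV%
        ka     0.0242768      2.57
        ke    0.00599562      1.71
       v_f      0.581667      1.29
Effect-compartment link fit  n_obs=25  SSR=324.444  AIC=74.081
     param      estimate       CV%
       ke0     0.0215896      16.3
        e0       98.6005      3.94
      emax       63.0617      16.9
      ec50        20.672      24.1
    hill_n       1.18383      33.3
Tau/ADM loop: counterclockwise (normalized area 0.402)
              -> delayed enhancement (Tau/Ach pattern)
```

Reading it: the probe recovers ~27% of the surrounding concentration at
the selected 2.0 µL/min perfusion rate, so dialysate concentrations are
multiplied by ~3.8 before PK analysis. The disease-model (ADM) group's
schisandrol A profile is one-compartment with absorption t½ ≈ 29 min and
elimination t½ ≈ 116 min (generating values 0.025 and 0.006 /min; both
recovered within ~3%). The taurine response lags the concentration — the
fitted equilibration rate ke0 ≈ 0.022/min means the effect site tracks
plasma with a ~32 min half-time — producing the counterclockwise
concentration-effect loop typical of a delayed stimulatory response.

A `mdpkpd` console script wraps the same pipeline
(`mdpkpd simulate | calibrate | recover | nca | fit-pk | fit-pd | link |
report`), writing tidy CSV/JSON artifacts plus a run manifest per stage.

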