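# Methods

This note documents the models, estimators, numerical choices and known
limitations of `mdpkpd`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model

A microdialysis observation is not an instantaneous concentration: the
probe integrates the extracellular fluid over a collection window (20 min
in the default design) and the assay reports the window average, further
attenuated by the probe's relative recovery R ∈ (0, 1]. `SampleSeries`
therefore carries (a) midpoint-assigned times — a 0–20 min sample sits at
t = 10, which makes the window average a second-order-accurate point
estimate of a smooth profile — and (b) the window width itself, so that
estimators may exploit the interval-average structure instead of merely
tolerating it.

## Calibration and validation arithmetic

Per-range ordinary least squares of peak area on concentration, unweighted
by default (a 1/x² option exists for assays whose variance grows with
concentration). Two overlapping ranges per analyte are supported because
dialysate assays typically pair a dense low range that brackets the LOQ
with a wide high range; when a back-calculated concentration falls in the
overlap the lower range wins (its low-end design is denser) and the result
is flagged. LOD and LOQ come from the signal-to-noise convention
(k·noise_sd/slope with k = 3 and 10); the noise SD is supplied by the
caller — the package does not parse chromatograms. RSD uses the n−1 sample
standard deviation, the bioanalytical convention at n = 3–6 replicates.

## Probe recovery

Gain-mode (immersion) relative recovery only; loss-mode retrodialysis and
in-vivo calibration (no-net-flux) are out of scope. Recovery is estimated
per (analyte, flow rate, standard concentration) cell from ≥3 replicates;
the operating flow rate maximises mean recovery across analytes, ties
breaking toward the lower rate. Concentration-independence is checked, not
assumed: a linear trend of recovery across the standard-concentration grid
exceeding 20% (relative, configurable) raises a warning. Whether
downstream PK uses recovery-corrected concentrations is a pipeline flag
(default: corrected); the correction C/R is exact for the generator's
attenuation model, so round trips are bit-clean.

## Non-compartmental analysis

- **AUC.** Three variants. `linear`: trapezoid anchored at zero
  concentration at the dose time. `linlog`: linear up / log down. For
  interval-averaged series (`interval` set), the default `auto` resolves
  to exact window sums: Σ C̄ᵢ·Δ telescopes to the integral over the covered
  span with no discretization error, because each C̄ᵢ *is* the window mean.
  On this design the midpoint trapezoid carries ~1.7% error (dominated by
  the poorly resolved absorption phase at 20-min resolution, where
  log-down interpolation does not help either), so the window-sum
  estimator is the package's default for microdialysis data.
- **λz.** Log-linear OLS over candidate terminal windows: every contiguous
  run of the last k ≥ 3 positive post-Tmax samples, Cmax excluded;
  maximise adjusted R², ties to the longer window. Zero (below-LOQ)
  samples are dropped from the regression but retained as zeros in AUC.
- **Extrapolation.** AUC0-∞ = AUC0-t + C_last/λz; AUMC via the first
  moment plus C_last·t_last/λz + C_last/λz²; MRT = AUMC/AUC. Pre-dose
  baselines are not subtracted for exogenous analytes (true zero
  baseline).

## Compartmental PK

One-compartment (Bateman) and two-compartment oral models in
macro-coefficient form. Only V/F is identifiable without an intravenous
arm, so dose is a carried constant. Fitting is multi-start weighted least
squares in log-parameter space (positivity structural; α > β enforced by
parameterising log β and log(α − β)): a curve-stripping start (terminal
slope → ke or β; Cmax scaling → V/F or coefficients) plus 8 log-jittered
restarts, seed recorded. When the series declares a collection interval
the model predicts window averages (analytic integrals of the exponential
terms), which removes midpoint bias entirely — noise-free recovery is
exact to optimizer tolerance.

Weighting: `uniform` (default for real dialysate work, where
concentrations span < 2 orders of magnitude), `1/C`, `1/C²`. The
simulation studies in the test suite use 1/C² because their noise is
proportional by construction; that is the variance-matched (maximum
likelihood) choice, and with uniform weights the heteroscedastic
misspecification measurably inflates absorption-rate error and lets the
richer model absorb noise.

Scores: AIC = n·ln(SSR/n) + 2p (Gaussian concentrated likelihood;
additive constants cancel in comparisons), BIC with p·ln n, CV% from the
asymptotic covariance at the optimum mapped to natural parameters by the
delta method. Selection: minimal AIC; within a 2-unit band the model with
fewer parameters wins. At n = 24 this rule still prefers the
two-compartment model for ~6% of one-compartment datasets — an intrinsic
property of AIC at this sample size, not an optimizer failure — so
selection claims in the tests are statistical (18–20 of 20 replicates),
not absolute.

## Pharmacodynamics and the effect-compartment link

Neurotransmitter series are normalised to percent of the first pre-dose
basal sample (pinned to exactly 100; a mean-of-window rule is available).
Stimulatory responses use E = E0 + Emax·Cⁿ/(EC50ⁿ + Cⁿ); inhibitory
responses use the multiplicative form E = E0·(1 − Imax·Cⁿ/(IC50ⁿ + Cⁿ)),
which keeps the effect non-negative and makes Imax a scale-free fraction
in (0, 1]. The Hill exponent is estimated within [0.1, 10] to exclude
step-function degeneracy. Transforms: log E0, log Emax / logit Imax,
log C50, log n.

The concentration-effect delay is modelled by a hypothetical effect
compartment, dCe/dt = ke0·(Cp − Ce), solved in closed form for any
sum-of-exponentials Cp (each A·e^(−λt) term contributes
A·ke0·(e^(−λt) − e^(−ke0·t))/(ke0 − λ); the λ = ke0 limit is
A·ke0·t·e^(−ke0·t)). Estimation is sequential, mirroring the usual
two-stage workflow: the compartmental PK fit is frozen, then (ke0, Hill
parameters) are fit to the effect series with a multi-start over a log ke0
grid (0.001–1 /min). Pre-dose effect samples are retained in the fit —
the effect compartment is empty there, so they anchor E0; without them the
optimizer can wander to degenerate near-zero-baseline solutions.

Identifiability caveat: with all five parameters free and ~10%
proportional effect noise on a 24-point series, the asymptotic CV of ke0
is ~40–45% — the data simply carry limited information about the
equilibration rate, and median recovery errors of 20–40% across seeds are
expected and observed. Reported CV% values surface this honestly.

## Hysteresis

The time-ordered (concentration, effect) trajectory is closed
last-to-first and its shoelace signed area computed with concentration on
x and effect on y, so counterclockwise is positive. The normalised area
divides by the bounding-box area, giving a dimensionless loop strength in
[−1, 1]; |normalised area| < 0.01 is classified as no loop, and a closure
chord exceeding 20% of the bounding-box diagonal flags an open loop.
Interpretation follows the standard reading: counterclockwise under a
stimulatory model is delayed enhancement, clockwise under an inhibitory
model is delayed suppression; other combinations are atypical.

Discretization floor: points sampled from a strictly single-valued
concentration-effect relation still enclose a polygon sliver between the
rising-limb and falling-limb chords. On the 20-min grid with a curved
Hill response this floor is |normalised area| ≈ 0.08, far above the 0.01
tolerance, so "no hysteresis" claims (e.g. the ke0 → ∞ limit) must be
evaluated on a dense grid; the tests use 2-min spacing, where the floor
is ~0.003.

## Synthetic experiments

The generator emulates the target study design: groups BLA (healthy
control), ADM (disease model) and SCH (treated), 8 subjects/group by
default, one pre-dose blank window then 24 post-dose 20-min windows
(480 min), oral dosing at t = 0. Eight detectable lignans receive
one-compartment truths (absorption 0.018–0.032 /min, elimination
0.005–0.009 /min, peak tissue concentrations 20–80 ng/mL — slow oral
kinetics plausible for herbal lignan constituents); per-analyte probe
recoveries sit inside the empirically typical 0.19–0.31 band. Four
neurotransmitters respond to the effect-site concentration of an index
lignan: Asp/Glu inhibitory (Imax 0.35–0.40), Tau/Ach stimulatory
(Emax 60–80%), ke0 0.015–0.025 /min, C50 near the mid-range of the
effect-site excursion. Group structure: ADM has 1.8× (SCH 1.3×) the
lignan exposure of BLA — emulating a compromised blood-brain barrier —
and shifted neurotransmitter baselines (excitatory up to 1.4–1.5×,
Tau/Ach down to 0.55–0.6×), so noise-free group AUC ordering
ADM > SCH > BLA and the direction pattern of the loops are assertable.
Noise is proportional (default CV 10%) plus an additive floor
(0.02 ng/mL), truncated at zero; a noise-free configuration silences the
calibration and recovery assay noise too. One RNG stream per
(subject, analyte), keyed from the config seed, makes regeneration
byte-identical and insertion-stable.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: probe depletion and tissue trauma
transients, drift in recovery over a session, correlated assay error
across analytes in one injection, circadian baseline drift in
neurotransmitters, inter-subject PK variability beyond group multipliers,
and indirect-response (turnover) PD dynamics. The link model is an
effect-compartment approximation; mechanistically a turnover model may be
more faithful for neurotransmitter pools, but the effect-compartment +
Hill combination is what the target workflow fits.

## Problem sizes and runtime choices

The simulation studies use 20 replicates per condition, 24-sample series,
and 1–4 subjects/group in pipeline round trips — sizes at which every
estimator's behaviour is already stable and the full suite plus the
acceptance script run in a couple of minutes on one CPU. Fit multi-starts
(1 stripped + 8 jittered; 7-point ke0 grid × 3 for the link) were sized so
that doubling them changes no reported estimate.
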