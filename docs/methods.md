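# Methods

## The relaxation model

An amorphous freeze-dried cake stored below its glass transition
temperature T_g releases its excess enthalpy slowly; the rate of that
release is a direct probe of global (α) molecular mobility, which in turn
controls how soon the amorphous matrix can crystallize.  `lyorelax` models
the unreleased fraction with the modified stretched exponential (MSE), a
two-timescale variant of the Kohlrausch–Williams–Watts (KWW) function:

    Φ(t) = exp[ −(t/τ₀) · (1 + t/τ₁)^(β−1) ],     τ₀ > τ₁ > 0,  0 < β ≤ 1.

At short times (t ≪ τ₁) the exponent is ≈ t/τ₀ (simple exponential); at
long times it approaches (t/τ)^β with τ^β = τ₀·τ₁^(β−1), i.e. a KWW decay.
An isothermal microcalorimeter measures the mass-normalised exothermic
power, which is the exact derivative of the enthalpy reservoir:

    P(t) = −277.8 · ΔH_r∞ · dΦ/dt
         = 277.8 · (ΔH_r∞/τ₀) · (1 + β·t/τ₁) · (1 + t/τ₁)^(β−2) · Φ(t)

in µW/g, with t in hours and the constant 277.8 ≈ 10⁶/3600 converting
J/(g·h) to µW/g.  The amplitude ΔH_r∞ = (T_g − T)·Δc_p (J/g) is the
maximum recoverable relaxation enthalpy; it is computed from DSC-derived
T_g and Δc_p and held fixed during fitting, never estimated from the IMC
record (the 12-h record contains far too little of the total decay to
identify an amplitude).  Samples at or above T_g are rejected — the model
has no meaning there.

The derivative identity is not decorative: it implies energy conservation
(∫₀^∞ P dt = 277.8·ΔH_r∞ µW·h/g) and both are enforced by tests, the
former to 10⁻⁶ relative by finite differences, the latter to 0.1 % by
log-time adaptive quadrature (plain quadrature on [0, ∞) fails for
β ≲ 0.1, whose stretched tail carries mass out to astronomically long
times).

### The τ_β summary

Fits of the MSE leave τ₀, τ₁ and β strongly correlated; no single raw
parameter is a robust mobility summary.  The package reports the composite

    τ_β = τ₀ · τ₁^(β−1)   [hours],

the quantity the long-time KWW exponent actually depends on.  It reduces
to τ₀ when τ₁ = 1 h or β = 1.  An alternative convention τ₀^β is
selectable (`tau_beta(params, "tau0_beta")`), and every fit-report row
records which convention produced its value.

## Fitting

`fit_mse` minimises unweighted squared residuals between the observed
power and the model.  The constraints τ₀ > τ₁ and 0 < β ≤ 1 are built into
the optimisation by reparameterisation —

    τ₁ = exp(u₁),  τ₀ = τ₁ + exp(u₂),  β = 1/(1 + exp(−u₃))

— so every iterate is admissible and no post-hoc clipping can produce
boundary-stuck estimates.  The unconstrained problem is solved with
Levenberg–Marquardt (`scipy.optimize.least_squares`, ftol 10⁻¹⁰, at most
5000 evaluations); identical inputs give bit-identical results.
Conventional starting values are τ₀ = 2 h, τ₁ = 1 h, β = 0.1.  A record
with no signal (all zeros / non-finite) returns a flagged non-converged
result rather than raising.  On noiseless synthetic records the fit
recovers generating parameters to ~10⁻³ relative or better; with 1 % white
noise the median τ_β error over 20 seeds is ≈ 0.3 %.

Records are fitted over their first 12 h (`preprocess` trims without
re-zeroing the time origin; default trim_start = 0, configurable up to
1 h if an equilibration transient must be cut).

## DSC feature extraction

Curves arrive already deconvolved (reversing + total), endothermic-up.
Conventions are standard thermal-analysis practice:

- **T_g midpoint**: temperature at half the step height between linear
  pre- and post-transition baselines (fitted over 15 K windows offset 5 K
  from the transition region, located via the smoothed derivative);
  **onset**: intersection of the pre-transition baseline with the tangent
  at the steepest slope.  **Δc_p**: baseline-to-baseline step divided by
  the heating rate.  A step below 5× the robust noise level raises
  "no glass transition found".
- **Crystallization exotherm** (total curve): detected as a downward peak
  ≥ 5× noise; onset by leading-edge tangent intersection with a local
  linear baseline; enthalpy as the baseline-subtracted area divided by the
  heating rate, hence invariant to heating rate and to any linear baseline
  tilt.  Several exotherms → the lowest-temperature one is analysed with a
  warning.

At signal-to-noise 50 the midpoint is recovered within 0.2 K and Δc_p
within 3 % across T_g from ~45 to ~110 °C.

## Crystallization times

**Fast path (IMC).**  Fast-crystallizing samples stay in the calorimeter
until the crystallization exotherm appears.  `detect_exotherm_peaks`
refits the MSE model on the first 12 h (where relaxation dominates),
subtracts it, smooths the residual over 15 min, and finds peaks whose
prominence exceeds 5× a median-absolute-deviation white-noise estimate.
Each peak's time is then refined by fitting a two-sided Gaussian plus a
local linear background on the raw residual, left to right, subtracting
each fitted peak before refining the next so that the slow tail of an
earlier exotherm cannot bias a later one (pooled vials produce double
peaks a few days apart).  The refined time is not quantised to the
sampling grid; in practice it lands well within one sampling interval of
the true maximum.  The crystallization time is the selected peak maximum:
policy `first` (default — the first vial to crystallize), `largest-area`,
or `mean-of-maxima`.

**Slow path (storage DSC).**  Slow samples are stored and aliquots
measured weekly.  As the cake crystallizes, the above-T_g exotherm
shrinks; the default rule takes the first time the exotherm enthalpy falls
below θ = 0.5 of its week-0 value, linearly interpolated between adjacent
weeks.  Enthalpy is preferred over the onset-temperature drop because it
tracks the remaining amorphous fraction directly; an `onset-drop` rule
(default 5 K) is provided as the alternative.  The rule is invariant to
uniform enthalpy rescaling; never crossing → still amorphous (`None`);
zero from week 0 → already crystalline (time 0).

## Correlation and prediction

Within one formulation at one storage temperature, crystallization time is
regressed on τ_β by ordinary least squares (prediction direction), with
r² = 1 − RSS/TSS and Kendall τ-b quantifying rank agreement between the
mobility ordering and the crystallization ordering.  Fits on fewer than
four points warn (not robust); pooling across formulations raises — only
processes of the same formulation are comparable.  Predictions for a new
process carry a standard OLS new-observation interval
point ± t·s·√(1 + 1/n + (x−x̄)²/S_xx), an extension beyond what such
studies usually report; queries outside 2× the fitted τ_β range are
flagged as extrapolation.

## The synthetic study

No raw instrument data are publicly available for this kind of study, so
the generator emulates the design end to end with known ground truth: five
freezing-step variants (CN, AN1.5, RN, AN3.0, QN) of one formulation at 25
and 40 °C.  Defaults, with reasoning:

- **True mobility**: τ₁ = 1 h, β = 0.15, τ₀ = 1.2/2.0/2.6/3.3/4.8 h for
  CN/AN1.5/RN/AN3.0/QN, i.e. τ_β spanning the realistic 1–5 h range at
  40 °C with controlled nucleation fastest and quench cooling slowest.
  At 25 °C all τ_β are multiplied by 2.5 (mobility slows below 40 °C; the
  default keeps the ordering, though real samples can reorder between
  temperatures — a limitation, see below).
- **Crystallization law**: t_c = a + b·τ_β + N(0, σ_c) with a = 0,
  b = 601.35 h per hour of τ_β, σ_c = 36 h (≈ 1.5 d, reflecting the
  few-day crystallization scatter between individual vials).
- **Acquisition**: 2 s sampling for the first hour, 10 s thereafter
  (5760 points per 12-h record); records longer than 24 h switch to 60 s
  to keep multi-day files proportionate — the peaks they exist to carry
  are hours wide.  White noise σ = 1 µW/g and a 0.02 µW/g/h linear drift.
- **IMC exotherm**: two-sided Gaussian (rise 6 h, fall 18 h), height
  415 µW/g so that its area matches the ~45 J/g crystallization enthalpy
  carried by the DSC exotherm — the two instruments see the same energy.
  Optional pooled-vial double peak (second maximum 2–5 d later) and an
  optional early-transient component for CN-like records (exothermic spike
  at 0.58 h), both off by default; they exist to stress the detector and
  fitter, not to model their physics.
- **DSC**: logistic c_p step (10–90 % width 3 K) on a gently sloped
  baseline, Gaussian exotherm placed so its tangent-method onset is exact
  (onset = centre − 2σ for a Gaussian), SNR 50.
- **Storage**: amorphous fraction decays logistically (scale 1 d) centred
  on the true crystallization time, so the θ = 0.5 enthalpy crossing
  recovers the truth up to weekly-grid interpolation; the exotherm onset
  drifts down by up to 15 K in proportion.  Enthalpy measurement noise 2 %.
- **Moisture**: an optional per-process factor multiplies τ_β and t_c
  together, emulating proportional plasticization of both.

All randomness flows from one integer seed: each record draws from
`SeedSequence([seed, crc32(role/labels)])`, so studies are bit-reproducible
and adding a record never perturbs the others.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: instrument baseline steps and disturbances
(ampoule lowering artefacts), non-white 1/f noise, relaxation that
deviates from the MSE form, crystallization exotherms of other shapes or
with incomplete conversion, vial-to-vial heterogeneity beyond the
double-peak option, temperature-dependent reordering of processes, and any
mechanistic link between formulation composition (e.g. surfactant content)
and the crystallization law.  The pipeline's accuracy numbers are
conditional on the generative model; on real records the MSE fit quality
(r²_fit, rss) and the peak-detection diagnostics must be inspected.

## Numerical choices and degenerate inputs

- Internal time unit is hours everywhere; readers convert seconds at
  ingestion, and the unit of a CSV time column must be stated explicitly.
- The 277.8 prefactor is used exactly as printed (not 10⁶/3600 =
  277.78), so "energy conservation" holds to the 0.008 % the rounded
  constant allows — inside the 0.1 % test tolerance.
- Fit non-convergence and empty peak lists are values, not exceptions;
  malformed files and inadmissible parameters raise with the offending
  line or constraint named.
- Ties in Kendall τ use the τ-b convention; an all-tied input is an error.
- A perfect-fit correlation has residual s = 0 and a zero-width prediction
  interval; with n = 2 there are no residual degrees of freedom and the
  interval is undefined (NaN bounds).

## Problem sizes

The test suite and the analysis scripts run desk-scale by construction:
12-h records are 5760 points; fast-path multi-day records are ~10⁴–10⁵
points at 60 s sampling; Monte-Carlo checks use 10–20 seeds for fit
recovery and the end-to-end study, 15 seeds for detection recall, 50
parameter draws for conservation, and 100 for the slope-recovery check.
The full suite completes in well under a minute.

## Known limitations

- τ_β is convention-dependent; comparisons across studies must use the
  same composite (the convention is recorded in every output row).
- The correlation is scoped to one formulation and one temperature; the
  package refuses to pool formulations but cannot detect subtler scope
  violations (e.g. mixed moisture histories).
- Five points per group is typical for such studies; r² and the prediction
  interval are honest but fragile at that n, and the code warns below
  n = 4.
- The storage-path crystallization time inherits the weekly grid's
  resolution (≈ ±0.4 d for the default logistic width).
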