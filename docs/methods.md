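# Methods

## The assay and its model

The package models a vesicle dye-leakage assay. Carboxyfluorescein (CF) is
encapsulated at a self-quenching concentration (7.5 mg/mL hydration
medium), so the interior is dark; only dye that has escaped into the
dilute exterior fluoresces. Release is driven thermally: the
DPPC:DPPG:cholesterol (75:10:15) bilayer is essentially impermeable in the
gel phase and becomes permeable near its melting temperature
T_m = 41.5 °C. A run has four stages — ambient baseline, heating, release
to an aqueous equilibrium plateau, and Triton X-100 micellization, which
frees the interior and membrane-bound dye and defines the 100% level.

The kinetic model is a two-compartment aqueous mass balance across a
single bilayer,

    V_in  dc_in/dt  = −P(T)·A·(c_in − c_out)
    V_out dc_out/dt = +P(T)·A·(c_in − c_out),

with three assumptions inherited from how such assays are evaluated:

1. **Static membrane pool.** Dye associated with the lipid phase
   (mass m_mem) neither fluoresces nor exchanges during release; it is
   freed only by Triton. Consequently the total aqueous mass
   m_aq = V_in·c_in + V_out·c_out is constant during release, and the
   exterior concentration follows a single exponential on isothermal
   segments: c_out(t) = c_eq − (c_eq − c_out(0))·e^(−kt) with
   k = P·A·(V_in+V_out)/(V_in·V_out).
2. **Dark interior, linear exterior.** Fluorescence is
   F = slope·c_out + intercept below `linear_max`; no Stern–Volmer
   model of partial quenching is attempted (none is identified by the
   assay itself).
3. **Logistic phase transition.** P(T) = P_gel + (P_fluid − P_gel) /
   (1 + e^(−(T−T_m)/T_width)). Only T_m and release rates at a few
   temperatures are experimentally constrained, so the interpolation
   width is a modelling choice: T_width = 1.5 °C, which keeps 30 °C
   release negligible (P(30)/P(40) ≈ 2·10⁻³) while 40 °C release is
   substantial, matching the assay's observed temperature window.
   P_gel defaults to 0.

### Geometry

All volumes and the permeation area derive from a log-normal vesicle
size distribution (median diameter, geometric SD), the bilayer thickness
d_mem = 4.059 nm, and the cuvette protocol (60 μL stock at 3.5 mg/mL
lipid + 1140 μL PBS). The volume-mean diameter d_v = Σnd⁴/Σnd³ and the
Sauter diameter d₃₂ = Σnd³/Σnd² are computed from the closed-form
log-normal moments (these definitions are the standard colloid-science
ones; the assay literature names but rarely defines them). The lipid
density is taken as 1.0 g/mL (order-unity standard for phospholipid
bilayers; configurable). Vesicle count = V_lip / per-vesicle shell
volume (π/6)[d_v³ − (d_v − 2·d_mem)³]; V_in, A and V_out follow. The
5 μL Triton aliquot is volumetrically negligible and ignored by default
(a protocol flag includes it).

Note that at the working geometry (200 nm vesicles, 4.059 nm bilayer) the
popular thin-shell shortcut k ≈ 6P/d₃₂ is ~13% off because
(d_v/d_inner)³ = 1.13; the package always uses the exact
compartment-volume expression, and its permeability inversion
P = b·V_in·V_out/(A·(V_in+V_out)) is the exact inverse of the forward
rate, so the round trip is identity by construction.

### Partitioning

The apparent membrane/water partition coefficient comes from the plateau
mass balance: K = (c_triton − c_fin)/c_fin · V_aq/V_lip. The generator is
parameterized directly by this apparent K — the membrane pool is loaded as
m_mem = K·c_fin·V_lip, with c_fin = m_aq/V_aq the aqueous equilibrium —
so ground truth and recovered value are defined on the same scale and the
pipeline is exactly identifiable. No thermodynamic loading model is
implied; apparent K folds in surface adsorption and dye dimerization,
which is why it can far exceed octanol/water expectations (log₁₀K ≈ 4.5
for the probe-alone reference).

With the membrane pool static, the plateau fraction is exactly
c_fin/c_triton = 1/(1 + K·V_lip/V_aq) for any V_in/V_out split.

## The synthetic data generator

`simulate` produces every experiment type the assay runs, with ground
truth attached to each trace:

- **Four-stage release traces.** Defaults: 25 °C start, heat onset at
  120 s, 60 s linear ramp to the 40 °C hold (a typical cuvette-heater
  lag; it creates the inflection point the fitting chain looks for),
  780 s release+plateau, Triton at 900 s, 60 s post-Triton, dt = 1 s —
  the ~15 min experiment. 10% of the aqueous dye starts outside the
  vesicles (the unencapsulated residue after column purification; the
  assay deduces "about 10%" from its baseline).
- **Copermeation panel.** The measured panel values (probe-alone
  P = 1.4·10⁻⁸ cm/s at 40 °C, K = 2.9·10⁴; eight binary drug conditions)
  are stored as `REFERENCE_PANEL`; conditions are expressed as
  multipliers (fP, fK) on the reference row. Copermeant action is
  represented *only* through these multipliers — no coupled two-species
  transport is modelled.
- **Enhancer scenarios.** Ethanol: each addition instantly lyses a fixed
  fraction of still-intact vesicles (released fraction after n steps is
  1 − (1−ℓ)ⁿ); mixing transients are ignored. Oleic acid: permeability
  steps from ~0 to the enhanced value at the addition time, 30 °C,
  10 h run.
- **Liposome titration.** Free-dye quenching by added empty vesicles:
  fluorescent fraction V_aq/(V_aq + K·V_lip,cum); Triton restores the
  original intensity (aliquot dilution neglected by default, available
  behind a flag).
- **Temperature scan.** 2 °C/min linear ramp; output normalized to its
  maximum; a T_m shift moves the half-release temperature accordingly.

Noise is i.i.d. Gaussian on intensity with sd = 0.5% of the condition's
Triton-level intensity by default (the instrument noise magnitude is not
published; this level is visually plausible against printed traces). The
calibration defaults (slope 5 a.u. per μg/mL, intercept 2 a.u., linear to
200 μg/mL) keep the Triton level of every panel condition below the
instrument's 1000 a.u. ceiling. All randomness derives from
`SeedSequence([master_seed, condition_index, replicate_index])`.

What the generator does *not* emulate — photobleaching, drift,
inner-filter effects, per-vesicle permeability heterogeneity, partial
self-quenching near the linear limit, multilamellar subpopulations. Tests
passing on this generator therefore demonstrate the *analysis chain's*
correctness and noise behavior under the model's own assumptions, not
robustness to instrument pathologies.

## The fitting chain

intensity → concentration (linear inverse, clipped at 0, saturation
flagged) → stage segmentation → exponential regression → P and K →
triplicate mean ± sample SD.

Segmentation details (all configurable):

- Baseline = samples before the heat-onset marker; c₀ = its mean
  concentration, subtracted before the regression and added back to the
  reported asymptote.
- Triton index = recorded event, else the largest positive single-sample
  jump (latest maximal jump wins); c_triton = mean of later samples.
- Inflection = maximum of the smoothed first difference (centered
  11-sample boxcar) between heat onset and Triton. Because the
  narrow-kernel derivative of a noisy plateau can dominate the true
  release peak, the maximum is first localized with a wide central-mean
  difference and tie-broken toward the earliest near-maximal point; for
  slow, nearly-linear release curves this keeps the whole window, for
  fast ones it sits at the heating-lag end (within a few samples on
  clean traces).
- Plateau window = last 10% of pre-Triton samples; a trace whose plateau
  is within 3 baseline-SDs of the baseline is flagged release-absent and
  excluded from aggregation rather than force-fitted.

The regression c(t) = c_fin − a·e^(−b(t−t₀)) uses nonlinear least squares
with the rate initialized from the log-slope of the derivative (exact on
clean data) and a 9-point log-spaced restart grid as fallback; c_fin is
the fitted asymptote, not the last sample, which makes truncated plateaus
(the 10 h oleic-acid run) usable. Degenerate inputs (constant c, < 5
samples) raise rather than return garbage.

Uncertainty is the sample SD over replicates only — matching how such
assays report — with no per-fit covariance propagation.

## Copermeation comparison

Fold changes are ratios of condition means to the reference mean. A
condition is *neutral* when its mean ± SD interval overlaps the
reference's (the assay reports only mean ± SD, so interval overlap is the
honest significance proxy); otherwise the sign of fold − 1 labels it
enhancer/retardant (P) or increase/decrease (K). A Welch t-test is
available behind `use_ttest=True` but off by default. The headline
statistic max(fold, 1/fold) over the panel measures the strongest effect
in either direction.

## SAXS

Curves are modelled as I(q) = c·q^(−D) + log-normal-shaped peaks
(Gaussian in ln q, maximum exactly at the center parameter — the precise
profile behind published "log-normal" peak fits is not specified, and
this choice makes the fitted center the peak position). Fitting is least
squares on log I so the decades-spanning background does not drown the
weak reflections; the background is initialized from the curve's flanks
and peak centers from prominence-ranked residual maxima. Lamellar spacing
d = 2π/q₁. Note 2π/0.077 Å⁻¹ = 8.16 nm: a spacing of 8.0 nm corresponds
to a *fitted* first-order peak at 0.0785 Å⁻¹, not to the rounded
"around 0.077" reading — the package reports exact arithmetic.
Lamellarity is reported as width/amplitude cues (broad, low peaks ⇒
unilamellar), not as a hard classifier.

## Numerical choices

- ODE integration: RK45, rtol 1e-8 / atol 1e-9, step capped at 1 s on
  ramp segments so the logistic P(T) is resolved; isothermal segments are
  unconstrained. Mass conservation holds to 1e-8 relative through heating
  and Triton events.
- The Triton event is an instantaneous well-mixed redistribution:
  c_in = c_out = (total mass)/V_aq, m_mem = 0.
- Trace CSVs are written with 17 significant digits and read with
  pandas' round-trip float parser, so write→read is bit-exact.
- YAML configs accept `2.9e4`-style scientific notation (YAML 1.1 parses
  it as a string; the loader coerces).

## Problem sizes

The default test and acceptance workloads are the assay's own scale: 961
samples per trace (16 min at 1 Hz), triplicates, a 9-condition panel, a
3×4 (P × K) identifiability grid, 10⁶-sample Monte-Carlo checks of the
size-distribution moments, and 600-point SAXS curves. The full suite runs
in a few seconds on one core.

## Known limitations

- Copermeant effects are effect multipliers on (P, K); no mechanistic or
  two-species transport model, and no pharmacokinetic extrapolation.
- The very fast release regime (50 °C, few informative points) is out of
  scope, as is fitting multi-exponential or stretched-exponential decays.
- DLS inversion, PDI estimation, zeta potential, and instrument-level
  SAXS geometry (wavelength, detector calibration, smearing) are not
  modelled; the q grid is consumed as given.
- Direction classification near fold ≈ 1 is noise-sensitive by nature;
  with noisy replicates, conditions whose true effect is within the
  replicate scatter can legitimately classify as neutral.
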