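# Methods

`phkin` estimates the pH dependence of maximal glycolytic enzyme rates
(Vmax) in *Saccharomyces cerevisiae* cell-free extracts from optical
progression curves, and projects the resulting activity-vs-pH profiles
onto intracellular pH dynamics. This note documents the models, the
estimators, the synthetic-data generator that stands in for raw
plate-reader data, and the numerical choices behind them.

## Assay models

Each of the eleven assays (HXK, PGI, PFK, ALD, TPI, GAPDH forward and
reverse, PGM, ENO, PYK, PDC) is described by an `AssayScheme`: the test
reaction, surplus coupling reactions, the initial reaction-mix
composition, and the monitored optical species — NADH or NADPH at
340 nm, or PEP at 240 nm for the direct enolase assay. The coupled
system is integrated as concatenated ODEs,

    dc_i/dt = sum_r n_ir * v_r(c),

with reversible Michaelis–Menten rate laws. Three forms cover every
reaction:

    uni-uni:  v = Vmax (S − P/Keq)/Km_S / (1 + S/Km_S + P/Km_P)
    bi-bi:    v = Vmax (A·B − P·Q/Keq)/(Km_A·Km_B)
                  / [(1 + A/Km_A + P/Km_P)(1 + B/Km_B + Q/Km_Q)]
    uni-bi:   v = Vmax (S − P·Q/Keq)/Km_S
                  / [(1 + S/Km_S) + (1 + P/Km_P)(1 + Q/Km_Q) − 1]

The uni-bi form (aldolase: one hexose bisphosphate cleaved into two
trioses) uses an additive site denominator that reduces to the uni-uni
denominator when the second product is absent. All forms collapse to
irreversible Michaelis–Menten as Keq → ∞. Keq has concentration units
where stoichiometry demands it (uni-bi).

Assumptions and conventions:

* **Units.** Concentrations in mM, time in minutes. Test-enzyme Vmax is
  stored per mg of extract protein (µmol·min⁻¹·mg⁻¹) and converted to an
  absolute in-assay rate via the assay protein concentration; coupling
  enzymes are purified additions whose printed U/mL values are absolute
  mM/min.
* **Coupling surplus.** Coupling Vmax values are inflated by a
  configurable surplus factor (default 10³) so the optical signal is
  controlled by the test enzyme. `check_coupling_excess` quantifies this
  as the ratio of the peak monitored-species rate to the
  stoichiometry-scaled test flux at the initial mix; all packaged
  schemes score ≥ 0.999.
* **Dilution.** Diluting the cell-free extract scales the test enzyme
  (and the assay protein concentration) but not the purified coupling
  enzymes.
* **Effectors.** Allosteric activators present at saturating fixed
  concentrations in the mixes (F16BP for PYK, 2,3-bisphosphoglycerate
  for PGM) are absorbed into Vmax rather than modeled mechanistically —
  the assays are designed for maximal activity.
* **Sinks.** CO₂ (PDC) and ethanol (ADH) are non-accumulating: they are
  excluded from rate laws and from conservation checks.
* **GAPDH reverse.** The default model is a single ODE in NADH and a
  1,3BPG-equivalent pool: the surplus-PGK pre-step converting 3PG is
  treated as instantaneous. A concatenated variant with an explicit PGK
  reaction (`schemes.gapdhr_explicit_pgk`) exists for sensitivity
  checks; there 1,3BPG sits at its small kinase-equilibrium level.
* **Parameter provenance.** Km and Keq reference values are plausible
  values of the standard yeast-glycolysis model family, chosen within
  reported ranges **such that the printed substrate loads are
  saturating** (S₀/Km ≳ 10 for start substrates) and product-inhibition
  constants are weak. This reflects the assays' design premise — every
  mix was composed so the enzyme runs near Vmax — and matters for the
  agreement between the slope estimator and the true capacity. These
  values serve as ground truth for the synthetic study; no headline
  result depends on their particular magnitudes.

Integration uses LSODA (stiff-capable) at rtol 10⁻⁸ / atol 10⁻¹⁰ mM with
dense output on the experimental sampling grid (the fitter relaxes to
10⁻⁷/10⁻⁹ for speed). Small negative excursions are clamped to zero
inside rate evaluation only; trajectories with negative concentrations
beyond 10⁻⁶ mM raise a numerical error. Two independent oracles validate
the simulation path: a name-keyed re-assembly of the derivatives checked
pointwise against the compiled right-hand side, and a naive fixed-step
RK4 integrator whose step is derived from the explicit-stability bound
dt < 2.8·safety / max(Vmax/Km_min) (capped at 10⁻³ min for accuracy on
non-stiff schemes). All eleven schemes agree with the oracle within
3×10⁻⁵ relative over a one-minute horizon, and every left-null-space
conservation law holds within 10⁻⁶ relative over ten minutes.

## Calibrations

Absorbance is converted to the amount of the monitored species through
fixed linear calibration lines (Abs = a·µmol + b): a = 4.8365,
b = 0.0628 for NAD(P)H and a = 1.223, b = −0.008 for PEP. The lines
absorb the molar absorption coefficient and path length; amounts divide
by the assay volume (default 0.3 mL) to give concentrations. Blank noise
may map to slightly negative amounts and is deliberately not clamped.

Cytosolic pH is read from the pHluorin excitation ratio R390/470 through
a degree-3 polynomial fitted by least squares to an in vivo titration
(pH as a function of ratio — the direction needed at run time). The fit
requires ≥ 5 points, warns if the fitted polynomial is not monotone over
the observed ratio range (checked on a 1000-point grid), and refuses to
extrapolate beyond the calibrated ratio range plus a 5% slack band.

## Slope-based ("direct") estimator

The classical initial-rate method:

1. **Background.** The OLS slope of the 5-min pre-start trace (enzyme
   mix without start chemical) is subtracted from the reaction slope.
2. **Window.** The regression window is anchored at the first post-start
   sample (optional lag-skip, default 0) and extended to the largest end
   index whose regression keeps R² ≥ 0.995 (minimum 5 points). A
   perfectly flat trace counts as a perfect fit (slope 0). If no window
   qualifies, the curve is dropped with a warning.
3. **Conversion.** capacity = (|slope|/a) · DF_sample · DF_assay /
   (protein · V_assay · monitor_stoichiometry), with DF_assay = 60 (the
   extract-to-assay dilution) and the stoichiometry factor 2 for the
   PGI/PFK/ALD assays (two trioses per hexose phosphate).
4. **Dilution consistency.** Capacities from the dilution series must
   agree after dilution correction: the largest subset of dilution
   factors within 25% of its subset median is retained (≥ 2 required,
   else an error naming the enzyme). The 25% tolerance is a stated
   substitute for the original semi-automated selection.
5. **Aggregation.** Arithmetic mean over retained curves; spread is the
   half-range (the original work reports variation, not SEM).

Estimates whose corrected slope opposes the assay direction are reported
negative and flagged, never silently clipped.

The window rule systematically underestimates high-turnover curves
(the regression averages a slightly decaying rate); under the synthetic
study conditions this bias stays below ~24% and is the main source of
slope-vs-fit disagreement, mirroring the known behavior of initial-rate
analysis.

## Progression-curve fitting

`ProgressionFitModel` treats one enzyme's full curve set
(pH × dilution × replicate) as a single bounded nonlinear least-squares
problem (the SSE form of maximum-likelihood estimation under Gaussian
noise):

* **Parameters.** One Vmax per assayed pH, plus Km values shared across
  the entire pH range. By default a single Km is freed: that of the
  least-saturated test-reaction substrate (the one whose depletion bends
  the curves; e.g. ATP for HXK, NADH for GAPDH reverse). The other Kms
  are held at their literature references — at saturation those
  directions carry no information and freeing them only adds
  degeneracy.
* **Residuals** are computed in concentration space (absorbance
  converted through the linear calibrations first — equivalent to
  absorbance-space SSE up to a constant factor). Replicates at the same
  (pH, dilution) share one simulation. Integrator failures at a trial
  point contribute a large finite residual (10³) rather than an
  exception.
* **Optimization** runs in log-parameter space (positivity, scale
  invariance) with bounds of 10⁴× around the start, scipy's
  trust-region-reflective least squares, and a Jacobian sparsity pattern
  exploiting the per-pH block structure (each Vmax touches only its own
  pH's residuals). Initial Vmax comes from the slope estimates, initial
  Km from the references. Single start by default; optional multistart
  perturbs the start with a recorded seed. An isotropic log-space trust
  region (x_scale = 1) avoids drift along nearly flat directions.
* **Uncertainties** are approximate 95% half-widths from the linearized
  residual covariance at the optimum. The Jacobian for this covariance
  is recomputed densely with a step (10⁻⁴ in log space) well above the
  integrator noise floor — the solver's own grouped finite differences
  use near-machine steps and misrepresent nearly flat directions.
* **Regularization.** cost = SSE + λ·Σ log²(Km/Km_ref). The default
  policy (`fit_enzyme(lam="auto")`) fits unregularized first and checks
  whether the data determine the fitted Km: if its approximate 95%
  half-width exceeds 50% of the estimate, a Vmax–Km dependency of the
  mutase type is declared and λ is chosen by a 10-point logarithmic
  sweep (10⁻⁴…10⁵) minimizing the unpenalized prediction error on a
  held-out replicate, then the model is refit warm-started. A
  condition-number trigger on the Fisher matrix was tried first and
  rejected: raw condition numbers conflate harmless flat directions with
  true collinearity and did not isolate the problematic assays
  (`fisher_correlation_condition` remains available as a diagnostic).

Two hypothesis-comparison analyses are built on the model:

* **Keq mode** (`compare_keq_modes`): identical data fitted with
  pH-dependent Keq versus Keq frozen at the reference pH 6.8; reports
  per-pH |ΔVmax|/Vmax. Because the mixes start substrate-rich and
  product-free (far from equilibrium), the difference is marginal — the
  design rationale of the assays.
* **pH dependence** (`compare_ph_dependence`): pH-dependent Vmax with
  global Km versus pH-dependent Km with global Vmax. Both layouts carry
  equal parameter counts (n_pH + 1); raw total SSEs are compared with no
  information-criterion correction. Equilibrium constants are never
  estimated.

## pH-dependent equilibrium constants

Keq(pH) tables ship as a frozen CSV fixture on a pH 6.0–8.0 grid
(step 0.1) and are interpolated log-linearly (transformed reaction
energies are near-linear in pH over narrow ranges). The fixture is
synthetic: log₁₀ Keq is linear in pH with per-reaction effective proton
stoichiometries chosen so that the proton-coupled reactions (HXK, PFK,
GAPDH, PYK, PDC) change 16–320-fold over pH 6–8 but only 2.6–7.5-fold
over the feast/famine window 6.4–7.1 — the separation of scales that
makes the Keq mode nearly irrelevant for Vmax estimation. The sidecar
JSON records the generating parameterization; the package never queries
a thermodynamics service.

## Activity dynamics

`ActivityProfile` interpolates measured (pH, Vmax) points piecewise
linearly (no overshoot between knots; a monotone cubic option exists for
smoother figures but linear is used in all analyses). Queries within
0.05 pH units outside the assayed range are clamped with a warning;
farther out is an error. `activity_trace` maps a cytosolic pH time trace
through a profile and normalizes to the activity at the trace's maximum
pH; `transition_summary` reports 100·(V(pH_hi) − V(pH_lo))/V(pH_hi) per
enzyme and counts decreases above a threshold (default 60%).

The packaged activity table (`data/activity_profiles_synthetic.csv`) is
a **synthetic reconstruction**, not measured data: per-pH capacities for
ten enzymes (TPI excluded for its inconsistent dilution series) chosen
to satisfy the published percent- and fold-change statements for the
feast/famine transition. It exists so the worked example is runnable
end-to-end.

## Synthetic-data generator

The generator is the package's stand-in for raw plate-reader exports and
defines the study conditions:

* pH grid 6.19, 6.40, 6.60, 6.80, 7.10, 7.40, 7.60, 7.90 (the buffer
  series); extract dilution factors 1–32 (default series 1, 2, 4, 32;
  the heavy recovery analyses use 1 and 2); 3 technical replicates;
  10 s sampling over a 10 min reaction window after a 5 min background
  window; additive i.i.d. Gaussian absorbance noise, σ = 0.002 AU
  (typical plate-reader noise); optional shared linear drift in
  background and reaction traces (default 0).
* Ground-truth Vmax(pH) profiles are smooth unimodal bells in pH
  (log-activity quadratic, hence symmetric about the optimum; width → ∞
  gives a flat profile). Per-enzyme optima and widths spread across the
  grid and give 0.3–1.7× relative spans — emulating the diversity of
  observed profiles while keeping every (pH, dilution) trace measurable
  at the stated noise. Capacities at the reference pH are of order
  0.25–2 µmol·min⁻¹·mg⁻¹ with extract protein 6 mg/mL (0.1 mg/mL in the
  assay at dilution 1), placing traces in the plate reader's useful
  range — the role dilution-factor choice played in the original
  protocol.
* Feast/famine pH traces are square waves between 7.1 (feast) and 6.4
  (famine) with 5-min half-cycles and first-order relaxation (default
  τ = 0.4 min), plus optional Gaussian noise.
* pHluorin titrations are generated from the inverse of a monotone
  "true" cubic over pH 4.86–8.41 with optional ratio noise.

Everything is seeded (`numpy.random.default_rng`); the same seed
reproduces byte-identical outputs, and per-enzyme child seeds make
enzyme subsets reproducible. What the generator does **not** emulate:
heteroscedastic noise at high absorbance, instrument drift/temperature
effects, pipetting errors across the dilution series, lot-to-lot
coupling-enzyme variation, and any real pH dependence of Km. Passing
recovery tests therefore demonstrate estimator correctness under the
stated noise model, not robustness to every artifact of real data.

## Problem sizes used in the shipped analyses

The recovery and concordance analyses use the full 11-enzyme study at
8 pH × 2 dilutions × 3 replicates (528 curves); the hypothesis
comparison uses 50 seeded repetitions per direction of a 4-pH enolase
design with a reduced (0.8 mM) substrate load so both Vmax and Km are
identifiable; the numerical oracle covers all 11 schemes over a
one-minute horizon. These sizes were chosen so a complete run finishes
in minutes on a single core while every quantity of interest is
estimated from hundreds of residual degrees of freedom.

## Known limitations

* Km estimates are only as identifiable as saturation allows; for
  assays whose free Km barely moves the curves, the estimate reverts to
  the literature prior (by regularization or by inertia), and its
  confidence interval says so. This mirrors the real study, which was
  optimized for Vmax.
* The slope estimator's window rule has a deterministic downward bias
  on strongly curved traces (up to ~24% under the study conditions);
  the progression-curve fit is the unbiased reference.
* The rate-law denominators are the standard reversible forms; the
  original models' exact expressions are not printed in the source
  literature, so coefficients beyond the Michaelis constants (e.g.
  interaction terms of ordered mechanisms) are not represented.
* Keq tables are a frozen parameterization, adequate for the pH range
  and analyses here; they are not a substitute for a thermodynamics
  database query at other conditions.
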