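# Methods

## Scope

`ferrohem` implements the quantitative core of an in-vitro analysis of
free-iron toxicity on packed red blood cells: preparation arithmetic
for ferrous sulfate working solutions, Beer–Lambert spectral unmixing
of hemoglobin derivatives, a closed-form mass-action model of
methemoglobin (MetHb) formation with parameter estimation, Hertz-model
membrane-stiffness estimation with empirical-distribution statistics,
AFM surface-profile features, and seeded generators that emulate the
measurements. Image-based cell-shape classification, AFM raw-curve
preprocessing and routine group statistics (ANOVA, post-hoc tests) are
deliberately out of scope.

## Solution preparation

The stock is iron(II) sulfate heptahydrate, molar mass fixed at
278.01 g/mol; 20 mg in 1.0 ml gives 71.94 mM ("71.9 mM" at three
significant figures). Dilution steps multiply the concentration by
`aliquot/(aliquot + diluent)` under the standard additive-volume
assumption. The canonical working solution — 100 µl of stock assembled
into 4200 µl total — is 1711.9 µM; the package always reports the exact
arithmetic value and leaves nominal rounding ("1700 µM") to the caller.

## Spectral unmixing

The forward model over 500–700 nm is

    D(λ) = [ε_HbO₂(λ)C_HbO₂ + ε_Hb(λ)C_Hb + ε_MetHb(λ)C_MetHb]·10⁻³·L
           + K + S·g(λ)

with ε in mM⁻¹cm⁻¹, concentrations in µM, L in cm (default 1.0).
Design choices:

* **Scattering basis.** K is a wavelength-flat term (large-particle
  scattering); S multiplies a Rayleigh basis. Rayleigh scattering
  scales as λ⁻⁴, so the default is g(λ) = (λ/550 nm)⁻⁴, normalised at
  550 nm to keep S on the same scale as K and the design matrix well
  conditioned. The literal exponent +4 is selectable
  (`scatter_exponent=+4`) for compatibility with sources that typeset
  the basis as λ⁴.
* **Solver.** The model is linear in its five parameters, so the
  non-negativity-constrained least-squares problem has a unique optimum
  that bounded linear least squares (`scipy.optimize.lsq_linear`,
  BVLS) reaches to machine precision — the same optimum an iterative
  Levenberg–Marquardt scheme targets, without initial-guess or
  convergence concerns. Noiseless round trips recover parameters to
  better than 1e-6 relative.
* **Bounds.** Concentrations, K and S are constrained ≥ 0 (absorbance
  and scattering are physically nonnegative). In lysate mode
  (`allow_scatter=False`) K and S are fixed at zero, matching the
  observation that fitted lysate scattering coefficients vanish.
* **Grids.** The extinction table is linearly interpolated onto the
  spectrum grid; a spectrum extending beyond the table's range is a
  grid error (absorptivities are not extrapolated). At least 10 common
  points are required.
* **Goodness of fit** is the adjusted R² with the number of free
  parameters (3 or 5).

The hemolysis estimator is a declared convention (the underlying
measurement procedure is under-specified in the source material): both
spectra are unmixed and hemolysis = 100·(1 − C_total(t)/C_total(0)),
clipped to [0, 100]. It reads the *loss of cell-associated pigment*;
other conventions (e.g. supernatant-based) would need their own
reference spectra.

## Kinetic model

With constant peroxide concentration `a` (quasi-steady state; peroxide
is continuously regenerated by downstream radical chemistry), mass
action gives dy/dt = −βay and dx/dt = γay(Z₀ − x), with y free Fe²⁺
and x MetHb, solved in closed form:

    y(t) = y₀ e^(−βat)
    x(t) = Z₀(1 − exp(−(γ/β) y₀ (1 − e^(−βat))))
    x_ss = Z₀(1 − exp(−γ y₀/β))

Units are fixed: minutes, µM, β in µM⁻¹min⁻¹, γ in µM⁻²min⁻¹. The
model conserves C_HbO₂ + C_MetHb = Z₀ (no other sinks). The degenerate
limit β·a → 0 uses the continuous series limit
x(t) = Z₀(1 − exp(−γ·a·y₀·t)), and `expm1` is used throughout for
small-argument accuracy. A numerical ODE integration (LSODA,
rtol 1e-10) is provided purely as a cross-check and agrees with the
closed forms to better than 1e-6 relative.

Reference parameter values used as generator defaults, from the
study's reported fit: a = 0.00090 µM, β = 0.973 µM⁻¹min⁻¹,
γ = 0.0030 µM⁻²min⁻¹, Z₀ = 5 µM, with initial Fe²⁺ spanning
212.5–13600 µM.

### Identifiability

x(t) depends on (a, β, γ) only through u = β·a and v = γ/β; the family
(k·a, β/k, γ/k) generates identical curves for every k > 0 (verified
to 1e-12 in the tests). Consequences adopted in the fitter:

* the optimiser always works in (u, v), with bounds u, v > 0;
* the physical triple is resolved only when `a` is supplied
  (`fix_a=...`), which the study's own cross-check of the fitted
  peroxide concentration against its measured value justifies;
* without `fix_a` the results are flagged `identifiable=False`, an
  `IdentifiabilityWarning` is emitted, and (a, β, γ) are NaN while
  (u, v) remain available. Summaries refuse ridge fits.

Initial guesses: v₀ by inverting the steady-state relation at the
largest observed MetHb level; u₀ from a log-linear fit of the gap to a
slightly inflated plateau, falling back to the reciprocal observation
window. Weighting is ordinary (unweighted) least squares. Parameter
covariance is the Gauss–Newton estimate from the jacobian, mapped to
(β, γ) by the delta method.

### Averaging protocol and its statistical limits

A single 0–120 min curve sampled at {0, 15, 30, 45, 60, 90, 120} min
with noise of 1 % of Z₀ carries very little information about β at any
single iron concentration: the Cramér–Rao bound for a per-replicate
two-parameter fit ranges from ≈1 to ≈9 µM⁻¹min⁻¹ across
212.5–13600 µM, and the nonlinear LS estimator is strongly
right-skewed along the soft (u, v) ridge. The package therefore
follows the replicate-averaging protocol: average replicates per
concentration, fit each mean curve, then combine per-curve estimates.
`summarize_fits` offers

* `weighting="equal"` — arithmetic mean ± sample SD (the plain
  contract), and
* `weighting="precision"` — inverse-variance weighting with weights
  re-evaluated at the consensus estimate (two extra passes), the
  standard combination when per-curve variances differ by an order of
  magnitude, as they do here: low-iron curves are nearly uninformative
  about β and would otherwise dominate the scatter of the mean.

Under the default study conditions (20 replicates per concentration),
the precision-weighted β is recovered with a seed-to-seed SD of ≈0.12
— essentially the total-Fisher-information floor of the experiment
(≈0.13) — while γ is recovered with SD ≈ 1e-5. Any single seed can
therefore still land a β estimate more than one reported SD (0.171)
from truth with roughly 5–10 % probability; this is an information
limit of the experimental design (grid, noise, replicate count), not
of the estimator.

## Membrane stiffness

The spherical (paraboloidal) indenter form
F = (4/3)·E/(1−ν²)·√R·h^(3/2) is used with ν = 0.5 (incompressible
membrane, the standard choice for cells) and probe radius 150 nm; both
are configurable. With kPa/nm/nN units the conversion factor is 1e-6.
The model is linear in E, so the fit is the closed-form least-squares
projection; a non-positive estimate raises a fit error. Contact is
assumed at h = 0 — contact-point detection and raw AFM preprocessing
are out of scope, so real force curves must be preprocessed upstream.

Group statistics are fully empirical: relative-frequency-density
histograms (area 1), the right-continuous ECDF, and the exceedance
fraction 100·P(E_treat > Q_control(level)) with the control quantile
computed by linear (type-7) interpolation at level 0.95 by default.
The exceedance fraction is invariant under any common monotone
rescaling of both samples.

Surface-profile features: after optional Savitzky–Golay smoothing, the
spatial period is the mean spacing between successive local minima and
the corrugation height the mean of (local maximum − mean of adjacent
minima); flat or monotone profiles raise a no-structure error.
Plateaus are collapsed so each flat extremum counts once.

## Synthetic data

The generators define the study conditions used by the tests and the
acceptance script:

* **Extinction fixture** — a synthetic stand-in for literature
  absorptivity tables: smooth Gaussian-sum curves on the
  500–700 nm/0.5 nm grid (401 rows) with the HbO₂ 542/577 nm double
  peak, the broad deoxy-Hb 555 nm band and the diagnostic MetHb 630 nm
  local peak; nonnegative by construction. It is *shape-realistic, not
  digitised reference data* — absolute absorptivity scales are
  plausible (order 10 mM⁻¹cm⁻¹) but not metrological, so all
  unmixing tests are self-consistent against this table.
* **MetHb time courses** — closed form + additive Gaussian noise
  (default SD 1 % of Z₀, a plausible spectrophotometric uncertainty;
  the source reports none), clipped to [0, Z₀], on the lysate grid
  {0, 15, 30, 45, 60, 90, 120} min, default 3 replicates (the study's
  repeat count; the recovery experiment uses 20).
* **Spectra series** — couples the kinetic trajectory to the forward
  spectral model (C_MetHb = x(t), C_HbO₂ = Z₀ − x(t), C_Hb = 0;
  deoxy-Hb can be enabled by building spectra directly), additive
  noise SD 0.002 absorbance.
* **Force curves** — per-cell moduli drawn from the printed group
  moments (11 ± 4 and 17 ± 5 kPa at 1 h; 15 ± 5 and 23 ± 8 kPa at
  24 h), truncated below 1 kPa, 100 cells per group, h ∈ [0, 1000] nm,
  multiplicative noise 2 % (typical AFM force noise).

All generators are pure functions of their configuration including the
seed; ground truth is always returned alongside. What passing tests on
these data do **not** show: robustness to baseline drift, wavelength
miscalibration, heteroscedastic or correlated noise, contact-point
error, or cell-to-cell Z₀ variation — none of which the generators
emulate.

## Numerical choices and degenerate inputs

* Fit tolerances: trust-region reflective least squares with
  xtol = ftol = gtol = 1e-12 (the kinetic ridge is shallow; tight
  tolerances make the optimum, not the stopping rule, determine the
  estimate).
* Flat MetHb series, zero total pigment, zero-variance vectors for
  R²/correlation, β = 0 steady states and negative times are rejected
  with specific exceptions rather than silently propagated.
* CSV output uses 10 significant digits; all dialects are UTF-8,
  comma-separated, '.' decimal.

## Known limitations

* The hemolysis convention is one of several defensible readings of an
  under-specified measurement.
* The kinetic model has no explicit radical chain, no peroxide
  depletion, and no transport limitation — it describes lysate
  kinetics; suspension kinetics are reported to be ~5–10× slower and
  are not modelled.
* Printed Young's moduli cannot be re-derived from raw curves (none
  are available); the mechanics module is validated by round trips and
  distribution statistics on synthetic ensembles.
* Per-curve β estimates from 0–120 min data are intrinsically
  low-information (see the identifiability section); results should
  always be reported with their uncertainties.
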