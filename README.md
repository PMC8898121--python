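# ferrohem

Quantitative analysis of free-iron (Fe²⁺) toxicity on packed red blood
cells (pRBCs): spectral unmixing of hemoglobin derivatives, a
closed-form mass-action model of Fenton-driven methemoglobin formation
with parameter fitting, and Hertz-model membrane-stiffness estimation —
together with seeded synthetic-data generators that emulate the
underlying in-vitro measurements, so the whole pipeline runs and is
testable without any external data.

The package is aimed at biophysicists and transfusion-medicine
researchers who expose stored erythrocytes (lysate or suspension) to
ferrous sulfate and track the resulting oxidative damage with a
spectrophotometer and an atomic force microscope.

## The models

**Spectral unmixing.** Over 500–700 nm, the optical density of a
hemoglobin-containing sample is a Beer–Lambert mixture of
oxyhemoglobin, deoxyhemoglobin and methemoglobin plus a scattering
baseline:

    D(λ) = [ε_HbO₂(λ)·C_HbO₂ + ε_Hb(λ)·C_Hb + ε_MetHb(λ)·C_MetHb]·10⁻³·L
           + K + S·(λ/550 nm)⁻⁴

with ε in mM⁻¹cm⁻¹, C in µM and path length L in cm. The model is
linear in its five parameters, so the non-negative least-squares
optimum is unique; goodness of fit is the adjusted R². The MetHb
fraction is `100·C_MetHb/C_total` with `C_total = C_HbO₂ + C_Hb + C_MetHb`.

**Kinetics.** The Fenton reaction Fe²⁺ + H₂O₂ → OH· + OH⁻ + Fe³⁺
triggers HbO₂ → MetHb conversion. With constant peroxide concentration
*a* (quasi-steady state), mass action gives

    dy/dt = −β·a·y,            y(0) = y₀        (free Fe²⁺)
    dx/dt = γ·a·y·(Z₀ − x),    x(0) = 0         (MetHb)

whose closed forms are y(t) = y₀·e^(−βat) and

    x(t)  = Z₀·(1 − exp(−(γ/β)·y₀·(1 − e^(−βat))))
    x_ss  = Z₀·(1 − exp(−γ·y₀/β))

(β in µM⁻¹min⁻¹, γ in µM⁻²min⁻¹, concentrations in µM, time in min).
Because x(t) depends only on the composites u = β·a and v = γ/β, a
three-parameter fit to one curve is structurally degenerate; the fitter
estimates (u, v) and resolves (β, γ) only when *a* is supplied,
otherwise it flags the ridge explicitly.

**Membrane stiffness.** A spherical AFM probe of radius R indenting a
membrane a depth h obeys the Hertz law F = (4/3)·E/(1−ν²)·√R·h^(3/2);
the fitted Young's modulus E (kPa) and its empirical distribution over
~100 cells per group quantify stiffening, summarised by the fraction of
treated cells beyond the control 0.95-quantile.

## Worked example

```python
import numpy as np
import ferrohem as fh
from ferrohem.kinetics import STUDY_FE_CONCENTRATIONS_UM, reported_params

# 1) unmix a synthetic 60-min lysate spectrum (1700 uM Fe2+)
table = fh.make_extinction_fixture()
sim = fh.simulate_spectra_series(fh.SimulationConfig(seed=42), table)
print(fh.fit_spectrum(sim.spectra[4], table, allow_scatter=False).summary())

# 2) recover the kinetic rate constants across the seven Fe2+ levels
fits = []
for i, y0 in enumerate(STUDY_FE_CONCENTRATIONS_UM):
    cfg = fh.SimulationConfig(kinetic_params=reported_params(y0),
                              n_replicates=20, seed=42 + i)
    mc = fh.simulate_methb_timeseries(cfg).mean_curve()
    fits.append(fh.MetHbKinetics(mc["time_min"].to_numpy(),
                                 mc["methb_um"].to_numpy(),
                                 y0=y0, z0=5.0).fit(fix_a=0.00090))
s = fh.summarize_fits(fits, weighting="precision")
print(f"beta  = {s.mean_beta:.3f} +/- {s.sd_beta:.3f} uM^-1 min^-1")
print(f"gamma = {s.mean_gamma:.5f} +/- {s.sd_gamma:.5f} uM^-2 min^-1")
```

prints

```
Spectral unmixing (Beer-Lambert + scattering baseline)
  points: 401  path length: 1 cm  scatter: off
  C_HbO2  =     3.7959 uM
  C_Hb    =     0.0000 uM
  C_MetHb =     1.1736 uM
  K       =    0.00000
  S       =    0.00000
  adjusted R2 = 0.986917
  MetHb% = 23.62  HbO2% = 76.38  Hb% = 0.00  (C_total = 4.9695 uM)
beta  = 0.991 +/- 0.389 uM^-1 min^-1
gamma = 0.00301 +/- 0.00002 uM^-2 min^-1
```

The unmixed spectrum shows roughly a quarter of the 5 µM hemoglobin
pool oxidised to MetHb after 60 min, and the ensemble fit recovers the
generating rate constants (β = 0.973 µM⁻¹min⁻¹, γ = 0.0030 µM⁻²min⁻¹)
within their uncertainties.

A command-line interface mirrors the library:

```bash
ferrohem prep stock --mass-mg 20 --volume-ml 1.0     # -> 71.94 mM
ferrohem simulate --seed 7 --out simdata/
ferrohem fit-kinetics methb.csv --y0 1700 --fix-a 0.0009
ferrohem fit-force force_curve.csv --radius-nm 150
ferrohem stiffness-stats treated.csv control.csv --level 0.95
```

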