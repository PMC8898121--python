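"""Seeded generators emulating the study's measurements.

No raw measurements from the study are deposited, so every pipeline
stage is exercised against synthetic data built from the study's own
forward models and printed parameters:

* an extinction-coefficient fixture with literature-shaped curves
  (MetHb local peak near 630 nm, HbO2 double peak near 542/577 nm) —
  a synthetic stand-in for the cited absorptivity tables;
* MetHb time courses from the closed-form kinetic solution with
  additive Gaussian noise, clipped to [0, Z0];
* absorbance spectra coupling the kinetic trajectory to the
  Beer-Lambert mixture (C_MetHb = x(t), C_HbO2 = Z0 − x(t), C_Hb = 0);
* Hertz force-curve ensembles with per-cell moduli drawn from the
  printed group means/SDs (truncated below at 1 kPa) and multiplicative
  noise.

Every generator is a pure function of its configuration (including the
seed); ground truth is always returned alongside the noisy data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .kinetics import (
    KineticParams,
    closed_form_series,
    methb_time,
    reported_params,
)
from .mechanics import ForceCurve, ProbeParams, hertz_force
from .spectra import ExtinctionTable, Spectrum, model_spectrum

__all__ = [
    "SimulationConfig",
    "make_extinction_fixture",
    "simulate_methb_timeseries",
    "simulate_spectra_series",
    "simulate_force_curves",
    "MethbSimulation",
    "SpectraSimulation",
    "ForceSimulation",
]

#: The lysate incubation grid, minutes.
DEFAULT_T_GRID = (0.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0)

#: Printed group moments for Young's moduli (kPa): control and
#: iron-exposed at 1 h, control and iron-exposed at 24 h.
DEFAULT_FORCE_GROUPS = ("control_1h", "fe1700_1h", "control_24h", "fe1700_24h")
DEFAULT_FORCE_MEANS = (11.0, 17.0, 15.0, 23.0)
DEFAULT_FORCE_SDS = (4.0, 5.0, 5.0, 8.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generators.

    Defaults reproduce the study's stated conditions: the mean fitted
    kinetic parameters at 1700 µM Fe2+ with Z0 = 5 µM, the 0-120 min
    lysate incubation grid, 100 force curves per group with the printed
    modulus moments, and measurement-noise magnitudes chosen as
    plausible instrument noise (the study reports none): 0.002
    absorbance units on spectra, 1 % of Z0 on MetHb readings, 2 %
    multiplicative on forces.
    """

    kinetic_params: KineticParams = field(default_factory=reported_params)
    t_grid_min: tuple = DEFAULT_T_GRID
    spectrum_noise_sd: float = 0.002
    methb_noise_sd_percent: float = 1.0
    force_noise_rel: float = 0.02
    n_replicates: int = 3
    seed: int = 0
    force_group_labels: tuple = DEFAULT_FORCE_GROUPS
    force_group_means_kpa: tuple = DEFAULT_FORCE_MEANS
    force_group_sds_kpa: tuple = DEFAULT_FORCE_SDS
    n_cells: int = 100

    def __post_init__(self):
        if self.spectrum_noise_sd < 0 or self.methb_noise_sd_percent < 0 or self.force_noise_rel < 0:
            raise ValidationError("noise magnitudes must be >= 0")
        if self.n_replicates < 1 or self.n_cells < 1:
            raise ValidationError("n_replicates and n_cells must be >= 1")
        if not (
            len(self.force_group_labels)
            == len(self.force_group_means_kpa)
            == len(self.force_group_sds_kpa)
        ):
            raise ValidationError("force group labels/means/sds must align")

    def with_y0(self, y0: float) -> "SimulationConfig":
        return replace(self, kinetic_params=self.kinetic_params.replace(y0=y0))


def _gauss(wl, mu, sd, amp):
    return amp * np.exp(-0.5 * ((wl - mu) / sd) ** 2)


def make_extinction_fixture() -> ExtinctionTable:
    """Synthetic molar-absorptivity table on the 500-700 nm / 0.5 nm grid.

    The curves are smooth sums of Gaussians shaped after the literature:
    HbO2 shows its double peak at 542/577 nm, deoxy-Hb a single broad
    band near 555 nm with a red-edge tail, and MetHb the 500 nm band
    plus the diagnostic local peak at 630 nm.  Values are in mM⁻¹cm⁻¹
    and nonnegative by construction.  This is a synthetic stand-in, not
    digitised reference data; users can supply their own CSV table.
    """
    wl = np.arange(500.0, 700.0 + 0.25, 0.5)
    eps_hbo2 = (
        _gauss(wl, 542.0, 9.0, 13.5)
        + _gauss(wl, 577.0, 8.5, 14.5)
        + _gauss(wl, 510.0, 22.0, 1.2)
        + 0.05
    )
    eps_hb = (
        _gauss(wl, 555.0, 13.0, 12.5)
        + _gauss(wl, 760.0, 60.0, 1.4)
        + _gauss(wl, 515.0, 25.0, 1.0)
        + 0.05
    )
    eps_methb = (
        _gauss(wl, 502.0, 14.0, 8.5)
        + _gauss(wl, 630.0, 13.0, 3.9)
        + _gauss(wl, 577.0, 20.0, 0.9)
        + 0.05
    )
    return ExtinctionTable(wl, eps_hbo2, eps_hb, eps_methb)


@dataclass
class MethbSimulation:
    """Noisy MetHb replicates plus the generating ground truth."""

    replicates: list  # of pandas DataFrames (time_min, methb_um)
    truth: pd.DataFrame  # time_min, methb_um (noiseless)
    config: SimulationConfig

    def mean_curve(self) -> pd.DataFrame:
        stacked = np.stack([r["methb_um"].to_numpy() for r in self.replicates])
        return pd.DataFrame(
            {"time_min": self.replicates[0]["time_min"], "methb_um": stacked.mean(axis=0)}
        )


def simulate_methb_timeseries(config: SimulationConfig) -> MethbSimulation:
    """Replicate MetHb time courses: closed form + N(0, sigma), clipped.

    sigma = methb_noise_sd_percent * Z0 / 100.
    """
    p = config.kinetic_params
    t = np.asarray(config.t_grid_min, dtype=float)
    truth = np.asarray(methb_time(t, p))
    sigma = config.methb_noise_sd_percent * p.z0 / 100.0
    rng = np.random.default_rng(config.seed)
    reps = []
    for _ in range(config.n_replicates):
        noisy = truth + rng.normal(0.0, sigma, t.size) if sigma > 0 else truth.copy()
        noisy = np.clip(noisy, 0.0, p.z0)
        reps.append(pd.DataFrame({"time_min": t, "methb_um": noisy}))
    return MethbSimulation(
        replicates=reps,
        truth=pd.DataFrame({"time_min": t, "methb_um": truth}),
        config=config,
    )


@dataclass
class SpectraSimulation:
    """Per-time-point spectra plus the generating concentration table."""

    spectra: list  # of Spectrum
    truth: pd.DataFrame  # time_min, c_hbo2, c_hb, c_methb
    config: SimulationConfig


def simulate_spectra_series(
    config: SimulationConfig,
    table: ExtinctionTable,
    k: float = 0.0,
    s: float = 0.0,
    path_length_cm: float = 1.0,
) -> SpectraSimulation:
    """Absorbance spectra along the kinetic trajectory.

    At each grid time, C_MetHb = x(t) and C_HbO2 = Z0 − x(t) (deoxy-Hb
    stays at zero in the default scenario); each spectrum gets additive
    Gaussian noise of SD ``spectrum_noise_sd``.
    """
    p = config.kinetic_params
    series = closed_form_series(p, np.asarray(config.t_grid_min, dtype=float))
    rng = np.random.default_rng(config.seed)
    spectra = []
    for x in series.x:
        sp = model_spectrum(p.z0 - x, 0.0, x, k, s, table, path_length_cm)
        if config.spectrum_noise_sd > 0:
            sp = Spectrum(
                sp.wavelengths,
                sp.optical_density + rng.normal(0.0, config.spectrum_noise_sd, len(sp)),
                sp.path_length_cm,
            )
        spectra.append(sp)
    truth = pd.DataFrame(
        {
            "time_min": series.t,
            "c_hbo2": series.hbo2,
            "c_hb": np.zeros_like(series.x),
            "c_methb": series.x,
        }
    )
    return SpectraSimulation(spectra=spectra, truth=truth, config=config)


@dataclass
class ForceSimulation:
    """Per-group force-curve ensembles plus drawn ground-truth moduli."""

    groups: dict  # label -> list of ForceCurve
    truth: pd.DataFrame  # group, cell, e_kpa
    config: SimulationConfig


def simulate_force_curves(
    config: SimulationConfig,
    probe: ProbeParams = ProbeParams(),
    n_points: int = 50,
    h_max_nm: float = 1000.0,
    e_min_kpa: float = 1.0,
) -> ForceSimulation:
    """Hertz force curves for each modulus group.

    Per cell, E ~ Normal(mean, SD) truncated below at ``e_min_kpa``;
    the curve is sampled on h in [0, h_max_nm] with multiplicative
    Gaussian noise of relative SD ``force_noise_rel``.
    """
    rng = np.random.default_rng(config.seed)
    h = np.linspace(0.0, h_max_nm, n_points)
    groups: dict = {}
    records = []
    for label, mean, sd in zip(
        config.force_group_labels, config.force_group_means_kpa, config.force_group_sds_kpa
    ):
        if mean <= 0 or sd <= 0:
            raise ValidationError("force group means and SDs must be positive")
        curves = []
        for cell in range(config.n_cells):
            e = rng.normal(mean, sd)
            while e <= e_min_kpa:
                e = rng.normal(mean, sd)
            f = np.asarray(hertz_force(e, probe, h))
            if config.force_noise_rel > 0:
                f = f * (1.0 + rng.normal(0.0, config.force_noise_rel, h.size))
            curves.append(ForceCurve(h.copy(), f))
            records.append({"group": label, "cell": cell, "e_kpa": e})
        groups[label] = curves
    return ForceSimulation(groups=groups, truth=pd.DataFrame(records), config=config)
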