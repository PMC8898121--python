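"""Hemoglobin-derivative quantification from visible absorbance spectra.

Optical density of a lysate or suspension over 500-700 nm is modelled as a
Beer-Lambert mixture of three hemoglobin derivatives plus a scattering
baseline:

    D(λ) = [ε_HbO2(λ)·C_HbO2 + ε_Hb(λ)·C_Hb + ε_MetHb(λ)·C_MetHb]·1e-3·L
           + K + S·g(λ)

with ε in mM⁻¹cm⁻¹, concentrations in µM (the 1e-3 factor converts to mM),
path length L in cm, K a wavelength-flat scattering term and S the
amplitude of a Rayleigh-like basis g(λ) = (λ/550 nm)^p.  The physical
Rayleigh exponent is p = -4 (the default); p = +4 is selectable for
compatibility with sources that print the basis as λ⁴.

The model is linear in its five parameters, so the unmixing fit is solved
by bounded (non-negative) linear least squares, which reaches the unique
constrained optimum to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .exceptions import FitError, GridError, UndefinedValueError, ValidationError

__all__ = [
    "ExtinctionTable",
    "Spectrum",
    "DerivativeFractions",
    "scatter_basis",
    "model_spectrum",
    "SpectralUnmixing",
    "SpectralUnmixingResults",
    "fit_spectrum",
    "derivative_fractions",
    "hemolysis_level",
]

#: Reference wavelength used to normalise the scattering basis (nm).
SCATTER_REF_NM = 550.0


@dataclass
class ExtinctionTable:
    """Per-wavelength molar absorptivities of HbO2, Hb and MetHb.

    Wavelengths in nm (strictly increasing); absorptivities in mM⁻¹cm⁻¹.
    """

    wavelengths: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray
    eps_methb: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.eps_hbo2 = np.asarray(self.eps_hbo2, dtype=float)
        self.eps_hb = np.asarray(self.eps_hb, dtype=float)
        self.eps_methb = np.asarray(self.eps_methb, dtype=float)
        n = self.wavelengths.size
        if any(a.size != n for a in (self.eps_hbo2, self.eps_hb, self.eps_methb)):
            raise ValidationError("extinction columns must all have the same length")
        if n >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValidationError("wavelengths must be strictly increasing")
        for name in ("eps_hbo2", "eps_hb", "eps_methb"):
            if np.any(getattr(self, name) < 0):
                raise ValidationError(f"{name} must be nonnegative")

    def __len__(self):
        return self.wavelengths.size

    def interp_to(self, wavelengths) -> "ExtinctionTable":
        """Linearly interpolate the table onto a new wavelength grid.

        Raises :class:`GridError` if the target grid extends beyond the
        table's range (extrapolation of absorptivities is not meaningful).
        """
        wl = np.asarray(wavelengths, dtype=float)
        if wl.min() < self.wavelengths[0] - 1e-9 or wl.max() > self.wavelengths[-1] + 1e-9:
            raise GridError(
                "spectrum grid extends beyond the extinction table "
                f"({wl.min():g}-{wl.max():g} nm vs table "
                f"{self.wavelengths[0]:g}-{self.wavelengths[-1]:g} nm)"
            )
        return ExtinctionTable(
            wavelengths=wl,
            eps_hbo2=np.interp(wl, self.wavelengths, self.eps_hbo2),
            eps_hb=np.interp(wl, self.wavelengths, self.eps_hb),
            eps_methb=np.interp(wl, self.wavelengths, self.eps_methb),
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths,
                "eps_hbo2": self.eps_hbo2,
                "eps_hb": self.eps_hb,
                "eps_methb": self.eps_methb,
            }
        )

    @classmethod
    def from_frame(cls, df) -> "ExtinctionTable":
        return cls(
            wavelengths=df["wavelength_nm"].to_numpy(),
            eps_hbo2=df["eps_hbo2"].to_numpy(),
            eps_hb=df["eps_hb"].to_numpy(),
            eps_methb=df["eps_methb"].to_numpy(),
        )


@dataclass
class Spectrum:
    """A measured (or modelled) absorbance spectrum.

    Optical density is dimensionless; path length in cm (default 1.0,
    the standard cuvette).
    """

    wavelengths: np.ndarray
    optical_density: np.ndarray
    path_length_cm: float = 1.0

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.optical_density = np.asarray(self.optical_density, dtype=float)
        if self.wavelengths.size != self.optical_density.size:
            raise ValidationError("wavelengths and optical_density must have equal length")
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if not self.path_length_cm > 0:
            raise ValidationError("path_length_cm must be > 0")

    def __len__(self):
        return self.wavelengths.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "optical_density": self.optical_density}
        )


@dataclass
class DerivativeFractions:
    """Total pigment and the percentage of each derivative (sums to 100)."""

    c_total: float
    methb_percent: float
    hbo2_percent: float
    hb_percent: float


def scatter_basis(wavelengths, exponent: int = -4, ref_nm: float = SCATTER_REF_NM):
    """Normalised scattering basis g(λ) = (λ/ref)^exponent."""
    if exponent not in (-4, 4):
        raise ValidationError("scatter exponent must be -4 or +4")
    return (np.asarray(wavelengths, dtype=float) / ref_nm) ** exponent


def model_spectrum(
    c_hbo2: float,
    c_hb: float,
    c_methb: float,
    k: float,
    s: float,
    table: ExtinctionTable,
    path_length_cm: float = 1.0,
    scatter_exponent: int = -4,
) -> Spectrum:
    """Forward Beer-Lambert + scattering model on the table's grid.

    Concentrations in µM, k/s in absorbance units.
    """
    for name, val in (("c_hbo2", c_hbo2), ("c_hb", c_hb), ("c_methb", c_methb)):
        if val < 0:
            raise ValidationError(f"{name} must be >= 0")
    if len(table) == 0:
        raise ValidationError("extinction table is empty")
    absorb = (
        table.eps_hbo2 * c_hbo2 + table.eps_hb * c_hb + table.eps_methb * c_methb
    ) * 1e-3 * path_length_cm
    od = absorb + k + s * scatter_basis(table.wavelengths, scatter_exponent)
    return Spectrum(table.wavelengths.copy(), od, path_length_cm)


class SpectralUnmixing:
    """Least-squares unmixing model for one spectrum.

    Parameters
    ----------
    spectrum : Spectrum
    table : ExtinctionTable
        Interpolated onto the spectrum grid if the grids differ.
    allow_scatter : bool
        When False, K and S are fixed at zero (lysate mode; measured
        lysate spectra show no scattering baseline).
    scatter_exponent : int
        -4 (Rayleigh, default) or +4.
    """

    N_PARAMS_FULL = 5
    N_PARAMS_NO_SCATTER = 3

    def __init__(
        self,
        spectrum: Spectrum,
        table: ExtinctionTable,
        allow_scatter: bool = True,
        scatter_exponent: int = -4,
    ):
        self.spectrum = spectrum
        self.allow_scatter = bool(allow_scatter)
        self.scatter_exponent = scatter_exponent
        if not np.array_equal(table.wavelengths, spectrum.wavelengths):
            table = table.interp_to(spectrum.wavelengths)
        self.table = table
        self.n_params = self.N_PARAMS_FULL if self.allow_scatter else self.N_PARAMS_NO_SCATTER
        n = len(spectrum)
        if n < 10:
            raise ValidationError(f"need at least 10 spectral points, got {n}")
        if n <= self.n_params:
            raise ValidationError("fewer spectral points than fit parameters")

    def design_matrix(self) -> np.ndarray:
        L = self.spectrum.path_length_cm
        cols = [
            self.table.eps_hbo2 * 1e-3 * L,
            self.table.eps_hb * 1e-3 * L,
            self.table.eps_methb * 1e-3 * L,
        ]
        if self.allow_scatter:
            cols.append(np.ones(len(self.spectrum)))
            cols.append(scatter_basis(self.spectrum.wavelengths, self.scatter_exponent))
        return np.column_stack(cols)

    def fit(self, max_iter: int | None = None, tol: float = 1e-14) -> "SpectralUnmixingResults":
        """Solve the non-negative least-squares problem.

        Raises :class:`FitError` (carrying the last residual norm) if the
        bounded solver does not converge.
        """
        A = self.design_matrix()
        d = self.spectrum.optical_density
        res = lsq_linear(
            A,
            d,
            bounds=(0.0, np.inf),
            tol=tol,
            max_iter=max_iter,
            method="bvls",
        )
        if res.status < 0 or not np.all(np.isfinite(res.x)):
            raise FitError(
                f"spectral unmixing did not converge: {res.message}",
                residuals=float(np.linalg.norm(res.fun)),
            )
        theta = res.x
        predicted = A @ theta
        residuals = d - predicted
        r2a = _adjusted_r2(d, predicted, self.n_params)
        k, s = (theta[3], theta[4]) if self.allow_scatter else (0.0, 0.0)
        return SpectralUnmixingResults(
            model=self,
            c_hbo2=float(theta[0]),
            c_hb=float(theta[1]),
            c_methb=float(theta[2]),
            k_scatter=float(k),
            s_scatter=float(s),
            r2_adjusted=r2a,
            residuals=residuals,
        )


def _adjusted_r2(observed, predicted, n_params) -> float:
    obs = np.asarray(observed, dtype=float)
    ss_res = float(np.sum((obs - predicted) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    n = obs.size
    if ss_tot == 0:
        # flat spectrum: perfect fit has R2 of 1 by convention, else undefined
        return 1.0 if ss_res < 1e-30 else float("nan")
    r2 = 1.0 - ss_res / ss_tot
    if n - n_params - 1 < 1:
        return r2
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


@dataclass
class SpectralUnmixingResults:
    """Unmixed concentrations (µM), scattering coefficients and diagnostics."""

    model: SpectralUnmixing
    c_hbo2: float
    c_hb: float
    c_methb: float
    k_scatter: float
    s_scatter: float
    r2_adjusted: float
    residuals: np.ndarray = field(repr=False)

    @property
    def c_total(self) -> float:
        return self.c_hbo2 + self.c_hb + self.c_methb

    @property
    def residual_norm(self) -> float:
        return float(np.linalg.norm(self.residuals))

    def fractions(self) -> DerivativeFractions:
        return derivative_fractions(self)

    def predicted(self) -> Spectrum:
        sp = self.model.spectrum
        return Spectrum(sp.wavelengths, sp.optical_density - self.residuals, sp.path_length_cm)

    def summary(self) -> str:
        lines = [
            "Spectral unmixing (Beer-Lambert + scattering baseline)",
            f"  points: {len(self.model.spectrum)}  "
            f"path length: {self.model.spectrum.path_length_cm:g} cm  "
            f"scatter: {'on' if self.model.allow_scatter else 'off'}"
            + (f" (exponent {self.model.scatter_exponent:+d})" if self.model.allow_scatter else ""),
            f"  C_HbO2  = {self.c_hbo2:10.4f} uM",
            f"  C_Hb    = {self.c_hb:10.4f} uM",
            f"  C_MetHb = {self.c_methb:10.4f} uM",
            f"  K       = {self.k_scatter:10.5f}",
            f"  S       = {self.s_scatter:10.5f}",
            f"  adjusted R2 = {self.r2_adjusted:.6f}",
        ]
        if self.c_total > 0:
            fr = self.fractions()
            lines.append(
                f"  MetHb% = {fr.methb_percent:.2f}  HbO2% = {fr.hbo2_percent:.2f}  "
                f"Hb% = {fr.hb_percent:.2f}  (C_total = {fr.c_total:.4f} uM)"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Overlay measured and fitted spectra."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sp = self.model.spectrum
        ax.plot(sp.wavelengths, sp.optical_density, ".", ms=2, label="measured")
        ax.plot(sp.wavelengths, self.predicted().optical_density, "-", label="fit")
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("optical density")
        ax.legend()
        return ax


def fit_spectrum(
    spectrum: Spectrum,
    table: ExtinctionTable,
    allow_scatter: bool = True,
    scatter_exponent: int = -4,
) -> SpectralUnmixingResults:
    """Convenience wrapper: build a :class:`SpectralUnmixing` model and fit."""
    return SpectralUnmixing(spectrum, table, allow_scatter, scatter_exponent).fit()


def derivative_fractions(fit) -> DerivativeFractions:
    """Percentage of each derivative, 100·C_i/C_total.

    Accepts any object exposing ``c_hbo2``, ``c_hb`` and ``c_methb``.
    """
    c_hbo2, c_hb, c_methb = fit.c_hbo2, fit.c_hb, fit.c_methb
    c_total = c_hbo2 + c_hb + c_methb
    if c_total <= 0:
        raise UndefinedValueError("derivative fractions undefined for zero total hemoglobin")
    return DerivativeFractions(
        c_total=c_total,
        methb_percent=100.0 * c_methb / c_total,
        hbo2_percent=100.0 * c_hbo2 / c_total,
        hb_percent=100.0 * c_hb / c_total,
    )


def hemolysis_level(
    spectrum_t: Spectrum,
    spectrum_0: Spectrum,
    table: ExtinctionTable,
    allow_scatter: bool = True,
) -> float:
    """Hemolysis from the loss of cell-associated pigment.

    Convention: both spectra are unmixed and the hemolysis level is
    100·(1 − C_total(t)/C_total(0)), clipped to [0, 100].  A fully
    absorbance-free spectrum at time t therefore reads 100 %.
    """
    fit0 = fit_spectrum(spectrum_0, table, allow_scatter=allow_scatter)
    if fit0.c_total <= 0:
        raise UndefinedValueError("hemolysis undefined: reference spectrum has zero pigment")
    fit_t = fit_spectrum(spectrum_t, table, allow_scatter=allow_scatter)
    level = 100.0 * (1.0 - fit_t.c_total / fit0.c_total)
    return float(np.clip(level, 0.0, 100.0))
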