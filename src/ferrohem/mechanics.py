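"""Membrane stiffness from AFM force-indentation curves and surface profiles.

A spherical (paraboloidal) indenter of radius R pressed a depth h into an
elastic half-space obeys the Hertz law

    F = (4/3) * E/(1 - nu^2) * sqrt(R) * h^(3/2)

Young's modulus E is in kPa, R and h in nm, F in nN (the unit conversion
factor is 1e-6).  The Poisson ratio defaults to 0.5, the incompressible
limit conventionally used for cell membranes.  Contact is assumed at
h = 0; raw-curve preprocessing (deflection conversion, contact-point
search) is out of scope.

Group comparisons use the empirical modulus distribution: normalised
histograms, the empirical cumulative distribution function, and the
fraction of treated cells whose modulus exceeds a control quantile
(default level 0.95).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import FitError, NoStructureError, ValidationError

__all__ = [
    "ProbeParams",
    "ForceCurve",
    "ModulusSample",
    "ModulusDistribution",
    "ProfileFeatures",
    "hertz_force",
    "HertzContact",
    "HertzContactResults",
    "fit_youngs_modulus",
    "modulus_distribution",
    "fraction_beyond_control",
    "profile_features",
]

#: kPa * sqrt(nm) * nm^1.5 -> nN
_HERTZ_UNIT = 1e-6


@dataclass(frozen=True)
class ProbeParams:
    """Spherical AFM probe: radius in nm, Poisson ratio of the sample."""

    radius_nm: float = 150.0
    poisson_ratio: float = 0.5

    def __post_init__(self):
        if not self.radius_nm > 0:
            raise ValidationError("probe radius must be > 0")
        if not (0.0 <= self.poisson_ratio < 0.5 + 1e-9):
            raise ValidationError("Poisson ratio must lie in [0, 0.5]")


@dataclass
class ForceCurve:
    """Indentation (nm, nonnegative, nondecreasing) vs force (nN)."""

    indentation_nm: np.ndarray
    force_nN: np.ndarray

    def __post_init__(self):
        self.indentation_nm = np.asarray(self.indentation_nm, dtype=float)
        self.force_nN = np.asarray(self.force_nN, dtype=float)
        if self.indentation_nm.size != self.force_nN.size:
            raise ValidationError("indentation and force must have equal length")
        if np.any(self.indentation_nm < 0):
            raise ValidationError("indentation must be nonnegative")
        if np.any(np.diff(self.indentation_nm) < 0):
            raise ValidationError("indentation must be nondecreasing")

    def __len__(self):
        return self.indentation_nm.size

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"indentation_nm": self.indentation_nm, "force_nN": self.force_nN}
        )


@dataclass
class ModulusSample:
    """Per-cell Young's moduli (kPa) for one experimental group."""

    values_kpa: np.ndarray
    group_label: str = ""

    def __post_init__(self):
        self.values_kpa = np.asarray(self.values_kpa, dtype=float)
        if self.values_kpa.size and np.any(self.values_kpa <= 0):
            raise ValidationError("moduli must be positive")

    def __len__(self):
        return self.values_kpa.size


def hertz_force(e_kpa: float, probe: ProbeParams, indentation_nm):
    """Hertz force (nN) at the given indentation depth(s)."""
    h = np.asarray(indentation_nm, dtype=float)
    if np.any(h < 0):
        raise ValidationError("indentation must be >= 0")
    prefac = (4.0 / 3.0) * e_kpa / (1.0 - probe.poisson_ratio**2)
    out = prefac * np.sqrt(probe.radius_nm) * h**1.5 * _HERTZ_UNIT
    return out if out.ndim else float(out)


class HertzContact:
    """Model object: least-squares Hertz fit of one force curve.

    The model is linear in E, so the estimate is the closed-form
    projection E = sum(F*phi)/sum(phi^2) with phi the unit-modulus force.
    """

    def __init__(self, curve: ForceCurve, probe: ProbeParams = ProbeParams()):
        if np.count_nonzero(curve.indentation_nm > 0) < 5:
            raise ValidationError("need at least 5 points with positive indentation")
        self.curve = curve
        self.probe = probe

    def fit(self) -> "HertzContactResults":
        phi = np.asarray(hertz_force(1.0, self.probe, self.curve.indentation_nm))
        f = self.curve.force_nN
        denom = float(phi @ phi)
        e = float(phi @ f) / denom
        if not np.isfinite(e) or e <= 0:
            raise FitError(
                f"Hertz fit produced non-physical modulus E = {e:g} kPa",
                residuals=f - e * phi,
            )
        resid = f - e * phi
        ss_tot = float(np.sum((f - f.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        n = len(self.curve)
        dof = max(n - 1, 1)
        stderr = float(np.sqrt(np.sum(resid**2) / dof / denom))
        return HertzContactResults(
            model=self, e_kpa=e, stderr_kpa=stderr, r2=r2, residuals=resid
        )


@dataclass
class HertzContactResults:
    model: HertzContact
    e_kpa: float
    stderr_kpa: float
    r2: float
    residuals: np.ndarray

    def predicted(self) -> np.ndarray:
        return np.asarray(
            hertz_force(self.e_kpa, self.model.probe, self.model.curve.indentation_nm)
        )

    def summary(self) -> str:
        p = self.model.probe
        return (
            "Hertz contact fit (spherical indenter)\n"
            f"  probe radius = {p.radius_nm:g} nm, Poisson ratio = {p.poisson_ratio:g}\n"
            f"  E = {self.e_kpa:.4f} +/- {self.stderr_kpa:.4f} kPa  (R2 = {self.r2:.6f}, "
            f"n = {len(self.model.curve)})"
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.curve
        ax.plot(c.indentation_nm, c.force_nN, ".", ms=3, label="measured")
        ax.plot(c.indentation_nm, self.predicted(), "-", label=f"Hertz, E={self.e_kpa:.1f} kPa")
        ax.set_xlabel("indentation (nm)")
        ax.set_ylabel("force (nN)")
        ax.legend()
        return ax


def fit_youngs_modulus(curve: ForceCurve, probe: ProbeParams = ProbeParams()) -> float:
    """Young's modulus (kPa) of one force curve under the Hertz model."""
    return HertzContact(curve, probe).fit().e_kpa


@dataclass
class ModulusDistribution:
    """Normalised histogram (density integrates to 1) plus the ECDF."""

    bin_edges: np.ndarray
    density: np.ndarray
    ecdf_x: np.ndarray
    ecdf_y: np.ndarray

    def ecdf(self, x) -> np.ndarray:
        """Right-continuous empirical CDF evaluated at x."""
        return np.searchsorted(self.ecdf_x, np.asarray(x, dtype=float), side="right") / self.ecdf_x.size


def modulus_distribution(sample: ModulusSample, bins: int = 10) -> ModulusDistribution:
    """Relative-frequency-density histogram and ECDF of a modulus sample."""
    if len(sample) == 0:
        raise ValidationError("modulus sample is empty")
    density, edges = np.histogram(sample.values_kpa, bins=bins, density=True)
    xs = np.sort(sample.values_kpa)
    ys = np.arange(1, xs.size + 1) / xs.size
    return ModulusDistribution(bin_edges=edges, density=density, ecdf_x=xs, ecdf_y=ys)


def fraction_beyond_control(
    treatment: ModulusSample, control: ModulusSample, level: float = 0.95
) -> float:
    """Percent of treated cells stiffer than the control `level`-quantile.

    The control quantile is empirical (linear/type-7 interpolation).  For
    treatment == control (large n) the answer approaches 100*(1-level).
    """
    if len(treatment) == 0 or len(control) == 0:
        raise ValidationError("both samples must be nonempty")
    if not 0.0 < level < 1.0:
        raise ValidationError("level must lie strictly between 0 and 1")
    threshold = float(np.quantile(control.values_kpa, level))
    return 100.0 * float(np.mean(treatment.values_kpa > threshold))


@dataclass
class ProfileFeatures:
    """Spatial period between profile minima and mean concave-to-peak height."""

    period_nm: float
    height_nm: float


def _local_extrema(y: np.ndarray):
    """Indices of strict local minima and maxima of a 1-D signal.

    Plateaus are collapsed to their midpoint.
    """
    dy = np.sign(np.diff(y))
    # propagate the sign over zero-runs so plateau edges count once
    for i in range(1, dy.size):
        if dy[i] == 0:
            dy[i] = dy[i - 1]
    turns = np.diff(dy)
    minima = np.where(turns > 0)[0] + 1
    maxima = np.where(turns < 0)[0] + 1
    return minima, maxima


def profile_features(
    heights, positions, smooth_window: int | None = None
) -> ProfileFeatures:
    """Extract the spatial period and corrugation height of an AFM profile.

    Period: mean spacing between successive local minima.  Height: mean of
    (local maximum − mean of adjacent minima) over maxima flanked by
    minima.  Optional Savitzky-Golay smoothing (odd window length) is
    applied first.

    Raises :class:`NoStructureError` for flat or monotone profiles.
    """
    y = np.asarray(heights, dtype=float)
    pos = np.asarray(positions, dtype=float)
    if y.size != pos.size:
        raise ValidationError("heights and positions must have equal length")
    if y.size < 5:
        raise ValidationError("profile too short")
    if smooth_window is not None:
        if smooth_window % 2 == 0 or smooth_window < 5:
            raise ValidationError("smooth_window must be an odd integer >= 5")
        y = savgol_filter(y, smooth_window, polyorder=2)
    if np.ptp(y) == 0:
        raise NoStructureError("flat profile: no periodic structure")
    minima, maxima = _local_extrema(y)
    if minima.size < 2 or maxima.size < 1:
        raise NoStructureError("profile has no resolvable periodic structure")
    period = float(np.mean(np.diff(pos[minima])))
    heights_list = []
    for m in maxima:
        left = minima[minima < m]
        right = minima[minima > m]
        if left.size and right.size:
            base = 0.5 * (y[left[-1]] + y[right[0]])
            heights_list.append(y[m] - base)
    if not heights_list:
        raise NoStructureError("no maxima flanked by minima")
    return ProfileFeatures(period_nm=period, height_nm=float(np.mean(heights_list)))
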