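"""Mass-action kinetics of Fenton-driven methemoglobin formation.

The model tracks two species in a pRBC lysate exposed to free ferrous
iron.  The Fenton reaction Fe2+ + H2O2 -> OH· + OH- + Fe3+ consumes iron
at a rate proportional to the product of reactant concentrations; the
hydroxyl radical then converts oxyhemoglobin (HbO2) to methemoglobin
(MetHb).  With the quasi-steady-state assumption that the peroxide
concentration ``a`` is constant, the system is

    dy/dt = -beta * a * y(t)                 y(0) = y0   (free Fe2+)
    dx/dt = gamma * a * y(t) * (Z0 - x(t))   x(0) = 0    (MetHb)

and has the closed-form solution

    y(t) = y0 * exp(-beta*a*t)
    x(t) = Z0 * (1 - exp(-(gamma/beta) * y0 * (1 - exp(-beta*a*t))))

with steady state x_ss = Z0 * (1 - exp(-gamma*y0/beta)).

Units: concentrations in µM, time in minutes, beta in µM⁻¹min⁻¹,
gamma in µM⁻²min⁻¹.

Identifiability note: x(t) depends on (a, beta, gamma) only through
u = beta*a and v = gamma/beta, so the transformation
(a, beta, gamma) -> (k*a, beta/k, gamma/k) leaves x(t) unchanged for any
k > 0.  Fitting all three parameters to a single MetHb curve is therefore
structurally degenerate; see :mod:`ferrohem.fitting`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import FitError, ValidationError

__all__ = [
    "KineticParams",
    "KineticTimeSeries",
    "fe_decay",
    "methb_time",
    "methb_steady_state",
    "methb_percent",
    "initial_rate",
    "closed_form_series",
    "ode_solve",
]


@dataclass(frozen=True)
class KineticParams:
    """Parameter set of the two/three-component kinetic model.

    a : constant H2O2 concentration (µM)
    beta : Fenton rate constant (µM⁻¹ min⁻¹)
    gamma : HbO2-oxidation rate constant (µM⁻² min⁻¹)
    y0 : initial free Fe2+ (µM)
    z0 : initial HbO2 (µM); 5 ± 0.5 µM under the study conditions
    """

    a: float
    beta: float
    gamma: float
    y0: float
    z0: float

    def __post_init__(self):
        for name in ("a", "beta", "gamma", "y0", "z0"):
            if getattr(self, name) < 0:
                raise ValidationError(f"KineticParams.{name} must be >= 0")

    def replace(self, **kw) -> "KineticParams":
        d = self.__dict__.copy()
        d.update(kw)
        return KineticParams(**d)

    @property
    def u(self) -> float:
        """Composite Fe2+ decay rate u = beta*a (min⁻¹)."""
        return self.beta * self.a

    @property
    def v(self) -> float:
        """Composite conversion yield v = gamma/beta (µM⁻¹)."""
        if self.beta == 0:
            raise ValidationError("v = gamma/beta undefined for beta = 0")
        return self.gamma / self.beta


#: Mean fitted parameters reported for the study's lysate curves
#: (a in µM, beta in µM⁻¹min⁻¹, gamma in µM⁻²min⁻¹, Z0 in µM).
REPORTED_A = 0.00090
REPORTED_BETA = 0.973
REPORTED_GAMMA = 0.0030
REPORTED_Z0 = 5.0

#: Initial Fe2+ concentrations (µM) covered by the exposure series.
STUDY_FE_CONCENTRATIONS_UM = (212.5, 425.0, 850.0, 1700.0, 3400.0, 6800.0, 13600.0)


def reported_params(y0: float = 1700.0, z0: float = REPORTED_Z0) -> KineticParams:
    """The study's mean fitted parameter set at a chosen initial Fe2+."""
    return KineticParams(REPORTED_A, REPORTED_BETA, REPORTED_GAMMA, y0, z0)


def _check_time(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValidationError("time must be >= 0")
    return t


def fe_decay(t, p: KineticParams):
    """Free Fe2+ concentration y(t) = y0·exp(−β·a·t), in µM."""
    t = _check_time(t)
    out = p.y0 * np.exp(-p.u * t)
    return out if out.ndim else float(out)


def methb_time(t, p: KineticParams):
    """MetHb concentration x(t) from the closed-form solution, in µM.

    The degenerate limit beta*a -> 0 is handled by the continuous
    series limit x(t) = Z0·(1 − exp(−gamma·a·y0·t)).
    """
    t = _check_time(t)
    if p.u == 0.0:
        expo = p.gamma * p.a * p.y0 * t
    else:
        expo = (p.gamma / p.beta) * p.y0 * (-np.expm1(-p.u * t))
    out = p.z0 * (-np.expm1(-expo))
    return out if out.ndim else float(out)


def methb_steady_state(p: KineticParams) -> float:
    """Plateau MetHb level x_ss = Z0·(1 − exp(−γ·y0/β)), in µM."""
    if p.beta == 0:
        raise ValidationError("steady state undefined for beta = 0")
    return p.z0 * (-np.expm1(-p.gamma * p.y0 / p.beta))


def methb_percent(x, p: KineticParams):
    """Express a MetHb concentration as percent of the initial HbO2 pool."""
    if p.z0 <= 0:
        raise ValidationError("z0 must be > 0 for percent reporting")
    return 100.0 * np.asarray(x, dtype=float) / p.z0


def initial_rate(p: KineticParams) -> float:
    """Initial MetHb formation rate V(0) = γ·a·y0·Z0, in µM/min."""
    return p.gamma * p.a * p.y0 * p.z0


@dataclass
class KineticTimeSeries:
    """Time course of the kinetic model on a grid.

    t : minutes; x : MetHb (µM); y : free Fe2+ (µM);
    hbo2 : remaining HbO2 = Z0 − x (µM);
    rate : instantaneous MetHb formation rate dC/dt (µM/min).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    hbo2: np.ndarray
    rate: np.ndarray
    params: KineticParams

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_min": self.t,
                "methb_um": self.x,
                "fe_um": self.y,
                "hbo2_um": self.hbo2,
                "rate_um_per_min": self.rate,
            }
        )


def _check_grid(t_grid) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValidationError("t_grid must be a nonempty 1-D array")
    if t[0] < 0 or np.any(np.diff(t) < 0):
        raise ValidationError("t_grid must be nondecreasing and start at t >= 0")
    return t


def closed_form_series(p: KineticParams, t_grid) -> KineticTimeSeries:
    """Evaluate the analytic solution on a grid."""
    t = _check_grid(t_grid)
    x = np.asarray(methb_time(t, p))
    y = np.asarray(fe_decay(t, p))
    rate = p.gamma * p.a * y * (p.z0 - x)
    return KineticTimeSeries(t=t, x=x, y=y, hbo2=p.z0 - x, rate=rate, params=p)


def ode_solve(p: KineticParams, t_grid, rtol: float = 1e-10, atol: float = 1e-12) -> KineticTimeSeries:
    """Numerically integrate the coupled ODE system (cross-check of the
    closed forms).

    Raises
    ------
    FitError
        If the integrator reports failure.
    """
    t = _check_grid(t_grid)

    def rhs(_t, s):
        x, y = s
        return [p.gamma * p.a * y * (p.z0 - x), -p.beta * p.a * y]

    t0, t1 = float(t[0]), float(t[-1])
    if t1 == t0:
        x = np.zeros_like(t)
        y = np.full_like(t, p.y0)
    else:
        sol = solve_ivp(
            rhs,
            (t0, t1),
            [0.0, p.y0],
            t_eval=t,
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise FitError(f"ODE integration failed: {sol.message}")
        x, y = sol.y
    rate = p.gamma * p.a * y * (p.z0 - x)
    return KineticTimeSeries(t=t, x=x, y=y, hbo2=p.z0 - x, rate=rate, params=p)
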