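"""Estimation of kinetic parameters from MetHb time series.

The closed-form MetHb solution (see :mod:`ferrohem.kinetics`)

    x(t) = Z0 * (1 - exp(-v * y0 * (1 - exp(-u * t))))

depends on (a, beta, gamma) only through the composites u = beta*a and
v = gamma/beta.  A three-parameter fit to a single curve is therefore
structurally degenerate: the family (k*a, beta/k, gamma/k) produces the
identical curve for every k > 0.  The fitter always estimates (u, v) and
resolves the physical triple only when the peroxide concentration ``a``
is supplied (the study validated the fitted ``a`` against its measured
value, which justifies treating it as known).  Without ``a`` the results
carry ``identifiable=False``, an :class:`IdentifiabilityWarning` is
emitted, and (a, beta, gamma) are reported as NaN.

Replicated measurements should be averaged per concentration before
fitting (the study's own protocol); :func:`summarize_fits` then combines
per-curve estimates either by plain arithmetic mean +/- SD or by
inverse-variance weighting, which is the appropriate choice when
per-curve uncertainties differ by an order of magnitude — as they do
here, because low-iron curves are nearly uninformative about beta.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import (
    DegenerateDataError,
    FitError,
    UndefinedValueError,
    ValidationError,
)
from .kinetics import KineticParams

__all__ = [
    "IdentifiabilityWarning",
    "CurveFitResult",
    "ParamSummary",
    "MetHbKinetics",
    "fit_methb_curve",
    "summarize_fits",
    "r_squared",
    "pearson_corr",
]


class IdentifiabilityWarning(UserWarning):
    """The requested parameterisation lies on the (a, beta, gamma) ridge."""


def r_squared(observed, predicted, n_params: int = 0, adjusted: bool = False) -> float:
    """Coefficient of determination R² = 1 − SS_res/SS_tot.

    With ``adjusted=True`` returns 1 − (1 − R²)(n − 1)/(n − n_params − 1).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValidationError("observed and predicted must have equal length")
    n = obs.size
    if n < 2:
        raise ValidationError("need at least 2 points for R2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedValueError("R2 undefined: observed values have zero variance")
    r2 = 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot
    if not adjusted:
        return r2
    if n - n_params - 1 < 1:
        raise ValidationError("adjusted R2 needs n - n_params - 1 >= 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def pearson_corr(x, y) -> float:
    """Product-moment correlation coefficient.

    Two points give +/-1 degenerately; a warning is emitted in that case.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValidationError("x and y must have equal length")
    if xv.size < 2:
        raise ValidationError("need at least 2 points for a correlation")
    if xv.size == 2:
        warnings.warn("correlation of 2 points is degenerately +/-1", UserWarning, stacklevel=2)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise UndefinedValueError("correlation undefined: zero variance")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    return float(np.sum(xc * yc) / math.sqrt(np.sum(xc**2) * np.sum(yc**2)))


def _curve_uv(u, v, y0, z0, t):
    """x(t) in the identifiable (u, v) parameterisation."""
    return z0 * (-np.expm1(-v * y0 * (-np.expm1(-u * t))))


@dataclass
class CurveFitResult:
    """One fitted MetHb curve.

    ``params`` holds (a, beta, gamma, y0, z0); a/beta/gamma are NaN when
    the fit was done without a known peroxide concentration (ridge).
    ``covariance`` is the 2x2 covariance of (beta, gamma) when
    identifiable, else of (u, v).
    """

    params: KineticParams | None
    u: float
    v: float
    r2: float
    n_points: int
    converged: bool
    covariance: np.ndarray
    identifiable: bool
    residuals: np.ndarray
    t: np.ndarray | None = None

    @property
    def beta(self) -> float:
        return self.params.beta if self.identifiable else float("nan")

    @property
    def gamma(self) -> float:
        return self.params.gamma if self.identifiable else float("nan")

    @property
    def a(self) -> float:
        return self.params.a if self.identifiable else float("nan")


@dataclass
class ParamSummary:
    """Location +/- spread of fitted parameters across curves."""

    mean_a: float
    sd_a: float
    mean_beta: float
    sd_beta: float
    mean_gamma: float
    sd_gamma: float
    mean_r2: float
    sd_r2: float
    n_fits: int
    weighting: str = "equal"


class MetHbKinetics:
    """Model object for fitting the closed-form MetHb solution to data.

    Parameters
    ----------
    t, x : arrays
        Time (min) and MetHb concentration (µM).
    y0 : float
        Initial free Fe2+ (µM), known from the exposure.
    z0 : float
        Initial HbO2 (µM), known from the assay (5 µM under the study
        conditions).
    """

    def __init__(self, t, x, y0: float, z0: float):
        t = np.asarray(t, dtype=float)
        x = np.asarray(x, dtype=float)
        if t.size != x.size:
            raise ValidationError("t and x must have equal length")
        if t.size < 4:
            raise ValidationError("need at least 4 time points")
        if np.any(t < 0) or np.any(np.diff(t) < 0):
            raise ValidationError("t must be nonnegative and nondecreasing")
        if y0 < 0 or z0 <= 0:
            raise ValidationError("require y0 >= 0 and z0 > 0")
        if np.any(x < 0) or np.any(x > 1.05 * z0):
            raise ValidationError("x values must lie within [0, 1.05*z0]")
        if np.ptp(x) == 0:
            raise DegenerateDataError("flat MetHb series: nothing to fit")
        self.t = t
        self.x = x
        self.y0 = float(y0)
        self.z0 = float(z0)

    @classmethod
    def from_dataframe(cls, df, y0: float, z0: float, methb_unit: str = "um") -> "MetHbKinetics":
        """Build from a table with columns ``time_min`` and ``methb``.

        ``methb_unit`` is ``"um"`` or ``"percent"`` (percent of z0).
        """
        x = df["methb"].to_numpy(dtype=float)
        if methb_unit == "percent":
            x = x * z0 / 100.0
        elif methb_unit != "um":
            raise ValidationError("methb_unit must be 'um' or 'percent'")
        return cls(df["time_min"].to_numpy(dtype=float), x, y0, z0)

    # -- initial guesses ---------------------------------------------------
    def _initial_guess(self) -> tuple[float, float]:
        """(u0, v0) from the plateau and the late-time approach to it.

        v0 inverts the steady-state relation at the largest observed
        level; u0 comes from a log-linear fit of the gap to a slightly
        inflated plateau, falling back to the reciprocal observation
        window when that fails.
        """
        t, x, z0, y0 = self.t, self.x, self.z0, self.y0
        frac = np.clip(np.max(x) / z0, 1e-6, 0.999)
        v0 = -np.log1p(-frac) / max(y0, 1e-12)
        u0 = 1.0 / max(t[-1], 1.0)
        xss = min(float(np.max(x)) * 1.05, z0 * 0.9999)
        gap = xss - x
        mask = (t > 0) & (gap > 0)
        if mask.sum() >= 2:
            A = np.column_stack([t[mask], np.ones(mask.sum())])
            slope = np.linalg.lstsq(A, np.log(gap[mask]), rcond=None)[0][0]
            if slope < 0:
                u0 = -slope
        return float(u0), float(max(v0, 1e-12))

    def fit(
        self,
        fix_a: float | None = None,
        initial: tuple[float, float] | None = None,
        max_nfev: int = 20000,
    ) -> CurveFitResult:
        """Least-squares fit of (u, v); resolve (beta, gamma) when
        ``fix_a`` is given.

        Raises :class:`FitError` (carrying the final residuals) on
        non-convergence.
        """
        t, x, y0, z0 = self.t, self.x, self.y0, self.z0
        u0, v0 = initial if initial is not None else self._initial_guess()

        def resid(p):
            return _curve_uv(p[0], p[1], y0, z0, t) - x

        res = least_squares(
            resid,
            x0=[u0, v0],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=max_nfev,
        )
        if not res.success:
            raise FitError(
                f"MetHb curve fit did not converge: {res.message}", residuals=res.fun
            )
        u, v = res.x
        predicted = _curve_uv(u, v, y0, z0, t)
        r2 = r_squared(x, predicted)
        cov_uv = self._covariance(res)

        if fix_a is not None:
            if fix_a <= 0:
                raise ValidationError("fix_a must be > 0")
            beta = u / fix_a
            gamma = v * beta
            # delta method: (beta, gamma) = (u/a, u*v/a)
            J = np.array([[1.0 / fix_a, 0.0], [v / fix_a, u / fix_a]])
            cov = J @ cov_uv @ J.T
            params = KineticParams(a=fix_a, beta=beta, gamma=gamma, y0=y0, z0=z0)
            identifiable = True
        else:
            warnings.warn(
                "a (H2O2 concentration) not supplied: only the composites "
                "u = beta*a and v = gamma/beta are identifiable; "
                "a/beta/gamma are reported as NaN",
                IdentifiabilityWarning,
                stacklevel=2,
            )
            cov = cov_uv
            params = None
            identifiable = False

        return CurveFitResult(
            params=params,
            u=float(u),
            v=float(v),
            r2=r2,
            n_points=t.size,
            converged=True,
            covariance=cov,
            identifiable=identifiable,
            residuals=x - predicted,
            t=t.copy(),
        )

    @staticmethod
    def _covariance(res) -> np.ndarray:
        """Gauss-Newton covariance of (u, v) from the least-squares jacobian."""
        n, p = res.jac.shape
        dof = max(n - p, 1)
        s2 = 2.0 * res.cost / dof
        jtj = res.jac.T @ res.jac
        try:
            return s2 * np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            return s2 * np.linalg.pinv(jtj)


def fit_methb_curve(t, x, y0: float, z0: float, fix_a: float | None = None) -> CurveFitResult:
    """Convenience wrapper: build a :class:`MetHbKinetics` model and fit."""
    return MetHbKinetics(t, x, y0, z0).fit(fix_a=fix_a)


def summarize_fits(fits, weighting: str = "equal") -> ParamSummary:
    """Combine per-curve parameter estimates.

    ``weighting='equal'`` (default): arithmetic mean +/- sample SD.
    ``weighting='precision'``: inverse-variance weighted mean with
    weights iterated at the consensus estimate, the standard combination
    when per-curve variances differ widely; the reported SD is the
    weighted SE scaled to a dispersion measure (sqrt of weighted
    variance of the estimates).
    Only converged fits enter; at least one is required.
    """
    fits = [f for f in fits if f.converged]
    if not fits:
        raise ValidationError("summarize_fits needs at least one converged fit")
    if any(not f.identifiable for f in fits):
        raise ValidationError(
            "cannot summarise (a, beta, gamma) from ridge fits; refit with fix_a"
        )
    a = np.array([f.params.a for f in fits])
    beta = np.array([f.params.beta for f in fits])
    gamma = np.array([f.params.gamma for f in fits])
    r2 = np.array([f.r2 for f in fits])
    n = len(fits)

    def sd(vals):
        return float(np.std(vals, ddof=1)) if n > 1 else 0.0

    if weighting == "equal":
        return ParamSummary(
            mean_a=float(a.mean()),
            sd_a=sd(a),
            mean_beta=float(beta.mean()),
            sd_beta=sd(beta),
            mean_gamma=float(gamma.mean()),
            sd_gamma=sd(gamma),
            mean_r2=float(r2.mean()),
            sd_r2=sd(r2),
            n_fits=n,
            weighting="equal",
        )
    if weighting != "precision":
        raise ValidationError("weighting must be 'equal' or 'precision'")

    var_beta = np.array([max(float(f.covariance[0, 0]), 1e-300) for f in fits])
    var_gamma = np.array([max(float(f.covariance[1, 1]), 1e-300) for f in fits])
    mean_beta = _consensus_weighted_mean(fits, beta, var_beta, index=0)
    mean_gamma = _consensus_weighted_mean(fits, gamma, var_gamma, index=1)
    wb = 1.0 / var_beta
    wg = 1.0 / var_gamma

    def wsd(vals, w, m):
        if n == 1:
            return 0.0
        return float(np.sqrt(np.sum(w * (vals - m) ** 2) / np.sum(w) * n / (n - 1)))

    return ParamSummary(
        mean_a=float(a.mean()),
        sd_a=sd(a),
        mean_beta=mean_beta,
        sd_beta=wsd(beta, wb, mean_beta),
        mean_gamma=mean_gamma,
        sd_gamma=wsd(gamma, wg, mean_gamma),
        mean_r2=float(r2.mean()),
        sd_r2=sd(r2),
        n_fits=n,
        weighting="precision",
    )


def _consensus_weighted_mean(fits, vals, var0, index: int, n_iter: int = 3) -> float:
    """Inverse-variance mean with weights re-evaluated at the consensus.

    Per-fit variance estimates are noisy exactly where the estimates are
    (along the soft likelihood ridge), so after a first pass the weights
    are recomputed from the model jacobian evaluated at the pooled
    (beta, gamma) and each curve's own design (y0, z0, t grid, residual
    scale).  Three passes are ample for convergence.
    """
    w = 1.0 / var0
    mean = float(np.sum(w * vals) / np.sum(w))
    a_ref = fits[0].params.a
    s2_pool = float(
        np.mean([np.sum(f.residuals**2) / max(f.n_points - 2, 1) for f in fits])
    )
    other = np.array([(f.params.gamma if index == 0 else f.params.beta) for f in fits])
    for _ in range(n_iter):
        variances = []
        for f in fits:
            if index == 0:
                beta_c, gamma_c = mean, float(np.mean(other))
            else:
                beta_c, gamma_c = float(np.mean(other)), mean
            var = _param_variance_at(
                beta_c, gamma_c, a_ref, f, s2_pool, index=index
            )
            variances.append(max(var, 1e-300))
        w = 1.0 / np.asarray(variances)
        mean = float(np.sum(w * vals) / np.sum(w))
    return mean


def _param_variance_at(beta, gamma, a, fit, s2, index: int) -> float:
    """Variance of beta (index 0) or gamma (index 1) at given parameters,
    from the Gauss-Newton information of that curve's design."""
    y0 = fit.params.y0
    z0 = fit.params.z0
    t = fit.t
    if t is None:
        raise ValidationError("fit lacks a stored time grid")
    u = beta * a
    v = gamma / beta
    eps = 1e-6
    du = (
        _curve_uv(u * (1 + eps), v, y0, z0, t) - _curve_uv(u * (1 - eps), v, y0, z0, t)
    ) / (2 * eps * u)
    dv = (
        _curve_uv(u, v * (1 + eps), y0, z0, t) - _curve_uv(u, v * (1 - eps), y0, z0, t)
    ) / (2 * eps * v)
    J = np.column_stack([du, dv])
    cov_uv = s2 * np.linalg.pinv(J.T @ J)
    Jt = np.array([[1.0 / a, 0.0], [v / a, u / a]])
    cov = Jt @ cov_uv @ Jt.T
    return float(cov[index, index])
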