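"""Nonlinear least-squares fitting of saturation curves and linear regression.

Three fitters cover the estimation problems of the analysis pipeline:

* :func:`fit_hill` — the Hill equation (p50, n_H) for a single curve;
* :func:`fit_mwc` — the tetrameric MWC saturation function (L, K_R, K_T),
  with any subset optionally held fixed;
* :func:`fit_global_shared_affinities` — several curves measured under
  different effector conditions fitted jointly, sharing one (K_R, K_T) pair
  (hence one c) while each curve keeps its own apparent allosteric constant,
  the estimator appropriate when effectors act on L alone;
* :func:`fit_effector_binding` — the non-exclusive effector-binding model
  for (L_base, K_IT, K_IR) from (I, L_app) pairs.

All MWC-type parameters are optimized as base-10 logarithms: L and the
dissociation constants span many decades, and the log parameterization both
enforces positivity and conditions the problem.  Least squares is unweighted
on saturation fractions.  The L–K_R trade-off creates local minima, so MWC
fits use a deterministic multistart lattice.  Fit adequacy is flagged at
R^2 > 0.97 and reported, never used to drop data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .core import (
    EffectorBinding,
    HillParameters,
    MWCParameters,
    SaturationCurve,
    apparent_allosteric_constant,
    hill_fractional_saturation,
    mwc_fractional_saturation,
)

__all__ = [
    "FitResult",
    "GlobalFitResult",
    "LinearRegressionResult",
    "ADEQUACY_R2",
    "fit_hill",
    "fit_mwc",
    "fit_global_shared_affinities",
    "fit_effector_binding",
    "linear_regression",
]

# R^2 above which a fit is reported as adequate
ADEQUACY_R2 = 0.97

# bounds for log10-space optimization
_LOG_L_BOUNDS = (-3.0, 10.0)
_LOG_K_BOUNDS = (math.log10(1e-3), math.log10(1e4))

# standard errors larger than this (in log10 units) flag a parameter as
# practically unidentifiable from the data at hand
_WIDE_STDERR = 10.0


@dataclass(frozen=True)
class FitResult:
    """Outcome of a nonlinear least-squares fit.

    ``parameters`` is the fitted domain object (HillParameters,
    MWCParameters or EffectorBinding); ``standard_errors`` maps parameter
    names to asymptotic standard errors (log10-space parameters carry a
    ``log10_`` prefix); ``adequate`` is True iff R^2 exceeds 0.97.
    """

    parameters: Union[HillParameters, MWCParameters, EffectorBinding, None]
    standard_errors: Dict[str, float]
    r_squared: float
    converged: bool
    residuals: Tuple[float, ...]
    message: str = ""

    @property
    def adequate(self) -> bool:
        return self.converged and self.r_squared > ADEQUACY_R2

    @property
    def unidentifiable(self) -> Tuple[str, ...]:
        """Names of parameters whose standard errors are effectively infinite."""
        return tuple(
            k
            for k, v in self.standard_errors.items()
            if not math.isfinite(v) or v > _WIDE_STDERR
        )

    def to_dict(self) -> dict:
        """JSON-compatible report of parameters, errors and diagnostics."""
        params: Dict[str, float] = {}
        p = self.parameters
        if isinstance(p, HillParameters):
            params = {"p50": p.K_half, "n_H": p.n_H}
        elif isinstance(p, MWCParameters):
            params = {"L": p.L, "K_R": p.K_R, "K_T": p.K_T, "c": p.c}
        elif isinstance(p, EffectorBinding):
            params = {"L_base": p.L_base, "K_IT": p.K_IT, "K_IR": p.K_IR}
        return {
            "parameters": params,
            "standard_errors": dict(self.standard_errors),
            "r_squared": self.r_squared,
            "converged": self.converged,
            "adequate": self.adequate,
            "unidentifiable": list(self.unidentifiable),
            "message": self.message,
        }


@dataclass(frozen=True)
class GlobalFitResult:
    """Joint fit of several curves sharing (K_R, K_T) with per-curve L_app."""

    K_R: float
    K_T: float
    L_app: Tuple[float, ...]
    standard_errors: Dict[str, float]
    r_squared: float
    converged: bool
    residuals: Tuple[float, ...]
    message: str = ""

    @property
    def c(self) -> float:
        return self.K_R / self.K_T

    @property
    def adequate(self) -> bool:
        return self.converged and self.r_squared > ADEQUACY_R2

    def to_dict(self) -> dict:
        return {
            "parameters": {
                "K_R": self.K_R,
                "K_T": self.K_T,
                "c": self.c,
                "L_app": list(self.L_app),
            },
            "standard_errors": dict(self.standard_errors),
            "r_squared": self.r_squared,
            "converged": self.converged,
            "adequate": self.adequate,
            "message": self.message,
        }


@dataclass(frozen=True)
class LinearRegressionResult:
    """Ordinary least-squares line on (already transformed) axes."""

    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float
    intercept_stderr: float
    n: int


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _r_squared(y: np.ndarray, residuals: np.ndarray) -> float:
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float("-inf") if ss_res > 0 else 1.0
    return 1.0 - ss_res / ss_tot


def _stderr_from_jacobian(jac: np.ndarray, residuals: np.ndarray) -> np.ndarray:
    """Asymptotic standard errors from the NLS Jacobian at the solution.

    Uses the pseudo-inverse of J^T J so that directions the data do not
    constrain come out as huge (not crashing) standard errors.
    """
    m, k = jac.shape
    dof = max(m - k, 1)
    s2 = float(np.sum(residuals**2)) / dof
    jtj = jac.T @ jac
    # detect near-singular directions explicitly
    try:
        cov = np.linalg.pinv(jtj, rcond=1e-12) * s2
    except np.linalg.LinAlgError:  # pragma: no cover
        return np.full(k, np.inf)
    err = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    # a direction with ~zero curvature is unidentifiable, not zero-error
    curv = np.diag(jtj)
    err[curv < 1e-12 * max(float(curv.max()), 1.0)] = np.inf
    return err


def _multistart_lattice(n_curves: int = 1) -> List[np.ndarray]:
    """8 deterministic starting points on a log-spaced (L, K_R, K_T) lattice."""
    starts = []
    for logL in (1.0, 3.0, 5.0, 7.0):
        for logKR, logKT in ((0.0, 2.2), (1.0, 2.8)):
            starts.append(
                np.concatenate([[logL] * n_curves, [logKR, logKT]])
            )
    return starts


def _check_curve(curve: SaturationCurve, min_points: int) -> None:
    if len(curve) < min_points:
        raise ValueError(
            f"curve '{curve.label}' has {len(curve)} points; "
            f"need >= {min_points} for this fit"
        )


# --------------------------------------------------------------------------
# Hill fit
# --------------------------------------------------------------------------

def fit_hill(curve: SaturationCurve, n_sites: int = 4) -> FitResult:
    """Fit (p50, n_H) of the Hill equation to one saturation curve.

    Bounded NLS in (log10 p50, n_H) with 0 < n_H <= n_sites, multistarted
    over a small deterministic set.  Non-convergence and degenerate inputs
    are reported through the ``converged`` flag, never raised.
    """
    _check_curve(curve, 4)
    S = curve.pressure_array
    y = curve.saturation_array
    if np.sum((y > 0.0) & (y < 1.0)) < 3:
        return FitResult(
            parameters=None,
            standard_errors={},
            r_squared=float("-inf"),
            converged=False,
            residuals=tuple(np.zeros_like(y)),
            message="fewer than 3 saturations strictly inside (0, 1)",
        )
    if float(np.std(y)) == 0.0:
        return FitResult(
            parameters=None,
            standard_errors={},
            r_squared=float("-inf"),
            converged=False,
            residuals=tuple(y - y.mean()),
            message="constant saturation: p50 and n_H are undefined",
        )

    log_p50_bounds = (math.log10(S.min()) - 3.0, math.log10(S.max()) + 3.0)

    def resid(theta: np.ndarray) -> np.ndarray:
        hp = HillParameters(10.0 ** theta[0], theta[1], n_sites)
        return hill_fractional_saturation(S, hp) - y

    # crude p50 guess: pressure nearest half-saturation
    p50_guess = float(S[np.argmin(np.abs(y - 0.5))])
    starts = [
        np.array([math.log10(p50_guess), nh0]) for nh0 in (1.0, 2.0, 3.0)
    ]
    best = None
    for x0 in starts:
        sol = least_squares(
            resid,
            x0,
            bounds=([log_p50_bounds[0], 1e-6], [log_p50_bounds[1], float(n_sites)]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None
    err = _stderr_from_jacobian(best.jac, best.fun)
    hp = HillParameters(10.0 ** best.x[0], float(best.x[1]), n_sites)
    return FitResult(
        parameters=hp,
        standard_errors={"log10_p50": float(err[0]), "n_H": float(err[1])},
        r_squared=_r_squared(y, best.fun),
        converged=bool(best.success),
        residuals=tuple(best.fun),
        message=best.message,
    )


# --------------------------------------------------------------------------
# MWC fits
# --------------------------------------------------------------------------

def _mwc_resid_factory(S: np.ndarray, y: np.ndarray, n_sites: int):
    def model(logL: float, logKR: float, logKT: float) -> np.ndarray:
        p = MWCParameters(10.0 ** logL, 10.0 ** logKR, 10.0 ** logKT, n_sites)
        return mwc_fractional_saturation(S, p)

    return model


def fit_mwc(
    curve: SaturationCurve,
    fixed: Optional[Dict[str, float]] = None,
    n_sites: int = 4,
) -> FitResult:
    """Fit (L, K_R, K_T) of the MWC saturation function to one curve.

    ``fixed`` may pin any subset of {"L", "K_R", "K_T"} to given values;
    the remaining parameters are optimized in log10 space over a
    deterministic multistart lattice.  Under-determined configurations are
    reported through ``converged``/standard errors, never silently.
    """
    fixed = dict(fixed or {})
    unknown = set(fixed) - {"L", "K_R", "K_T"}
    if unknown:
        raise ValueError(f"cannot fix unknown parameters: {sorted(unknown)}")
    n_free = 3 - len(fixed)
    _check_curve(curve, 6 if n_free == 3 else 4)
    S = curve.pressure_array
    y = curve.saturation_array
    model = _mwc_resid_factory(S, y, n_sites)

    names = [p for p in ("L", "K_R", "K_T") if p not in fixed]
    lo = {"L": _LOG_L_BOUNDS[0], "K_R": _LOG_K_BOUNDS[0], "K_T": _LOG_K_BOUNDS[0]}
    hi = {"L": _LOG_L_BOUNDS[1], "K_R": _LOG_K_BOUNDS[1], "K_T": _LOG_K_BOUNDS[1]}

    def unpack(theta: np.ndarray) -> Dict[str, float]:
        vals = {k: math.log10(v) for k, v in fixed.items()}
        vals.update(dict(zip(names, theta)))
        return vals

    def resid(theta: np.ndarray) -> np.ndarray:
        v = unpack(theta)
        return model(v["L"], v["K_R"], v["K_T"]) - y

    full_starts = _multistart_lattice()
    starts = [
        np.array([s[("L", "K_R", "K_T").index(nm)] for nm in names])
        for s in full_starts
    ]
    # de-duplicate starts that collapse after dropping fixed coordinates
    seen, uniq = set(), []
    for s in starts:
        key = tuple(np.round(s, 6))
        if key not in seen:
            seen.add(key)
            uniq.append(s)

    best = None
    for x0 in uniq:
        sol = least_squares(
            resid,
            x0,
            bounds=([lo[nm] for nm in names], [hi[nm] for nm in names]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None
    v = unpack(best.x)
    params = MWCParameters(10.0 ** v["L"], 10.0 ** v["K_R"], 10.0 ** v["K_T"], n_sites)
    err = _stderr_from_jacobian(best.jac, best.fun)
    return FitResult(
        parameters=params,
        standard_errors={f"log10_{nm}": float(e) for nm, e in zip(names, err)},
        r_squared=_r_squared(y, best.fun),
        converged=bool(best.success),
        residuals=tuple(best.fun),
        message=best.message,
    )


def fit_global_shared_affinities(
    curves: Sequence[SaturationCurve], n_sites: int = 4
) -> GlobalFitResult:
    """Jointly fit several curves with shared (K_R, K_T) and per-curve L_app.

    The MWC prediction for heterotropic effectors is that only L moves, so
    the stacked residual over all curves is minimized with one (K_R, K_T)
    pair — hence one c — and an apparent allosteric constant per curve.
    With a single curve this is exactly the single-curve MWC objective.
    """
    if len(curves) < 1:
        raise ValueError("need at least one curve")
    for cu in curves:
        _check_curve(cu, 6)
    n = len(curves)
    S_list = [cu.pressure_array for cu in curves]
    y_all = np.concatenate([cu.saturation_array for cu in curves])

    def resid(theta: np.ndarray) -> np.ndarray:
        logLs, logKR, logKT = theta[:n], theta[n], theta[n + 1]
        out = []
        for logL, S in zip(logLs, S_list):
            p = MWCParameters(10.0 ** logL, 10.0 ** logKR, 10.0 ** logKT, n_sites)
            out.append(mwc_fractional_saturation(S, p))
        return np.concatenate(out) - y_all

    lo = [_LOG_L_BOUNDS[0]] * n + [_LOG_K_BOUNDS[0]] * 2
    hi = [_LOG_L_BOUNDS[1]] * n + [_LOG_K_BOUNDS[1]] * 2
    best = None
    for x0 in _multistart_lattice(n_curves=n):
        sol = least_squares(
            resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14
        )
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None
    err = _stderr_from_jacobian(best.jac, best.fun)
    errors = {
        f"log10_L_app[{i}]": float(err[i]) for i in range(n)
    }
    errors["log10_K_R"] = float(err[n])
    errors["log10_K_T"] = float(err[n + 1])
    return GlobalFitResult(
        K_R=10.0 ** float(best.x[n]),
        K_T=10.0 ** float(best.x[n + 1]),
        L_app=tuple(10.0 ** best.x[:n]),
        standard_errors=errors,
        r_squared=_r_squared(y_all, best.fun),
        converged=bool(best.success),
        residuals=tuple(best.fun),
        message=best.message,
    )


# --------------------------------------------------------------------------
# effector-binding fit
# --------------------------------------------------------------------------

def fit_effector_binding(
    I_values: Sequence[float],
    L_app_values: Sequence[float],
    n_sites: int = 4,
) -> FitResult:
    """Fit (L_base, K_IT, K_IR) of the non-exclusive effector model.

    The residual is taken in log10 L_app space, where the model is the sum
    of a constant and n_sites-scaled log terms and errors are closer to
    homoscedastic.  When all concentrations are far below K_IR the R-state
    affinity is unidentifiable; this is flagged through huge standard
    errors rather than an exception.
    """
    I = np.asarray(I_values, dtype=float)
    Lapp = np.asarray(L_app_values, dtype=float)
    if I.shape != Lapp.shape or I.ndim != 1:
        raise ValueError("I_values and L_app_values must be matched 1-D sequences")
    if len(I) < 4:
        raise ValueError(f"need >= 4 (I, L_app) pairs, got {len(I)}")
    if np.any(I < 0):
        raise ValueError("effector concentrations must be >= 0")
    if np.any(Lapp <= 0):
        raise ValueError("apparent allosteric constants must be > 0")
    y = np.log10(Lapp)
    I_pos = I[I > 0]
    k_lo = math.log10(I_pos.min()) - 4.0 if I_pos.size else -4.0
    k_hi = math.log10(I.max()) + 4.0 if I.max() > 0 else 4.0

    def resid(theta: np.ndarray) -> np.ndarray:
        eb = EffectorBinding(
            10.0 ** theta[0], 10.0 ** theta[1], 10.0 ** theta[2], n_sites
        )
        return np.log10(apparent_allosteric_constant(eb, I)) - y

    starts = []
    for kt in (k_lo + 2.0, 0.5 * (k_lo + k_hi), k_hi - 2.0):
        starts.append(np.array([y[np.argmin(I)], kt, kt + 2.0]))
    best = None
    for x0 in starts:
        sol = least_squares(
            resid,
            x0,
            bounds=(
                [_LOG_L_BOUNDS[0], k_lo, k_lo],
                [_LOG_L_BOUNDS[1], k_hi, k_hi],
            ),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None
    err = _stderr_from_jacobian(best.jac, best.fun)
    eb = EffectorBinding(
        10.0 ** float(best.x[0]),
        10.0 ** float(best.x[1]),
        10.0 ** float(best.x[2]),
        n_sites,
    )
    return FitResult(
        parameters=eb,
        standard_errors={
            "log10_L_base": float(err[0]),
            "log10_K_IT": float(err[1]),
            "log10_K_IR": float(err[2]),
        },
        r_squared=_r_squared(y, best.fun),
        converged=bool(best.success),
        residuals=tuple(best.fun),
        message=best.message,
    )


# --------------------------------------------------------------------------
# ordinary least squares
# --------------------------------------------------------------------------

def linear_regression(
    x_values: Sequence[float], y_values: Sequence[float]
) -> LinearRegressionResult:
    """OLS line through (x, y); R^2 = 1 - SS_res/SS_tot."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matched 1-D sequences")
    if len(x) < 3:
        raise ValueError(f"need >= 3 points for a regression, got {len(x)}")
    if float(np.std(x)) == 0.0:
        raise ValueError("zero variance in x: regression slope undefined")
    res = stats.linregress(x, y)
    return LinearRegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        slope_stderr=float(res.stderr),
        intercept_stderr=float(res.intercept_stderr),
        n=len(x),
    )
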