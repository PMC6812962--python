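"""Exact evaluation of the Hill and tetrameric MWC saturation functions.

The two-state concerted (MWC) model describes a protein of ``n`` identical
binding sites in equilibrium between a tense (T) and a relaxed (R) quaternary
conformation.  The conformational equilibrium in the absence of ligand is the
allosteric constant ``L = [T]/[R]``; ligand dissociation constants from the
two states are ``K_T`` and ``K_R``, and their ratio ``c = K_R/K_T`` measures
the relative affinity of the two states (``c < 1``: R binds more tightly).
Fractional saturation for a tetramer is

    Ybar(a) = [a(1+a)^3 + L c a (1+c a)^3] / [(1+a)^4 + L (1+c a)^4]

with ``a = [S]/K_R`` the ligand concentration scaled in units of ``K_R``.
Cooperativity is quantified by the local Hill slope

    n_H([S]) = [S] (dYbar/d[S]) / (Ybar (1 - Ybar)),

evaluated here (as in routine Hill fits of saturation data) at the point of
half-saturation.  Heterotropic (effector) regulation enters exclusively
through L: a non-exclusively binding inhibitor I with affinities K_IT, K_IR
for the two states rescales the allosteric constant to

    L_app = L ((1 + I/K_IT) / (1 + I/K_IR))^n.

All evaluations are written to remain numerically stable for L up to ~1e12
by working with the T/R-weighted term ratio in log space rather than with
the raw binding polynomials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MWCParameters",
    "HillParameters",
    "EffectorBinding",
    "SaturationCurve",
    "HalfSaturationPoint",
    "mwc_fractional_saturation",
    "mwc_fractional_saturation_scaled",
    "hill_fractional_saturation",
    "half_saturation_concentration",
    "apparent_allosteric_constant",
    "hill_slope_at",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MWCParameters:
    """Microscopic state of the two-state concerted model.

    Parameters
    ----------
    L : float
        T/R equilibrium constant in the absence of ligand (dimensionless,
        >= 0).
    K_R : float
        Ligand dissociation constant of the R state (mmHg, > 0).
    K_T : float
        Ligand dissociation constant of the T state (mmHg, > 0).
    n_sites : int
        Number of binding sites (default 4, the tetramer; only the
        tetramer is within tested scope).
    """

    L: float
    K_R: float
    K_T: float
    n_sites: int = 4

    def __post_init__(self) -> None:
        if not (self.L >= 0) or math.isnan(self.L):
            raise ValueError(f"allosteric constant L must be >= 0, got {self.L}")
        if not (self.K_R > 0 and self.K_T > 0):
            raise ValueError(
                f"dissociation constants must be > 0, got K_R={self.K_R}, K_T={self.K_T}"
            )
        if self.n_sites < 1:
            raise ValueError("n_sites must be a positive integer")

    @property
    def c(self) -> float:
        """Relative affinity c = K_R / K_T (derived, never stored)."""
        return self.K_R / self.K_T

    def relabeled(self) -> "MWCParameters":
        """The T<->R relabeled parameter set (1/L, K_T, K_R).

        Defines the identical saturation function: which conformation is
        called tense is a convention, so (L, K_R, K_T) and (1/L, K_T, K_R)
        are the same physical model.
        """
        if self.L == 0:
            raise ValueError("cannot relabel L=0 (pure R state has no T twin)")
        return MWCParameters(1.0 / self.L, self.K_T, self.K_R, self.n_sites)

    @classmethod
    def from_c(cls, L: float, c: float, K_T: float, n_sites: int = 4) -> "MWCParameters":
        """Build from (L, c, K_T) with K_R = c * K_T."""
        return cls(L=L, K_R=c * K_T, K_T=K_T, n_sites=n_sites)


@dataclass(frozen=True)
class HillParameters:
    """Macroscopic descriptors of a saturation curve: p50 and n_H."""

    K_half: float
    n_H: float
    n_sites: int = 4

    def __post_init__(self) -> None:
        if not self.K_half > 0:
            raise ValueError(f"K_half must be > 0, got {self.K_half}")
        if not 0 < self.n_H <= self.n_sites:
            raise ValueError(
                f"n_H must lie in (0, {self.n_sites}], got {self.n_H}"
            )


@dataclass(frozen=True)
class EffectorBinding:
    """Non-exclusive binding of an allosteric effector to both states.

    ``K_IT < K_IR`` means the effector binds the T state more tightly and
    therefore acts as an inhibitor: L_app increases with concentration.
    """

    L_base: float
    K_IT: float
    K_IR: float
    n_sites: int = 4

    def __post_init__(self) -> None:
        if not self.L_base >= 0:
            raise ValueError(f"L_base must be >= 0, got {self.L_base}")
        if not (self.K_IT > 0 and self.K_IR > 0):
            raise ValueError("effector dissociation constants must be > 0")
        if self.n_sites < 1:
            raise ValueError("n_sites must be a positive integer")


@dataclass(frozen=True)
class SaturationCurve:
    """(pressure, fractional saturation) observations with metadata.

    Pressures are in mmHg and strictly increasing; saturations are
    fractions in [0, 1].  Curves intended for fitting need >= 4 points.
    """

    pressures: tuple
    saturations: tuple
    label: str = ""
    effector_id: Optional[str] = None
    effector_conc: Optional[float] = None

    def __init__(
        self,
        pressures: Sequence[float],
        saturations: Sequence[float],
        label: str = "",
        effector_id: Optional[str] = None,
        effector_conc: Optional[float] = None,
    ) -> None:
        p = tuple(float(x) for x in pressures)
        y = tuple(float(x) for x in saturations)
        if len(p) != len(y):
            raise ValueError(
                f"pressures ({len(p)}) and saturations ({len(y)}) differ in length"
            )
        if any(x <= 0 for x in p):
            raise ValueError("pressures must be > 0 mmHg")
        if any(b <= a for a, b in zip(p, p[1:])):
            raise ValueError("pressures must be strictly increasing")
        if any(not 0.0 <= v <= 1.0 for v in y):
            raise ValueError("saturations must be fractions in [0, 1]")
        object.__setattr__(self, "pressures", p)
        object.__setattr__(self, "saturations", y)
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "effector_id", effector_id)
        object.__setattr__(self, "effector_conc", effector_conc)

    def __len__(self) -> int:
        return len(self.pressures)

    @property
    def pressure_array(self) -> np.ndarray:
        return np.asarray(self.pressures, dtype=float)

    @property
    def saturation_array(self) -> np.ndarray:
        return np.asarray(self.saturations, dtype=float)


@dataclass(frozen=True)
class HalfSaturationPoint:
    """Concentration at Ybar = 0.5, dimensional and K_R-scaled."""

    S_half: float
    alpha_half: float


# --------------------------------------------------------------------------
# saturation functions
# --------------------------------------------------------------------------

def _state_ratio(alpha, L: float, c: float, n: int):
    """q = L ((1+c*alpha)/(1+alpha))^n, computed in log space.

    q is the T-state weight relative to the R-state weight in the binding
    polynomial; factoring it out keeps the evaluation stable for huge L.
    """
    alpha = np.asarray(alpha, dtype=float)
    if L == 0.0:
        return np.zeros_like(alpha)
    return np.exp(math.log(L) + n * (np.log1p(c * alpha) - np.log1p(alpha)))


def mwc_fractional_saturation_scaled(alpha, L: float, c: float, n_sites: int = 4):
    """Fractional saturation of the MWC tetramer at scaled concentration alpha.

    Equals the dimensional form with K_R = 1, K_T = 1/c.  Invariant under
    the relabeling (L, c, alpha) -> (1/L, 1/c, c*alpha).
    """
    alpha_arr = np.asarray(alpha, dtype=float)
    if np.any(alpha_arr < 0):
        raise ValueError("scaled concentration alpha must be >= 0")
    if not c > 0:
        raise ValueError(f"c must be > 0, got {c}")
    if not L >= 0:
        raise ValueError(f"L must be >= 0, got {L}")
    f_R = alpha_arr / (1.0 + alpha_arr)
    f_T = (c * alpha_arr) / (1.0 + c * alpha_arr)
    q = _state_ratio(alpha_arr, L, c, n_sites)
    # weighted mean of the pure-state hyperbolas; branch on which state
    # dominates so neither 1+q nor 1+1/q overflows
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        y_r = (f_R + q * f_T) / (1.0 + q)
        inv_q = np.where(q > 0.0, 1.0 / q, np.inf)
        y_t = (f_R * inv_q + f_T) / (inv_q + 1.0)
    y = np.where(q > 1.0, y_t, y_r)
    y = np.where(np.isinf(q), f_T, y)
    if np.ndim(alpha) == 0:
        return float(y)
    return y


def mwc_fractional_saturation(S, params: MWCParameters):
    """Fractional saturation Ybar at ligand pressure S (mmHg)."""
    S_arr = np.asarray(S, dtype=float)
    if np.any(S_arr < 0):
        raise ValueError("ligand concentration S must be >= 0")
    return mwc_fractional_saturation_scaled(
        S_arr / params.K_R, params.L, params.c, params.n_sites
    )


def hill_fractional_saturation(S, hp: HillParameters):
    """Hill (all-or-none) saturation: S^nH / (S^nH + K_half^nH).

    Evaluated as a logistic in log concentration for stability at large
    Hill exponents and extreme concentrations.
    """
    S_arr = np.asarray(S, dtype=float)
    if np.any(S_arr < 0):
        raise ValueError("ligand concentration S must be >= 0")
    with np.errstate(divide="ignore", over="ignore"):
        logit = hp.n_H * (np.log(S_arr) - math.log(hp.K_half))
        y = np.where(np.isneginf(logit), 0.0, 1.0 / (1.0 + np.exp(-logit)))
    if np.isscalar(S) or np.ndim(S) == 0:
        return float(y)
    return y


# --------------------------------------------------------------------------
# half-saturation point
# --------------------------------------------------------------------------

def _half_saturation_alpha(L: float, c: float) -> float:
    """Root of (1+a)^3 (a-1) + L (1+ca)^3 (ca-1) = 0 on the alpha scale.

    The Ybar = 1/2 condition rearranged; the root is unique and bracketed
    by the pure-state half-saturation points alpha = 1 (R) and alpha = 1/c
    (T).
    """
    if L == 0.0 or c == 1.0:
        return 1.0

    def g(a: float) -> float:
        return (1.0 + a) ** 3 * (a - 1.0) + L * (1.0 + c * a) ** 3 * (c * a - 1.0)

    lo, hi = (1.0, 1.0 / c) if c < 1.0 else (1.0 / c, 1.0)
    if g(lo) == 0.0:
        return lo
    if g(hi) == 0.0:
        return hi
    root = brentq(g, lo, hi, xtol=1e-300, rtol=4.0 * np.finfo(float).eps)
    # one Newton polish against the scaled saturation itself
    eps = root * 1e-7
    y0 = mwc_fractional_saturation_scaled(root, L, c)
    dy = (
        mwc_fractional_saturation_scaled(root + eps, L, c)
        - mwc_fractional_saturation_scaled(root - eps, L, c)
    ) / (2.0 * eps)
    if dy > 0:
        root -= (y0 - 0.5) / dy
    return float(root)


def half_saturation_concentration(params: MWCParameters) -> HalfSaturationPoint:
    """Ligand concentration [S]_0.5 at which Ybar = 1/2.

    Bracketed between min(K_R, K_T) and max(K_R, K_T); relative accuracy
    better than 1e-10.
    """
    if math.isinf(params.L):
        raise ValueError("L must be finite to locate the half-saturation point")
    alpha_half = _half_saturation_alpha(params.L, params.c)
    return HalfSaturationPoint(S_half=alpha_half * params.K_R, alpha_half=alpha_half)


# --------------------------------------------------------------------------
# effector scaling
# --------------------------------------------------------------------------

def apparent_allosteric_constant(eb: EffectorBinding, I) -> float:
    """L_app = L ((1 + I/K_IT)/(1 + I/K_IR))^n for inhibitor concentration I."""
    I_arr = np.asarray(I, dtype=float)
    if np.any(I_arr < 0):
        raise ValueError("effector concentration must be >= 0")
    ratio = (1.0 + I_arr / eb.K_IT) / (1.0 + I_arr / eb.K_IR)
    out = eb.L_base * ratio ** eb.n_sites
    if np.isscalar(I) or np.ndim(I) == 0:
        return float(out)
    return out


# --------------------------------------------------------------------------
# local Hill slope
# --------------------------------------------------------------------------

def _hill_slope_scaled(alpha: float, L: float, c: float) -> float:
    """Local Hill slope at scaled concentration alpha (tetramer).

    Analytic derivative of the MWC saturation quotient, with every term
    pre-divided by the R-state binding polynomial (1+alpha)^4 so that
    magnitudes stay bounded for L up to ~1e12.
    """
    if alpha <= 0:
        raise ValueError("hill slope is defined for alpha > 0")
    f_R = alpha / (1.0 + alpha)
    f_T = (c * alpha) / (1.0 + c * alpha)
    t = (1.0 + c * alpha) / (1.0 + alpha)
    q = float(_state_ratio(alpha, L, c, 4))  # L t^4
    q3 = q / t                               # L t^3
    # scaled binding polynomial pieces (all divided by powers of 1+alpha)
    n_tilde = f_R + q * f_T                      # N / (1+a)^4
    d_tilde = 1.0 + q                            # D / (1+a)^4
    m_tilde = 1.0 + q3                           # (D - N) / (1+a)^3
    np_tilde = (1.0 + 4.0 * alpha) / (1.0 + alpha) + q3 * c * (
        1.0 + 4.0 * c * alpha
    ) / (1.0 + c * alpha)                        # dN/da / (1+a)^3
    dp_tilde = 4.0 + 4.0 * c * q3                # dD/da / (1+a)^3
    ybar = n_tilde / d_tilde
    if not 0.0 < ybar < 1.0:
        raise ValueError(
            f"saturation is numerically {ybar} at alpha={alpha}; Hill slope undefined"
        )
    num = alpha * (np_tilde * d_tilde - n_tilde * dp_tilde)
    den = n_tilde * m_tilde
    return float(num / den)


def hill_slope_at(S: float, params: MWCParameters) -> float:
    """Local Hill slope n_H(S) = S (dYbar/dS) / (Ybar (1-Ybar)).

    Reduces to 1 for a hyperbola (L = 0 or c = 1) and is bounded by the
    number of sites.  At S = [S]_0.5 this is the Hill coefficient at
    half-saturation reported by routine Hill fits.
    """
    if not S > 0:
        raise ValueError("S must be > 0")
    if params.L == 0.0 or params.c == 1.0:
        return 1.0
    return _hill_slope_scaled(S / params.K_R, params.L, params.c)
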