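"""The biophysical Hill landscape of a tetrameric MWC protein.

The Hill coefficient at half-saturation, n_H(L, c), evaluated over a grid of
log10(c) and log10(L) forms a surface ("Hill landscape") whose topology
summarizes the cooperativity behaviour of the two-state concerted model:

* every value lies between 1 (hyperbola) and the number of sites;
* at fixed c < 1 the profile over log L is bell-shaped (unimodal), so each
  c has a unique allosteric constant L* maximizing cooperativity;
* the maxima trace a ridge satisfying L = c^(-n/2) (Lc^2 = 1 for the
  tetramer), obtained by setting the derivative of n_H with respect to
  log L to zero.

Around each ridge point the bell is flat enough that L can move over a wide
range — the "buffering of cooperativity" range — with almost no change in
n_H.  Functions here locate the ridge, sample cross-sections, and measure
those buffering ranges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .core import MWCParameters, half_saturation_concentration, hill_slope_at

__all__ = [
    "CooperativityLandscape",
    "MaxCooperativityPoint",
    "BufferingRange",
    "hill_coefficient_at_half_saturation",
    "landscape_grid",
    "maximum_cooperativity_point",
    "bell_cross_section",
    "buffering_range",
]

# reference T-state dissociation constant (mmHg): the evolutionary-dataset
# average for mammalian hemoglobin, used as the dimensional convention for
# landscape evaluation.  n_H depends on (L, c) only, so this choice does not
# affect any landscape value.
K_T_REFERENCE = 143.0


@dataclass(frozen=True)
class MaxCooperativityPoint:
    """Argmax of n_H over L at fixed c, with the scaled affinity there."""

    c: float
    L_star: float
    n_H_max: float
    log_alpha_half: float
    degenerate: bool = False


@dataclass(frozen=True)
class BufferingRange:
    """Contiguous L interval around L* where n_H stays within rel_tol of max."""

    c: float
    L_low: float
    L_star: float
    L_high: float
    rel_tol: float

    @property
    def delta_logL(self) -> float:
        return float(np.log10(self.L_high) - np.log10(self.L_low))


@dataclass(frozen=True)
class CooperativityLandscape:
    """n_H at half-saturation on a (log10 c, log10 L) grid plus its ridge."""

    log_c_grid: np.ndarray
    log_L_grid: np.ndarray
    n_H_surface: np.ndarray  # shape (len(log_L_grid), len(log_c_grid))
    ridge: Tuple[MaxCooperativityPoint, ...]

    def to_long_table(self):
        """Long-format (log10_c, log10_L, n_H) rows as a pandas DataFrame."""
        import pandas as pd

        cc, ll = np.meshgrid(self.log_c_grid, self.log_L_grid)
        return pd.DataFrame(
            {
                "log10_c": cc.ravel(),
                "log10_L": ll.ravel(),
                "n_H": self.n_H_surface.ravel(),
            }
        )

    def ridge_table(self):
        """Ridge trajectory as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "log10_c": [np.log10(p.c) for p in self.ridge],
                "log10_L_star": [np.log10(p.L_star) for p in self.ridge],
                "n_H_max": [p.n_H_max for p in self.ridge],
                "log10_alpha_half": [p.log_alpha_half for p in self.ridge],
            }
        )


def hill_coefficient_at_half_saturation(params: MWCParameters) -> float:
    """n_H^MWC: the local Hill slope evaluated at the half-saturation point.

    This is the quantity a routine Hill fit of saturation data reports, and
    the height of the Hill landscape at (log c, log L).
    """
    if params.L == 0.0 or params.c == 1.0:
        return 1.0
    hs = half_saturation_concentration(params)
    return hill_slope_at(hs.S_half, params)


def _nh_of_logL(logL: float, c: float) -> float:
    params = MWCParameters.from_c(10.0 ** logL, c, K_T_REFERENCE)
    return hill_coefficient_at_half_saturation(params)


def _canonical_c(c: float) -> float:
    """Map c >= 1 through the T/R relabeling symmetry onto (0, 1)."""
    if not c > 0:
        raise ValueError(f"c must be > 0, got {c}")
    return 1.0 / c if c > 1.0 else c


def maximum_cooperativity_point(c: float, xatol: float = 1e-8) -> MaxCooperativityPoint:
    """Locate L* maximizing n_H at fixed c by bounded 1-D maximization.

    The bell-shaped profile is unimodal, so golden-section/Brent search on
    log10 L over a bracket centred on the analytic criterion L = c^(-2) is
    robust.  c >= 1 is handled through the relabeling symmetry; c = 1 is the
    degenerate flat profile (n_H identically 1).
    """
    c = _canonical_c(c)
    if c == 1.0:
        return MaxCooperativityPoint(
            c=1.0, L_star=1.0, n_H_max=1.0, log_alpha_half=0.0, degenerate=True
        )
    center = -2.0 * np.log10(c)
    res = minimize_scalar(
        lambda x: -_nh_of_logL(x, c),
        bounds=(center - 4.0, center + 4.0),
        method="bounded",
        options={"xatol": xatol},
    )
    L_star = 10.0 ** float(res.x)
    params = MWCParameters.from_c(L_star, c, K_T_REFERENCE)
    alpha_half = half_saturation_concentration(params).alpha_half
    return MaxCooperativityPoint(
        c=c,
        L_star=L_star,
        n_H_max=float(-res.fun),
        log_alpha_half=float(np.log10(alpha_half)),
    )


def bell_cross_section(
    c: float, log_L_values: Sequence[float]
) -> List[Tuple[float, float]]:
    """Sample the n_H(log L) profile at fixed c (a landscape cross-section)."""
    c = _canonical_c(c)
    return [(float(x), _nh_of_logL(float(x), c)) for x in log_L_values]


def buffering_range(
    c: float, rel_tol: float = 0.01, logL_xtol: float = 1e-8
) -> BufferingRange:
    """L interval around L* over which n_H changes by less than rel_tol.

    Bisects on each side of the maximum for the L where
    n_H = (1 - rel_tol) * n_H_max; strict unimodality makes each side's root
    unique.  rel_tol = 0 returns the degenerate zero-width range.
    """
    if not 0.0 <= rel_tol < 1.0:
        raise ValueError(f"rel_tol must lie in [0, 1), got {rel_tol}")
    c = _canonical_c(c)
    peak = maximum_cooperativity_point(c)
    logL_star = np.log10(peak.L_star)
    if rel_tol == 0.0 or peak.degenerate:
        return BufferingRange(
            c=c, L_low=peak.L_star, L_star=peak.L_star, L_high=peak.L_star,
            rel_tol=rel_tol,
        )
    target = (1.0 - rel_tol) * peak.n_H_max
    if target <= 1.0:
        raise ValueError(
            "buffering range is unbounded: (1 - rel_tol) * n_H_max does not "
            "exceed the hyperbolic limit n_H = 1"
        )

    def f(logL: float) -> float:
        return _nh_of_logL(logL, c) - target

    # expand outward until the target level is bracketed on each side
    def side_root(direction: float) -> float:
        step = 0.5
        lo = logL_star
        hi = logL_star + direction * step
        while f(hi) > 0.0:
            lo = hi
            step *= 2.0
            hi = logL_star + direction * step
            if step > 64.0:  # pragma: no cover - n_H -> 1 long before this
                raise RuntimeError("failed to bracket buffering-range edge")
        a, b = (hi, lo) if direction < 0 else (lo, hi)
        return brentq(f, a, b, xtol=logL_xtol)

    logL_low = side_root(-1.0)
    logL_high = side_root(+1.0)
    return BufferingRange(
        c=c,
        L_low=10.0 ** logL_low,
        L_star=peak.L_star,
        L_high=10.0 ** logL_high,
        rel_tol=rel_tol,
    )


def landscape_grid(
    log_c_range: Tuple[float, float] = (-4.0, 0.0),
    log_L_range: Tuple[float, float] = (-2.0, 9.0),
    resolution: int = 200,
    ridge_points: int = 50,
) -> CooperativityLandscape:
    """Evaluate the Hill landscape on a regular (log10 c, log10 L) grid.

    Returns the n_H surface (rows indexed by log L, columns by log c) and
    the ridge trajectory over the c range.  Deterministic.
    """
    if resolution < 2 or ridge_points < 2:
        raise ValueError("resolution and ridge_points must be >= 2")
    c_lo, c_hi = log_c_range
    L_lo, L_hi = log_L_range
    if not (c_lo < c_hi and L_lo < L_hi):
        raise ValueError("grid ranges must be non-degenerate (lo < hi)")
    log_c_grid = np.linspace(c_lo, c_hi, resolution)
    log_L_grid = np.linspace(L_lo, L_hi, resolution)
    surface = np.empty((resolution, resolution))
    for j, lc in enumerate(log_c_grid):
        c = _canonical_c(10.0 ** lc)
        for i, ll in enumerate(log_L_grid):
            surface[i, j] = _nh_of_logL(ll, c)
    # the ridge exists only for c strictly below 1
    ridge_c = np.linspace(c_lo, min(c_hi, -1e-9), ridge_points)
    ridge = tuple(maximum_cooperativity_point(10.0 ** lc) for lc in ridge_c)
    return CooperativityLandscape(
        log_c_grid=log_c_grid,
        log_L_grid=log_L_grid,
        n_H_surface=surface,
        ridge=ridge,
    )
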