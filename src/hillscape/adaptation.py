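"""Downstream adaptation analyses built on the Hill landscape.

Given ridge-located (maximum-cooperativity) parameter sets, these routines
quantify what the position on the ridge buys an oxygen carrier:

* unloading sensitivity — the saturation drop per decade of scaled
  concentration across a physiological loading→unloading window (lungs at
  ~100 mmHg to tissue at ~40 mmHg corresponds to a nominal fall from full
  to 40% saturation);
* how little that sensitivity varies while the allosteric constant roams
  the buffering-of-cooperativity range (effectors retune p50, not n_H);
* the breadth ΔlogL of that range (the dynamic range available to
  physiological regulation) as a function of the attainable n_H maximum;
* ridge mapping of measured (L, c) panels: per-species n_H, the log-log
  regression whose slope is −2 for a panel sitting exactly on the ridge,
  and offsets from the ridge;
* correlations of Hill descriptors with whole-animal metabolic rate.

Everything here is deterministic given its inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import MWCParameters, half_saturation_concentration
from .fitting import LinearRegressionResult, linear_regression
from .landscape import (
    buffering_range,
    hill_coefficient_at_half_saturation,
    maximum_cooperativity_point,
    K_T_REFERENCE,
)

__all__ = [
    "RIDGE_POINTS",
    "UnloadingSensitivity",
    "MetabolicRecord",
    "max_cooperativity_table",
    "unloading_sensitivity",
    "sensitivity_variation_over_buffering_range",
    "ridge_offset",
    "evolutionary_ridge_analysis",
    "physiological_buffering_analysis",
    "metabolic_rate_correlations",
    "dynamic_range_profile",
]

# Literature maximum-cooperativity (c, L) pairs for a tetramer with
# K_T = 143 mmHg, spanning the mammalian hemoglobin range; each pair obeys
# L*c^2 = 1 up to the ~0.5% rounding of the printed L values.  The bold
# human point is (0.01741, 3300).
RIDGE_POINTS: Tuple[Tuple[float, float], ...] = (
    (0.07071, 200.0),
    (0.04472, 500.0),
    (0.02582, 1500.0),
    (0.01741, 3300.0),
    (0.01222, 6700.0),
    (0.00524, 36400.0),
    (0.0035, 81800.0),
    (0.00262, 145400.0),
    (0.00175, 327200.0),
)


@dataclass(frozen=True)
class UnloadingSensitivity:
    """Saturation drop per decade of scaled concentration over a window.

    ``sensitivity`` = nominal_drop / delta_log_alpha where delta_log_alpha
    is the log10 width of the scaled-concentration interval between the
    window's upper and lower saturation edges.  For the pure hyperbola with
    window 0.9 -> 0.5 and nominal drop 0.4 this is 0.4/log10(9) exactly.
    """

    Y_high: float
    Y_low: float
    nominal_drop: float
    alpha_high: float
    alpha_low: float

    @property
    def delta_log_alpha(self) -> float:
        return float(np.log10(self.alpha_high / self.alpha_low))

    @property
    def sensitivity(self) -> float:
        return self.nominal_drop / self.delta_log_alpha


@dataclass(frozen=True)
class MetabolicRecord:
    """Per-species Hill descriptors plus weight-normalized metabolic rate."""

    species: str
    metabolic_rate: float
    p50: float
    n_H: float

    def __post_init__(self) -> None:
        if not self.metabolic_rate > 0:
            raise ValueError("metabolic_rate must be > 0")
        if not self.p50 > 0:
            raise ValueError("p50 must be > 0")


# --------------------------------------------------------------------------
# ridge table
# --------------------------------------------------------------------------

def max_cooperativity_table(
    c_values: Sequence[float],
    K_T: float = K_T_REFERENCE,
    L_values: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Rows (c, L, n_H_max, K_R) of maximum-cooperativity parameter sets.

    By default L = c^(-2) (the ridge criterion) and K_R = c*K_T; printed
    literature L values may be supplied instead via ``L_values`` to honor
    their rounding.  n_H is the Hill coefficient at half-saturation
    evaluated at the (c, L) pair.
    """
    c_arr = [float(c) for c in c_values]
    if any(not 0.0 < c < 1.0 for c in c_arr):
        raise ValueError("all c values must lie in (0, 1)")
    if L_values is None:
        L_arr = [c ** -2.0 for c in c_arr]
    else:
        L_arr = [float(L) for L in L_values]
        if len(L_arr) != len(c_arr):
            raise ValueError("L_values must match c_values in length")
    rows = []
    for c, L in zip(c_arr, L_arr):
        params = MWCParameters.from_c(L, c, K_T)
        rows.append(
            {
                "c": c,
                "L": L,
                "n_H_max": hill_coefficient_at_half_saturation(params),
                "K_R": c * K_T,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# unloading sensitivity
# --------------------------------------------------------------------------

def _invert_saturation_alpha(params: MWCParameters, y_target: float) -> float:
    """alpha at which Ybar(alpha) = y_target, by bisection on log alpha."""
    from .core import mwc_fractional_saturation_scaled

    if not 0.0 < y_target < 1.0:
        raise ValueError("saturation target must lie strictly inside (0, 1)")
    L, c = params.L, params.c

    def f(log_alpha: float) -> float:
        return mwc_fractional_saturation_scaled(10.0 ** log_alpha, L, c) - y_target

    lo, hi = -6.0, 6.0 + math.log10(max(1.0, 1.0 / c))
    while f(lo) > 0.0:
        lo -= 6.0
    while f(hi) < 0.0:
        hi += 6.0
    return 10.0 ** brentq(f, lo, hi, xtol=1e-13)


def unloading_sensitivity(
    params: MWCParameters,
    Y_high: float = 0.999,
    Y_low: float = 0.40,
    nominal_drop: float = 0.60,
) -> UnloadingSensitivity:
    """Sensitivity of the carrier to substrate unloading over a Y window.

    The physiological construction is a drop from the loaded edge
    (operationalized as the cap Ybar = 0.999, since full saturation is
    unattainable at finite pressure) to 40% saturation — nominally a 60%
    fall; the sensitivity is that nominal drop divided by the log10 width
    of the scaled-concentration interval traversed.  The result depends on
    (L, c) and the window only, not on the K_R scale.
    """
    if not (0.0 < Y_low < Y_high < 1.0):
        raise ValueError("need 0 < Y_low < Y_high < 1")
    if not nominal_drop > 0:
        raise ValueError("nominal_drop must be > 0")
    alpha_high = _invert_saturation_alpha(params, Y_high)
    alpha_low = _invert_saturation_alpha(params, Y_low)
    return UnloadingSensitivity(
        Y_high=Y_high,
        Y_low=Y_low,
        nominal_drop=nominal_drop,
        alpha_high=alpha_high,
        alpha_low=alpha_low,
    )


def sensitivity_variation_over_buffering_range(
    c: float,
    rel_tol: float = 0.01,
    Y_high: float = 0.999,
    Y_low: float = 0.40,
    nominal_drop: float = 0.60,
    K_T: float = K_T_REFERENCE,
) -> float:
    """Max percent deviation of unloading sensitivity across a buffering range.

    Computes the sensitivity at L_low, L_star and L_high of the rel_tol
    buffering range at fixed c and returns the largest absolute percent
    deviation of the endpoint values from the ridge-point value.
    """
    br = buffering_range(c, rel_tol=rel_tol)
    if br.L_low == br.L_high:
        return 0.0

    def sens(L: float) -> float:
        p = MWCParameters.from_c(L, br.c, K_T)
        return unloading_sensitivity(p, Y_high, Y_low, nominal_drop).sensitivity

    s_star = sens(br.L_star)
    devs = [abs(sens(L) - s_star) / s_star * 100.0 for L in (br.L_low, br.L_high)]
    return max(devs)


# --------------------------------------------------------------------------
# ridge mapping
# --------------------------------------------------------------------------

def ridge_offset(L: float, c: float) -> float:
    """log10(L) + 2 log10(c): zero exactly on the maximum-cooperativity ridge."""
    if not L > 0:
        raise ValueError("L must be > 0")
    if not 0.0 < c < 1.0:
        raise ValueError("c must lie in (0, 1)")
    return float(np.log10(L) + 2.0 * np.log10(c))


def evolutionary_ridge_analysis(
    param_table: pd.DataFrame,
) -> Dict[str, object]:
    """Map a per-species (L, c) panel onto the landscape and its ridge.

    ``param_table`` needs columns species, L, c (K_T optional; defaults to
    the reference convention).  Returns per-species n_H, the OLS regression
    of log10 L on log10 c, and ridge-offset statistics.  With fewer than
    three species the regression is impossible and reported as None while
    per-species n_H values are still returned.
    """
    required = {"species", "L", "c"}
    missing = required - set(param_table.columns)
    if missing:
        raise ValueError(f"parameter table lacks columns: {sorted(missing)}")
    if len(param_table) < 1:
        raise ValueError("parameter table is empty")
    K_T = (
        param_table["K_T"].astype(float)
        if "K_T" in param_table.columns
        else pd.Series(K_T_REFERENCE, index=param_table.index)
    )
    table = param_table.copy()
    table["n_H"] = [
        hill_coefficient_at_half_saturation(
            MWCParameters.from_c(float(L), float(c), float(kt))
        )
        for L, c, kt in zip(table["L"], table["c"], K_T)
    ]
    table["log10_L"] = np.log10(table["L"].astype(float))
    table["log10_c"] = np.log10(table["c"].astype(float))
    table["ridge_offset"] = table["log10_L"] + 2.0 * table["log10_c"]
    regression: Optional[LinearRegressionResult]
    if len(table) >= 3:
        regression = linear_regression(table["log10_c"], table["log10_L"])
    else:
        regression = None
    return {
        "table": table,
        "regression": regression,
        "mean_abs_ridge_offset": float(table["ridge_offset"].abs().mean()),
    }


def physiological_buffering_analysis(
    L_app_values: Sequence[float],
    c: float,
    K_T: float = K_T_REFERENCE,
) -> Dict[str, object]:
    """n_H of each condition on the fixed-c cross-section, and its spread.

    Emulates mapping effector-condition curves (which share c and differ in
    L_app) onto the bell-shaped n_H(log L) profile: per-condition n_H, the
    maximal fractional spread of n_H, and each point's log10 offset from
    the cross-section's maximum-cooperativity L*.
    """
    L_app = [float(L) for L in L_app_values]
    if len(L_app) < 2:
        raise ValueError("need >= 2 effector conditions")
    if any(L <= 0 for L in L_app):
        raise ValueError("all L_app values must be > 0")
    peak = maximum_cooperativity_point(c)
    n_H = [
        hill_coefficient_at_half_saturation(MWCParameters.from_c(L, peak.c, K_T))
        for L in L_app
    ]
    spread = (max(n_H) - min(n_H)) / max(n_H)
    table = pd.DataFrame(
        {
            "L_app": L_app,
            "log10_L_app": np.log10(L_app),
            "n_H": n_H,
            "offset_from_L_star": np.log10(L_app) - math.log10(peak.L_star),
        }
    )
    return {
        "table": table,
        "n_H_spread": float(spread),
        "L_star": peak.L_star,
        "n_H_max": peak.n_H_max,
    }


# --------------------------------------------------------------------------
# metabolic-rate correlations
# --------------------------------------------------------------------------

def metabolic_rate_correlations(
    records: Sequence[MetabolicRecord],
) -> Dict[str, LinearRegressionResult]:
    """The organismal-level regressions linking Hill descriptors to metabolism.

    Returns cooperativity vs log metabolic rate, affinity (log10(1/p50))
    vs log metabolic rate, and cooperativity vs log p50.
    """
    if len(records) < 3:
        raise ValueError(f"need >= 3 records, got {len(records)}")
    log_mr = [math.log10(r.metabolic_rate) for r in records]
    n_H = [r.n_H for r in records]
    log_p50 = [math.log10(r.p50) for r in records]
    affinity = [-x for x in log_p50]
    return {
        "n_H_vs_log_metabolic_rate": linear_regression(log_mr, n_H),
        "affinity_vs_log_metabolic_rate": linear_regression(log_mr, affinity),
        "n_H_vs_log_p50": linear_regression(log_p50, n_H),
    }


# --------------------------------------------------------------------------
# dynamic range of buffering
# --------------------------------------------------------------------------

def dynamic_range_profile(
    c_values: Sequence[float], rel_tol: float = 0.01
) -> pd.DataFrame:
    """Breadth ΔlogL of the buffering range per ridge point.

    One row (c, n_H_max, delta_logL) per c value; along the ridge the
    breadth grows with the attainable cooperativity maximum.
    """
    rows = []
    for c in c_values:
        if rel_tol == 0.0:
            peak = maximum_cooperativity_point(c)
            rows.append(
                {"c": peak.c, "n_H_max": peak.n_H_max, "delta_logL": 0.0}
            )
            continue
        br = buffering_range(c, rel_tol=rel_tol)
        peak_nh = hill_coefficient_at_half_saturation(
            MWCParameters.from_c(br.L_star, br.c, K_T_REFERENCE)
        )
        rows.append(
            {"c": br.c, "n_H_max": peak_nh, "delta_logL": br.delta_logL}
        )
    return pd.DataFrame(rows)
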