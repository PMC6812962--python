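"""Synthetic saturation panels with the statistical structure the analyses assume.

Two kinds of panel are generated:

* an "evolutionary" panel — one species per curve, with (L, c) pairs drawn
  on or near the maximum-cooperativity ridge log10 L = -2 log10 c at a
  shared K_T of 143 mmHg, emulating a mammalian hemoglobin panel;
* a "physiological" panel — one carrier (fixed c, shared K_R/K_T) measured
  at several inhibitor concentrations, with each curve's apparent L given
  by the non-exclusive effector-binding model.

Observation noise is additive Gaussian on the saturation fraction (default
sd 0.01, typical of digitization-scale scatter), clipped to [0, 1].  All
randomness flows from one master seed; every curve gets an independent
stream keyed by (master seed, curve index) so changing the panel size never
reshuffles earlier curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    EffectorBinding,
    MWCParameters,
    SaturationCurve,
    apparent_allosteric_constant,
    mwc_fractional_saturation,
)
from .adaptation import MetabolicRecord
from .landscape import K_T_REFERENCE

__all__ = [
    "SyntheticPanel",
    "DEFAULT_PRESSURE_GRID",
    "sample_curve",
    "generate_evolutionary_panel",
    "generate_physiological_panel",
    "generate_metabolic_records",
]

# 30 log-spaced pressures, 1-300 mmHg: spans <1% to >99% saturation for
# human-like parameters (L=3300, c=0.01741, K_T=143)
DEFAULT_PRESSURE_GRID: Tuple[float, ...] = tuple(
    np.logspace(0.0, math.log10(300.0), 30)
)

# default log10 c range for evolutionary panels, spanning the literature
# ridge set (c from 0.00175 to 0.07071)
DEFAULT_LOG_C_RANGE: Tuple[float, float] = (-2.76, -1.15)


@dataclass(frozen=True)
class SyntheticPanel:
    """Curves plus the ground-truth parameters that generated them."""

    curves: Tuple[SaturationCurve, ...]
    truth: Tuple[MWCParameters, ...]
    seed: int
    noise_sd: float
    ridge_sd: float = 0.0
    effector: Optional[EffectorBinding] = None
    effector_concentrations: Tuple[float, ...] = ()

    @property
    def true_L_app(self) -> Tuple[float, ...]:
        return tuple(p.L for p in self.truth)

    def __len__(self) -> int:
        return len(self.curves)


def _curve_rng(seed: int, index: int) -> np.random.Generator:
    """Independent, stable stream for curve ``index`` under master ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def sample_curve(
    params: MWCParameters,
    pressure_grid: Sequence[float] = DEFAULT_PRESSURE_GRID,
    noise_sd: float = 0.01,
    seed: int = 0,
    label: str = "",
    effector_id: Optional[str] = None,
    effector_conc: Optional[float] = None,
    _index: int = 0,
) -> SaturationCurve:
    """One noisy saturation curve: Ybar(S_i) + eps_i, clipped to [0, 1].

    eps_i are i.i.d. Gaussian(0, noise_sd); noise_sd = 0 returns the exact
    model evaluation.  Deterministic per (seed, _index).
    """
    grid = np.asarray(pressure_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("pressure grid is empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("pressure grid must be strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    y = mwc_fractional_saturation(grid, params)
    if noise_sd > 0:
        rng = _curve_rng(seed, _index)
        y = np.clip(y + rng.normal(0.0, noise_sd, size=grid.size), 0.0, 1.0)
    return SaturationCurve(
        pressures=grid,
        saturations=y,
        label=label,
        effector_id=effector_id,
        effector_conc=effector_conc,
    )


def generate_evolutionary_panel(
    n_species: int = 14,
    log_c_range: Tuple[float, float] = DEFAULT_LOG_C_RANGE,
    ridge_sd: float = 0.0,
    noise_sd: float = 0.01,
    K_T: float = K_T_REFERENCE,
    seed: int = 0,
    pressure_grid: Sequence[float] = DEFAULT_PRESSURE_GRID,
) -> SyntheticPanel:
    """A cross-species panel with (L, c) on or near the cooperativity ridge.

    Per species: c is log-uniform over ``log_c_range``;
    log10 L = -2 log10 c + Gaussian(0, ridge_sd); K_R = c * K_T.  One curve
    per species on the shared pressure grid.  ridge_sd = 0 puts every truth
    pair exactly on the ridge.
    """
    if n_species < 2:
        raise ValueError("need n_species >= 2")
    lo, hi = log_c_range
    if not lo < hi < 0.0:
        raise ValueError("log_c_range must satisfy lo < hi < 0 (c in (0, 1))")
    if ridge_sd < 0:
        raise ValueError("ridge_sd must be >= 0")
    curves: List[SaturationCurve] = []
    truth: List[MWCParameters] = []
    for i in range(n_species):
        rng = _curve_rng(seed, i)
        log_c = rng.uniform(lo, hi)
        log_L = -2.0 * log_c + (rng.normal(0.0, ridge_sd) if ridge_sd > 0 else 0.0)
        params = MWCParameters.from_c(10.0 ** log_L, 10.0 ** log_c, K_T)
        truth.append(params)
        curves.append(
            sample_curve(
                params,
                pressure_grid,
                noise_sd,
                seed=seed,
                label=f"species_{i:02d}",
                _index=i,
            )
        )
    return SyntheticPanel(
        curves=tuple(curves),
        truth=tuple(truth),
        seed=seed,
        noise_sd=noise_sd,
        ridge_sd=ridge_sd,
    )


def generate_physiological_panel(
    c: float = 0.01741,
    L_base: float = 3300.0,
    effector: Optional[EffectorBinding] = None,
    I_values: Sequence[float] = (0.0, 0.5, 1.0, 2.0, 5.0, 10.0),
    noise_sd: float = 0.01,
    K_T: float = K_T_REFERENCE,
    seed: int = 0,
    pressure_grid: Sequence[float] = DEFAULT_PRESSURE_GRID,
    effector_id: str = "inhibitor",
) -> SyntheticPanel:
    """One carrier titrated with an inhibitory effector (fixed c, moving L).

    Each concentration I rescales the allosteric constant via the
    non-exclusive binding model; all curves share (K_R, K_T).  The default
    carrier is the human-like ridge point (c = 0.01741, L = 3300); the
    default effector (K_IT = 1, K_IR = 100 concentration units) stabilizes
    the T state, raising L_app with concentration.
    """
    I_arr = [float(I) for I in I_values]
    if len(I_arr) < 2:
        raise ValueError("need >= 2 effector concentrations")
    if any(I < 0 for I in I_arr):
        raise ValueError("effector concentrations must be >= 0")
    if effector is None:
        effector = EffectorBinding(L_base=L_base, K_IT=1.0, K_IR=100.0)
    elif effector.L_base != L_base:
        raise ValueError("effector.L_base must equal L_base")
    curves: List[SaturationCurve] = []
    truth: List[MWCParameters] = []
    for i, I in enumerate(I_arr):
        L_app = apparent_allosteric_constant(effector, I)
        params = MWCParameters.from_c(L_app, c, K_T)
        truth.append(params)
        curves.append(
            sample_curve(
                params,
                pressure_grid,
                noise_sd,
                seed=seed,
                label=f"I_{i:02d}",
                effector_id=effector_id,
                effector_conc=I,
                _index=i,
            )
        )
    return SyntheticPanel(
        curves=tuple(curves),
        truth=tuple(truth),
        seed=seed,
        noise_sd=noise_sd,
        effector=effector,
        effector_concentrations=tuple(I_arr),
    )


def generate_metabolic_records(
    n: int = 8,
    nH_vs_logMR_slope: float = 0.6,
    affinity_vs_logMR_slope: float = -0.28,
    noise_sd: float = 0.0,
    seed: int = 0,
    log_mr_range: Tuple[float, float] = (-0.5, 1.5),
    nH_intercept: float = 2.6,
    log_p50_intercept: float = 1.45,
) -> List[MetabolicRecord]:
    """Per-species records with linear n_H and log(1/p50) trends in log MR.

    log10 metabolic rate is uniform over ``log_mr_range``; n_H and
    log10(1/p50) are linear in it plus Gaussian(0, noise_sd).  The default
    slopes and intercepts put the records in the mammalian range (n_H
    between ~2.3 and ~3.5, p50 between ~20 and ~60 mmHg across a 100-fold
    span of weight-normalized metabolic rate).
    """
    if n < 3:
        raise ValueError("need n >= 3 records")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    records: List[MetabolicRecord] = []
    for i in range(n):
        rng = _curve_rng(seed, i)
        lo, hi = log_mr_range
        log_mr = float(rng.uniform(lo, hi))
        nh = nH_intercept + nH_vs_logMR_slope * log_mr
        log_affinity = -log_p50_intercept + affinity_vs_logMR_slope * log_mr
        if noise_sd > 0:
            nh += rng.normal(0.0, noise_sd)
            log_affinity += rng.normal(0.0, noise_sd)
        records.append(
            MetabolicRecord(
                species=f"species_{i:02d}",
                metabolic_rate=10.0 ** log_mr,
                p50=10.0 ** (-log_affinity),
                n_H=float(np.clip(nh, 1e-3, 4.0)),
            )
        )
    return records
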