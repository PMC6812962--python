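# hillscape

Cooperativity analysis for tetrameric two-state (MWC) oxygen carriers such
as hemoglobin, for structural biologists and molecular physiologists who
work with oxygen saturation curves and allosteric parameters.

Tissue oxygen delivery is controlled by two macroscopic descriptors of the
saturation curve: the half-saturation pressure `p50` and the Hill
coefficient `n_H`. Both are functions of the microscopic MWC parameters —
the allosteric constant `L = [T]/[R]` and the relative affinity
`c = K_R/K_T` of the relaxed and tense quaternary states. For a tetramer,

```
Ȳ(α) = [α(1+α)³ + Lcα(1+cα)³] / [(1+α)⁴ + L(1+cα)⁴],   α = [S]/K_R,

n_H = [S] (∂Ȳ/∂[S]) / (Ȳ(1−Ȳ))  evaluated at Ȳ = 1/2.
```

Plotted over `(log c, log L)`, `n_H` forms a landscape whose ridge of
maximum cooperativity obeys `L·c² = 1`. The package computes this landscape
exactly, locates the ridge and the "buffering of cooperativity" ranges
around it (where effectors shift `p50` without moving `n_H`), quantifies
oxygen-unloading sensitivity, fits Hill and MWC models to measured curves
(including global fits sharing `c` across effector conditions and the
non-exclusive effector-binding model `L_app = L((1+I/K_IT)/(1+I/K_IR))⁴`),
and generates the synthetic evolutionary and physiological panels the whole
pipeline is validated on. See `docs/methods.md` for the numerical details.

## Worked example

```python
from hillscape import (MWCParameters, half_saturation_concentration,
                       hill_coefficient_at_half_saturation,
                       maximum_cooperativity_point, buffering_range,
                       unloading_sensitivity)

p = MWCParameters.from_c(L=3300, c=0.01741, K_T=143.0)   # human-like carrier

hs = half_saturation_concentration(p)
print(hs.S_half, hs.alpha_half)       # 18.87 mmHg, 7.579
print(hill_coefficient_at_half_saturation(p))            # 2.764

peak = maximum_cooperativity_point(0.01741)
print(peak.L_star, peak.n_H_max)      # 3299.2, 2.764  (L* = c^-2: on the ridge)

br = buffering_range(0.01741, rel_tol=0.01)
print(br.L_low, br.L_high, br.delta_logL)   # 1402, 7766, 0.744

print(unloading_sensitivity(p).sensitivity)              # 0.274
```

Reading: this carrier half-saturates at 18.9 mmHg with a Hill coefficient
of 2.76, which is the maximum attainable at its `c` — it sits on the ridge.
Its allosteric constant can move across a 0.74-decade range (L from ~1400
to ~7800, e.g. under effector binding) while `n_H` changes by less than 1%,
and across the physiological loading→unloading window it delivers 0.274
units of saturation per decade of scaled oxygen pressure.

The same analyses are available from the shell:

```bash
hillscape --out-dir out ridge-table          # max-cooperativity table
hillscape --out-dir out --seed 7 simulate-evolutionary
hillscape --out-dir out fit-mwc out/evolutionary_curves.tsv
hillscape --out-dir out sensitivity          # per-ridge-point sensitivities
```

Every run writes tab-delimited tables, a JSON manifest of the effective
configuration, and a log. Exit codes: 0 success, 1 validation error, 2 fit
non-convergence (results still written, flagged).

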