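# Methods

## Model

The package treats a tetrameric two-state concerted (MWC) protein: all four
subunits switch together between a tense (T) and a relaxed (R) quaternary
conformation. Three microscopic parameters define the model:

* `L = [T]/[R]` — the allosteric constant, the conformational equilibrium in
  the absence of ligand (dimensionless, ≥ 0);
* `K_T`, `K_R` — ligand dissociation constants of the two states (mmHg);
* `c = K_R/K_T` — their ratio; `c < 1` means the R state binds more tightly.

With `α = [S]/K_R` the scaled ligand concentration, fractional saturation is

```
Ȳ(α) = [α(1+α)³ + Lcα(1+cα)³] / [(1+α)⁴ + L(1+cα)⁴].
```

Macroscopic descriptors are the half-saturation point `p50` (the `[S]` where
`Ȳ = 1/2`) and the Hill coefficient, the local slope of the logit:

```
n_H([S]) = [S] (∂Ȳ/∂[S]) / (Ȳ(1−Ȳ)),
```

evaluated at `p50` — the quantity an ordinary Hill fit of saturation data
reports. Heterotropic effectors act on `L` alone; a non-exclusively binding
inhibitor I with state affinities `K_IT < K_IR` rescales it to
`L_app = L((1+I/K_IT)/(1+I/K_IR))⁴`.

Evaluated over a `(log₁₀ c, log₁₀ L)` grid, `n_H` forms a surface (the Hill
landscape) with a single ridge: at fixed `c < 1` the profile over `log L` is
bell-shaped, and the maxima satisfy `L = c^(−n/2)` (`Lc² = 1` for the
tetramer). Around each ridge point `n_H` is locally flat — the "buffering of
cooperativity" range — so effectors move `p50` without moving `n_H`.

## Numerical choices

* **Saturation evaluation.** The quotient is computed from the pure-state
  hyperbolas `f_R = α/(1+α)`, `f_T = cα/(1+cα)` and the T/R weight ratio
  `q = L((1+cα)/(1+α))⁴` taken in log space, branching on which state
  dominates. This stays accurate for `L` up to ~10¹² where the raw binding
  polynomials would lose precision or overflow.
* **Half-saturation.** Root of `(1+α)³(α−1) + L(1+cα)³(cα−1) = 0`, bracketed
  by the pure-state half-saturation points `α = 1` and `α = 1/c`; Brent's
  method at machine tolerance plus one Newton polish. Relative accuracy is
  better than 1e−10 (verified against dense-grid bisection on the raw
  quotient).
* **Hill slope.** Analytic derivative of the quotient with every term
  pre-divided by `(1+α)⁴`, validated against a centered finite difference of
  the logit to ≤ 1e−6 relative over a 100-point `(log L, log c)` lattice.
* **Ridge location.** Bounded Brent maximization of `n_H` over `log₁₀ L` in
  a ±4-decade bracket centred on the analytic criterion `−2 log₁₀ c`;
  unimodality makes this robust. Tolerance 1e−8 on `log₁₀ L` by default.
  `c ≥ 1` inputs are mapped through the exact T/R relabeling symmetry
  `(L, K_R, K_T) ≡ (1/L, K_T, K_R)`; `c = 1` is the degenerate flat profile
  and is returned flagged with `n_H = 1`.
* **Buffering range.** Bisection on each side of the maximum for the `L`
  where `n_H = (1 − rel_tol)·n_H_max` (default `rel_tol = 0.01`, the "less
  than 1% change" convention), tolerance 1e−8 on `log₁₀ L`. `rel_tol = 0`
  yields the degenerate zero-width range. When `(1−rel_tol)·n_H_max ≤ 1`
  (c very close to 1) the range is unbounded and an error is raised.
* **Unloading sensitivity.** The loaded edge of the physiological window is
  operationalized as a cap `Ȳ = 0.999` (full saturation is unattainable at
  finite pressure); the unloaded edge is `Ȳ = 0.40`; the numerator is the
  nominal 0.60 drop. Sensitivity = 0.60 / Δlog₁₀α between the edges,
  computed by inverting the monotone saturation curve by bisection. The
  result depends only on `(L, c)` and the window, not on the `K_R` scale.
  **Caveat:** the percent variation of this sensitivity across a buffering
  range depends materially on the cap, not marginally: over the nine
  reference ridge sets the maximum variation is 12.0% at cap 0.99, 10.9% at
  0.999 (the default), 6.9% at 0.9999 and 4.9% at 0.99999. The cap is an
  exposed parameter (`Y_high`) so this dependence is directly reproducible.

## Fitting

All saturation-curve fits are unweighted nonlinear least squares on
fractions, with MWC-type parameters optimized as base-10 logarithms (bounds
`log₁₀ L ∈ [−3, 10]`, dissociation constants in `[10⁻³, 10⁴]` mmHg). The
L–K_R trade-off creates local minima, so MWC fits run from a deterministic
8-point log-spaced multistart lattice and keep the best solution. Standard
errors come from the pseudo-inverse of `JᵀJ` at the solution; directions the
data do not constrain surface as effectively infinite errors and the
parameter is flagged unidentifiable rather than silently reported. Fit
adequacy is flagged at `R² > 0.97` and reported, never used to drop data.
The global fitter stacks the residuals of several curves sharing one
`(K_R, K_T)` pair — hence one `c` — with an apparent `L` per curve, the
estimator implied by effectors acting on `L` alone; with a single curve it
is exactly the single-curve objective. The effector-binding fit works in
`log₁₀ L_app` space, where the model is closer to homoscedastic. Earlier
work derived per-curve parameters through a three-equation system; this
package uses direct and global NLS instead, a deliberate methodological
substitution. Linear regressions are ordinary least squares
(`scipy.stats.linregress`).

## Synthetic data

The generators define the study conditions the pipeline is validated under:

* **Evolutionary panel** (default 14 species): `c` log-uniform over
  `log₁₀ c ∈ [−2.76, −1.15]` (the span of the reference ridge table),
  `log₁₀ L = −2 log₁₀ c + N(0, ridge_sd)`, `K_R = c·K_T` with
  `K_T = 143` mmHg (the evolutionary-dataset average used as the
  dimensional convention throughout). One curve per species.
* **Physiological panel**: one carrier (default the human-like ridge point
  `c = 0.01741`, `L = 3300`) titrated with an inhibitor (default
  `K_IT = 1`, `K_IR = 100` concentration units) at six concentrations;
  `L_app` follows the non-exclusive binding model, `(K_R, K_T)` shared.
* **Metabolic records**: log₁₀ metabolic rate uniform over `[−0.5, 1.5]`;
  `n_H` and `log₁₀(1/p50)` linear in it (default slopes +0.6 and −0.28,
  intercepts 2.6 and −1.45) plus Gaussian noise. Defaults keep `n_H` in
  ~2.3–3.5 and `p50` in ~20–75 mmHg, the mammalian range.

Observation noise is additive Gaussian on the saturation fraction, default
sd 0.01 (digitization-scale scatter; the bias from clipping to [0, 1] is
negligible at that level). Pressure grids default to 30 log-spaced points,
1–300 mmHg, spanning <1% to >99% saturation for human-like parameters. One
master seed drives everything; each curve draws from an independent stream
keyed by (seed, curve index), so growing a panel never reshuffles earlier
curves and equal seeds reproduce byte-identical output.

What the generators deliberately do not emulate: technique-specific
measurement artifacts (tonometry vs thin-film methods), multiple hemoglobin
isoforms, pH/CO₂/organophosphate chemistry beyond their common action on
`L`, and real phylogenetic correlation between species. Passing recovery
tests therefore demonstrates correctness of the estimators under the stated
noise model, not robustness to those real-data complications.

## Problem sizes

The test suite and the acceptance script run the nine-point ridge analyses
in full; replicate simulation studies (noisy-fit identifiability, slope
scatter under ridge noise) use 12–100 replicates, enough to pin medians and
spread without long runtimes. Landscape grids in tests use 15–25 points per
axis; the library default is 200×200.

## Known limitations

* Only the tetramer (`n_sites = 4`) is within tested scope; the functions
  accept other site counts but no guarantees are made.
* `n_H` is evaluated at half-saturation, not as the maximum of the local
  slope over the whole curve; the two coincide exactly on the ridge (this
  is verified numerically, not assumed) and differ slightly off it.
* Uncertainty reporting is asymptotic (Jacobian-based); no bootstrap or
  Bayesian intervals.
* Kinetic (time-dependent) schemes, sequential (KNF) models, and
  exclusive-binding effector variants are out of scope.
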