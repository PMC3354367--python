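# Methods

## Model class

`adaptraj` works with mass-action reaction networks: each reaction has a
rate constant and at most one modifier (a state or a constant input), so its
flux is `k · x_mod`, `k · u_mod`, or `k` for a zeroth-order source. State
dynamics are `ẋ = S v(x, θ, u)` with `S` the stoichiometric matrix. Outputs
are weighted sums of states or fluxes, flux ratios, or registered derived
formulas. Units are fixed throughout: concentrations in mM, fluxes in mM/h,
first-order constants in 1/h, zeroth-order constants in mM/h. Inputs are
constants; every analysis in the package is a steady-state analysis.

Because each flux is linear in at most one state, every model in this class
is linear time-invariant for fixed θ and u: `ẋ = A(θ,u) x + b(θ,u)`. The
steady-state solver exploits this with a direct solve of `A x* = −b`
(method `"linear"`, the default inside estimation and trajectory code); a
generic path — long integration with horizon doubling up to 10⁶ h followed
by Newton root refinement — is retained as the reference method and
cross-checked against the linear path in the tests. Convergence is judged
by `‖S v(x*)‖∞ ≤ atol` (default 10⁻⁹ mM/h) relaxed by the float64
backward-error scale of the solve, since an absolute 10⁻⁹ residual is not
representable when fluxes are of order 10⁶. Non-convergence is a flagged
result, not an exception, so ensemble screening can discard the candidate.
Time courses use LSODA with rtol 10⁻⁸, atol 10⁻¹⁰ mM.

## Bundled hepatic model

The shipped model is a reconstruction of hepatic lipid and plasma
lipoprotein metabolism with three conceptual compartments (liver, plasma,
periphery), 8 mass-carrying species and 22 rate constants:

* Triglycerides: FFA uptake/esterification (v1, from the constant plasma-FFA
  input) and de novo lipogenesis (v2) feed cytosolic TG, which is oxidized
  (v3) or mobilized to the ER (v4, back-transfer v5); ER TG is secreted as
  VLDL-TG (v6); plasma VLDL-TG undergoes peripheral lipolysis (v16) or
  hepatic remnant re-uptake (v17).
* Cholesterol: synthesis (v7), biliary excretion (v8), cytosolic and ER
  esterification/hydrolysis cycles (v9–v12), CE mobilization to the ER
  (v13), VLDL-CE secretion (v14), remnant CE re-uptake to hepatic free
  cholesterol (v18 — lysosomal-hydrolysis assumption), peripheral
  lipoprotein uptake (v19), HDL-CE formation in the periphery (v20), hepatic
  (v21) and peripheral (v22) HDL-CE uptake.
* apoB particle production (v15) carries no mass: particle number is not a
  pooled state; the rate only spreads the secreted lipid flux over particles
  in the diameter observable. This keeps exactly 8 mass-carrying species.
* Plasma FFA is an input, not a state: the measured FFA level is matched by
  construction through the input value.

The derived VLDL diameter observable is
`d = c_geom · ((ν_TG v6 + ν_CE v14)/v15)^(1/3)` with ν_TG = ν_CE = 1 and
`c_geom` calibrated once so the wild-type reference flux triple
(1.0, 0.3, 0.05) maps to 94 nm, the reported wild-type particle size. Both
volume coefficients and the prefactor are stored in the model constants and
configurable.

A ground-truth wild-type parameter set is shipped as JSON. It was designed
by fixing a physiological steady state (pools 0.25–2 mM, fluxes 0.05–2.2
mM/h, all far below the 100 mM/h feasibility bound) and reading the rate
constants off the balance equations. The treated phenotype applies fold
factors to 16 parameters in the directions expected under pharmacological
LXR activation (lipogenesis, TG mobilization, VLDL secretion, lipolysis and
hepatic re-uptake, HDL fluxes up; apoB production slightly down); the folds
were sized so the VLDL-TG secretion flux increases ≈2.7-fold, inside the
reported ≈2.6-fold induction band.

## Estimation protocol

Sampling is log₁₀-uniform per coordinate on [10⁻⁶, 10⁶]. Each candidate is
scored against its own Gaussian realization of the data (seed derived from
the global seed and the candidate index), mirroring the Monte-Carlo
treatment of experimental uncertainty; the realization keeps raw draws (no
truncation at zero) and always carries the dataset's σ as weights.
Optimization runs in log₁₀-parameter space (positivity plus the 12-decade
scale) with box bounds equal to the sampling range, scipy's trust-region
reflective least squares, and a safeguard that never returns a point worse
than the start. Acceptance compares optimized outputs to the dataset means
μ (not the realization): `|yᵢ − μᵢ| ≤ z_{1−α′/2} σᵢ` with `α′ = α/N`,
α = 0.05; flux feasibility (every steady-state flux ≤ 100 mM/h, equality
passing) is evaluated at the optimized steady state only. Ties in the
top-n selection are broken by candidate index. Desk-scale defaults are
2000 samples with the top 20 optimized; the full-protocol scale (10⁸/10⁴)
is recorded as a constant but is not a desk-scale computation.

## Trajectories

Interpolation schemes are monotone weights w(q) with exact endpoints:
linear (w = q), quadratic-like (w = q²), inverse-quadratic-like
(w = 1 − (1−q)²). σ and the model inputs interpolate with the same weight
as the means — the objective needs a positive σ^q everywhere, and linear
interpolation in w is the simplest choice consistent with the endpoints.
One realization each of the A and B data is drawn per trajectory and
interpolated deterministically between steps; fresh draws per step would
conflate measurement noise with path dispersion.

The reference set of the penalty `X_r = Σⱼ ((θⱼ − θⱼ^ref)/θⱼ^ref)²` is fixed
for a whole pass at the pass's starting parameters: θ⁰ (phenotype A) going
forward, and the B-side set after the swap for backward passes. λ defaults
to 0.1 — in the sweep (`lambda_sweep`) the median endpoint X_r drops
sharply already for small λ while endpoint fits remain acceptable, so the
smallest effective value is preferred to bias the data fit as little as
possible. The q = 0 point is recorded without re-optimization; each
subsequent step warm-starts from the previous parameters and state with a
per-step optimizer budget (default 200 evaluations) that keeps
100-step passes cheap. Consistency cycles run independent forward+backward
pairs with fresh realizations per repetition (a chained mode is available);
dispersion is summarized by quantiles of log₁₀ θ across passes — parameter
clouds span decades, so quantiles in log space rather than Gaussian moments.

### Constrained-effort comparison of single- vs multi-step optimization

With the default budget, the trust-region optimizer turned out to reach the
same endpoint whether the B data is approached in one jump or in 100 steps —
the steady-state map of this model class is smooth enough that no local
minimum intervenes at desk scale. The value of step-wise re-optimization
shows when per-step effort is fixed and small: at 2 trust-region iterations
per step, a single jump to the treated phenotype misses endpoint acceptance
for most ensemble members while the 100-step warm-started pass succeeds for
all of them (the classic homotopy-continuation advantage). The test suite
pins one such member/seed pair as a fixture.

## Synthetic data

The generator emulates steady-state measurements of pools, fluxes, and
derived quantities for two phenotypes: means are the exact ground-truth
steady-state outputs (optionally perturbed once to emulate noisy reported
means), and σ = cv·|mean| with a 10⁻⁶ floor. The default cv = 0.2 matches
the relative spread of the reported hepatic lipid values. The default mask
hides the cytosolic/ER pool-split observables, reflecting that only total
pools are typically measured while fraction-specific production rates are
available; the never-measured CE split then shows the expected wide
prediction spread across the accepted ensemble, while the TG split stays
constrained by the flux data. What the generator does not emulate: between-
animal covariance structure, non-Gaussian measurement error, or any real
dynamic response — passing tests demonstrate correctness of the machinery
and recoverability under the stated noise model, not fidelity to any
particular laboratory dataset.

The demonstration dataset (`lxr_demo_dataset`) replaces the hepatic-TG and
VLDL-diameter rows with literature-reported values for wild-type vs
T0901317-treated mice (6.92 ± 2.65 → 57.74 ± 16.61 nmol/mg liver; 94 ± 12 →
129 ± 9 nm). Units differ per observable (pools in nmol/mg liver, fluxes in
mM/h); the weighted objective is scale-free per observable, so mixed units
are legitimate — each observable is only ever compared to itself.

## Numerical choices and degenerate inputs

* Undefined outputs (flux ratio with zero denominator) propagate as NaN and
  turn into +∞ cost / non-acceptance, never exceptions.
* Steady-state failure inside an optimization penalizes the candidate with
  large constant residuals instead of aborting the run.
* A trajectory step that cannot be optimized truncates the pass and flags
  it (`completed = False`).
* The backward q-grid is built from the same rationals as the forward grid
  so forward and backward points align exactly.
* All randomness flows from a single seed through documented
  `SeedSequence`-based derivation (`derive_seed`), keeping every derived
  seed below 2³¹; identical runs are byte-identical.

## Problem sizes

Defaults in tests and the acceptance script: 2000 sampled candidates with
the top 20 optimized, 100-step trajectories, 3 data realizations per member
for reported medians, 10 repetitions for recovery statistics, 2000-point
clouds for ellipse coverage. These sizes give stable statistics for the
bundled 8-state model on a single CPU; all are configurable, and the
full-protocol constants are kept alongside them.

## Known limitations

* Only mass-action rate laws with at most one modifier; no Michaelis-Menten
  kinetics, time-varying inputs, or delays.
* Steady-state data only; the interpolation coordinate q is an abstract
  progression coordinate, not time.
* One global λ; per-process regularization weights are not implemented.
* Switch-like/bistable transition schemes are out of scope.
* The SBML layer targets this model class (one compartment, mass-action
  kinetic laws); observables have no SBML representation and are not
  round-tripped.
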