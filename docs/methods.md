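# Methods

## Model family

All four forecasters solve one grey Bernoulli difference equation on an
accumulated version of the training series. With X⁽⁰⁾ the raw positive
series of length n, the ζ-order damping accumulation is
x⁽ᶻ⁾(k) = Σᵢ₌₁ᵏ x⁽⁰⁾(i)/ζ^(i−1); its background (adjacent-mean) sequence
z(k) = ½(x⁽ᶻ⁾(k) + x⁽ᶻ⁾(k−1)) enters the difference equation

x⁽ᶻ⁾(k) − x⁽ᶻ⁾(k−1) + a·z(k) = b·z(k)^α,  k = 2 … n.

(a, b) are the linear least-squares solution of the stacked system with
rows (−z(k), z(k)^α) against the accumulated first differences. Fitted
and forecast values evaluate the whitening ODE's closed-form time
response anchored at x̂⁽ᶻ⁾(1) = x⁽⁰⁾(1), then restore through the exact
inverse operator x̂⁽⁰⁾(k) = (x̂⁽ᶻ⁾(k) − x̂⁽ᶻ⁾(k−1))·ζ^(k−1).

Assumptions: the data are strictly positive, annual and consecutive;
the underlying trend is quasi-exponential (possibly saturating via the
Bernoulli term); n is small (the design targets n ≈ 8–15, and nothing
here consults asymptotics). The integration constant of the time
response is fixed by the first-observation anchor,
c = x⁽⁰⁾(1)^(1−α) − b/a — the only choice consistent with
x̂⁽ᶻ⁾(1) = x⁽⁰⁾(1) at k = 0.

## Parameters

| parameter | meaning | domain | default |
|---|---|---|---|
| α | Bernoulli power exponent; 0 = linear GM(1,1), 2 = Verhulst-type | α ≠ 1 | 0 (tuned in NGBM families) |
| ζ | damping coefficient; weight ratio between consecutive years is 1/ζ | (0, 1] | 1 (tuned in damped families) |
| a | development coefficient (estimated) | a ≠ 0 | — |
| b | grey action quantity (estimated) | — | — |

ζ = 1 is deliberately inside the admissible domain: the damped families
must be able to degenerate onto their classical counterparts (this
happens in practice — on the Nanjing series the tuned damped GM(1,1)
selects ζ = 1 and collapses onto GM(1,1)).

Hyperparameter search uses the whale optimization algorithm with
population 30 and 50 iterations (the conventional WOA defaults; only the
iteration count is dictated by the study protocol), spiral constant
b = 1, branch probability ½, search box α ∈ [−1, 1], ζ ∈ [0.01, 1].
The fitness is the **training-set** fitting MAPE only — using held-out
years in the fitness would leak the test set. Infeasible candidates
(singular exponent, rank-deficient design, non-positive time-response
base) receive +∞ fitness rather than aborting the search. Position
updates are clamped to the box; ties on fitness keep the earlier
incumbent, and the global best is never discarded, so the best-fitness
trace is non-increasing and any run is exactly reproducible from its
seed.

## Evaluation protocol

Series of ten annual values are split 8/2: the first eight years fit the
model, the last two score one- and two-step-ahead predictions. Errors
are absolute percentage errors (APE); summaries are their means (MAPE).
Two denominator conventions exist for the fitting MAPE because the first
fitted year is anchored to the data (APE exactly 0 by construction):
`include_first` averages all n training years, `exclude_first` averages
years 2..n. Published grey-model tables mix the two — damped-family rows
average over all eight years while classical GM(1,1)/NGBM rows average
over years 2–8 — so each family carries its conventional default and
every function accepts an override.

## Synthetic data generator

`generate_synthetic` manufactures series lying exactly in a family's
solution set: the accumulated sequence is propagated step by step through
the grey difference equation itself (closed form at α = 0, a bracketed
scalar root-find otherwise) and restored. Least squares on a noise-free
product therefore recovers (a, b) to machine precision, which is the
generator's contract and what the round-trip tests assert. Generating
from the continuous time response instead would *not* round-trip: least
squares on exact exponential data returns a′ = 2·tanh(a/2) ≠ a (off by
a³/12), an inherent discretization gap between the difference equation
and its whitening ODE.

Noise, when requested, is additive Gaussian on the restored values, the
simplest perturbation structure for recovery experiments. The generator
emulates the *shape* of grey-compatible data (quasi-exponential,
positive, short); it does not emulate policy breaks, measurement
revisions or level shifts — passing recovery tests says the estimator is
self-consistent, not that real demographic series satisfy the model.

## Numerical choices

- Least squares is solved by a rank-revealing orthogonal decomposition
  (`numpy.linalg.lstsq`), not by inverting BᵀB; the normal-equations
  form is the mathematical contract and equivalence is asserted in
  tests, including against a matrix-algebra-free nested grid-refinement
  oracle.
- Damping weights 1/ζ^(i−1) are built by running product rather than
  repeated exponentiation.
- Rejected with named errors: α = 1 (singular exponent), |â| < 1e−12
  (degenerate development coefficient), rank-deficient designs,
  non-positive background values under a fractional α, and a
  non-positive time-response base anywhere in the requested range.
- The first restored value is set to x⁽⁰⁾(1) directly instead of through
  b/a + (c − b/a) cancellation.
- The accumulate → restore round trip is exact to 1e−12 relative for
  series whose dynamic range resembles real annual indicators; a tiny
  value following a value ~10⁶ times larger loses precision to
  cancellation, which the property tests' generators bound away.

## Structural guarantees under test

- Round-trip identity of accumulation/restoration; accumulation strictly
  increasing in k; pointwise anti-monotone in ζ; information differences
  equal x⁽⁰⁾(k+1)/ζᵏ in closed form.
- Exact degeneracy: damped families at ζ = 1 equal their classical
  counterparts output-for-output (1e−10), and α = 0 collapses NGBM onto
  GM(1,1).
- Restoration error bound: perturbing the accumulated response by at
  most ε moves the k-th restored value by at most 2ζ^(k−1)ε.
- Prediction growth: for a fitted model, the out-of-sample growth ratio
  of restored predictions increases with the ζ used in restoration.
  (With per-ζ *refitting* the ratio is monotone only up to ~1e−4 wobble
  at the top of the ζ grid, because the estimated a shifts with ζ; the
  guarantee proper holds the fitted parameters fixed.)

## Design notes and limitations

- The estimators follow the scikit-learn protocol (`fit`/`predict`,
  `get_params`, trailing-underscore attributes) so they compose with
  sklearn tooling; `fit` takes the training values directly since the
  models are univariate autoregressive-in-time rather than X→y maps.
- On series with pronounced fluctuation (the birth-rate case) the
  training-MAPE surface over (α, ζ) is a flat curved valley: distinct
  hyperparameter pairs fit nearly equally well, so tuned optima are
  reproducible in *fitness* but not in parameter location. On smooth
  monotone series (Jiangsu, Nanjing) the optimum is sharp and tuning
  reproduces the published values to ~1e−3.
- Published parameter values are reproduced within the precision their
  own 4-decimal hyperparameter rounding permits: a to ~3 decimals, b to
  ~5e−4 relative. Two-step-ahead errors on volatile series amplify that
  rounding; the bundled birth-rate case pins the 2020 APE at 18.04%
  regardless of 4-decimal-compatible hyperparameter perturbations.
- Baselines are intentionally standard: simple exponential smoothing
  (level initialized at the first observation, weight selected on a
  0.01-step grid by training one-step MAPE, flat multi-step forecasts)
  and a logistic growth curve fitted by multi-start nonlinear least
  squares. They serve as references, not as reproductions of any
  particular published variant, whose recursions are not specified.
- Out of scope: multivariate grey models, fractional/complex-order
  accumulation, seasonal operators, interval forecasts and significance
  testing between models.
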