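# Methods

## Model

Degradation is a homogeneous gamma process D(t): increments over an
interval of length s are Gamma(shape a·s, scale-rate β), independent
and stationary, with D(0) = 0 and nondecreasing paths. The event time
is the first crossing of a threshold c, T = inf{t : D(t) ≥ c}. The law
of T depends on β and c only through βc, so c is fixed at 1 and β is
the free scale parameter. Then

- cdf: F(t) = Q(a t, β), the regularized upper incomplete gamma ratio;
- survival: S(t) = P(a t, β), i.e. exactly the gamma cdf in β with
  shape a t, computed directly (never as 1 − F) so the deep tail keeps
  full relative precision;
- density: f(t) = −a · ∂P/∂α(a t, β).

The monotone-path assumption is the substantive modelling choice: the
model is meant for irreversible deterioration (capacity fade, ageing),
in contrast to Wiener-process FHT models whose latent health can
fluctuate upward.

Covariates act on both parameters through log links, ln a = Xθ and
ln β = Xγ, with an all-ones first design column. The fit criterion is
the right-censored log-likelihood: events contribute ln f, censored
observations ln S.

## Incomplete-gamma shape derivatives

Everything reduces to P(α, x) and its partial derivatives up to second
order. The x-derivatives are elementary closed forms. The α-derivatives
have no closed form and are computed by term-by-term differentiation of

- the power series of P when x ≤ 1 or x < α (digamma/trigamma values
  advanced by recurrence; truncation when the term falls below 1e-14 of
  the accumulated sum, hard cap 10,000 terms), and
- the Legendre continued fraction of Q = 1 − P otherwise: the
  convergent recurrences A_n = b_n A_{n−1} + a_n A_{n−2} are linear in
  α, so first and second derivatives propagate through the same
  recurrences differentiated once and twice, with periodic rescaling to
  keep convergents bounded (tolerance 1e-13, cap 1000 iterations).

Points where neither expansion converges fall back, with a warning, to
Richardson-extrapolated central differences of `scipy.special.gammainc`
(differencing the complementary function where P > 1/2 to avoid
cancellation). The fallback is a supported code path, not only a test
device, so a fitting loop never aborts on one hard (α, x) pair.
Arguments are clamped away from zero at 1e-300 because boosting can
transiently drive exp(linear predictor) to extremes. Against
arbitrary-precision references the analytic paths agree to ~1e-11
relative over α ∈ [0.3, 200], x ∈ [0.1, 300].

An independent high-precision density route via the generalized
hypergeometric series ₂F₂(at, at; at+1, at+1; −β) (mpmath) is kept as a
cross-check oracle only; exact Meijer-G gradient expressions are out of
scope — the approximation-based gradients are the fitting path.

## Gradients

The scores are reduced algebraically from the upper-incomplete-gamma
quotient forms (h = Γ(α, β), g = Γ(α)) to regularized-P derivatives,
which avoids overflow of raw g, h factors for α = a t beyond ~170:

- event: u_a = 1/a + t·P_αα/P_α, u_β = P_αβ/P_α;
- censored: u_a = t·P_α/P, u_β = P_x/P.

The raw h/g bundle (h = g − gP and its five derivatives, with g, g′,
g″ formed in log space) is still exposed and tested for moderate α.
Because the additive predictors live on the log scale, per-observation
gradients are lifted by the chain rule (×a, resp. ×β) before base
learners are fit — the base learners see the predictor-scale gradient,
as in distributional (GAMLSS-style) boosting. Non-finite
per-observation gradients (density underflow in a far tail) are zeroed
with a warning — the observation sits out that step — rather than
aborting the run.

## Initialization

Intercepts start at the intercept-only maximum likelihood estimate,
found by multi-start BFGS on (ln a, ln β) with the analytic score:
ln β starts at {−2, 0, 2}, and ln a is inverted from the mean-hitting-
time approximation E[T] ≈ (β + 1/2)/a at the observed mean time.

One pitfall is handled explicitly. When covariates carry strong
unmodelled heterogeneity, the *marginal* intercept-only likelihood can
increase monotonically along a ridge into the corner a → 0, β → 0,
where the FHT law degenerates to an exponential: verified by grid
profiling, there is then no interior maximum at all. Starting boosting
from that corner freezes the β path (its lifted gradients scale with
β). `init_mle` therefore accepts only interior converged stationary
points (|coefficient| < 15) and otherwise falls back, with a warning,
to a variance-matched moment initializer: near the mean-path crossing
E[T] ≈ (β + ½)/a and sd[T] ≈ √β/a, so the coefficient of variation
cv ≈ √β/(β + ½) determines β alone (capped at its maximum cv = 1/√2,
attained at β = ½, for overdispersed samples) and the mean then fixes
a. On homogeneous data the interior MLE exists and is returned as-is
(recovered to ±0.1 at n = 2000 in the tests).

## Boosting

Componentwise gradient boosting with step length ν = 0.1 (default) and
either of two base learners per covariate: simple least squares on
(1, x_j) — the all-ones column competing as its own constant learner —
or a single-split stump (candidate splits at midpoints of sorted unique
values, ties to the smallest split; "penalisation" of stumps is
realized solely through ν-shrinkage). Selection among candidates is by
minimal residual sum of squares against the current negative gradient;
ties break to the lowest column index.

- Cyclic variant: each iteration updates the ln-a predictor (with the
  current ln-β fit as offset), then the ln-β predictor; the two
  predictors may carry different stopping iterations (a parameter
  freezes once its count is exhausted, on a shared iteration counter).
- Noncyclic variant: candidates are fit for both parameters and only
  the single update with the larger decrease in training loss is kept
  (parameter a wins exact ties).

A non-finite training loss rolls the step back and terminates the run
early with a warning. The training-loss path is recorded and is
non-increasing in practice for small ν (asserted to 1e-8 per step in
the tests).

Cross-validated stopping uses seeded folds stratified by event status
(a fold without events triggers one refold). Each fold is fit once to
the maximum iteration count while recording held-out negative
log-likelihood per iteration; the minimizer of the fold-summed curve is
returned — a scalar for the noncyclic variant and an equal (m, m) pair
for the cyclic one. Asymmetric stops are honored by the fitter but not
searched over: a full two-dimensional grid of refits per fold is
disproportionate at the problem sizes this package targets.

Models serialize to a structured JSON text document (coefficients,
stump lists, configuration, initialization); round trips are bit-exact
because floats survive JSON shortest-repr round-tripping.

## Simulator

`sample_fht` draws hitting times for fixed (a, β) by rejection under a
piecewise-constant majorizer of the density on the [1e-6, 1 − 1e-6]
quantile window (128 cells, cell heights from a 4× denser probe grid,
safety factor 1.05; envelope violations raise). A bisection inverse-cdf
sampler (time tolerance 1e-10) serves as the reference method and as
the vectorized route for heterogeneous per-row parameters in the
scenario generators — per-row envelope construction would cost a full
grid per individual for the identical law. Both samplers are KS-tested
against the cdf.

Two benchmark scenarios are built in as the package defaults: a
strong-signal design (four U(0,1) covariates, ln a = 1.5 + 3x₁ − 1.5x₂,
ln β = 2 + 0.25x₃ − 0.5x₄, exponential censoring with rate 0.1) and a
sparse design (20 + 20 U(0,1) covariates with ten active per parameter,
ln a = 2.5 + 0.3Σx, ln β = 2.0 − 0.3Σz, censoring rate 3). Both censor
about 10% of observations. The a-block and β-block are kept as separate
design columns and both predictors are regressed on all 40 columns, so
the cross-block truth is zero.

What the generators emulate — and what they do not: covariates are
independent uniforms, censoring is independent exponential, and the
data-generating law *is* the fitted family. Passing recovery tests
therefore demonstrates correctness of the estimation machinery, not
robustness to misspecification, correlated designs, informative
censoring, or covariate-dependent censoring found in real cohorts.

## Evaluation

Kaplan-Meier product-limit estimation is implemented in-package because
the IPCW corrections need explicit conventions: the censoring
distribution G is the KM of flipped status with events preceding
censorings at ties, and event weights use the left limit G(t⁻). The
Brier score at horizon t follows the standard IPCW decomposition
(events before t weighted by 1/G(tᵢ⁻), individuals at risk by 1/G(t),
censored-before-t contribute nothing; zero weights drop the term with a
warning). The integrated Brier score is a span-normalized trapezoid
over the unique test event times (or a caller-supplied grid), optionally
truncated at t*. The concordance index uses Uno-type weights 1/G(tᵢ⁻)²
over usable pairs, with risk ties counting ½; the default risk score is
the negated predicted median hitting time, obtained by interpolating
each row's survival curve at ½ (an alternative is 1 − Ŝ at a fixed
horizon). lifelines and scikit-survival serve as independent oracles in
the tests, never as the implementation.

For real-data-style responses with many values near zero, the time
preprocessing t ↦ t/5 + 2 (inverse available) stabilizes the
likelihood without changing the shape of the distribution.

## Problem sizes and defaults

Defaults are the study conditions: ν = 0.1, five-fold CV, benchmark
sample sizes n = 500–2000 with 1500–2000 boosting iterations for
coefficient recovery, 20 seeds for censoring-proportion estimates, and
ten 2/3–1/3 stratified train/test repetitions for the predictive
comparison (at n = 450 and 250 iterations, sizes at which the
strong-signal comparison is already decisive). The unit suites use
smaller n (300–800) chosen to keep each property sharp at desk scale.

## Known limitations

- The shape function is linear, α(t) = a t; nonhomogeneous shapes,
  random thresholds and individual frailty are out of scope.
- The intercept-only initializer's moment fallback assumes a unimodal,
  not-too-extreme marginal; pathological marginals (e.g. strongly
  multimodal times) may start the path poorly even though boosting can
  still correct the predictors.
- Cross-validation searches a shared stopping iteration for the two
  predictors; genuinely asymmetric optima must be supplied explicitly.
- The concordance index loops over event observations in Python; it is
  intended for test-set sizes in the hundreds-to-thousands, not for
  massive cohorts.
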