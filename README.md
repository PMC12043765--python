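# gammafht

Boosted first-hitting-time (FHT) survival models driven by a monotone
gamma degradation process, for right-censored time-to-event data in
reliability and biomedical settings — including high-dimensional
problems (p > n) where componentwise boosting provides built-in
variable selection.

## The model

Latent degradation is a homogeneous gamma process D(t) with shape
function α(t) = a·t and scale β: increments over an interval of length
s are Gamma(a·s, β), paths are nondecreasing, and E[D(t)] = a·t/β. The
event occurs when D(t) first crosses a threshold c; since the law of
the hitting time depends on β and c only through β·c, the threshold is
fixed at c = 1. The hitting time T then has

```
F_T(t) = Γ(a t, β) / Γ(a t) = Q(a t, β)        (regularized upper incomplete gamma)
S_T(t) = P(a t, β)                             (the gamma cdf itself)
f_T(t) = -a · ∂P/∂α (a t, β)
```

Unlike Wiener-process FHT models, the gamma-process version encodes
*irreversible* deterioration — appropriate for battery capacity fade,
ageing, or any system that does not recover.

Both parameters are regressed on covariates through log links,
ln a = Xθ and ln β = Xγ, and fitted by componentwise gradient boosting
of the censored negative log-likelihood

```
ℓ(θ, γ) = Σᵢ dᵢ ln f_T(tᵢ; aᵢ, βᵢ) + (1 − dᵢ) ln S_T(tᵢ; aᵢ, βᵢ).
```

Each iteration fits simple base learners (per-covariate linear fits or
stumps) to the negative gradient and adds a shrunken copy (ν = 0.1) of
the best one, updating a single covariate per step. Cyclic updates
alternate between the two predictors; noncyclic updates perform only
the single best update across both. The stopping iteration — the main
tuning parameter — is chosen by stratified k-fold cross-validation.

The numerical core is a vectorized implementation of the first and
second derivatives of the regularized incomplete gamma function
P(α, x) with respect to *both* arguments (series and continued-fraction
expansions with a finite-difference fallback), from which the density,
likelihood and all boosting gradients are assembled in closed form.

## Worked example

`examples/02_boosting_recovery.py` simulates 1000 individuals from the
strong-signal benchmark design (ln a = 1.5 + 3x₁ − 1.5x₂,
ln β = 2 + 0.25x₃ − 0.5x₄, uniform covariates, ~10% exponential
censoring) and fits 1500 cyclic boosting iterations:

```
n = 1000, censored fraction = 0.092

initial intercepts (ln a, ln beta) = (0.005, -0.693)
training loss: 1122.5 -> -31.8 over 1500 iterations

ln a predictor            fitted    true
  intercept             1.149    1.50
  x1                    3.230    3.00
  x2                   -1.126   -1.50
  ...
ln beta predictor         fitted    true
  intercept             1.619    2.00
  x3                    0.353    0.25
  x4                   -0.384   -0.50
```

Every active covariate is selected and converges toward its generating
value; the weak β effects converge more slowly than the strong a
effects, and the intercepts approach the truth along the boosting path.
The other examples cover the distribution functions
(`01_distribution.py`), sparse variable selection
(`03_sparse_selection.py`) and censoring-corrected predictive metrics
— IPCW Brier score, integrated Brier score, concordance index — against
a Kaplan-Meier reference (`04_prediction_metrics.py`).

A thin CLI mirrors the library:

```
gammafht simulate --example 1 --n 500 --seed 1 --out data.csv
gammafht fit --data data.csv --m-stop 500 --seed 1 --out model.json
gammafht evaluate --model model.json --data data.csv --out report.csv
```

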