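"""Recovering regression coefficients by componentwise boosting.

Simulates the strong-signal benchmark design
    ln a    = 1.5 + 3 x1 - 1.5 x2
    ln beta = 2 + 0.25 x3 - 0.5 x4,   x_j ~ U(0,1), ~10% censoring,
then fits the boosted FHT model (cyclic updates, linear base learners,
step length nu = 0.1) and prints the coefficient paths' endpoints.
"""

import warnings

import numpy as np

from gammafht import BoostConfig, boost_fit, generate_example1

data = generate_example1(1000, seed=21)
print(f"n = {data.n}, censored fraction = {1 - data.status.mean():.3f}")

config = BoostConfig(nu=0.1, m_stop=1500, variant="cyclic", learner="linear", seed=21)
with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)
    state = boost_fit(data, config)

la0, lb0 = state.init_intercepts
print(f"\ninitial intercepts (ln a, ln beta) = ({la0:.3f}, {lb0:.3f})")
print(f"training loss: {state.loss_path[0]:.1f} -> {state.loss_path[-1]:.1f} "
      f"over {state.iterations_run} iterations")

true_theta = [1.5, 3.0, -1.5, 0.0, 0.0]
true_gamma = [2.0, 0.0, 0.0, 0.25, -0.5]
names = ["intercept", "x1", "x2", "x3", "x4"]
print("\nln a predictor            fitted    true")
for name, fit, tr in zip(names, state.theta, true_theta):
    print(f"  {name:<10}         {fit:8.3f}  {tr:6.2f}")
print("ln beta predictor         fitted    true")
for name, fit, tr in zip(names, state.gamma, true_gamma):
    print(f"  {name:<10}         {fit:8.3f}  {tr:6.2f}")
print("\nEvery active covariate is selected and its coefficient approaches "
      "the generating value; the weak beta effects (0.25, -0.5) converge "
      "more slowly than the strong a effects.")
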