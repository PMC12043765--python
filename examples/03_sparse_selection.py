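"""Implicit variable selection in a sparse high-dimensional design.

The sparse benchmark has 40 covariates of which ten drive ln a and ten
drive ln beta (all slopes 0.3 in magnitude); the rest have no effect.
Componentwise boosting updates one covariate per step, so zero-effect
covariates should be selected rarely.
"""

import warnings

import numpy as np

from gammafht import BoostConfig, boost_fit, generate_example2

data = generate_example2(500, seed=7)
print(f"n = {data.n}, p = {data.p}, censored fraction = {1 - data.status.mean():.3f}")

with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)
    state = boost_fit(data, BoostConfig(nu=0.1, m_stop=2000, seed=7))

active = state.theta[1:11]
inactive = state.theta[11:21]
print(f"\nln a active coefficients (true 0.3):   mean = {active.mean():.3f}")
print(f"ln a zero-effect coefficients (true 0): mean |.| = "
      f"{np.abs(inactive).mean():.3f}")

sel = [(r["iter"], r["j"]) for r in state.selection_log if r["param"] == "a"]
for window in (100, state.iterations_run):
    hits_active = sum(1 for it, j in sel if it <= window and 1 <= j <= 10)
    hits_zero = sum(1 for it, j in sel if it <= window and 11 <= j <= 20)
    print(f"ln a selections in first {window:4d} iterations: "
          f"active block {hits_active}, zero block {hits_zero}")
print("\nWhile the weak signals are being absorbed (early iterations) the "
      "active covariates dominate the selections — boosting's built-in "
      "variable selection. Once the signal is fitted, further updates chase "
      "noise and the preference fades: stopping at a cross-validated m_stop "
      "is what keeps spurious covariates out.")
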