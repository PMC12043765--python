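"""Predictive evaluation with censoring-corrected metrics.

Fits the boosted FHT model on two thirds of a simulated cohort and
evaluates the predicted survival curves on the held-out third with the
IPCW Brier score, its integral (IBS), and the concordance index,
against the Kaplan-Meier curve as a covariate-free reference.
"""

import warnings

import numpy as np

from gammafht import (
    BoostConfig,
    SurvivalDataset,
    boost_fit,
    c_index,
    generate_example1,
    integrated_brier,
    kaplan_meier,
    predict_survival,
)
from gammafht.metrics import predicted_median

data = generate_example1(600, seed=5)
rng = np.random.default_rng(5)
train_mask = np.zeros(data.n, dtype=bool)
for val in (0, 1):  # stratify the split by event status
    idx = rng.permutation(np.nonzero(data.status == val)[0])
    train_mask[idx[: int(round(2 / 3 * idx.size))]] = True
train = SurvivalDataset(data.times[train_mask], data.status[train_mask],
                        data.X[train_mask], list(data.columns))
test = SurvivalDataset(data.times[~train_mask], data.status[~train_mask],
                       data.X[~train_mask], list(data.columns))

with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)
    model = boost_fit(train, BoostConfig(m_stop=300, seed=5))

grid = np.unique(test.times)
S_model = predict_survival(model, test.X, grid)
S_km = np.tile(kaplan_meier(train.times, train.status)(grid), (test.n, 1))

ibs_model = integrated_brier(grid, S_model, test)
ibs_km = integrated_brier(grid, S_km, test)
ci = c_index(-predicted_median(grid, S_model), test)

print(f"train n = {train.n}, test n = {test.n}")
print(f"IBS  boosted FHT model : {ibs_model:.4f}")
print(f"IBS  Kaplan-Meier ref. : {ibs_km:.4f}")
print(f"C-index (risk = -predicted median): {ci:.3f}")
print("\nLower IBS is better; the covariate-aware model should clearly beat "
      "the marginal Kaplan-Meier curve on this strong-signal design, and a "
      "C-index well above 0.5 confirms the predicted ranking is informative.")
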