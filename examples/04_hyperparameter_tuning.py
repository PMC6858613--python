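"""Tune the three LSTM hyperparameters by Bayesian optimization.

The search box is dropout in [0.10, 0.45] (step 0.01), LSTM units in
[5, 60] and dense units in [5, 40] - 67,375 grid combinations in total.
Instead of exhausting the grid, 15 Latin-hypercube settings seed a
Gaussian-process surrogate, and expected improvement proposes further
settings until the validation RMSE stops improving.
"""

from glucoforecast import LSTMConfig, simulate_cohort
from glucoforecast.hyperopt import SearchSpace, grid_size, lstm_objective, optimize
from glucoforecast.preprocess import prepare_patient

space = SearchSpace()
print(f"full grid: {grid_size(space):,} combinations; "
      "Bayesian optimization will evaluate a couple of dozen")

patient = simulate_cohort(10, 3, seed=0)[1]
prep = prepare_patient(patient)
base = LSTMConfig(epochs=80, seed=0)

best, state = optimize(lstm_objective(prep, base), space, seed=0,
                       budget=24, n_init=15)
trail = state.trail_frame()
print(trail.tail(6).round(3).to_string(index=False))
print(f"\nbest setting after {len(trail)} evaluations: "
      f"dropout={best[0]:.2f}, lstm_units={int(best[1])}, dense_units={int(best[2])}; "
      f"validation RMSE {state.incumbent[1]:.2f} mg/dL")
# The audit trail's incumbent column is non-increasing; the run stops as soon
# as a proposed setting fails to improve the incumbent (patience 1).
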