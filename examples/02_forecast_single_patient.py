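"""Train the LSTM forecaster for one patient and score the test block.

The pipeline: LOCF imputation -> proportional 120:30:30 chronological split
-> per-feature min-max scaling to [-1, 1] fitted on training days only ->
sliding windows (yesterday's six features -> today's glucose) -> full-batch
Adam on squared error, keeping the epoch with the best validation RMSE.
"""

from glucoforecast import LSTMConfig, simulate_cohort, train
from glucoforecast.evaluation import rmse, within_pct
from glucoforecast.forecaster import predict_series
from glucoforecast.preprocess import prepare_patient

patient = simulate_cohort(10, 3, seed=0)[0]
prep = prepare_patient(patient)
print(f"patient {patient.patient_id}: {patient.n_days} days "
      f"-> split {prep.split.as_tuple()} (train/val/test)")

config = LSTMConfig(dropout_rate=0.2, n_lstm_units=20, n_dense_units=10,
                    epochs=200, seed=0)
result = train(prep.train, prep.val, config, scaler=prep.scaler)
print(f"best epoch {result.best_epoch}: validation RMSE "
      f"{result.best_val_rmse:.2f} mg/dL")

preds = predict_series(prep.series, result.params, prep.scaler, prep.split)
print(preds.head(5).to_string(index=False))
print(f"test RMSE {rmse(preds['actual_mgdl'], preds['predicted_mgdl']):.2f} mg/dL, "
      f"±10% accuracy {within_pct(preds['actual_mgdl'], preds['predicted_mgdl']):.1f}%")
# RMSE is in the original units; ±10% accuracy is the share of test days whose
# forecast lands within 10% of the actual reading (point-of-care criterion).
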