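"""Clinical accuracy assessment of glucose forecasts.

Three criteria, all computed on the same test-day pairs of (reference,
predicted) glucose in mg/dL:

* **Clarke Error Grid** zones A-E (Clarke et al., 1987): a partition of the
  (reference, prediction) plane grading the clinical consequence of an
  error.  Zone A is clinically accurate (within 20% of reference, or both
  readings hypoglycemic <= 70 mg/dL); zone E is the dangerous confusion of
  hypo- and hyperglycemia.
* **±10% point-of-care accuracy**: share of predictions within 10% of the
  reference value.
* **RMSE** in mg/dL.

``compare_methods`` runs the whole pipeline for every requested method on a
cohort and emits a pooled zone-percentage table (one column per method) and a
per-patient ±10% accuracy matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from glucoforecast.baselines import BaselineConfig, BaselinePredictor
from glucoforecast.cohort import PatientSeries
from glucoforecast.forecaster import LSTMConfig, forward
from glucoforecast.preprocess import (
    PreparedPatient,
    inverse_scale_glucose,
    prepare_patient,
)
from glucoforecast.transfer import make_plan, pretrain_finetune

ZONES = ("A", "B", "C", "D", "E")

LSTM_METHODS = {"lstm": "none", "lstm_tf_all": "all", "lstm_tf_dtw": "dtw"}
BASELINE_METHODS = ("ann", "knn", "ridge", "kernel_ridge", "moving_average")
ALL_METHODS = tuple(LSTM_METHODS) + BASELINE_METHODS


def clarke_zone(reference: float, prediction: float) -> str:
    """Clarke Error Grid zone of one (reference, prediction) pair, mg/dL.

    The canonical piecewise rules, evaluated in order A, E, C, D, else B;
    boundary equalities are inclusive toward the zone listed first.
    """
    r, p = float(reference), float(prediction)
    if r <= 0 or p <= 0:
        raise ValueError("glucose values must be positive")
    if (r <= 70 and p <= 70) or abs(p - r) <= 0.2 * r:
        return "A"
    if (r >= 180 and p <= 70) or (r <= 70 and p >= 180):
        return "E"
    if (70 <= r <= 290 and p >= r + 110) or (130 <= r <= 180 and p <= (7.0 / 5.0) * r - 182):
        return "C"
    if (
        (r >= 240 and 70 <= p <= 180)
        or (r <= 175.0 / 3.0 and 70 <= p <= 180)
        or (175.0 / 3.0 <= r <= 70 and p >= (6.0 / 5.0) * r)
    ):
        return "D"
    return "B"


@dataclass
class ClarkeZoneCounts:
    """Per-zone counts and percentages for a set of prediction pairs."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[str, float]:
        n = self.total
        return {z: round(100.0 * self.counts[z] / n, 2) for z in ZONES}

    def __add__(self, other: "ClarkeZoneCounts") -> "ClarkeZoneCounts":
        return ClarkeZoneCounts({z: self.counts[z] + other.counts[z] for z in ZONES})


def zone_table(references: np.ndarray, predictions: np.ndarray) -> ClarkeZoneCounts:
    """Classify every pair and tabulate zone counts/percentages."""
    r = np.asarray(references, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if r.shape != p.shape:
        raise ValueError("references and predictions must have equal length")
    if r.size == 0:
        raise ValueError("no pairs to classify")
    counts = dict.fromkeys(ZONES, 0)
    for ri, pi in zip(r, p):
        counts[clarke_zone(ri, pi)] += 1
    return ClarkeZoneCounts(counts)


def within_pct(references: np.ndarray, predictions: np.ndarray, pct: float = 10.0) -> float:
    """Percentage of predictions within ±pct% of the reference."""
    r = np.asarray(references, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if r.shape != p.shape:
        raise ValueError("references and predictions must have equal length")
    if r.size == 0:
        raise ValueError("no pairs to assess")
    return float(100.0 * np.mean(np.abs(p - r) <= (pct / 100.0) * r))


def rmse(references: np.ndarray, predictions: np.ndarray) -> float:
    """Root mean squared error, mg/dL."""
    r = np.asarray(references, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if r.shape != p.shape:
        raise ValueError("references and predictions must have equal length")
    if r.size == 0:
        raise ValueError("no pairs to assess")
    return float(np.sqrt(np.mean((p - r) ** 2)))


@dataclass
class EvalReport:
    """All three criteria for one method on one patient's test days."""

    patient_id: str
    method: str
    rmse: float
    within_10pct: float
    zones: ClarkeZoneCounts


@dataclass
class CohortEvaluation:
    """compare_methods output: per-(patient, method) reports plus the two
    publication-shaped tables."""

    reports: list[EvalReport]
    predictions: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)

    def accuracy_matrix(self) -> pd.DataFrame:
        """Per-patient ±10% accuracy, patients x methods (missing = NaN)."""
        rows: dict[str, dict[str, float]] = {}
        for rep in self.reports:
            rows.setdefault(rep.patient_id, {})[rep.method] = rep.within_10pct
        return pd.DataFrame(rows).T

    def pooled_zone_table(self) -> pd.DataFrame:
        """Pooled Clarke zone percentages, zones x methods.

        All patients' test pairs are pooled per method before computing
        percentages (counts are additive across patients)."""
        pooled: dict[str, ClarkeZoneCounts] = {}
        for rep in self.reports:
            if rep.method in pooled:
                pooled[rep.method] = pooled[rep.method] + rep.zones
            else:
                pooled[rep.method] = rep.zones
        return pd.DataFrame(
            {m: pd.Series(z.percentages) for m, z in pooled.items()}
        ).reindex(list(ZONES))

    def rmse_matrix(self) -> pd.DataFrame:
        rows: dict[str, dict[str, float]] = {}
        for rep in self.reports:
            rows.setdefault(rep.patient_id, {})[rep.method] = rep.rmse
        return pd.DataFrame(rows).T


def evaluate_pairs(patient_id: str, method: str,
                   references: np.ndarray, predictions: np.ndarray) -> EvalReport:
    return EvalReport(
        patient_id,
        method,
        rmse(references, predictions),
        within_pct(references, predictions),
        zone_table(references, predictions),
    )


def _lstm_predictions(prep: PreparedPatient, params) -> tuple[np.ndarray, np.ndarray]:
    refs = inverse_scale_glucose(prep.test.targets, prep.scaler)
    preds = inverse_scale_glucose(forward(prep.test.inputs, params), prep.scaler)
    return refs, preds


def compare_methods(
    cohort: list[PatientSeries],
    methods: tuple[str, ...] = ALL_METHODS,
    lstm_config: LSTMConfig | None = None,
    baseline_configs: dict[str, BaselineConfig] | None = None,
    seed: int = 0,
    lookback: int = 1,
    sample_budget: int | None = None,
) -> CohortEvaluation:
    """Run every requested method on every patient and collect the reports.

    All methods share the identical preprocessing (imputation, split, scaler,
    windows) per patient, and identical boundary rules in every metric.  A
    method failing on a patient is recorded as a missing cell and the run
    continues.
    """
    lstm_config = lstm_config or LSTMConfig(seed=seed)
    baseline_configs = baseline_configs or {}
    prepared = {s.patient_id: prepare_patient(s, lookback=lookback) for s in cohort}
    imputed = {s.patient_id: prep.series for s, prep in zip(cohort, prepared.values())}
    patient_index = {pid: i for i, pid in enumerate(prepared)}

    evaluation = CohortEvaluation(reports=[])
    for method in methods:
        for pid, prep in prepared.items():
            try:
                if method in LSTM_METHODS:
                    strategy = LSTM_METHODS[method]
                    cfg = replace(lstm_config, seed=seed + 1000 * patient_index[pid])
                    plan = make_plan(pid, prepared, strategy, cfg,
                                     sample_budget=sample_budget)
                    result = pretrain_finetune(pid, prepared, plan, seed=seed)
                    refs, preds = _lstm_predictions(prep, result.params)
                elif method in BASELINE_METHODS:
                    cfg_b = baseline_configs.get(method, BaselineConfig(method, seed=seed))
                    predictor = BaselinePredictor(cfg_b).fit(
                        prep.train, prep.val, series=imputed[pid]
                    )
                    raw = predictor.predict(prep.test)
                    refs = inverse_scale_glucose(prep.test.targets, prep.scaler)
                    preds = raw if method == "moving_average" else inverse_scale_glucose(
                        raw, prep.scaler
                    )
                else:
                    raise ValueError(f"unknown method {method!r}")
            except Exception:
                continue  # missing cell; other methods/patients still run
            evaluation.reports.append(evaluate_pairs(pid, method, refs, preds))
            evaluation.predictions[(pid, method)] = pd.DataFrame(
                {
                    "date": prep.series.dates[prep.test.day_indices],
                    "actual_mgdl": refs,
                    "predicted_mgdl": preds,
                }
            )
    return evaluation
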