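"""Synthetic patient cohort generator for daily lifestyle/glucose logs.

Real mobile-health self-monitoring data of the kind this pipeline targets
(calories, fat, carbohydrates, calories burned, weight, one glucose reading
per day, with heavy missingness) are rarely shareable.  This module generates
cohorts with the statistical structure the forecasting pipeline assumes:

* next-day glucose follows a lag-1 autoregression around a patient baseline,
  driven by the previous day's (mean-centered) carbohydrate intake and
  calories burned, plus a weak coupling to weight and Gaussian noise;
* lifestyle covariates are drawn from per-archetype truncated normals;
* weight is a slow random walk with drift, clipped to [100, 400] lbs;
* cells go missing either independently (MCAR) or in bursts (a two-state
  Markov chain calibrated to the same marginal rate), emulating patients who
  stop logging for stretches of days;
* patients are grouped into archetypes that share glucose dynamics, so
  similarity-weighted transfer learning has signal to exploit, and one
  patient can be made "data-scarce" (short series, high missingness).

Glucose means land in roughly [100, 200] mg/dL and weights in [140, 360] lbs,
matching descriptive statistics typical of overweight/obese type-2-diabetes
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical feature order used across the whole package.
FEATURES = ["calories", "fat_g", "carb_g", "calories_burned", "weight_lbs", "glucose_mgdl"]

#: Index of the glucose column inside FEATURES.
GLUCOSE = FEATURES.index("glucose_mgdl")

LIFESTYLE_FEATURES = ["calories", "fat_g", "carb_g", "calories_burned"]


@dataclass(frozen=True)
class PatientArchetype:
    """Generative parameters shared by all patients assigned to the archetype.

    Parameters
    ----------
    baseline_glucose : float
        Stationary mean glucose, mg/dL.
    ar_coefficient : float
        Lag-1 autoregressive coefficient, in (0, 1).
    carb_effect : float
        mg/dL change per gram of carbohydrate (previous day, mean-centered).
    exercise_effect : float
        mg/dL change per kcal burned (previous day, mean-centered); <= 0.
    weight_drift : float
        lbs/day drift of the weight random walk.
    noise_sd : float
        SD of the daily glucose innovation, mg/dL.
    missing_rate_glucose, missing_rate_lifestyle : float
        Marginal probability that a glucose / lifestyle cell is unobserved.
    n_days : int
        Length of the simulated series.
    weight_effect : float
        mg/dL per lb of deviation from the starting weight (weak coupling).
    weight_noise_sd : float
        SD of the weight random-walk innovation, lbs/day.
    burst_missing : bool
        If True, missingness arrives in multi-day runs (mean length
        ``burst_length``) instead of independently per cell.
    """

    baseline_glucose: float = 140.0
    ar_coefficient: float = 0.5
    carb_effect: float = 0.12
    exercise_effect: float = -0.03
    weight_drift: float = 0.0
    noise_sd: float = 10.0
    missing_rate_glucose: float = 0.2
    missing_rate_lifestyle: float = 0.05
    n_days: int = 180
    weight_effect: float = 0.1
    weight_noise_sd: float = 0.3
    burst_missing: bool = False
    burst_length: float = 5.0
    # lifestyle covariate distributions (truncated normals)
    calories_mean: float = 2000.0
    calories_sd: float = 300.0
    fat_mean: float = 70.0
    fat_sd: float = 15.0
    carb_mean: float = 220.0
    carb_sd: float = 40.0
    burned_mean: float = 300.0
    burned_sd: float = 120.0
    initial_weight: float = 200.0

    def __post_init__(self) -> None:
        if not (0.0 < self.ar_coefficient < 1.0):
            raise ValueError(f"ar_coefficient must be in (0, 1), got {self.ar_coefficient}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for name in ("missing_rate_glucose", "missing_rate_lifestyle"):
            rate = getattr(self, name)
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {rate}")
        if self.n_days <= 0:
            raise ValueError(f"n_days must be positive, got {self.n_days}")
        if self.exercise_effect > 0:
            raise ValueError("exercise_effect must be <= 0 (exercise lowers glucose)")


@dataclass
class PatientSeries:
    """One patient's daily log: values plus an observed/missing mask.

    ``values`` holds the complete (simulated or imputed) numbers; ``observed``
    marks which cells a real logger would have recorded.  Dates are strictly
    increasing, one row per calendar day.
    """

    patient_id: str
    values: pd.DataFrame  # index: DatetimeIndex, columns: FEATURES
    observed: pd.DataFrame  # same shape, boolean
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.values.columns) != FEATURES:
            raise ValueError(f"values columns must be {FEATURES}")
        if self.values.shape != self.observed.shape:
            raise ValueError("values and observed must have identical shape")
        idx = self.values.index
        if len(idx) > 1:
            deltas = np.diff(idx.values).astype("timedelta64[D]").astype(int)
            if not np.all(deltas == 1):
                raise ValueError("dates must be consecutive calendar days")

    @property
    def n_days(self) -> int:
        return len(self.values)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.values.index

    def masked_values(self) -> pd.DataFrame:
        """Values with unobserved cells set to NaN (the raw-log view)."""
        return self.values.where(self.observed)

    def glucose(self) -> np.ndarray:
        return self.values["glucose_mgdl"].to_numpy()

    def copy(self) -> "PatientSeries":
        return PatientSeries(
            self.patient_id, self.values.copy(), self.observed.copy(), dict(self.metadata)
        )


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, n: int) -> np.ndarray:
    return np.maximum(rng.normal(mean, sd, size=n), lo)


def _missing_mask(rng: np.random.Generator, n: int, rate: float,
                  burst: bool, burst_length: float) -> np.ndarray:
    """Boolean array, True where the cell is MISSING, marginal P(missing)=rate."""
    if rate == 0.0:
        return np.zeros(n, dtype=bool)
    if not burst:
        return rng.random(n) < rate
    # two-state Markov chain: stay-missing prob chosen for mean run length,
    # entry prob chosen so the stationary missing fraction equals `rate`
    p_stay = 1.0 - 1.0 / burst_length
    p_enter = min(1.0, (1.0 - p_stay) * rate / (1.0 - rate))
    out = np.empty(n, dtype=bool)
    state = rng.random() < rate
    for t in range(n):
        out[t] = state
        p = p_stay if state else p_enter
        state = rng.random() < p
    return out


def simulate_patient(
    archetype: PatientArchetype,
    seed: int,
    patient_id: str = "p1",
    start_date: str = "2016-01-01",
) -> PatientSeries:
    """Simulate one patient's daily series from an archetype.

    Glucose recursion (all covariates from the *previous* day, mean-centered)::

        g_t = b + ar*(g_{t-1} - b) + carb_effect*(carb_{t-1} - carb_mean)
                + exercise_effect*(burned_{t-1} - burned_mean)
                + weight_effect*(w_{t-1} - w_0) + N(0, noise_sd)

    The same seed always yields the identical series.
    """
    a = archetype
    if a.n_days < 10:
        raise ValueError(f"n_days must be >= 10, got {a.n_days}")
    rng = np.random.default_rng(seed)
    n = a.n_days

    calories = _truncnorm(rng, a.calories_mean, a.calories_sd, 800.0, n)
    fat = _truncnorm(rng, a.fat_mean, a.fat_sd, 5.0, n)
    carbs = _truncnorm(rng, a.carb_mean, a.carb_sd, 10.0, n)
    burned = _truncnorm(rng, a.burned_mean, a.burned_sd, 1.0, n)

    weight = np.empty(n)
    weight[0] = a.initial_weight
    w_steps = rng.normal(a.weight_drift, a.weight_noise_sd, size=n - 1)
    for t in range(1, n):
        weight[t] = np.clip(weight[t - 1] + w_steps[t - 1], 100.0, 400.0)

    glucose = np.empty(n)
    eps = rng.normal(0.0, a.noise_sd, size=n) if a.noise_sd > 0 else np.zeros(n)
    glucose[0] = a.baseline_glucose + eps[0]
    for t in range(1, n):
        glucose[t] = (
            a.baseline_glucose
            + a.ar_coefficient * (glucose[t - 1] - a.baseline_glucose)
            + a.carb_effect * (carbs[t - 1] - a.carb_mean)
            + a.exercise_effect * (burned[t - 1] - a.burned_mean)
            + a.weight_effect * (weight[t - 1] - a.initial_weight)
            + eps[t]
        )
    glucose = np.clip(glucose, 40.0, 600.0)

    dates = pd.date_range(start_date, periods=n, freq="D")
    values = pd.DataFrame(
        {
            "calories": calories,
            "fat_g": fat,
            "carb_g": carbs,
            "calories_burned": burned,
            "weight_lbs": weight,
            "glucose_mgdl": glucose,
        },
        index=dates,
    )

    observed = pd.DataFrame(True, index=dates, columns=FEATURES)
    for col in LIFESTYLE_FEATURES + ["weight_lbs"]:
        observed[col] = ~_missing_mask(rng, n, a.missing_rate_lifestyle,
                                       a.burst_missing, a.burst_length)
    observed["glucose_mgdl"] = ~_missing_mask(rng, n, a.missing_rate_glucose,
                                              a.burst_missing, a.burst_length)

    return PatientSeries(patient_id, values, observed, metadata={"seed": seed})


def _draw_archetype(rng: np.random.Generator) -> PatientArchetype:
    """Draw archetype parameters from ranges that keep the cohort realistic."""
    return PatientArchetype(
        baseline_glucose=rng.uniform(105.0, 195.0),
        ar_coefficient=rng.uniform(0.35, 0.7),
        carb_effect=rng.uniform(0.08, 0.2),
        exercise_effect=-rng.uniform(0.01, 0.05),
        weight_drift=rng.uniform(-0.05, 0.02),
        noise_sd=rng.uniform(6.0, 14.0),
        missing_rate_glucose=rng.uniform(0.08, 0.35),
        missing_rate_lifestyle=rng.uniform(0.02, 0.15),
        n_days=int(rng.integers(150, 191)),
        initial_weight=rng.uniform(145.0, 350.0),
        carb_mean=rng.uniform(180.0, 260.0),
        burned_mean=rng.uniform(200.0, 400.0),
    )


def simulate_cohort(
    n_patients: int = 10,
    n_archetypes: int = 3,
    seed: int = 0,
    scarce_last: bool = True,
    scarce_days: int = 40,
    scarce_missing: float = 0.4,
) -> list[PatientSeries]:
    """Simulate a cohort whose patients share dynamics within archetypes.

    Patients are assigned to archetypes round-robin, so with
    ``n_archetypes < n_patients`` several patients share the same glucose
    dynamics and similarity-weighted transfer learning is informative.  When
    ``scarce_last`` is set, the last patient is data-scarce: a short series
    (``scarce_days`` days) with ``scarce_missing`` glucose missingness, but
    the *same dynamics* as its archetype mates.
    """
    if n_archetypes > n_patients:
        raise ValueError(
            f"n_archetypes ({n_archetypes}) must be <= n_patients ({n_patients})"
        )
    rng = np.random.default_rng(seed)
    archetypes = [_draw_archetype(rng) for _ in range(n_archetypes)]
    patient_seeds = rng.integers(0, 2**31 - 1, size=n_patients)

    cohort: list[PatientSeries] = []
    for i in range(n_patients):
        k = i % n_archetypes
        arch = archetypes[k]
        if scarce_last and i == n_patients - 1:
            arch = replace(arch, n_days=scarce_days, missing_rate_glucose=scarce_missing)
        series = simulate_patient(arch, int(patient_seeds[i]), patient_id=f"p{i + 1}")
        series.metadata.update({"archetype": k, "scarce": scarce_last and i == n_patients - 1})
        cohort.append(series)
    return cohort


# ---------------------------------------------------------------------------
# On-disk dialect: one CSV per patient, empty cell = missing, plus a manifest.
# ---------------------------------------------------------------------------

def write_patient_csv(series: PatientSeries, path: str | Path) -> None:
    """Write the raw-log view (unobserved cells empty) to a CSV file."""
    df = series.masked_values().copy()
    df.insert(0, "date", series.dates.strftime("%Y-%m-%d"))
    df.to_csv(path, index=False, float_format="%.4f")


def read_patient_csv(path: str | Path, patient_id: str | None = None) -> PatientSeries:
    """Read a patient CSV written by :func:`write_patient_csv`."""
    df = pd.read_csv(path, parse_dates=["date"])
    df = df.set_index("date")
    df.index.name = None
    missing = [c for c in FEATURES if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    values = df[FEATURES].astype(float)
    observed = values.notna()
    # keep values finite so downstream math never sees NaN before imputation
    values = values.ffill().bfill()
    pid = patient_id or Path(path).stem.replace("patient_", "")
    return PatientSeries(pid, values, observed)


def write_cohort(cohort: Sequence[PatientSeries], outdir: str | Path) -> Path:
    """Write per-patient CSVs plus a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for series in cohort:
        fname = f"patient_{series.patient_id}.csv"
        write_patient_csv(series, outdir / fname)
        rows.append(
            {
                "patient_id": series.patient_id,
                "file": fname,
                "n_days": series.n_days,
                "archetype": series.metadata.get("archetype", ""),
                "scarce": series.metadata.get("scarce", False),
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(outdir: str | Path) -> list[PatientSeries]:
    """Read a cohort written by :func:`write_cohort`."""
    outdir = Path(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    cohort = []
    for _, row in manifest.iterrows():
        series = read_patient_csv(outdir / row["file"], patient_id=str(row["patient_id"]))
        series.metadata.update(
            {"archetype": row.get("archetype"), "scarce": bool(row.get("scarce", False))}
        )
        cohort.append(series)
    return cohort
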