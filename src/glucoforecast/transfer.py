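"""Transfer learning across patients for data-scarce personalization.

Two strategies, both "pretrain then fine-tune":

* ``all`` — one global model is pretrained on every patient's pooled training
  windows (target included), then fine-tuned on the target's own training
  windows at a reduced learning rate.
* ``dtw`` — a per-target transfer dataset is assembled by sampling training
  windows from *other* patients with probabilities proportional to glucose-
  pattern similarity.  Similarity is measured by dynamic time warping (DTW)
  on the imputed, scaled training-block glucose; smaller DTW distance means a
  larger sampling weight (inverse-distance with a small floor).

``none`` bypasses pretraining and is byte-identical to training on the
target's data alone with the same seed.

DTW here is the classic dynamic program: absolute-difference local cost,
full window (no Sakoe-Chiba band), boundary-matched monotone paths.  DTW is
not a metric (no triangle inequality), so only symmetry and nonnegativity
are relied on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from glucoforecast.forecaster import LSTMConfig, LSTMParams, TrainResult, train
from glucoforecast.preprocess import PreparedPatient, WindowedDataset


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Dynamic-time-warping distance between two 1-D sequences.

    Minimum, over all monotone boundary-matched warping paths, of the summed
    absolute differences of matched elements.  Symmetric and nonnegative;
    zero for identical sequences.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("dtw_distance requires non-empty sequences")
    n, m = a.size, b.size
    cost = np.abs(a[:, None] - b[None, :])
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            acc[i, j] = cost[i - 1, j - 1] + min(
                acc[i - 1, j], acc[i, j - 1], acc[i - 1, j - 1]
            )
    return float(acc[n, m])


def similarity_matrix(glucose_by_patient: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise DTW distance matrix (symmetric, zero diagonal)."""
    ids = list(glucose_by_patient)
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, pa in enumerate(ids):
        for pb in ids[i + 1 :]:
            d = dtw_distance(glucose_by_patient[pa], glucose_by_patient[pb])
            mat.loc[pa, pb] = d
            mat.loc[pb, pa] = d
    return mat


def similarity_weights(distances: np.ndarray) -> np.ndarray:
    """Donor sampling weights, inverse to DTW distance.

    ``w_j ∝ 1/(d_j + eps)`` with ``eps = 1e-6 * max(d) + 1e-12`` so a
    zero-distance donor dominates without dividing by zero; normalized to
    sum to 1.  Strictly decreasing in distance.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 1:
        raise ValueError("need at least one donor")
    eps = 1e-6 * (d.max() if d.size else 0.0) + 1e-12
    w = 1.0 / (d + eps)
    return w / w.sum()


@dataclass
class TransferPlan:
    """What to transfer and how: strategy, donor weights, sample budget, and
    the pretrain / fine-tune training configurations."""

    strategy: str  # one of {"none", "all", "dtw"}
    target_patient: str
    pretrain_config: LSTMConfig
    finetune_config: LSTMConfig | None = None
    sampling_weights: dict[str, float] | None = None  # per-donor, dtw only
    sample_budget: int | None = None  # default: 120 * n_donors

    def __post_init__(self) -> None:
        if self.strategy not in ("none", "all", "dtw"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.sample_budget is not None and self.sample_budget < 0:
            raise ValueError("sample_budget must be >= 0")
        if self.finetune_config is None:
            # fine-tune continues at a tenth of the pretraining learning rate
            self.finetune_config = replace(
                self.pretrain_config,
                learning_rate=self.pretrain_config.learning_rate * 0.1,
            )


def make_plan(
    target: str,
    prepared: dict[str, PreparedPatient],
    strategy: str,
    config: LSTMConfig,
    sample_budget: int | None = None,
) -> TransferPlan:
    """Build a TransferPlan, computing DTW weights when strategy is ``dtw``."""
    weights = None
    if strategy == "dtw":
        donors = [p for p in prepared if p != target]
        if not donors:
            raise ValueError("dtw strategy needs at least one donor patient")
        dists = np.array([
            dtw_distance(prepared[target].scaled_train_glucose(),
                         prepared[d].scaled_train_glucose())
            for d in donors
        ])
        weights = dict(zip(donors, similarity_weights(dists)))
        if sample_budget is None:
            sample_budget = 120 * len(donors)
    return TransferPlan(strategy, target, config,
                        sampling_weights=weights, sample_budget=sample_budget)


def build_transfer_dataset(
    target: str,
    prepared: dict[str, PreparedPatient],
    plan: TransferPlan,
    seed: int = 0,
) -> WindowedDataset:
    """Assemble the pretraining dataset for one target patient.

    ``all``: every patient's training windows concatenated (target included),
    unweighted.  ``dtw``: ``sample_budget`` windows drawn with replacement
    from donors (target excluded), donors chosen with probability
    ``sampling_weights``, windows uniform within donor.  Seeded.
    """
    if plan.strategy == "all":
        return WindowedDataset.concatenate([p.train for p in prepared.values()])
    if plan.strategy != "dtw":
        raise ValueError("no transfer dataset for strategy 'none'")
    donors = [p for p in prepared if p != target]
    if not donors:
        raise ValueError("no donor patients available")
    if plan.sampling_weights is None:
        raise ValueError("dtw strategy requires sampling_weights")
    budget = plan.sample_budget if plan.sample_budget is not None else 120 * len(donors)
    if budget <= 0:
        raise ValueError("dtw strategy requires a positive sample_budget")
    w = np.array([plan.sampling_weights[d] for d in donors])
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    chosen_donors = rng.choice(len(donors), size=budget, p=w)
    inputs, targets, days = [], [], []
    for k in chosen_donors:
        ds = prepared[donors[k]].train
        i = rng.integers(len(ds))
        inputs.append(ds.inputs[i])
        targets.append(ds.targets[i])
        days.append(ds.day_indices[i])
    return WindowedDataset(np.stack(inputs), np.asarray(targets),
                           np.asarray(days, dtype=int))


def pretrain_finetune(
    target: str,
    prepared: dict[str, PreparedPatient],
    plan: TransferPlan,
    seed: int = 0,
) -> TrainResult:
    """Pretrain on the transfer dataset, then fine-tune on the target.

    Strategy ``none`` bypasses pretraining entirely (identical to training on
    the target alone with the same seed).  Fine-tuning keeps all layers
    unfrozen and, by default, a tenth of the pretraining learning rate.  With
    zero target training windows, the pretrained parameters are returned
    unchanged.
    """
    tgt = prepared[target]
    assert plan.finetune_config is not None
    if plan.strategy == "none":
        return train(tgt.train, tgt.val, plan.finetune_config, scaler=tgt.scaler)

    transfer_ds = build_transfer_dataset(target, prepared, plan, seed=seed)
    empty = WindowedDataset(
        np.empty((0,) + transfer_ds.inputs.shape[1:]), np.empty(0), np.empty(0, dtype=int)
    )
    # pretraining selects its last epoch by training loss (no target leakage)
    pre = train(transfer_ds, empty, plan.pretrain_config)
    if len(tgt.train) == 0:
        return pre
    return train(tgt.train, tgt.val, plan.finetune_config,
                 init=pre.params, scaler=tgt.scaler)
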