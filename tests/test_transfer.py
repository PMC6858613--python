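import numpy as np
import pytest

from glucoforecast.forecaster import LSTMConfig, forward, train
from glucoforecast.preprocess import prepare_patient, inverse_scale_glucose
from glucoforecast.transfer import (
    TransferPlan,
    build_transfer_dataset,
    dtw_distance,
    make_plan,
    pretrain_finetune,
    similarity_matrix,
    similarity_weights,
)


def brute_force_dtw(a, b):
    """Exhaustive enumeration of all monotone boundary-matched warping paths.

    Depth-first search over steps (down, right, diagonal) from (0,0) to
    (n-1, m-1); independent of the package's dynamic program.
    """
    a, b = list(a), list(b)
    n, m = len(a), len(b)
    best = [np.inf]

    def walk(i, j, cost):
        cost += abs(a[i] - b[j])
        if i == n - 1 and j == m - 1:
            best[0] = min(best[0], cost)
            return
        if i + 1 < n:
            walk(i + 1, j, cost)
        if j + 1 < m:
            walk(i, j + 1, cost)
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost)

    walk(0, 0, 0.0)
    return best[0]


def test_dtw_simple_values():
    assert dtw_distance([1, 2, 3], [1, 2, 3]) == 0.0
    assert dtw_distance([0.0], [3.0]) == 3.0
    # [1,2,3] vs [1,2,2,3]: the repeated 2 is absorbed by a zero-cost warp
    assert dtw_distance([1, 2, 3], [1, 2, 2, 3]) == 0.0


def test_dtw_rejects_empty():
    with pytest.raises(ValueError):
        dtw_distance([], [1.0])


def test_dtw_matches_brute_force_enumeration(rng):
    """Dynamic program equals exhaustive path enumeration, 200 random pairs."""
    for _ in range(200):
        n, m = rng.integers(1, 7, size=2)
        a = rng.normal(size=int(n)).round(2)
        b = rng.normal(size=int(m)).round(2)
        assert dtw_distance(a, b) == pytest.approx(brute_force_dtw(a, b), abs=1e-12)


def test_dtw_symmetry_and_nonnegativity(rng):
    for _ in range(50):
        a = rng.normal(size=int(rng.integers(1, 20)))
        b = rng.normal(size=int(rng.integers(1, 20)))
        d = dtw_distance(a, b)
        assert d >= 0
        assert d == pytest.approx(dtw_distance(b, a), abs=1e-12)


def test_similarity_matrix_symmetric_zero_diagonal(small_cohort):
    glucose = {s.patient_id: s.glucose()[:30] for s in small_cohort}
    mat = similarity_matrix(glucose)
    assert np.allclose(mat.values, mat.values.T)
    assert np.all(np.diag(mat.values) == 0.0)
    assert (mat.values >= 0).all()


def test_similarity_weights_rules():
    w = similarity_weights(np.array([2.0, 2.0, 2.0]))
    assert np.allclose(w, 1 / 3)
    w = similarity_weights(np.array([0.0, 100.0, 100.0]))
    assert w[0] > 0.999
    w = similarity_weights(np.array([1.0, 2.0, 5.0, 0.3]))
    assert abs(w.sum() - 1.0) < 1e-12
    # strictly decreasing in distance
    assert w[3] > w[0] > w[1] > w[2]


@pytest.fixture(scope="module")
def prepared_cohort(small_cohort):
    return {s.patient_id: prepare_patient(s) for s in small_cohort}


def test_plan_validation(tiny_config):
    with pytest.raises(ValueError):
        TransferPlan("bogus", "p1", tiny_config)
    with pytest.raises(ValueError):
        TransferPlan("dtw", "p1", tiny_config, sample_budget=-1)


def test_degenerate_weights_sample_single_donor(prepared_cohort, tiny_config):
    target = "p1"
    donors = [p for p in prepared_cohort if p != target]
    weights = {d: 0.0 for d in donors}
    weights[donors[0]] = 1.0
    plan = TransferPlan("dtw", target, tiny_config,
                        sampling_weights=weights, sample_budget=50)
    ds = build_transfer_dataset(target, prepared_cohort, plan, seed=1)
    donor_targets = set(np.round(prepared_cohort[donors[0]].train.targets, 12))
    assert set(np.round(ds.targets, 12)) <= donor_targets


def test_sampling_shares_match_weights(prepared_cohort, tiny_config):
    """Binomial oracle: donor-1 share within 3*sqrt(p(1-p)/n) of its weight."""
    target = "p1"
    donors = [p for p in prepared_cohort if p != target][:2]
    two = {d: prepared_cohort[d] for d in donors}
    two[target] = prepared_cohort[target]
    plan = TransferPlan("dtw", target, tiny_config,
                        sampling_weights={donors[0]: 0.7, donors[1]: 0.3},
                        sample_budget=10_000)
    ds = build_transfer_dataset(target, two, plan, seed=2)
    donor1_targets = set(np.round(prepared_cohort[donors[0]].train.targets, 12))
    share = np.mean([round(t, 12) in donor1_targets for t in ds.targets])
    assert abs(share - 0.7) <= 3 * np.sqrt(0.7 * 0.3 / 10_000)


def test_transfer_dataset_determinism(prepared_cohort, tiny_config):
    plan = make_plan("p1", prepared_cohort, "dtw", tiny_config, sample_budget=200)
    a = build_transfer_dataset("p1", prepared_cohort, plan, seed=3)
    b = build_transfer_dataset("p1", prepared_cohort, plan, seed=3)
    assert np.array_equal(a.inputs, b.inputs)
    assert np.array_equal(a.targets, b.targets)


def test_all_strategy_pools_everyone(prepared_cohort, tiny_config):
    plan = make_plan("p1", prepared_cohort, "all", tiny_config)
    ds = build_transfer_dataset("p1", prepared_cohort, plan)
    assert len(ds) == sum(len(p.train) for p in prepared_cohort.values())


def test_strategy_none_is_plain_training(prepared_cohort, tiny_config):
    target = "p2"
    plan = make_plan(target, prepared_cohort, "none", tiny_config)
    # bypass contract: identical to forecaster.train on the target alone,
    # but note the plan's fine-tune config carries the reduced learning rate
    assert plan.finetune_config is not None
    via_plan = pretrain_finetune(target, prepared_cohort, plan, seed=0)
    prep = prepared_cohort[target]
    direct = train(prep.train, prep.val, plan.finetune_config, scaler=prep.scaler)
    assert np.array_equal(via_plan.params.flatten(), direct.params.flatten())


def test_finetune_with_zero_target_windows_returns_pretrained(prepared_cohort, tiny_config):
    import copy
    target = "p1"
    mutated = dict(prepared_cohort)
    prep = copy.copy(prepared_cohort[target])
    empty = prepared_cohort[target].train
    from glucoforecast.preprocess import WindowedDataset
    prep.train = WindowedDataset(np.empty((0,) + empty.inputs.shape[1:]),
                                 np.empty(0), np.empty(0, dtype=int))
    mutated[target] = prep
    plan = make_plan(target, mutated, "dtw", tiny_config, sample_budget=100)
    result = pretrain_finetune(target, mutated, plan, seed=0)
    pre_ds = build_transfer_dataset(target, mutated, plan, seed=0)
    direct = train(pre_ds, prep.train, plan.pretrain_config)
    # identical pretraining outcome, untouched by fine-tuning
    assert np.array_equal(result.params.flatten(), direct.params.flatten())


def test_architecture_mismatch_rejected(prepared_cohort, tiny_config):
    from dataclasses import replace
    plan = make_plan("p1", prepared_cohort, "all", tiny_config)
    plan.finetune_config = replace(tiny_config, n_lstm_units=tiny_config.n_lstm_units + 1)
    with pytest.raises(ValueError, match="architecture mismatch"):
        pretrain_finetune("p1", prepared_cohort, plan, seed=0)


def test_dtw_transfer_helps_scarce_patient(prepared_cohort):
    """The scarce patient's test RMSE with DTW transfer should not be worse
    than no-transfer for a typical seed (the full replicate suite lives in
    the acceptance tests)."""
    target = [p for p in prepared_cohort
              if prepared_cohort[p].series.metadata.get("scarce")][0]
    cfg = LSTMConfig(dropout_rate=0.1, n_lstm_units=12, n_dense_units=8,
                     epochs=150, seed=3)
    prep = prepared_cohort[target]
    refs = inverse_scale_glucose(prep.test.targets, prep.scaler)

    def test_rmse(strategy):
        plan = make_plan(target, prepared_cohort, strategy, cfg)
        res = pretrain_finetune(target, prepared_cohort, plan, seed=3)
        preds = inverse_scale_glucose(forward(prep.test.inputs, res.params), prep.scaler)
        return np.sqrt(np.mean((preds - refs) ** 2))

    assert test_rmse("dtw") <= test_rmse("none") * 1.05
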