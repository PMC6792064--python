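"""Splits, scaling, coding, metrics, tuning and the benchmark protocol."""

import numpy as np
import pandas as pd
import pytest

from simkern.benchmark import (accuracy, dummy_code, fit_predict_kernelized,
                               fit_predict_standard, make_splits, r_squared,
                               run_benchmark, scale_unit_interval,
                               subsample_training, tune_evaluate)
from simkern.datasets import FeatureMeta
from simkern.kernel import SimilarityKernel


# ------------------------------------------------------------------- splits

def test_split_sizes_and_partition():
    splits = make_splits(1000, repetitions=3, seed=1)
    for sp in splits:
        assert len(sp.train) == 500
        assert len(sp.validation) == 250
        assert len(sp.test) == 250
        union = np.concatenate([sp.train, sp.validation, sp.test])
        assert len(np.unique(union)) == 1000
    assert not np.array_equal(splits[0].train, splits[1].train)
    with pytest.raises(ValueError):
        make_splits(5)


def test_subsample_sizes_and_determinism():
    sp = make_splits(1000, 1, seed=2)[0]
    sub = subsample_training(sp, 0.1, seed=3)
    assert len(sub) == 50
    assert set(sub) <= set(sp.train)
    np.testing.assert_array_equal(sub, subsample_training(sp, 0.1, seed=3))
    np.testing.assert_array_equal(subsample_training(sp, 1.0, seed=3),
                                  sp.train)
    with pytest.raises(ValueError):
        subsample_training(sp, 1.5, seed=3)


def test_subsample_retries_for_class_diversity():
    sp = make_splits(200, 1, seed=4)[0]
    y = np.array(["a"] * 199 + ["b"], dtype=object)
    y[sp.train[0]] = "b"  # exactly one positive in training
    got_both = sum(
        len(set(y[subsample_training(sp, 0.1, seed=s, y=y)])) >= 2
        for s in range(10))
    assert got_both >= 8  # nearly always finds both classes by retrying


# ------------------------------------------------------------------ scaling

def test_scaling_rule_examples():
    train = pd.DataFrame({"a": [2.0, 4.0, 6.0], "c": [7.0, 7.0, 7.0]})
    rule, scaled = scale_unit_interval(train)
    assert scaled["a"].tolist() == [0.0, 0.5, 1.0]
    assert scaled["c"].tolist() == [0.0, 0.0, 0.0]  # zero-range column
    test = rule.transform(pd.DataFrame({"a": [8.0], "c": [9.0]}))
    assert test["a"].iloc[0] == pytest.approx(1.5)  # no clipping


def test_dummy_code_shapes_and_errors(toy_classification_dataset):
    ds = toy_classification_dataset
    coded = dummy_code(ds.X, ds.feature_meta)
    assert coded.shape == (ds.n_samples, 1 + 1 + 3)
    assert {"colour=red", "colour=green", "colour=blue"} <= set(coded.columns)
    bad = ds.X.copy()
    bad.loc[0, "colour"] = "violet"
    with pytest.raises(ValueError, match="violet"):
        dummy_code(bad, ds.feature_meta)


# ------------------------------------------------------------------ metrics

def test_metric_hand_examples():
    assert accuracy(["a", "b", "a"], ["a", "b", "a"]) == 1.0
    # binary TP=3 TN=2 FP=1 FN=0 -> 5/6
    truth = ["p", "p", "p", "n", "n", "n"]
    pred = ["p", "p", "p", "p", "n", "n"]
    assert accuracy(truth, pred) == pytest.approx(5 / 6)
    assert r_squared([1, 2, 3], [1, 2, 3]) == 1.0
    assert r_squared([1, 2, 3], [2, 2, 2]) == 0.0
    assert r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        accuracy([], [])
    with pytest.raises(ValueError):
        r_squared([1.0, 1.0], [1.0, 2.0])


def test_metrics_match_brute_force_reimplementation():
    rng = np.random.default_rng(21)
    for _ in range(200):
        n = rng.integers(2, 30)
        t = rng.integers(0, 3, size=n)
        p = rng.integers(0, 3, size=n)
        assert accuracy(t, p) == pytest.approx(
            sum(int(a == b) for a, b in zip(t, p)) / n)
        y = rng.normal(size=n)
        if np.var(y) == 0:
            continue
        yhat = rng.normal(size=n)
        sse = sum((a - b) ** 2 for a, b in zip(yhat, y))
        sst = sum((a - np.mean(y)) ** 2 for a in y)
        assert r_squared(y, yhat) == pytest.approx(1 - sse / sst)


def test_accuracy_permutation_invariant():
    rng = np.random.default_rng(22)
    t = rng.integers(0, 2, size=50)
    p = rng.integers(0, 2, size=50)
    perm = rng.permutation(50)
    assert accuracy(t, p) == accuracy(t[perm], p[perm])


# --------------------------------------------------------------- predictors

def test_nn1_predicts_nearest_training_row():
    Xtr = np.array([[0.0, 0.0], [1.0, 1.0]])
    ytr = np.array(["lo", "hi"], dtype=object)
    pred = fit_predict_standard("nn1", {}, Xtr, ytr,
                                np.array([[0.1, 0.0], [0.9, 1.0], [0, 0]]),
                                "classification")
    assert pred.tolist() == ["lo", "hi", "lo"]


def test_linear_svm_separates_separable_data():
    rng = np.random.default_rng(23)
    X = np.vstack([rng.normal(-2, 0.3, size=(20, 2)),
                   rng.normal(2, 0.3, size=(20, 2))])
    y = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
    pred = fit_predict_standard("linear-svm", {"C": 1000.0}, X, y, X,
                                "classification")
    assert accuracy(y, pred) == 1.0


def test_kernelized_nn1_follows_max_similarity():
    K_tt = np.eye(3)
    ytr = np.array(["a", "b", "c"], dtype=object)
    K_st = np.array([[0.1, 0.9, 0.2], [1.0, 0.0, 0.0]])
    pred = fit_predict_kernelized("simkern-nn1", {}, K_tt, ytr, K_st,
                                  "classification")
    assert pred.tolist() == ["b", "a"]
    with pytest.raises(ValueError):
        fit_predict_kernelized("simkern-nn1", {}, K_tt, ytr,
                               np.ones((2, 4)), "classification")


def test_tune_evaluate_selects_planted_configuration():
    truth = {"validation": np.array([0., 0., 1., 1.]),
             "test": np.array([0., 1.])}

    def fit_score(hyper, part):
        if hyper["magic"] == 7:  # the planted optimum predicts perfectly
            return truth[part]
        return truth[part][::-1]

    fit_score.truth = truth
    grid = ({"magic": 1}, {"magic": 7}, {"magic": 9})
    score, chosen = tune_evaluate("toy", grid, fit_score, "classification")
    assert chosen == {"magic": 7}
    assert score == 1.0


# ---------------------------------------------------------------- benchmark

def _truth_kernel(ds):
    K = (ds.y[:, None] == ds.y[None, :]).astype(float)
    return SimilarityKernel(list(ds.sample_ids), K)


def _ones_kernel(ds):
    return SimilarityKernel(list(ds.sample_ids),
                            np.ones((ds.n_samples, ds.n_samples)))


def test_perfect_indicator_kernel_gives_ceiling_accuracy(netflow_dataset):
    """Kernel 1-NN and kernelized SVM reach accuracy 1.0 with the
    ground-truth indicator kernel."""
    ds = netflow_dataset
    res = run_benchmark(ds, _truth_kernel(ds),
                        algorithms=["simkern-nn1", "simkern-svm"],
                        fractions=(1.0,), repetitions=3, seed=5)
    assert (res["value"] == 1.0).all()


def test_all_ones_kernel_gives_floor_performance(boolean_dataset):
    """A constant kernel carries no information: accuracy collapses to
    the majority-class rate."""
    ds = boolean_dataset
    majority = pd.Series(ds.y).value_counts(normalize=True).iloc[0]
    res = run_benchmark(ds, _ones_kernel(ds),
                        algorithms=["simkern-svm", "simkern-rf"],
                        fractions=(1.0,), repetitions=3, seed=5)
    assert res["value"].max() <= majority + 0.1


def test_run_benchmark_shape_determinism_and_id_checks(netflow_dataset):
    ds = netflow_dataset
    kern = _truth_kernel(ds)
    res = run_benchmark(ds, kern, algorithms=["nn1", "simkern-nn1"],
                        fractions=(0.2, 1.0), repetitions=2, seed=6)
    assert len(res) == 2 * 2 * 2  # algorithms x fractions x repetitions
    assert sorted(res["repetition"].unique()) == [1, 2]
    res2 = run_benchmark(ds, kern, algorithms=["nn1", "simkern-nn1"],
                         fractions=(0.2, 1.0), repetitions=2, seed=6)
    pd.testing.assert_frame_equal(res, res2)
    bad = SimilarityKernel([f"x{i}" for i in range(ds.n_samples)], kern.K)
    with pytest.raises(ValueError):
        run_benchmark(ds, bad)


def test_standard_learning_curve_trends_upward(netflow_dataset):
    """More training data helps feature-based learners: the median metric
    rises from the smallest to the largest subsample fraction (trend
    check, not strict per-step ordering)."""
    res = run_benchmark(netflow_dataset, None, algorithms=["rf"],
                        fractions=(0.1, 0.5, 1.0), repetitions=5, seed=8)
    med = res.groupby("fraction")["value"].median()
    assert med.loc[1.0] > med.loc[0.1]
    # weak monotonicity within noise: no step loses more than 5 points
    assert (np.diff(med.loc[[0.1, 0.5, 1.0]]) > -0.05).all()


def test_no_information_leak_into_scaling(toy_classification_dataset):
    """The scaling rule is fitted on the training subsample only."""
    ds = toy_classification_dataset
    from simkern.benchmark import _prepare_cell

    sp = make_splits(ds.n_samples, 1, seed=7)[0]
    cell = _prepare_cell(ds, None, sp, 0.5, seed=7)
    # training block scaled to [0, 1]; recomputing the rule from the
    # subsample reproduces validation/test blocks exactly
    coded = dummy_code(ds.X, ds.feature_meta)
    rule, _ = scale_unit_interval(coded.iloc[cell.sub_train])
    np.testing.assert_allclose(
        cell.scaled["validation"],
        rule.transform(coded.iloc[sp.validation]).to_numpy())
    assert set(cell.sub_train).isdisjoint(sp.test)
    assert set(sp.validation).isdisjoint(sp.test)
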