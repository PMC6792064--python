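"""Standard versus kernelized ML benchmarking.

The comparison protocol: each repetition draws a fresh 50/25/25
train/validation/test split; training may be restricted to a subsample
fraction of the training set (learning curves); features are min-max
scaled to [0, 1] and categorical features dummy-coded for SVM and
nearest-neighbour learners (random forests see the raw columns);
hyperparameters are chosen on the validation set, the winning
configuration is refit on the training subsample and scored once on the
test set.  Metrics are exact-match accuracy for classification and the
coefficient of determination R^2 for regression.

Standard algorithms consume feature vectors; SimKern algorithms consume
kernel submatrices: the kernelized SVM takes the precomputed Gram matrix
directly, the kernelized random forest uses each sample's vector of
similarities to the training samples as its features, and the kernelized
one-nearest-neighbour predicts the outcome of the most similar training
sample.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.svm import SVC, SVR

__all__ = [
    "SplitSpec", "make_splits", "subsample_training", "ScalingRule",
    "scale_unit_interval", "dummy_code", "accuracy", "r_squared",
    "tune_evaluate", "run_benchmark", "ALGORITHMS", "best_kernelized",
]

SUBSAMPLE_FRACTIONS = (0.05, 0.10, 0.20, 0.50, 1.00)

_C_GRID = tuple(float(c) for c in np.logspace(-2, 3, 6))
_GAMMA_GRID = tuple(float(g) for g in np.logspace(-3, 2, 6))
_RF_GRID = tuple({"n_estimators": n, "max_depth": d}
                 for n in (100, 500) for d in (None, 10))

ALGORITHMS = {
    "linear-svm": {"group": "standard",
                   "grid": tuple({"C": c} for c in _C_GRID)},
    "rbf-svm": {"group": "standard",
                "grid": tuple({"C": c, "gamma": g}
                              for c in _C_GRID for g in _GAMMA_GRID)},
    "rf": {"group": "standard", "grid": _RF_GRID},
    "nn1": {"group": "standard", "grid": ({},)},
    "simkern-svm": {"group": "simkern",
                    "grid": tuple({"C": c} for c in _C_GRID)},
    "simkern-rf": {"group": "simkern", "grid": _RF_GRID},
    "simkern-nn1": {"group": "simkern", "grid": ({},)},
}


# ------------------------------------------------------------------ metrics

def accuracy(truth, predicted) -> float:
    """Exact-match fraction; reduces to (TP+TN)/(TP+TN+FP+FN) for two
    classes."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.size == 0 or truth.shape != predicted.shape:
        raise ValueError("need equal-length nonempty label vectors")
    return float(np.mean(truth == predicted))


def r_squared(truth, predicted) -> float:
    """1 - SSE/SST around the truth mean; may be negative."""
    y = np.asarray(truth, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.size < 2 or y.shape != yhat.shape:
        raise ValueError("need equal-length vectors with >= 2 entries")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("R^2 undefined for zero-variance truth")
    return 1.0 - float(np.sum((yhat - y) ** 2)) / sst


# ------------------------------------------------------------------- splits

@dataclass(frozen=True)
class SplitSpec:
    repetition: int
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int = 0

    def __post_init__(self):
        parts = np.concatenate([self.train, self.validation, self.test])
        if len(set(parts.tolist())) != parts.size:
            raise ValueError("split index sets overlap")


def make_splits(N: int, repetitions: int = 10, seed: int = 0) -> list:
    """Fresh 50/25/25 permutation splits per repetition.

    Sizes are floor(N/2) train and floor(N/4) validation, test takes the
    remainder.
    """
    if N < 8:
        raise ValueError("need N >= 8 to populate all three sets")
    out = []
    for rep in range(1, repetitions + 1):
        rng = np.random.default_rng(np.random.SeedSequence(seed,
                                                           spawn_key=(rep,)))
        perm = rng.permutation(N)
        n_tr, n_va = N // 2, N // 4
        out.append(SplitSpec(rep, perm[:n_tr], perm[n_tr:n_tr + n_va],
                             perm[n_tr + n_va:], seed=seed))
    return out


def subsample_training(split: SplitSpec, fraction: float, seed: int,
                       y=None) -> np.ndarray:
    """ceil(fraction * |train|) training indices, sampled without
    replacement; for classification the draw is retried with a shifted
    seed until at least two classes are present (when the training set
    has two)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    train = split.train
    m = int(np.ceil(fraction * train.size))
    if m == train.size:
        return train.copy()
    for attempt in range(50):
        rng = np.random.default_rng(np.random.SeedSequence(
            seed, spawn_key=(split.repetition, int(fraction * 10000),
                             attempt)))
        sub = rng.choice(train, size=m, replace=False)
        if y is None or m < 2:
            return sub
        labels = np.asarray(y)[sub]
        if len(set(labels.tolist())) >= 2 or \
                len(set(np.asarray(y)[train].tolist())) < 2:
            return sub
    return sub


# ------------------------------------------------------- feature pipelines

@dataclass
class ScalingRule:
    """Min-max rule fitted on training data only; columns with zero range
    map to 0; validation/test values outside the training range are NOT
    clipped."""

    mins: pd.Series
    ranges: pd.Series

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for c in X.columns:
            r = self.ranges[c]
            out[c] = 0.0 if r == 0 else (X[c] - self.mins[c]) / r
        return out


def scale_unit_interval(train: pd.DataFrame):
    """Fit the [0, 1] scaling rule on training data; returns (rule,
    transformed training frame)."""
    mins = train.min(axis=0)
    ranges = train.max(axis=0) - mins
    rule = ScalingRule(mins, ranges)
    return rule, rule.transform(train)


def dummy_code(X: pd.DataFrame, feature_meta) -> pd.DataFrame:
    """One indicator column per categorical level (level sets fixed from
    the dataset schema); binary and continuous columns pass through."""
    cols = []
    for m in feature_meta:
        if m.kind == "categorical":
            col = X[m.name].astype(str)
            unseen = set(col.unique()) - set(map(str, m.levels))
            if unseen:
                raise ValueError(f"unseen level(s) {sorted(unseen)} in "
                                 f"column {m.name!r}")
            for lev in m.levels:
                cols.append(pd.Series((col == str(lev)).astype(float),
                                      name=f"{m.name}={lev}", index=X.index))
        else:
            cols.append(X[m.name].astype(float))
    return pd.concat(cols, axis=1)


def integer_code(X: pd.DataFrame, feature_meta) -> pd.DataFrame:
    """Categorical levels as integer codes (for tree learners)."""
    out = X.copy()
    for m in feature_meta:
        if m.kind == "categorical":
            lut = {str(lev): i for i, lev in enumerate(m.levels)}
            out[m.name] = X[m.name].astype(str).map(lut)
    return out.astype(float)


# ------------------------------------------------------------- predictors

def _make_rf(task, hyper, seed):
    # mtry follows the classic randomForest convention: sqrt(p) for
    # classification, p/3 for regression
    if task == "classification":
        return RandomForestClassifier(random_state=seed, n_jobs=1,
                                      max_features="sqrt", **hyper)
    return RandomForestRegressor(random_state=seed, n_jobs=1,
                                 max_features=1 / 3, **hyper)


class _ConstantPredictor:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        n = X.shape[0]
        return np.full(n, self.value, dtype=object if
                       isinstance(self.value, str) else float)


def _nn1_predict(train_X, train_y, score_X):
    d = ((score_X[:, None, :] - train_X[None, :, :]) ** 2).sum(axis=2)
    return np.asarray(train_y)[np.argmin(d, axis=1)]


def fit_predict_standard(alg: str, hyper: dict, train_X, train_y, score_X,
                         task: str, seed: int = 0):
    """Fit a feature-based learner and predict the score rows."""
    train_y = np.asarray(train_y)
    if task == "classification" and len(set(train_y.tolist())) < 2:
        warnings.warn("single-class training set; constant predictor")
        return _ConstantPredictor(train_y[0]).predict(score_X)
    Xtr = np.asarray(train_X, dtype=float)
    Xsc = np.asarray(score_X, dtype=float)
    if alg == "nn1":
        return _nn1_predict(Xtr, train_y, Xsc)
    if alg == "linear-svm":
        est = (SVC(kernel="linear", **hyper) if task == "classification"
               else SVR(kernel="linear", **hyper))
    elif alg == "rbf-svm":
        est = (SVC(kernel="rbf", **hyper) if task == "classification"
               else SVR(kernel="rbf", **hyper))
    elif alg == "rf":
        est = _make_rf(task, hyper, seed)
    else:
        raise ValueError(f"not a standard algorithm: {alg!r}")
    est.fit(Xtr, train_y)
    return est.predict(Xsc)


def fit_predict_kernelized(alg: str, hyper: dict, K_tt, train_y, K_st,
                           task: str, seed: int = 0):
    """Fit a kernel-consuming learner.

    K_tt is the train x train kernel submatrix, K_st the score x train
    block.  simkern-rf treats similarity rows as feature vectors;
    simkern-nn1 predicts the outcome of the argmax-similarity training
    sample (ties broken toward the lowest index).
    """
    K_tt = np.asarray(K_tt, dtype=float)
    K_st = np.asarray(K_st, dtype=float)
    train_y = np.asarray(train_y)
    if K_tt.shape[0] != K_tt.shape[1] or K_st.shape[1] != K_tt.shape[0]:
        raise ValueError("kernel submatrix shapes do not conform")
    if task == "classification" and len(set(train_y.tolist())) < 2:
        warnings.warn("single-class training set; constant predictor")
        return _ConstantPredictor(train_y[0]).predict(K_st)
    if alg == "simkern-nn1":
        return train_y[np.argmax(K_st, axis=1)]
    if alg == "simkern-svm":
        est = (SVC(kernel="precomputed", **hyper)
               if task == "classification"
               else SVR(kernel="precomputed", **hyper))
        est.fit(K_tt, train_y)
        return est.predict(K_st)
    if alg == "simkern-rf":
        est = _make_rf(task, hyper, seed)
        est.fit(K_tt, train_y)
        return est.predict(K_st)
    raise ValueError(f"not a kernelized algorithm: {alg!r}")


# -------------------------------------------------------------- evaluation

def _metric(task: str):
    return accuracy if task == "classification" else r_squared


def tune_evaluate(alg: str, grid, fit_score, task: str):
    """Grid tuning on validation, refit on train, single test score.

    ``fit_score(hyper, part)`` must return predictions for partition
    ``part`` in {"validation", "test"} from a model fitted on the
    (subsampled) training data under hyperparameters ``hyper``; truth
    vectors are supplied via ``fit_score.truth``.
    Ties in validation score go to the first grid entry.
    """
    metric = _metric(task)
    best_hyper, best_score = None, -np.inf
    for hyper in grid:
        try:
            pred = fit_score(hyper, "validation")
            score = metric(fit_score.truth["validation"], pred)
        except Exception:
            continue
        if score > best_score:
            best_hyper, best_score = hyper, score
    if best_hyper is None:
        raise RuntimeError(f"all {alg} fits failed")
    pred = fit_score(best_hyper, "test")
    return metric(fit_score.truth["test"], pred), best_hyper


@dataclass
class _CellData:
    """Prepared per-(repetition, fraction) inputs for all algorithms."""

    sub_train: np.ndarray
    scaled: dict          # partition -> dummy-coded scaled matrix
    raw: dict             # partition -> integer-coded raw matrix (for RF)
    truth: dict           # partition -> outcome vector
    K_tt: np.ndarray | None
    K_blocks: dict        # partition -> score x train kernel block


def _prepare_cell(dataset, kernel, split, fraction, seed):
    sub = subsample_training(split, fraction, seed,
                             y=dataset.y if
                             dataset.task == "classification" else None)
    parts = {"train": sub, "validation": split.validation,
             "test": split.test}
    meta = dataset.feature_meta
    dummied = dummy_code(dataset.X, meta)
    rule, _ = scale_unit_interval(dummied.iloc[sub])
    scaled = {p: rule.transform(dummied.iloc[idx]).to_numpy(dtype=float)
              for p, idx in parts.items()}
    raw_all = integer_code(dataset.X, meta)
    raw = {p: raw_all.iloc[idx].to_numpy(dtype=float)
           for p, idx in parts.items()}
    truth = {p: dataset.y[idx] for p, idx in parts.items()}
    K_tt, K_blocks = None, {}
    if kernel is not None:
        K_tt = kernel.submatrix(sub, sub)
        K_blocks = {p: kernel.submatrix(idx, sub)
                    for p, idx in parts.items() if p != "train"}
    return _CellData(sub, scaled, raw, truth, K_tt, K_blocks)


def _make_fit_score(alg, cell, task, seed):
    group = ALGORITHMS[alg]["group"]

    def fit_score(hyper, part):
        if group == "standard":
            X = cell.raw if alg == "rf" else cell.scaled
            return fit_predict_standard(alg, hyper, X["train"],
                                        cell.truth["train"], X[part],
                                        task, seed=seed)
        return fit_predict_kernelized(alg, hyper, cell.K_tt,
                                      cell.truth["train"],
                                      cell.K_blocks[part], task, seed=seed)

    fit_score.truth = cell.truth
    return fit_score


def run_benchmark(dataset, kernel=None, algorithms=None,
                  fractions=SUBSAMPLE_FRACTIONS, repetitions: int = 10,
                  seed: int = 0, kernel_name: str = "") -> pd.DataFrame:
    """Full factorial (algorithm x fraction x repetition) benchmark.

    Returns the long-form result table with one row per cell.  Kernelized
    algorithms are skipped when no kernel is supplied; a supplied kernel
    must cover the dataset's samples in order.
    """
    if algorithms is None:
        algorithms = list(ALGORITHMS)
    if kernel is not None and list(map(str, kernel.sample_ids)) != \
            list(map(str, dataset.sample_ids)):
        raise ValueError("kernel and dataset sample ids do not match")
    metric_name = "accuracy" if dataset.task == "classification" else "r2"
    splits = make_splits(dataset.n_samples, repetitions, seed)
    rows = []
    for split in splits:
        rep_seed = int(np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(split.repetition,))
        ).integers(2 ** 31))
        for fraction in fractions:
            cell = _prepare_cell(dataset, kernel, split, fraction, seed)
            for alg in algorithms:
                if ALGORITHMS[alg]["group"] == "simkern" and kernel is None:
                    continue
                fs = _make_fit_score(alg, cell, dataset.task, rep_seed)
                try:
                    value, hyper = tune_evaluate(alg, ALGORITHMS[alg]["grid"],
                                                 fs, dataset.task)
                except RuntimeError:
                    continue
                rows.append({
                    "model": dataset.model,
                    "algorithm": alg,
                    "group": ALGORITHMS[alg]["group"],
                    "kernel": kernel_name if
                    ALGORITHMS[alg]["group"] == "simkern" else "",
                    "fraction": fraction,
                    "repetition": split.repetition,
                    "metric": metric_name,
                    "value": value,
                    "hyperparameters": json.dumps(hyper),
                })
    return pd.DataFrame(rows)


def best_kernelized(results: pd.DataFrame) -> str:
    from simkern.reporting import best_algorithm

    return best_algorithm(results, "simkern")
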