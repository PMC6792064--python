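"""Similarity kernels from ensembles of simulation outputs.

For each trial r a symmetric matrix of pairwise similarities
z(i, j, r) in [0, 1] is computed from the trial's outputs; the SimKern
kernel is the entrywise average K(i, j) = (1/R) sum_r z(i, j, r).
Categorical outputs use the indicator similarity (1 iff equal), whose
averaged kernel is automatically positive semidefinite.  Trajectory
outputs use a population-rescaled mean-absolute-difference similarity and
may require a PSD repair step before kernelized SVM training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from simkern.ensemble import TrajectorySet, TrialOutputs

_CONTRACT_TOL = 1e-9


class KernelError(ValueError):
    pass


class KernelFormatError(KernelError):
    pass


@dataclass
class SimilarityKernel:
    """An N x N SimKern similarity matrix with provenance.

    Invariants (checked on construction): K is symmetric, K(i, i) = 1 and
    0 <= K(i, j) <= 1.
    """

    sample_ids: list
    K: np.ndarray
    R: int = 1
    snapshots: list = field(default_factory=list)   # [(r, K^(r)), ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.sample_ids)
        if self.K.shape != (n, n):
            raise KernelError("kernel shape does not match sample ids")
        validate_kernel_matrix(self.K)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def submatrix(self, rows, cols) -> np.ndarray:
        return self.K[np.ix_(rows, cols)]


def validate_kernel_matrix(K: np.ndarray, tol: float = 1e-8) -> None:
    if not np.allclose(K, K.T, atol=tol):
        raise KernelError("kernel matrix is not symmetric")
    if not np.allclose(np.diag(K), 1.0, atol=tol):
        raise KernelError("kernel diagonal is not 1")
    if K.min() < -tol or K.max() > 1 + tol:
        raise KernelError("kernel entries outside [0, 1]")


# ---------------------------------------------------------------- similarity

def categorical_similarity(a, b) -> float:
    """Indicator similarity of two class labels: 1 iff equal."""
    return 1.0 if a == b else 0.0


def population_bounds(outputs, variables) -> dict:
    """Per-variable (min, max) over a trial's whole output population."""
    bounds = {}
    for v in variables:
        lo, hi = np.inf, -np.inf
        for o in outputs:
            if o is None:
                continue
            s = o.series(v)
            lo = min(lo, float(s.min()))
            hi = max(hi, float(s.max()))
        if not np.isfinite(lo):
            raise KernelError(f"no finite outputs to bound variable {v!r}")
        bounds[v] = (lo, hi)
    return bounds


def trajectory_similarity(a: TrajectorySet, b: TrajectorySet,
                          variables, bounds) -> float:
    """Similarity of two trajectory sets, in [0, 1].

    Each selected variable's series is rescaled to [0, 1] by the trial
    population's (min, max); the per-variable similarity is one minus the
    mean absolute difference of the rescaled series, and the result is the
    mean over variables.  A variable that is constant across the whole
    population (degenerate bounds) contributes similarity 1.
    """
    if not variables:
        raise KernelError("no variables selected for trajectory similarity")
    if a.grid.size != b.grid.size or not np.allclose(a.grid, b.grid):
        raise KernelError("trajectories are not on a shared grid")
    sims = []
    for v in variables:
        lo, hi = bounds[v]
        if hi - lo <= 0:
            sims.append(1.0)
            continue
        d = np.abs(a.series(v) - b.series(v)) / (hi - lo)
        sims.append(1.0 - float(np.clip(d, 0.0, 1.0).mean()))
    return float(np.mean(sims))


# ------------------------------------------------------------ trial matrices

def per_trial_matrix(outputs, variables=None) -> np.ndarray:
    """The N x N matrix of z(i, j, r) for one trial's outputs.

    ``outputs`` is a list of per-sample outputs (class labels or
    TrajectorySets, with None marking failed simulations).  Failed
    samples' rows/columns are NaN so that averaging can mask them
    pairwise.  Vectorized internally; agrees entrywise with the scalar
    similarity functions.
    """
    n = len(outputs)
    live = [i for i, o in enumerate(outputs) if o is not None]
    if not live:
        raise KernelError("all outputs in this trial failed")
    if len({isinstance(outputs[i], TrajectorySet) for i in live}) > 1:
        raise KernelError("mixed output variants within a trial")

    Z = np.full((n, n), np.nan)
    if isinstance(outputs[live[0]], TrajectorySet):
        if not variables:
            variables = list(outputs[live[0]].names)
        bounds = population_bounds(outputs, variables)
        T = outputs[live[0]].grid.size
        scaled = np.empty((len(live), len(variables), T))
        for a, i in enumerate(live):
            for b, v in enumerate(variables):
                lo, hi = bounds[v]
                s = outputs[i].series(v)
                scaled[a, b] = 0.0 if hi - lo <= 0 else \
                    np.clip((s - lo) / (hi - lo), 0.0, 1.0)
        degenerate = np.array([bounds[v][1] - bounds[v][0] <= 0
                               for v in variables])
        # mean over (variables, time) of |a - b|; degenerate vars add 0
        m = len(live)
        sub = np.empty((m, m))
        for a in range(m):
            d = np.abs(scaled[a, None, :, :] - scaled).mean(axis=2)  # (m, V)
            d[:, degenerate] = 0.0
            sub[a] = 1.0 - d.mean(axis=1)
        idx = np.asarray(live)
        Z[np.ix_(idx, idx)] = 0.5 * (sub + sub.T)  # symmetrize roundoff
        Z[idx, idx] = 1.0
    else:
        labels = np.asarray([outputs[i] for i in live], dtype=object)
        sub = (labels[:, None] == labels[None, :]).astype(float)
        idx = np.asarray(live)
        Z[np.ix_(idx, idx)] = sub
    return Z


def average_kernel(matrices, sample_ids=None, provenance=None) -> SimilarityKernel:
    """Entrywise mean of per-trial matrices, masking failed pairs.

    Each pair (i, j) is averaged over the trials in which both samples
    simulated successfully (its *effective* trial count); a pair with zero
    effective trials is an error.
    """
    matrices = list(matrices)
    if not matrices:
        raise KernelError("need at least one per-trial matrix")
    n = matrices[0].shape[0]
    if any(m.shape != (n, n) for m in matrices):
        raise KernelError("per-trial matrices disagree on dimension")
    stack = np.stack(matrices)
    counts = np.sum(~np.isnan(stack), axis=0)
    if np.any(counts == 0):
        i, j = np.argwhere(counts == 0)[0]
        raise KernelError(f"pair ({i}, {j}) has zero effective trials")
    with np.errstate(invalid="ignore"):
        K = np.nansum(stack, axis=0) / counts
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    np.clip(K, 0.0, 1.0, out=K)
    if sample_ids is None:
        sample_ids = list(range(n))
    return SimilarityKernel(sample_ids, K, R=len(matrices),
                            provenance=provenance or {})


def running_kernels(matrices, start: int = 3) -> list:
    """Partial-average snapshots K^(r) = mean of the first r matrices.

    Snapshots are emitted from r = ``start`` (default 3; kernels from
    fewer trials are too noisy to be worth writing) through R.  Returns a
    list of (r, matrix) pairs.
    """
    matrices = list(matrices)
    R = len(matrices)
    start = max(1, min(start, R))
    out = []
    stack = np.stack(matrices)
    for r in range(start, R + 1):
        counts = np.sum(~np.isnan(stack[:r]), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            K = np.nansum(stack[:r], axis=0) / counts
        out.append((r, K))
    return out


def convergence_trace(snapshots) -> np.ndarray:
    """Frobenius norms ||K^(r) - K^(r-1)||_F between consecutive snapshots."""
    mats = [m for _, m in snapshots] if snapshots and \
        isinstance(snapshots[0], tuple) else list(snapshots)
    if len(mats) < 2:
        raise KernelError("need at least two snapshots for a trace")
    n = mats[0].shape
    trace = []
    for a, b in zip(mats, mats[1:]):
        if b.shape != n:
            raise KernelError("snapshot dimension mismatch")
        trace.append(float(np.linalg.norm(b - a, "fro")))
    return np.asarray(trace)


# ------------------------------------------------------------------ psd

def project_psd(kernel: SimilarityKernel, tol: float = 1e-8) -> SimilarityKernel:
    """Repair indefiniteness by clipping negative eigenvalues at zero.

    Kernelized SVM training needs a PSD Gram matrix.  Indicator-based
    kernels are PSD by construction and are returned unchanged; trajectory
    kernels can pick up small negative eigenvalues.  After clipping, the
    diagonal is renormalized to 1 and off-diagonals are clipped to [0, 1].
    The amount of clipped spectral mass is recorded in the provenance.
    """
    K = kernel.K
    w = np.linalg.eigvalsh(K)
    if w.min() >= -tol:
        return kernel
    w, V = np.linalg.eigh(K)
    clipped_mass = float(-w[w < 0].sum())
    w = np.clip(w, 0.0, None)
    K2 = (V * w) @ V.T
    d = np.sqrt(np.clip(np.diag(K2), 1e-12, None))
    K2 = K2 / np.outer(d, d)
    K2 = 0.5 * (K2 + K2.T)
    np.clip(K2, 0.0, 1.0, out=K2)
    np.fill_diagonal(K2, 1.0)
    prov = dict(kernel.provenance, psd_clipped_mass=clipped_mass)
    return SimilarityKernel(kernel.sample_ids, K2, R=kernel.R,
                            snapshots=kernel.snapshots, provenance=prov)


def min_eigenvalue(kernel: SimilarityKernel) -> float:
    return float(np.linalg.eigvalsh(kernel.K).min())


# ------------------------------------------------------------------- IO

def write_kernel(kernel: SimilarityKernel, path) -> None:
    """CSV with sample ids as first row and first column."""
    import pandas as pd

    frame = pd.DataFrame(kernel.K, index=kernel.sample_ids,
                         columns=kernel.sample_ids)
    frame.to_csv(path, float_format="%.12g")


def read_kernel(path) -> SimilarityKernel:
    import pandas as pd

    frame = pd.read_csv(path, index_col=0)
    ids = [str(c) for c in frame.columns]
    if [str(i) for i in frame.index] != ids:
        raise KernelFormatError("kernel file row/column ids disagree")
    K = frame.to_numpy(dtype=float)
    try:
        validate_kernel_matrix(K)
    except KernelError as exc:
        raise KernelFormatError(str(exc)) from exc
    return SimilarityKernel(ids, K)
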