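"""High-level workflows tying the stages together.

``build_kernel`` streams an uncertainty ensemble trial by trial, turning
each trial's outputs into a per-trial similarity matrix and averaging
them into the SimKern kernel, optionally keeping running snapshots for
convergence analysis and repairing indefiniteness for trajectory-based
similarities.
"""

from __future__ import annotations

import hashlib

import numpy as np

from simkern.kernel import (SimilarityKernel, average_kernel,
                            convergence_trace, min_eigenvalue,
                            per_trial_matrix, project_psd, running_kernels)
from simkern.models import get_model
from simkern.uncertainty import draw_parameters


def _spec_hash(spec) -> str:
    payload = repr(sorted((k, repr(v)) for k, v in spec.entries.items()))
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def build_kernel(model, dataset, variant: str = "baseline", R: int = 10,
                 seed: int = 0, spec=None, snapshots: bool = False,
                 snapshot_start: int = 3, psd_repair: bool = True,
                 variables=None) -> SimilarityKernel:
    """Run the R-trial ensemble and average per-trial similarities.

    The same parameter draw theta_r is applied to every sample within
    trial r.  Trajectory-based kernels are eigenvalue-clipped to PSD when
    needed (indicator kernels are PSD by construction and skip the
    repair).
    """
    if isinstance(model, str):
        model = get_model(model)
    if spec is None:
        spec = model.default_uncertainty(variant)
    spec.validate_against(model.uncertain_names())
    if variables is None:
        variables = model.similarity_variables(variant)
    transform = getattr(model, "similarity_transform", lambda v: None)(variant)
    draws = draw_parameters(spec, R, seed)
    matrices = []
    for draw in draws:
        outputs = model.run_trial_batch(dataset.X, draw)
        if transform is not None:
            outputs = [o.__class__(o.grid, o.names, transform(o.values))
                       if o is not None else None for o in outputs]
        matrices.append(per_trial_matrix(outputs, variables))
    prov = {"model": model.name, "variant": variant, "R": R, "seed": seed,
            "spec_hash": _spec_hash(spec),
            "variables": list(variables) if variables else None}
    kern = average_kernel(matrices, sample_ids=list(dataset.sample_ids),
                          provenance=prov)
    if snapshots:
        kern.snapshots = running_kernels(matrices, start=snapshot_start)
    if psd_repair and variables is not None and \
            min_eigenvalue(kern) < -1e-8:
        kern = project_psd(kern)
    return kern


def kernel_convergence(kernel: SimilarityKernel) -> np.ndarray:
    if len(kernel.snapshots) < 2:
        raise ValueError("kernel was built without snapshots")
    return convergence_trace(kernel.snapshots)
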