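"""The four bundled complex-system models.

Each model exposes the same plugin surface: ``generate(n, seed)`` builds
a labelled ground-truth dataset; ``default_uncertainty(variant)``
describes the uncertain simulation parameters; ``run_trial_batch(X,
draw)`` runs every sample through one perturbed simulation; and
``similarity_variables(variant)`` names the trajectory variables the
kernel should compare (``None`` for categorical outputs).
"""

from functools import lru_cache

MODEL_NAMES = ("radiation", "flowering", "boolean", "netflow")


@lru_cache(maxsize=None)
def get_model(name: str):
    if name == "radiation":
        from simkern.models.radiation import RadiationModel
        return RadiationModel()
    if name == "flowering":
        from simkern.models.flowering import FloweringModel
        return FloweringModel()
    if name == "boolean":
        from simkern.models.boolean_cancer import BooleanCancerModel
        return BooleanCancerModel()
    if name == "netflow":
        from simkern.models.netflow import NetflowModel
        return NetflowModel()
    raise KeyError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
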