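"""Ensemble execution: every sample through every trial's simulation.

One parameter draw theta_r is shared by *all* samples within trial r; the
draws vary across trials only.  Simulation outputs are either a
:class:`TrajectorySet` (ODE models) or a plain class-label string
(discrete models).  Individual trial failures are recorded rather than
raised, so a partially failed ensemble still yields a kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from simkern.uncertainty import UncertaintySpec, ParameterDraw, draw_parameters


class EnsembleError(RuntimeError):
    """Raised when too many trials fail to produce a usable ensemble."""


class SimulationError(RuntimeError):
    def __init__(self, message, sample_id=None):
        super().__init__(message)
        self.sample_id = sample_id


@dataclass
class TrajectorySet:
    """Named time courses of one simulated sample on a shared grid."""

    grid: np.ndarray          # (T,)
    names: list               # S variable names
    values: np.ndarray        # (S, T)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.names), self.grid.size):
            raise ValueError("trajectory shape does not match names/grid")

    def series(self, name: str) -> np.ndarray:
        return self.values[self.names.index(name)]


# A SimulationOutput is TrajectorySet | str (class label); failures are None.


@dataclass
class TrialOutputs:
    """The N x R grid of simulation outputs plus per-trial provenance."""

    model: str
    sample_ids: list
    outputs: list                     # outputs[r-1][i] -> output or None
    draws: list = field(default_factory=list)
    seed: int = 0
    failures: set = field(default_factory=set)  # {(sample_index, r)}

    @property
    def R(self) -> int:
        return len(self.outputs)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def trial(self, r: int) -> list:
        return self.outputs[r - 1]


def write_trial_outputs(trial_outputs: TrialOutputs, outdir) -> None:
    """Persist an ensemble: one CSV per (trial, output kind) plus a
    manifest (model, R, seed, failures)."""
    import json
    from pathlib import Path

    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for r in range(1, trial_outputs.R + 1):
        outs = trial_outputs.trial(r)
        live = [o for o in outs if o is not None]
        if live and isinstance(live[0], TrajectorySet):
            frames = []
            for sid, o in zip(trial_outputs.sample_ids, outs):
                if o is None:
                    continue
                f = pd.DataFrame(o.values.T, columns=o.names)
                f.insert(0, "time", o.grid)
                f.insert(0, "id", sid)
                frames.append(f)
            pd.concat(frames).to_csv(
                outdir / f"trial_{r:03d}_trajectories.csv", index=False)
        else:
            pd.DataFrame({"id": trial_outputs.sample_ids,
                          "label": outs}).to_csv(
                outdir / f"trial_{r:03d}_labels.csv", index=False)
    manifest = {
        "model": trial_outputs.model,
        "R": trial_outputs.R,
        "seed": trial_outputs.seed,
        "n_samples": trial_outputs.n_samples,
        "failures": sorted([i, r] for i, r in trial_outputs.failures),
        "draws": [d.values for d in trial_outputs.draws],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_trial(model, features, draw: ParameterDraw):
    """Simulate a single sample under one parameter draw."""
    import pandas as pd

    from simkern.models import get_model

    if isinstance(model, str):
        model = get_model(model)
    row = features if isinstance(features, pd.DataFrame) \
        else pd.DataFrame([features])
    out = model.run_trial_batch(row, draw)
    return out[0]


def run_ensemble(model, dataset, spec: UncertaintySpec, R: int,
                 seed: int, max_failure_fraction: float = 0.5) -> TrialOutputs:
    """Run all N samples through R perturbed simulations.

    Returns the complete output grid; output (i, r) was produced from
    sample i's features under the trial-r draw.  Samples whose simulation
    diverges in a trial are recorded in ``failures`` and stored as None.
    """
    from simkern.models import get_model

    if isinstance(model, str):
        model = get_model(model)
    if R < 1:
        raise ValueError("R must be >= 1")
    if dataset.n_samples == 0:
        raise ValueError("dataset is empty")

    spec.validate_against(model.uncertain_names())
    draws = draw_parameters(spec, R, seed)
    all_outputs, failures = [], set()
    for draw in draws:
        try:
            outs = model.run_trial_batch(dataset.X, draw)
        except Exception:
            outs = [None] * dataset.n_samples
        for i, o in enumerate(outs):
            if o is None:
                failures.add((i, draw.r))
        all_outputs.append(outs)

    n_cells = dataset.n_samples * R
    if len(failures) > max_failure_fraction * n_cells:
        raise EnsembleError(
            f"{len(failures)}/{n_cells} simulations failed; ensemble unusable")
    return TrialOutputs(model.name, list(dataset.sample_ids), all_outputs,
                        draws=draws, seed=seed, failures=failures)
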