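"""Boolean cancer signalling model (synchronous update dynamics).

The ground-truth network has 32 nodes wired into damage-response,
EMT/metastasis and phenotype read-out circuitry.  A sample is a choice of
the 32 initial on/off states plus mutation flags for five genes (p53,
AKT1, AKT2, NICD, TGFbeta) that force the corresponding node to a fixed
value throughout the dynamics.  Iterating the synchronous update rules
drives every sample into an attractor (a fixed point or limit cycle, the
state space being finite); the attractor's marker nodes label the sample
apoptotic, metastasizing or other.

The SimKern variant is a modularly reduced network: the 32 nodes are
partitioned into modules, each governed by a coarse-grained rule.  How a
full-model initial state maps onto module initial states is ambiguous, so
each ensemble trial resolves it at random — every module copies the
initial value of one uniformly chosen member node.  That random mapping
is the model's uncertainty, and the resulting kernel is deliberately
*biased*: the reduction discards information the ground truth uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from simkern.datasets import Dataset, FeatureMeta, sample_ids
from simkern.uncertainty import CategoricalChoice, UncertaintySpec

_ALLOWED = {"__builtins__": {}}


def _compile_rule(expr: str, names):
    code = compile(expr, f"<rule {expr!r}>", "eval")
    for v in code.co_names:
        if v not in names:
            raise ValueError(f"rule references unknown node {v!r}")
    return code


@dataclass
class BooleanNetwork:
    """Synchronously updated Boolean network with per-sample overrides.

    Rules are boolean expressions over node names using ``&``, ``|``,
    ``~`` and parentheses; they are evaluated on whole sample populations
    at once (numpy boolean arrays).
    """

    node_names: list
    rules: dict                      # node -> expression string
    mutable: list = field(default_factory=list)  # nodes that may be forced

    def __post_init__(self):
        missing = [n for n in self.node_names if n not in self.rules]
        if missing:
            raise ValueError(f"nodes without rules: {missing}")
        self._codes = [_compile_rule(self.rules[n], set(self.node_names))
                       for n in self.node_names]
        self._weights = (2 ** np.arange(len(self.node_names),
                                        dtype=np.uint64))

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)

    def idx(self, name: str) -> int:
        return self.node_names.index(name)

    def _apply_overrides(self, states, force_mask, force_value):
        if force_mask is not None:
            states = np.where(force_mask, force_value, states)
        return states

    def step(self, states, force_mask=None, force_value=None) -> np.ndarray:
        """One synchronous update of a (n_samples, n_nodes) bool array."""
        states = np.atleast_2d(np.asarray(states, dtype=bool))
        env = dict(zip(self.node_names, states.T))
        new = np.empty_like(states)
        for j, code in enumerate(self._codes):
            val = eval(code, _ALLOWED, env)  # noqa: S307 - vetted node names
            new[:, j] = np.asarray(val, dtype=bool)
        return self._apply_overrides(new, force_mask, force_value)

    def _pack(self, states) -> np.ndarray:
        return (states.astype(np.uint64) * self._weights).sum(axis=1)

    def attractors(self, states, force_mask=None, force_value=None,
                   max_steps: int = 512) -> list:
        """Attractor (list of state vectors) reached from each start state.

        Synchronous updates are iterated with cycle detection; the finite
        state space guarantees a fixed point or limit cycle is reached.
        """
        states = np.atleast_2d(np.asarray(states, dtype=bool))
        if self.n_nodes > 64:
            raise ValueError("packing supports up to 64 nodes")
        states = self._apply_overrides(
            states, force_mask, force_value)
        n = states.shape[0]
        history_codes = [self._pack(states)]
        history_states = [states]
        first_seen = [dict([(int(history_codes[0][i]), 0)]) for i in range(n)]
        cycle_span = [None] * n
        unresolved = n
        for t in range(1, max_steps + 1):
            states = self.step(states, force_mask, force_value)
            codes = self._pack(states)
            history_codes.append(codes)
            history_states.append(states)
            for i in range(n):
                if cycle_span[i] is not None:
                    continue
                c = int(codes[i])
                if c in first_seen[i]:
                    cycle_span[i] = (first_seen[i][c], t)
                    unresolved -= 1
                else:
                    first_seen[i][c] = t
            if unresolved == 0:
                break
        if unresolved:
            raise RuntimeError("attractor search exceeded max_steps")
        out = []
        for i in range(n):
            lo, hi = cycle_span[i]
            out.append([history_states[t][i] for t in range(lo, hi)])
        return out


def marker_on(attractor, idx: int) -> bool:
    """A marker counts as on if it is on in at least half the cycle states."""
    vals = np.array([s[idx] for s in attractor])
    return bool(vals.mean() >= 0.5)


def _load_constants() -> dict:
    ref = resources.files("simkern.models").joinpath("data/boolean.yaml")
    return yaml.safe_load(ref.read_text())


class BooleanCancerModel:
    name = "boolean"
    task = "classification"
    classes = ("apoptotic", "metastasizing", "other")
    MUTATED_GENES = ("p53", "AKT1", "AKT2", "NICD", "TGFbeta")

    def __init__(self):
        doc = _load_constants()
        self.full = BooleanNetwork(doc["nodes"], doc["rules"],
                                   mutable=list(self.MUTATED_GENES))
        # forced value each mutated gene takes when its flag is set
        self.mutation_states = {g: bool(doc["mutation_states"][g])
                                for g in self.MUTATED_GENES}
        self.init_prob = {n: float(doc["init_prob"].get(n, 0.5))
                          for n in doc["nodes"]}
        self.mutation_prob = float(doc["mutation_prob"])
        self.markers = doc["markers"]            # {apoptotic: node, ...}
        self.modules = {m: list(v) for m, v in doc["modules"].items()}
        self.reduced = BooleanNetwork(list(self.modules),
                                      doc["reduced_rules"])
        self.reduced_markers = doc["reduced_markers"]
        # module forced by each mutation flag in the reduced model
        self.reduced_mutations = {
            g: (self._module_of(g), self.mutation_states[g])
            for g in self.MUTATED_GENES}

    def _module_of(self, gene: str) -> str:
        for m, members in self.modules.items():
            if gene in members:
                return m
        raise KeyError(gene)

    # -- structure ----------------------------------------------------
    def structure(self) -> dict:
        return {
            "n_nodes": self.full.n_nodes,
            "n_features": self.full.n_nodes + len(self.MUTATED_GENES),
            "n_modules": len(self.modules),
        }

    # -- classification -----------------------------------------------
    def _classify(self, net: BooleanNetwork, markers: dict,
                  attractor) -> str:
        if marker_on(attractor, net.idx(markers["apoptotic"])):
            return "apoptotic"
        if marker_on(attractor, net.idx(markers["metastasizing"])):
            return "metastasizing"
        return "other"

    def attractor_class(self, initial, mutations) -> str:
        """Label one full-model sample from its attractor's markers."""
        initial = np.asarray(initial, dtype=bool).reshape(1, -1)
        mask, val = self._full_overrides(np.asarray(mutations,
                                                    dtype=bool).reshape(1, -1))
        att = self.full.attractors(initial, mask, val)[0]
        return self._classify(self.full, self.markers, att)

    def _full_overrides(self, mutations):
        n = mutations.shape[0]
        mask = np.zeros((n, self.full.n_nodes), dtype=bool)
        val = np.zeros((n, self.full.n_nodes), dtype=bool)
        for k, g in enumerate(self.MUTATED_GENES):
            j = self.full.idx(g)
            mask[:, j] = mutations[:, k]
            val[:, j] = self.mutation_states[g]
        return mask, val

    # -- ground truth -------------------------------------------------
    def feature_columns(self) -> list:
        return [f"init_{n}" for n in self.full.node_names] + \
               [f"mut_{g}" for g in self.MUTATED_GENES]

    def generate(self, n: int, seed: int) -> Dataset:
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(np.random.SeedSequence(seed,
                                                           spawn_key=(0,)))
        p = np.array([self.init_prob[nm] for nm in self.full.node_names])
        init = rng.random((n, self.full.n_nodes)) < p[None, :]
        mut = rng.random((n, len(self.MUTATED_GENES))) < self.mutation_prob
        mask, val = self._full_overrides(mut)
        atts = self.full.attractors(np.where(mask, val, init), mask, val)
        y = np.array([self._classify(self.full, self.markers, a)
                      for a in atts], dtype=object)
        X = pd.DataFrame(np.hstack([init, mut]).astype(int),
                         columns=self.feature_columns())
        meta = [FeatureMeta(c, "binary") for c in X.columns]
        return Dataset(sample_ids(n), X, y, meta, task="classification",
                       model=self.name, classes=self.classes)

    # -- SimKern (reduced model with random module mapping) -----------
    def uncertain_names(self) -> list:
        return [f"map:{m}" for m in self.modules]

    def default_uncertainty(self, variant: str = "baseline") -> UncertaintySpec:
        return UncertaintySpec({f"map:{m}": CategoricalChoice(tuple(members))
                                for m, members in self.modules.items()})

    def similarity_variables(self, variant: str = "baseline"):
        return None

    def run_trial_batch(self, X: pd.DataFrame, draw) -> list:
        n = len(X)
        init_cols = [f"init_{nm}" for nm in self.full.node_names]
        init = X[init_cols].to_numpy(dtype=bool)
        mut = X[[f"mut_{g}" for g in self.MUTATED_GENES]].to_numpy(dtype=bool)
        # module initial state = initial value of the trial's chosen member
        red_init = np.zeros((n, self.reduced.n_nodes), dtype=bool)
        for j, m in enumerate(self.reduced.node_names):
            member = draw.values[f"map:{m}"]
            red_init[:, j] = init[:, self.full.idx(member)]
        mask = np.zeros((n, self.reduced.n_nodes), dtype=bool)
        val = np.zeros((n, self.reduced.n_nodes), dtype=bool)
        for k, g in enumerate(self.MUTATED_GENES):
            module, forced = self.reduced_mutations[g]
            j = self.reduced.idx(module)
            mask[:, j] |= mut[:, k]
            val[:, j] = np.where(mut[:, k], forced, val[:, j])
        atts = self.reduced.attractors(np.where(mask, val, red_init),
                                       mask, val)
        return [self._classify(self.reduced, self.reduced_markers, a)
                for a in atts]
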