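"""Layered min-cost network flow model.

A unit of flow is routed from a source to a sink through a layered,
acyclic, 80-arc directed network so as to minimize total arc cost.  The
network is built so every source-to-sink path traverses exactly one of
the three *final-layer* arcs, and the index of that arc is the sample's
class.  Samples differ in the costs of 12 designated arcs (the feature
vector); the SimKern simulation perturbs a configured superset of arc
costs multiplicatively — 23 arcs (including the 12 varied ones) in the
"better" variant, 44 arcs with larger noise in the "worse" variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from simkern.datasets import Dataset, FeatureMeta, sample_ids
from simkern.uncertainty import MultiplicativeNormal, UncertaintySpec


class ModelDefinitionError(ValueError):
    pass


@dataclass
class LayeredFlowNetwork:
    """Directed acyclic layered network with one source and one sink."""

    nodes: list                  # in topological order
    arcs: list                   # list of (tail, head); arc id = index
    costs: np.ndarray            # nominal arc costs, shape (n_arcs,)
    source: str
    sink: str

    def __post_init__(self):
        self.costs = np.asarray(self.costs, dtype=float)
        if len(self.arcs) != self.costs.size:
            raise ModelDefinitionError("arc list and cost vector disagree")
        order = {n: i for i, n in enumerate(self.nodes)}
        for u, v in self.arcs:
            if order[u] >= order[v]:
                raise ModelDefinitionError("arcs must respect layer order")

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    @property
    def final_arc_ids(self) -> list:
        return [i for i, (u, v) in enumerate(self.arcs) if v == self.sink]


def min_cost_route(net: LayeredFlowNetwork, costs) -> tuple:
    """Cheapest source->sink path; returns (class label, arc-usage vector).

    Ties are broken deterministically in favour of the lexicographically
    smallest arc-id sequence.  The class is the index (1-based) of the
    final-layer arc the optimal path uses.
    """
    costs = np.asarray(costs, dtype=float)
    if costs.shape != (net.n_arcs,) or not np.all(np.isfinite(costs)):
        raise ValueError("need one finite cost per arc")
    out_arcs = {}
    for aid, (u, v) in enumerate(net.arcs):
        out_arcs.setdefault(u, []).append((aid, v))
    best = {net.source: (0.0, ())}
    for u in net.nodes:
        if u not in best:
            continue
        cu, pu = best[u]
        for aid, v in out_arcs.get(u, []):
            cand = (cu + costs[aid], pu + (aid,))
            if v not in best or cand < best[v]:
                best[v] = cand
    if net.sink not in best:
        raise ModelDefinitionError("sink unreachable from source")
    _, path = best[net.sink]
    finals = net.final_arc_ids
    last = path[-1]
    if last not in finals:
        raise ModelDefinitionError("optimal path misses the final layer")
    usage = np.zeros(net.n_arcs)
    usage[list(path)] = 1.0
    return f"route-{finals.index(last) + 1}", usage


def _load_constants() -> dict:
    ref = resources.files("simkern.models").joinpath("data/netflow.yaml")
    return yaml.safe_load(ref.read_text())


class NetflowModel:
    """Ground-truth and SimKern variants of the network-flow problem."""

    name = "netflow"
    task = "classification"
    classes = ("route-1", "route-2", "route-3")

    def __init__(self):
        doc = _load_constants()
        self.net = LayeredFlowNetwork(
            nodes=doc["nodes"],
            arcs=[tuple(a) for a in doc["arcs"]],
            costs=np.asarray(doc["costs"], dtype=float),
            source=doc["source"], sink=doc["sink"])
        self.varied_arcs = list(doc["varied_arcs"])          # 12 features
        self.perturbed_better = list(doc["perturbed_better"])  # 23 arcs
        self.perturbed_worse = list(doc["perturbed_worse"])    # 44 arcs
        self.noise_better = float(doc["noise_better"])
        self.noise_worse = float(doc["noise_worse"])
        self.vary_sigma = float(doc["vary_sigma"])

    # -- structure ----------------------------------------------------
    def structure(self) -> dict:
        return {
            "n_arcs": self.net.n_arcs,
            "n_final_arcs": len(self.net.final_arc_ids),
            "n_varied_arcs": len(self.varied_arcs),
            "n_perturbed_better": len(self.perturbed_better),
            "n_perturbed_worse": len(self.perturbed_worse),
            "n_features": len(self.varied_arcs),
        }

    # -- ground truth -------------------------------------------------
    def _full_costs(self, row) -> np.ndarray:
        costs = self.net.costs.copy()
        for k, aid in enumerate(self.varied_arcs):
            costs[aid] = row[k]
        return costs

    def generate(self, n: int, seed: int) -> Dataset:
        """Sample n cost vectors and label each by its optimal final arc."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(np.random.SeedSequence(seed,
                                                           spawn_key=(0,)))
        nominal = self.net.costs[self.varied_arcs]
        X = nominal[None, :] * np.exp(
            self.vary_sigma * rng.standard_normal((n, len(self.varied_arcs))))
        y = np.array([min_cost_route(self.net, self._full_costs(X[i]))[0]
                      for i in range(n)], dtype=object)
        cols = [f"cost_arc{aid:02d}" for aid in self.varied_arcs]
        meta = [FeatureMeta(c, "continuous") for c in cols]
        return Dataset(sample_ids(n), pd.DataFrame(X, columns=cols), y,
                       meta, task="classification", model=self.name,
                       classes=self.classes)

    # -- SimKern ------------------------------------------------------
    def uncertain_names(self) -> list:
        return [f"cost:arc{aid:02d}" for aid in range(self.net.n_arcs)]

    def default_uncertainty(self, variant: str = "better") -> UncertaintySpec:
        if variant in ("better", "baseline"):
            arcs, sd = self.perturbed_better, self.noise_better
        elif variant == "worse":
            arcs, sd = self.perturbed_worse, self.noise_worse
        else:
            raise ValueError(f"unknown netflow variant {variant!r}")
        return UncertaintySpec({f"cost:arc{aid:02d}":
                                MultiplicativeNormal(1.0, sd)
                                for aid in arcs})

    def similarity_variables(self, variant: str = "better"):
        return None  # categorical outputs -> indicator similarity

    def run_trial_batch(self, X: pd.DataFrame, draw) -> list:
        mult = np.ones(self.net.n_arcs)
        for name, value in draw.values.items():
            mult[int(name.split("arc")[1])] = value
        rows = X.to_numpy(dtype=float)
        out = []
        for i in range(rows.shape[0]):
            costs = self._full_costs(rows[i]) * mult
            out.append(min_cost_route(self.net, costs)[0])
        return out
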