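"""Ground-truth simulators: structure, determinism, oracles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from simkern.ensemble import TrajectorySet
from simkern.models import get_model
from simkern.models.boolean_cancer import BooleanNetwork, marker_on
from simkern.models.flowering import flowering_time
from simkern.models.netflow import LayeredFlowNetwork, min_cost_route
from simkern.models.radiation import classify_radiation


# ----------------------------------------------------------------- structure

def test_structural_counts(radiation_model, flowering_model, boolean_model,
                           netflow_model):
    rs = radiation_model.structure()
    assert rs["n_states"] == 34
    assert rs["n_features"] == 39
    assert rs["n_uncertain_params"] == 87
    assert flowering_model.structure()["n_states"] == 6
    bs = boolean_model.structure()
    assert bs["n_nodes"] == 32
    assert bs["n_features"] == 37
    ns = netflow_model.structure()
    assert ns["n_arcs"] == 80
    assert ns["n_final_arcs"] == 3
    assert ns["n_varied_arcs"] == 12
    assert ns["n_perturbed_better"] == 23
    assert ns["n_perturbed_worse"] == 44


@pytest.mark.parametrize("name,n_feat", [
    ("radiation", 39), ("boolean", 37), ("netflow", 12)])
def test_feature_counts_and_determinism(name, n_feat):
    model = get_model(name)
    a = model.generate(5, seed=9)
    b = model.generate(5, seed=9)
    assert a.X.shape == (5, n_feat)
    pd.testing.assert_frame_equal(a.X, b.X)
    assert list(a.y) == list(b.y)


@pytest.mark.parametrize("name", ["radiation", "flowering", "boolean",
                                  "netflow"])
def test_nonpositive_n_rejected(name):
    with pytest.raises(ValueError):
        get_model(name).generate(0, seed=1)


def test_radiation_all_classes_present(radiation_model):
    """Every one of the four fates occurs with frequency >= 2% at n=2000."""
    ds = radiation_model.generate(2000, seed=1)
    freqs = pd.Series(ds.y).value_counts(normalize=True)
    assert set(freqs.index) == set(radiation_model.classes)
    assert freqs.min() >= 0.02


def test_boolean_all_classes_present(boolean_model):
    ds = boolean_model.generate(2000, seed=1)
    freqs = pd.Series(ds.y).value_counts(normalize=True)
    assert set(freqs.index) == set(boolean_model.classes)
    assert freqs.min() >= 0.02


def test_netflow_all_classes_present(netflow_model):
    ds = netflow_model.generate(2000, seed=1)
    freqs = pd.Series(ds.y).value_counts(normalize=True)
    assert set(freqs.index) == set(netflow_model.classes)
    assert freqs.min() >= 0.02


# ----------------------------------------------------------------- radiation

def test_radiation_trajectories_finite(radiation_model):
    ds = radiation_model.generate(3, seed=2)
    traj = radiation_model.trajectories(ds.X.iloc[[0]])
    assert len(traj.names) == 34
    assert np.all(np.isfinite(traj.values))


def test_radiation_mutations_change_dynamics(radiation_model):
    cols = radiation_model.feature_columns()
    base = {c: 1.0 for c in cols if c.startswith("pert_")}
    off = pd.DataFrame([{**base, **{c: 0 for c in cols
                                    if c.startswith("mut_")}}])[cols]
    on = pd.DataFrame([{**base, **{c: 1 for c in cols
                                   if c.startswith("mut_")}}])[cols]
    t_off = radiation_model.trajectories(off)
    t_on = radiation_model.trajectories(on)
    assert not np.allclose(t_off.values, t_on.values)


def test_classify_radiation_priority_and_default():
    grid = np.array([0.0, 1.0])
    thresholds = {"apoptosis": 1.0, "mitotic": 1.0, "cycling": 1.0,
                  "residual_dsb": 1.0}
    names = ["DSB", "PARPc", "MITDAM", "CYCLING"]

    def traj(dsb, parp, mit, cyc):
        vals = np.array([[dsb, dsb], [parp, parp], [mit, mit], [cyc, cyc]])
        return TrajectorySet(grid, names, vals)

    # apoptosis marker wins regardless of other readouts
    assert classify_radiation(traj(9, 9, 9, 9), thresholds) == "apoptosis"
    # everything below threshold -> quiescence
    assert classify_radiation(traj(0, 0, 0, 0), thresholds) == "quiescence"
    assert classify_radiation(traj(9, 0, 9, 9), thresholds) == \
        "mitotic-catastrophe"
    assert classify_radiation(traj(0.5, 0, 0, 9), thresholds) == \
        "repaired-and-cycling"


def test_radiation_class_frequencies_reproducible(radiation_model):
    a = radiation_model.generate(200, seed=1).y
    b = radiation_model.generate(200, seed=1).y
    assert list(a) == list(b)


# ----------------------------------------------------------------- flowering

def test_flowering_time_interpolation():
    assert flowering_time([0, 10], [0.0, 1.0], 0.25) == pytest.approx(2.5)


def test_flowering_time_immediate_and_censored():
    assert flowering_time([0, 5, 10], [2.0, 2.0, 2.0], 1.0) == 0.0
    assert flowering_time([0, 5, 10], [0.1, 0.2, 0.3], 1.0) == 10.0
    with pytest.raises(ValueError):
        flowering_time([0.0], [], 1.0)


def test_flowering_nominal_deterministic(flowering_model):
    X = pd.DataFrame({"genotype": ["WT"]})
    for p in flowering_model.perturbed:
        X[f"pert_{p}"] = 1.0
    t1 = flowering_model.simulate_population(X)
    t2 = flowering_model.simulate_population(X)
    np.testing.assert_array_equal(t1, t2)
    ap1 = t1[0, 5, :]
    y = flowering_time(flowering_model.ode.grid, ap1,
                       flowering_model.threshold)
    assert 0 < y < flowering_model.ode.horizon


def test_flowering_outcome_has_spread(flowering_model):
    ds = flowering_model.generate(500, seed=3)
    assert ds.X.shape[1] == 1 + 34  # genotype + 34 rate perturbations
    assert np.std(ds.y) > 1.0


# ------------------------------------------------------------------ boolean

def _toy_net():
    return BooleanNetwork(["a", "b", "c"],
                          {"a": "b & c", "b": "a | c", "c": "~a"})


def test_boolean_attractor_matches_exhaustive_enumeration():
    """Cycle detection agrees with brute force over all 2^n start states."""
    net = _toy_net()

    def brute(state):
        seen = {}
        s = tuple(state)
        steps = [s]
        while s not in seen:
            seen[s] = len(seen)
            s = tuple(net.step(np.array([s]))[0])
            steps.append(s)
        lo = seen[s]
        return steps[lo:-1]

    starts = np.array(list(itertools.product([0, 1], repeat=3)), dtype=bool)
    atts = net.attractors(starts)
    for s, att in zip(starts, atts):
        expected = brute(s)
        got = [tuple(a) for a in att]
        # same cycle up to rotation
        assert len(got) == len(expected)
        assert set(got) == set(tuple(bool(x) for x in e) for e in expected)


def test_boolean_override_forced_in_every_state():
    net = _toy_net()
    mask = np.array([[False, True, False]])
    val = np.array([[False, False, False]])  # b forced off
    atts = net.attractors(np.array([[True, True, True]]), mask, val)
    assert all(not s[1] for s in atts[0])


def test_boolean_fixed_point_classified_directly(boolean_model):
    ds = boolean_model.generate(30, seed=6)
    init_cols = [f"init_{n}" for n in boolean_model.full.node_names]
    for i in range(5):
        init = ds.X.iloc[i][init_cols].to_numpy(dtype=bool)
        mut = ds.X.iloc[i][[f"mut_{g}" for g in
                            boolean_model.MUTATED_GENES]
                           ].to_numpy(dtype=bool)
        assert boolean_model.attractor_class(init, mut) == ds.y[i]


def test_boolean_identical_features_identical_labels(boolean_model):
    ds = boolean_model.generate(50, seed=7)
    X2 = pd.concat([ds.X.iloc[[0]], ds.X.iloc[[0]]], ignore_index=True)
    mask = np.zeros((2, 32), dtype=bool)
    # deterministic dynamics: same row twice -> same label
    init = X2[[f"init_{n}" for n in
               boolean_model.full.node_names]].to_numpy(dtype=bool)
    mut = X2[[f"mut_{g}" for g in
              boolean_model.MUTATED_GENES]].to_numpy(dtype=bool)
    a = boolean_model.attractor_class(init[0], mut[0])
    b = boolean_model.attractor_class(init[1], mut[1])
    assert a == b


def test_marker_on_majority_rule():
    cyc = [np.array([True, False]), np.array([False, False]),
           np.array([True, True]), np.array([True, False])]
    assert marker_on(cyc, 0)       # on in 3/4 states
    assert not marker_on(cyc, 1)   # on in 1/4 states


# ------------------------------------------------------------------ netflow

def _random_layered_net(rng):
    sizes = [1, rng.integers(2, 4), rng.integers(2, 4),
             rng.integers(2, 4), 1]
    nodes, layers = [], []
    for li, k in enumerate(sizes):
        layer = [f"n{li}_{j}" for j in range(k)]
        layers.append(layer)
        nodes.extend(layer)
    arcs = []
    for la, lb in zip(layers, layers[1:]):
        for u in la:
            for v in lb:
                if rng.random() < 0.8 or v == lb[0]:
                    arcs.append((u, v))
    costs = rng.integers(1, 10, size=len(arcs)).astype(float)
    return LayeredFlowNetwork(nodes, arcs, costs, layers[0][0],
                              layers[-1][0])


def _enumerate_best(net, costs):
    g = nx.DiGraph()
    for aid, (u, v) in enumerate(net.arcs):
        g.add_edge(u, v, aid=aid)
    best = None
    for path in nx.all_simple_paths(g, net.source, net.sink):
        aids = tuple(g[u][v]["aid"] for u, v in zip(path, path[1:]))
        cand = (sum(costs[a] for a in aids), aids)
        if best is None or cand < best:
            best = cand
    return best


def test_min_cost_route_matches_brute_force_enumeration():
    """DP routing equals exhaustive path enumeration on 100 random layered
    networks, including the lexicographic tie-break."""
    rng = np.random.default_rng(12345)
    for _ in range(100):
        net = _random_layered_net(rng)
        costs = net.costs.copy()
        try:
            label, usage = min_cost_route(net, costs)
        except Exception:
            continue  # disconnected instance
        best = _enumerate_best(net, costs)
        used = tuple(np.flatnonzero(usage))
        assert sum(costs[a] for a in used) == pytest.approx(best[0])
        assert used == best[1]


def test_min_cost_route_tie_break_and_stability(netflow_model):
    net = netflow_model.net
    costs = np.ones(net.n_arcs)
    # all-equal costs: many optimal paths; result must be stable
    l1, u1 = min_cost_route(net, costs)
    l2, u2 = min_cost_route(net, costs)
    assert l1 == l2 and np.array_equal(u1, u2)
    # raising the cost of an unused arc leaves the route unchanged
    unused = int(np.flatnonzero(u1 == 0)[0])
    costs2 = costs.copy()
    costs2[unused] += 100
    l3, u3 = min_cost_route(net, costs2)
    assert l3 == l1 and np.array_equal(u3, u1)


def test_netflow_identical_costs_identical_class(netflow_model):
    ds = netflow_model.generate(10, seed=3)
    row = ds.X.iloc[[0]]
    c1 = min_cost_route(netflow_model.net,
                        netflow_model._full_costs(row.to_numpy()[0]))[0]
    assert c1 == ds.y[0]
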