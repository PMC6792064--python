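"""Flowering-time gene regulatory network (regression task).

Six coupled ODEs describe the floral-integrator circuit of an annual
plant: the mobile florigen signal FT binds the bZIP factor FD; the
FT-FD complex activates SOC1, which feeds a mutual-activation loop with
AGL24; both converge on the meristem-identity gene LFY, which forms a
bistable positive feedback with AP1.  Flowering time is the first time
the AP1 concentration crosses a fixed threshold (linearly interpolated
between output grid points); trajectories that never cross are censored
at the simulation horizon.

A sample is one of 19 genotypes (wild type, single knockouts,
overexpression lines and selected double knockouts) together with 34
multiplicative perturbations of the rate parameters.  The SimKern
simulation is the same ODE system with those 34 rates treated as
uncertain: multiplicative Gaussian noise (baseline sd 0.2, less/more
noisy variants sd 0.1/0.4) or, for a structurally biased variant,
multipliers drawn uniformly from {0.01, 1, 5, 10}.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import yaml

from simkern.datasets import Dataset, FeatureMeta, sample_ids
from simkern.ensemble import TrajectorySet
from simkern.models._odecore import NetworkOde
from simkern.uncertainty import (Discrete, MultiplicativeNormal,
                                 UncertaintySpec)

STATES = ["FT", "FD", "SOC1", "AGL24", "LFY", "AP1"]

# production parameters per gene, zeroed by a knockout / boosted by an
# overexpression allele
GENE_PRODUCTION = {
    "FT": ["b_FT", "v_FT"],
    "FD": ["b_FD", "v_FD"],
    "SOC1": ["b_S", "v_S1", "v_S2"],
    "AGL24": ["b_A", "v_A1"],
    "LFY": ["b_L", "v_L1", "v_L2", "v_L3"],
    "AP1": ["b_P", "v_P1", "v_P2"],
}


def _load_constants() -> dict:
    ref = resources.files("simkern.models").joinpath("data/flowering.yaml")
    return yaml.safe_load(ref.read_text())


def build_ode(rates: dict, horizon: float, dt: float,
              out_every: float) -> NetworkOde:
    """Wire the six-state network from a named rate dictionary."""
    names = list(rates)
    ode = NetworkOde(STATES, names, np.array([rates[k] for k in names]),
                     horizon=horizon, dt=dt, out_every=out_every)
    a = ode.add_term
    # FT: leaky induction with weak self-amplification
    a("FT", +1, "b_FT")
    a("FT", +1, "v_FT", ("act", "FT", "K_FT"))
    a("FT", -1, "g_FT", ("mass", "FT"))
    # FD: basal + SOC1 feedback
    a("FD", +1, "b_FD")
    a("FD", +1, "v_FD", ("act", "SOC1", "K_FD"))
    a("FD", -1, "g_FD", ("mass", "FD"))
    # SOC1: activated by the FT-FD complex and by AGL24
    a("SOC1", +1, "b_S")
    a("SOC1", +1, "v_S1", ("act", "FT", "K_S1a"), ("act", "FD", "K_S1b"))
    a("SOC1", +1, "v_S2", ("act", "AGL24", "K_S2"))
    a("SOC1", -1, "g_S", ("mass", "SOC1"))
    # AGL24: mutual activation with SOC1, repressed by AP1
    a("AGL24", +1, "b_A")
    a("AGL24", +1, "v_A1", ("act", "SOC1", "K_A1"), ("inh", "AP1", "K_A2"))
    a("AGL24", -1, "g_A", ("mass", "AGL24"))
    # LFY: integrates SOC1, AGL24 and the AP1 feedback
    a("LFY", +1, "b_L")
    a("LFY", +1, "v_L1", ("act", "SOC1", "K_L1"))
    a("LFY", +1, "v_L2", ("act", "AGL24", "K_L2"))
    a("LFY", +1, "v_L3", ("act", "AP1", "K_L3"))
    a("LFY", -1, "g_L", ("mass", "LFY"))
    # AP1: LFY feedback (held off by AGL24) plus direct FT-FD activation
    a("AP1", +1, "b_P")
    a("AP1", +1, "v_P1", ("act", "LFY", "K_P1"), ("inh", "AGL24", "K_P3"))
    a("AP1", +1, "v_P2", ("act", "FT", "K_P2a"), ("act", "FD", "K_P2b"))
    a("AP1", -1, "g_P", ("mass", "AP1"))
    return ode


def flowering_time(grid, ap1_series, threshold: float) -> float:
    """First time AP1 exceeds the threshold, linearly interpolated.

    Series that never exceed the threshold are censored at the last grid
    time (the horizon).
    """
    grid = np.asarray(grid, dtype=float)
    s = np.asarray(ap1_series, dtype=float)
    if s.size == 0:
        raise ValueError("empty AP1 series")
    above = s > threshold
    if above[0]:
        return 0.0
    if not above.any():
        return float(grid[-1])
    j = int(np.argmax(above))
    t0, t1, s0, s1 = grid[j - 1], grid[j], s[j - 1], s[j]
    return float(t0 + (threshold - s0) / (s1 - s0) * (t1 - t0))


class FloweringModel:
    name = "flowering"
    task = "regression"

    def __init__(self):
        doc = _load_constants()
        self.rates = {k: float(v) for k, v in doc["rates"].items()}
        self.threshold = float(doc["threshold"])
        self.oe_factor = float(doc["oe_factor"])
        self.vary_sigma = float(doc["vary_sigma"])
        self.perturbed = list(doc["perturbed_params"])
        self.genotypes = {g: dict(v or {}) for g, v in doc["genotypes"].items()}
        self.ode = build_ode(self.rates, float(doc["horizon"]),
                             float(doc["dt"]), float(doc["out_every"]))
        unknown = [p for p in self.perturbed if p not in self.rates]
        if unknown:
            raise ValueError(f"perturbed params not in rate table: {unknown}")

    # -- structure ----------------------------------------------------
    def structure(self) -> dict:
        return {
            "n_states": len(STATES),
            "n_genotypes": len(self.genotypes),
            "n_perturbed_rates": len(self.perturbed),
            "n_features": 1 + len(self.perturbed),
        }

    # -- feature handling --------------------------------------------
    def feature_columns(self) -> list:
        return ["genotype"] + [f"pert_{p}" for p in self.perturbed]

    def _multipliers(self, X: pd.DataFrame) -> np.ndarray:
        """Per-sample multiplicative factors on the full rate vector."""
        n = len(X)
        mult = np.ones((n, self.ode.nominal.size))
        for k, p in enumerate(self.perturbed):
            mult[:, self.ode.pidx(p)] = X[f"pert_{p}"].to_numpy(dtype=float)
        for i, g in enumerate(X["genotype"]):
            for gene, allele in self.genotypes[g].items():
                factor = 0.0 if allele == "ko" else self.oe_factor
                for p in GENE_PRODUCTION[gene]:
                    mult[i, self.ode.pidx(p)] *= factor
        return mult

    def simulate_population(self, X: pd.DataFrame,
                            extra: np.ndarray | None = None) -> np.ndarray:
        mult = self._multipliers(X)
        if extra is not None:
            mult = mult * extra[None, :]
        return self.ode.simulate(mult)

    # -- ground truth -------------------------------------------------
    def generate(self, n: int, seed: int) -> Dataset:
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(np.random.SeedSequence(seed,
                                                           spawn_key=(0,)))
        genos = list(self.genotypes)
        gcol = [genos[k] for k in rng.integers(len(genos), size=n)]
        pert = np.exp(self.vary_sigma *
                      rng.standard_normal((n, len(self.perturbed))))
        X = pd.DataFrame({"genotype": gcol})
        for k, p in enumerate(self.perturbed):
            X[f"pert_{p}"] = pert[:, k]
        traj = self.simulate_population(X)
        ap1 = traj[:, STATES.index("AP1"), :]
        y = np.array([flowering_time(self.ode.grid, ap1[i], self.threshold)
                      for i in range(n)])
        meta = [FeatureMeta("genotype", "categorical", levels=tuple(genos))]
        meta += [FeatureMeta(f"pert_{p}", "continuous")
                 for p in self.perturbed]
        return Dataset(sample_ids(n), X, y, meta, task="regression",
                       model=self.name)

    # -- SimKern ------------------------------------------------------
    def uncertain_names(self) -> list:
        return [f"theta:{p}" for p in self.rates]

    def default_uncertainty(self, variant: str = "baseline") -> UncertaintySpec:
        """Noise variants: sd 0.1 / 0.2 / 0.4 Gaussian multipliers, or the
        biased uniform-discrete {0.01, 1, 5, 10} multipliers, applied to
        the same 34 rate parameters the ground truth varies."""
        sds = {"less-noise": 0.1, "baseline": 0.2, "more-noise": 0.4}
        if variant in sds:
            dist = MultiplicativeNormal(1.0, sds[variant])
            return UncertaintySpec({f"theta:{p}": dist for p in self.perturbed})
        if variant == "biased":
            dist = Discrete((0.01, 1.0, 5.0, 10.0))
            return UncertaintySpec({f"theta:{p}": dist for p in self.perturbed})
        raise ValueError(f"unknown flowering variant {variant!r}")

    def similarity_variables(self, variant: str = "baseline"):
        return list(STATES)

    def similarity_transform(self, variant: str = "baseline"):
        """Trajectories are compared on the log scale: expression levels
        span orders of magnitude across genotypes, and log1p keeps the
        population rescaling from being dominated by a few extreme
        overexpression samples."""
        return np.log1p

    def run_trial_batch(self, X: pd.DataFrame, draw) -> list:
        extra = np.ones(self.ode.nominal.size)
        for name, value in draw.values.items():
            extra[self.ode.pidx(name.split("theta:")[1])] = value
        traj = self.simulate_population(X, extra)
        grid = self.ode.grid
        out = []
        for i in range(traj.shape[0]):
            vals = traj[i]
            out.append(TrajectorySet(grid, STATES, vals)
                       if np.all(np.isfinite(vals)) else None)
        return out
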