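"""Radiation-response cell-fate model (four-class classification).

A 34-state ODE network captures, in stylized form, what happens after a
cell absorbs ionizing radiation: double-strand breaks (DSB) activate ATM,
which stabilizes and tetramerizes p53; p53 targets then drive four
competing programmes — DNA repair (GADD45/repair complex), cell-cycle
arrest (p21, 14-3-3sigma, Reprimo), apoptosis (PUMA/BAX/cytochrome-c/
apoptosome/caspases) and re-entry into cycling (CDC25, cyclins, RB/E2F).
The p53 core follows the classic ATM-phosphorylation / tetramerization
circuit; the arrest, repair and apoptosis blocks are this package's own
additions, with rate constants chosen for class diversity rather than
biochemical realism.

A sample is a cell type: multiplicative perturbations of 33 rate
constants plus knockout flags for six genes (ARF, BAX, SIAH, Reprimo,
p53, APAF1), 39 features in all.  End-of-horizon readouts are thresholded
into one of four fates, in fixed priority order: apoptosis (cleaved-PARP
marker), mitotic catastrophe (mitotic-damage marker: cycling with
unrepaired breaks), repaired-and-cycling (cycling with breaks cleared),
and quiescence otherwise.

The SimKern simulation is the same ODE system with 87 parameters marked
uncertain (Gaussian multipliers around their true values); its output is
the 34 time courses, not a classification.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import yaml

from simkern.datasets import Dataset, FeatureMeta, sample_ids
from simkern.ensemble import TrajectorySet
from simkern.models._odecore import NetworkOde
from simkern.uncertainty import MultiplicativeNormal, UncertaintySpec

STATES = [
    "DSB", "ATM", "ATMp", "CHK2", "p53", "p53p", "p53tet", "MDM2", "WIP1",
    "ARF", "SIAH", "REPRIMO", "P21", "GADD45", "SFN", "CDC25", "CYCE",
    "CYCB", "RB", "E2F", "PUMA", "BAX", "BCL2", "CYTC", "APAF1", "APOP",
    "CASP9", "CASP3", "PARPc", "REPAIR", "KU", "CYCLING", "MITDAM", "SEN",
]

CLASSES = ("apoptosis", "repaired-and-cycling", "mitotic-catastrophe",
           "quiescence")

MUTATED_GENES = ("ARF", "BAX", "SIAH", "Reprimo", "p53", "APAF1")

# production parameters silenced by each gene knockout
KNOCKOUT_PARAMS = {
    "ARF": ["b_arf", "v_arf"],
    "BAX": ["v_bax"],
    "SIAH": ["b_siah", "v_siah"],
    "Reprimo": ["v_repr"],
    "p53": ["b_p53"],
    "APAF1": ["b_apaf"],
}


def _load_constants() -> dict:
    ref = resources.files("simkern.models").joinpath("data/radiation.yaml")
    return yaml.safe_load(ref.read_text())


def build_ode(rates: dict, initial: dict, horizon: float, dt: float,
              out_every: float) -> NetworkOde:
    names = list(rates)
    init = np.zeros(len(STATES))
    for k, v in initial.items():
        init[STATES.index(k)] = float(v)
    ode = NetworkOde(STATES, names, np.array([rates[k] for k in names]),
                     initial_state=init, horizon=horizon, dt=dt,
                     out_every=out_every)
    a = ode.add_term
    # DNA damage and repair
    a("DSB", -1, "k_fix", ("mass", "REPAIR"), ("act", "DSB", "K_fix"))
    a("DSB", -1, "k_spont", ("mass", "DSB"))
    # ATM activation by damage
    a("ATM", +1, "b_atm")
    a("ATM", -1, "g_atm", ("mass", "ATM"))
    a("ATM", -1, "k_aact", ("mass", "ATM"), ("act", "DSB", "K_aact"))
    a("ATMp", +1, "k_aact", ("mass", "ATM"), ("act", "DSB", "K_aact"))
    a("ATMp", -1, "k_adeph", ("mass", "ATMp"), ("act", "WIP1", "K_adeph"))
    a("ATMp", -1, "g_atmp", ("mass", "ATMp"))
    a("CHK2", +1, "k_chk", ("act", "ATMp", "K_chk"))
    a("CHK2", -1, "g_chk", ("mass", "CHK2"))
    # p53 core: MDM2-mediated turnover (blocked by ARF), activation,
    # tetramerization, WIP1 feedback
    a("p53", +1, "b_p53")
    a("p53", -1, "k_mdm", ("mass", "p53"), ("act", "MDM2", "K_mdm"),
      ("inh", "ARF", "K_arf"))
    a("p53", -1, "k_pact", ("mass", "p53"), ("act", "ATMp", "K_pact"))
    a("p53", -1, "g_p53", ("mass", "p53"))
    a("p53p", +1, "k_pact", ("mass", "p53"), ("act", "ATMp", "K_pact"))
    a("p53p", -1, "k_pdeph", ("mass", "p53p"), ("act", "WIP1", "K_pdeph"))
    a("p53p", -1, "k_tet", ("mass", "p53p"), ("act", "p53p", "K_tet"))
    a("p53p", -1, "g_p53p", ("mass", "p53p"))
    a("p53tet", +1, "k_tet", ("mass", "p53p"), ("act", "p53p", "K_tet"))
    a("p53tet", -1, "k_mdm2t", ("mass", "p53tet"), ("act", "MDM2", "K_mdm"),
      ("inh", "ARF", "K_arf"))
    a("p53tet", -1, "g_ptet", ("mass", "p53tet"))
    a("MDM2", +1, "b_mdm")
    a("MDM2", +1, "v_mdm", ("act", "p53tet", "K_vmdm"))
    a("MDM2", -1, "k_sdeg", ("mass", "MDM2"), ("act", "SIAH", "K_sdeg"))
    a("MDM2", -1, "g_mdm", ("mass", "MDM2"))
    a("WIP1", +1, "v_wip", ("act", "p53tet", "K_vwip"))
    a("WIP1", -1, "g_wip", ("mass", "WIP1"))
    # p53 target genes
    a("ARF", +1, "b_arf")
    a("ARF", +1, "v_arf", ("act", "E2F", "K_varf"))
    a("ARF", -1, "g_arf", ("mass", "ARF"))
    a("SIAH", +1, "b_siah")
    a("SIAH", +1, "v_siah", ("act", "p53tet", "K_vsiah"))
    a("SIAH", -1, "g_siah", ("mass", "SIAH"))
    a("REPRIMO", +1, "v_repr", ("act", "p53tet", "K_vrepr"))
    a("REPRIMO", -1, "g_repr", ("mass", "REPRIMO"))
    a("P21", +1, "v_p21", ("act", "p53tet", "K_vp21"))
    a("P21", -1, "g_p21", ("mass", "P21"))
    a("GADD45", +1, "v_gad", ("act", "p53tet", "K_vgad"))
    a("GADD45", -1, "g_gad", ("mass", "GADD45"))
    a("SFN", +1, "v_sfn", ("act", "p53tet", "K_vsfn"))
    a("SFN", -1, "g_sfn", ("mass", "SFN"))
    # cell-cycle machinery
    a("CDC25", +1, "b_cdc")
    a("CDC25", -1, "k_cdcin", ("mass", "CDC25"), ("act", "CHK2", "K_cdcin"))
    a("CDC25", -1, "g_cdc", ("mass", "CDC25"))
    a("CYCE", +1, "v_ce", ("act", "E2F", "K_vce"), ("inh", "P21", "K_cep21"))
    a("CYCE", -1, "g_ce", ("mass", "CYCE"))
    a("CYCB", +1, "v_cb", ("act", "CDC25", "K_cbcdc"),
      ("inh", "SFN", "K_cbsfn"), ("inh", "P21", "K_cbp21"))
    a("CYCB", -1, "g_cb", ("mass", "CYCB"))
    a("RB", +1, "b_rb")
    a("RB", -1, "k_rbp", ("mass", "RB"), ("act", "CYCE", "K_rbp"))
    a("RB", -1, "g_rb", ("mass", "RB"))
    a("E2F", +1, "v_e2f", ("inh", "RB", "K_e2frb"))
    a("E2F", -1, "g_e2f", ("mass", "E2F"))
    # apoptosis cascade
    a("PUMA", +1, "v_puma", ("act", "p53tet", "K_vpuma"))
    a("PUMA", -1, "g_puma", ("mass", "PUMA"))
    a("BAX", +1, "v_bax", ("act", "p53tet", "K_vbax"))
    a("BAX", -1, "k_bcl", ("mass", "BAX"), ("act", "BCL2", "K_bcl"))
    a("BAX", -1, "g_bax", ("mass", "BAX"))
    a("BCL2", +1, "b_bcl2")
    a("BCL2", -1, "k_pb", ("mass", "BCL2"), ("act", "PUMA", "K_pb"))
    a("BCL2", -1, "g_bcl2", ("mass", "BCL2"))
    a("CYTC", +1, "k_cyt", ("act", "BAX", "K_cyt"))
    a("CYTC", -1, "g_cyt", ("mass", "CYTC"))
    a("APAF1", +1, "b_apaf")
    a("APAF1", -1, "k_apop", ("mass", "APAF1"), ("act", "CYTC", "K_apop"))
    a("APAF1", -1, "g_apaf", ("mass", "APAF1"))
    a("APOP", +1, "k_apop", ("mass", "APAF1"), ("act", "CYTC", "K_apop"))
    a("APOP", -1, "g_apop", ("mass", "APOP"))
    a("CASP9", +1, "k_c9", ("act", "APOP", "K_c9"))
    a("CASP9", -1, "g_c9", ("mass", "CASP9"))
    a("CASP3", +1, "k_c3", ("act", "CASP9", "K_c3"))
    a("CASP3", -1, "g_c3", ("mass", "CASP3"))
    a("PARPc", +1, "k_parp", ("act", "CASP3", "K_parp"))
    a("PARPc", -1, "g_parp", ("mass", "PARPc"))
    # repair machinery
    a("REPAIR", +1, "v_repair", ("act", "ATMp", "K_vrep"),
      ("act", "KU", "K_repku"))
    a("REPAIR", +1, "v_rep2", ("act", "GADD45", "K_rep2"))
    a("REPAIR", -1, "g_repair", ("mass", "REPAIR"))
    a("KU", +1, "b_ku")
    a("KU", -1, "g_ku", ("mass", "KU"))
    # integrated fate readouts
    a("CYCLING", +1, "k_cyc", ("act", "CYCB", "K_cycb"),
      ("act", "CYCE", "K_cyce"), ("inh", "REPRIMO", "K_cycrep"))
    a("CYCLING", -1, "g_cyc", ("mass", "CYCLING"))
    a("MITDAM", +1, "k_mit", ("act", "CYCB", "K_mitb"),
      ("act", "DSB", "K_mitd"))
    a("MITDAM", -1, "g_mit", ("mass", "MITDAM"))
    a("SEN", +1, "k_sen", ("act", "P21", "K_senp"))
    a("SEN", +1, "k_sen2", ("act", "REPRIMO", "K_senr"))
    a("SEN", -1, "g_sen", ("mass", "SEN"))
    return ode


def classify_radiation(traj: TrajectorySet, thresholds: dict) -> str:
    """Threshold end-of-horizon readouts into one of the four fates.

    The rule is total and applied in fixed priority order: an apoptosis
    marker above threshold wins outright; then mitotic catastrophe
    (mitotic-damage readout); then repaired-and-cycling (cycling readout
    high with breaks below the residual-damage threshold); quiescence is
    the default.
    """
    parp = traj.series("PARPc")[-1]
    mitdam = traj.series("MITDAM")[-1]
    cycling = traj.series("CYCLING")[-1]
    dsb = traj.series("DSB")[-1]
    if parp > thresholds["apoptosis"]:
        return "apoptosis"
    if mitdam > thresholds["mitotic"]:
        return "mitotic-catastrophe"
    if cycling > thresholds["cycling"] and dsb <= thresholds["residual_dsb"]:
        return "repaired-and-cycling"
    return "quiescence"


class RadiationModel:
    name = "radiation"
    task = "classification"
    classes = CLASSES

    def __init__(self):
        doc = _load_constants()
        self.rates = {k: float(v) for k, v in doc["rates"].items()}
        self.thresholds = {k: float(v) for k, v in doc["thresholds"].items()}
        self.varied = list(doc["varied_params"])        # 33 rate features
        self.uncertain = list(doc["uncertain_params"])  # 87 SimKern params
        self.vary_sigma = float(doc["vary_sigma"])
        self.mutation_prob = float(doc["mutation_prob"])
        self.simkern_sd = float(doc["simkern_sd"])
        self.relevant_vars = list(doc["classification_variables"])
        self.ode = build_ode(self.rates, doc["initial_state"],
                             float(doc["horizon"]), float(doc["dt"]),
                             float(doc["out_every"]))
        for group in (self.varied, self.uncertain):
            unknown = [p for p in group if p not in self.rates]
            if unknown:
                raise ValueError(f"unknown rate names: {unknown}")

    # -- structure ----------------------------------------------------
    def structure(self) -> dict:
        return {
            "n_states": len(STATES),
            "n_features": len(self.varied) + len(MUTATED_GENES),
            "n_uncertain_params": len(self.uncertain),
        }

    # -- feature handling ---------------------------------------------
    def feature_columns(self) -> list:
        return [f"pert_{p}" for p in self.varied] + \
               [f"mut_{g}" for g in MUTATED_GENES]

    def _multipliers(self, X: pd.DataFrame) -> np.ndarray:
        mult = np.ones((len(X), self.ode.nominal.size))
        for p in self.varied:
            mult[:, self.ode.pidx(p)] = X[f"pert_{p}"].to_numpy(dtype=float)
        for g in MUTATED_GENES:
            flag = X[f"mut_{g}"].to_numpy(dtype=float)
            for p in KNOCKOUT_PARAMS[g]:
                mult[:, self.ode.pidx(p)] *= (1.0 - flag)
        return mult

    def simulate_population(self, X: pd.DataFrame,
                            extra: np.ndarray | None = None) -> np.ndarray:
        mult = self._multipliers(X)
        if extra is not None:
            mult = mult * extra[None, :]
        return self.ode.simulate(mult)

    def trajectories(self, features_row) -> TrajectorySet:
        """Ground-truth dynamics of a single sample (34 time courses)."""
        from simkern.ensemble import SimulationError

        row = features_row if isinstance(features_row, pd.DataFrame) \
            else pd.DataFrame([features_row])
        traj = self.simulate_population(row)
        if not np.all(np.isfinite(traj[0])):
            raise SimulationError("radiation ODE integration diverged",
                                  sample_id=row.index[0])
        return TrajectorySet(self.ode.grid, STATES, traj[0])

    # -- ground truth -------------------------------------------------
    def generate(self, n: int, seed: int) -> Dataset:
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(np.random.SeedSequence(seed,
                                                           spawn_key=(0,)))
        pert = np.exp(self.vary_sigma *
                      rng.standard_normal((n, len(self.varied))))
        mut = (rng.random((n, len(MUTATED_GENES))) <
               self.mutation_prob).astype(int)
        X = pd.DataFrame(
            np.hstack([pert, mut]), columns=self.feature_columns())
        traj = self.simulate_population(X)
        y = np.array([
            classify_radiation(TrajectorySet(self.ode.grid, STATES, traj[i]),
                               self.thresholds)
            for i in range(n)], dtype=object)
        meta = [FeatureMeta(f"pert_{p}", "continuous") for p in self.varied]
        meta += [FeatureMeta(f"mut_{g}", "binary") for g in MUTATED_GENES]
        return Dataset(sample_ids(n), X, y, meta, task="classification",
                       model=self.name, classes=CLASSES)

    # -- SimKern ------------------------------------------------------
    def uncertain_names(self) -> list:
        return [f"theta:{p}" for p in self.rates]

    def default_uncertainty(self, variant: str = "baseline") -> UncertaintySpec:
        """87 rate parameters get Gaussian multipliers around truth."""
        dist = MultiplicativeNormal(1.0, self.simkern_sd)
        return UncertaintySpec({f"theta:{p}": dist for p in self.uncertain})

    def similarity_variables(self, variant: str = "baseline"):
        """'more-knowledge' restricts the kernel to the readouts the
        ground-truth classification actually uses; 'less-knowledge'
        (and the baseline) uses all 34 time courses."""
        if variant == "more-knowledge":
            return list(self.relevant_vars)
        return list(STATES)

    def similarity_transform(self, variant: str = "baseline"):
        # compare concentrations on the log scale so the population
        # rescaling is not dominated by a few extreme samples
        return np.log1p

    def run_trial_batch(self, X: pd.DataFrame, draw) -> list:
        extra = np.ones(self.ode.nominal.size)
        for name, value in draw.values.items():
            extra[self.ode.pidx(name.split("theta:")[1])] = value
        traj = self.simulate_population(X, extra)
        grid = self.ode.grid
        return [TrajectorySet(grid, STATES, traj[i])
                if np.all(np.isfinite(traj[i])) else None
                for i in range(traj.shape[0])]
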