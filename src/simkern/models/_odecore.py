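"""Vectorized regulatory-network ODE engine.

Models are declared as a list of production/degradation *terms*.  Each term
adds ``sign * k * prod(factors)`` to one state's derivative, where ``k`` is
a named rate parameter and each factor is one of

* ``mass(s)``  — the raw concentration of state ``s`` (mass action),
* ``act(s, K)`` — a saturating activation ``x_s / (K + x_s)``,
* ``inh(s, K)`` — a saturating inhibition ``K / (K + x_s)``.

All rate and Michaelis-type constants are named parameters, so a whole
population of samples can be simulated in one call by passing a matrix of
per-sample parameter multipliers.  Integration is fixed-step classical
Runge-Kutta with non-negativity clamping, which is adequate for the smooth
saturating kinetics used here and keeps the ensemble simulations fast and
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MASS, ACT, INH = 0, 1, 2


@dataclass(frozen=True)
class Factor:
    kind: int          # MASS | ACT | INH
    state: int
    kparam: int = -1   # parameter index of K for ACT/INH


@dataclass(frozen=True)
class Term:
    target: int
    sign: float
    rate: int          # parameter index of the rate constant
    factors: tuple = ()


@dataclass
class NetworkOde:
    """A population-vectorized ODE system over named states and rates."""

    state_names: list
    param_names: list
    nominal: np.ndarray          # nominal parameter values, shape (P,)
    terms: list = field(default_factory=list)
    initial_state: np.ndarray = None
    horizon: float = 50.0
    dt: float = 0.05
    out_every: float = 0.5

    def __post_init__(self):
        self.nominal = np.asarray(self.nominal, dtype=float)
        if self.initial_state is None:
            self.initial_state = np.zeros(len(self.state_names))
        self.initial_state = np.asarray(self.initial_state, dtype=float)
        if len(self.param_names) != self.nominal.size:
            raise ValueError("param_names / nominal length mismatch")
        self._pindex = {n: i for i, n in enumerate(self.param_names)}
        self._sindex = {n: i for i, n in enumerate(self.state_names)}

    # -- declarative construction ------------------------------------
    def pidx(self, name: str) -> int:
        return self._pindex[name]

    def sidx(self, name: str) -> int:
        return self._sindex[name]

    def add_term(self, target: str, sign: float, rate: str, *factors):
        """factors: tuples ('mass', state) | ('act'|'inh', state, Kparam)."""
        fs = []
        for f in factors:
            kind = {"mass": MASS, "act": ACT, "inh": INH}[f[0]]
            kp = self.pidx(f[2]) if kind != MASS else -1
            fs.append(Factor(kind, self.sidx(f[1]), kp))
        self.terms.append(Term(self.sidx(target), float(sign),
                               self.pidx(rate), tuple(fs)))

    # -- simulation ---------------------------------------------------
    @property
    def grid(self) -> np.ndarray:
        n_out = int(round(self.horizon / self.out_every))
        return np.linspace(0.0, n_out * self.out_every, n_out + 1)

    def _rhs(self, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        # x: (n, S), p: (n, P) effective parameters
        dx = np.zeros_like(x)
        for t in self.terms:
            r = t.sign * p[:, t.rate]
            for f in t.factors:
                xs = x[:, f.state]
                if f.kind == MASS:
                    r = r * xs
                elif f.kind == ACT:
                    r = r * xs / (p[:, f.kparam] + xs)
                else:
                    r = r * p[:, f.kparam] / (p[:, f.kparam] + xs)
            dx[:, t.target] += r
        return dx

    def simulate(self, multipliers: np.ndarray | None = None,
                 initial: np.ndarray | None = None) -> np.ndarray:
        """Integrate the population; returns trajectories (n, S, T).

        Parameters
        ----------
        multipliers:
            (n, P) per-sample multiplicative factors on the nominal
            parameter vector (1.0 = nominal).  ``None`` means one nominal
            sample.
        initial:
            optional (n, S) initial states; defaults to the model's.
        """
        if multipliers is None:
            multipliers = np.ones((1, self.nominal.size))
        multipliers = np.atleast_2d(np.asarray(multipliers, dtype=float))
        n = multipliers.shape[0]
        p = multipliers * self.nominal[None, :]
        if initial is None:
            x = np.tile(self.initial_state, (n, 1))
        else:
            x = np.array(np.atleast_2d(initial), dtype=float, copy=True)

        grid = self.grid
        steps_per_out = int(round(self.out_every / self.dt))
        if abs(steps_per_out * self.dt - self.out_every) > 1e-9:
            raise ValueError("out_every must be a multiple of dt")
        out = np.empty((n, len(self.state_names), grid.size))
        out[:, :, 0] = x
        h = self.dt
        # states couple only within a sample, so a numerical blow-up stays
        # confined to its own row and surfaces as NaN in that trajectory
        with np.errstate(over="ignore", invalid="ignore"):
            for j in range(1, grid.size):
                for _ in range(steps_per_out):
                    k1 = self._rhs(x, p)
                    k2 = self._rhs(x + 0.5 * h * k1, p)
                    k3 = self._rhs(x + 0.5 * h * k2, p)
                    k4 = self._rhs(x + h * k3, p)
                    x = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                    np.maximum(x, 0.0, out=x)
                out[:, :, j] = x
        return out
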