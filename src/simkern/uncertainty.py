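"""Uncertain-parameter specifications and seeded parameter draws.

The SimKern method treats the simulation model's questionable constants as
a random vector theta.  An :class:`UncertaintySpec` names each uncertain
parameter and attaches a marginal distribution; :func:`draw_parameters`
instantiates theta R times, one :class:`ParameterDraw` per ensemble trial.
Entries are drawn independently of one another (no covariance structure is
supported).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml


class SpecError(ValueError):
    """Raised for malformed uncertainty specifications."""


@dataclass(frozen=True)
class Point:
    """Degenerate distribution: the parameter is known exactly."""

    value: float

    def sample(self, rng):
        return self.value


@dataclass(frozen=True)
class Normal:
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd < 0:
            raise SpecError("normal sd must be >= 0")

    def sample(self, rng):
        return self.mean + self.sd * rng.standard_normal()


@dataclass(frozen=True)
class MultiplicativeNormal:
    """Gaussian multiplier applied to a nominal value, floored at a small
    positive value so multiplicative rates can never flip sign."""

    mean: float = 1.0
    sd: float = 0.2
    floor: float = 1e-6

    def __post_init__(self):
        if self.sd < 0:
            raise SpecError("multiplicative-normal sd must be >= 0")

    def sample(self, rng):
        return max(self.floor, self.mean + self.sd * rng.standard_normal())


@dataclass(frozen=True)
class Discrete:
    values: tuple
    probabilities: tuple = None

    def __post_init__(self):
        if not self.values:
            raise SpecError("discrete distribution needs values")
        if self.probabilities is not None:
            p = np.asarray(self.probabilities, dtype=float)
            if p.size != len(self.values) or np.any(p < 0) \
                    or abs(p.sum() - 1.0) > 1e-9:
                raise SpecError("discrete probabilities must be a "
                                "distribution over the values")

    def sample(self, rng):
        idx = rng.choice(len(self.values), p=self.probabilities)
        return self.values[idx]


@dataclass(frozen=True)
class CategoricalChoice:
    """Uniform pick among structurally different modelling options."""

    options: tuple

    def __post_init__(self):
        if not self.options:
            raise SpecError("categorical choice needs options")

    def sample(self, rng):
        return self.options[rng.integers(len(self.options))]


_DIST_TAGS = {
    "point": Point,
    "normal": Normal,
    "multiplicative-normal": MultiplicativeNormal,
    "discrete": Discrete,
    "categorical-choice": CategoricalChoice,
}


@dataclass
class UncertaintySpec:
    """Named marginal distributions for the uncertain parameter vector."""

    entries: dict = field(default_factory=dict)  # name -> distribution

    def __post_init__(self):
        for name, dist in self.entries.items():
            if not hasattr(dist, "sample"):
                raise SpecError(f"entry {name!r} is not a distribution")

    @property
    def names(self) -> list:
        return list(self.entries)

    def validate_against(self, known_names) -> None:
        known = set(known_names)
        missing = [n for n in self.entries if n not in known]
        if missing:
            raise SpecError(f"unknown model parameters: {missing}")

    # -- YAML round trip ---------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {}
        for name, d in self.entries.items():
            tag = next(t for t, cls in _DIST_TAGS.items() if isinstance(d, cls))
            fields = {k: (list(v) if isinstance(v, tuple) else v)
                      for k, v in d.__dict__.items() if v is not None}
            doc[name] = {"dist": tag, **fields}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "UncertaintySpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        entries = {}
        for name, body in doc.items():
            body = dict(body)
            tag = body.pop("dist")
            if tag not in _DIST_TAGS:
                raise SpecError(f"unknown distribution tag {tag!r}")
            body = {k: (tuple(v) if isinstance(v, list) else v)
                    for k, v in body.items()}
            entries[name] = _DIST_TAGS[tag](**body)
        return cls(entries)


@dataclass(frozen=True)
class ParameterDraw:
    """One instantiation theta_r of the uncertain parameter vector."""

    r: int
    values: dict  # parameter name -> drawn value

    def __getitem__(self, name):
        return self.values[name]


def _trial_rng(seed: int, r: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(r,)))


def draw_parameters(spec: UncertaintySpec, R: int, seed: int) -> list:
    """Instantiate theta_r for r = 1..R, reproducibly from (spec, seed)."""
    if R < 1:
        raise ValueError("R must be >= 1")
    draws = []
    for r in range(1, R + 1):
        rng = _trial_rng(seed, r)
        values = {name: dist.sample(rng) for name, dist in spec.entries.items()}
        draws.append(ParameterDraw(r, values))
    return draws
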