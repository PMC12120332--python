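"""Small sampler-spec language used by the synthetic study generator.

A sampler spec is either a plain number (a degenerate, constant sampler),
an already-constructed :class:`Sampler`, or a mapping such as
``{"dist": "lognormal", "mean_log": 3.35, "sd_log": 0.45}``.  Every sampler
exposes its analytic ``mean`` and ``sd`` so Monte-Carlo checks can compare
empirical moments against the intended ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class ConfigurationError(ValueError):
    """Raised when a sampler spec (or a SimConfig field) is invalid."""


class Sampler:
    def draw(self, rng: np.random.Generator, size=None):
        raise NotImplementedError

    @property
    def mean(self) -> float:
        raise NotImplementedError

    @property
    def sd(self) -> float:
        raise NotImplementedError


@dataclass(frozen=True)
class Constant(Sampler):
    value: float

    def draw(self, rng, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value, dtype=float)

    @property
    def mean(self):
        return float(self.value)

    @property
    def sd(self):
        return 0.0


@dataclass(frozen=True)
class Uniform(Sampler):
    low: float
    high: float

    def __post_init__(self):
        if not self.low <= self.high:
            raise ConfigurationError(f"uniform sampler needs low <= high, got {self.low} > {self.high}")

    def draw(self, rng, size=None):
        return rng.uniform(self.low, self.high, size=size)

    @property
    def mean(self):
        return 0.5 * (self.low + self.high)

    @property
    def sd(self):
        return (self.high - self.low) / math.sqrt(12.0)


@dataclass(frozen=True)
class Normal(Sampler):
    loc: float
    scale: float

    def __post_init__(self):
        if self.scale < 0:
            raise ConfigurationError("normal sampler needs scale >= 0")

    def draw(self, rng, size=None):
        return rng.normal(self.loc, self.scale, size=size)

    @property
    def mean(self):
        return float(self.loc)

    @property
    def sd(self):
        return float(self.scale)


@dataclass(frozen=True)
class LogNormal(Sampler):
    mean_log: float
    sd_log: float

    def __post_init__(self):
        if self.sd_log < 0:
            raise ConfigurationError("lognormal sampler needs sd_log >= 0")

    def draw(self, rng, size=None):
        return rng.lognormal(self.mean_log, self.sd_log, size=size)

    @property
    def mean(self):
        return math.exp(self.mean_log + 0.5 * self.sd_log**2)

    @property
    def sd(self):
        v = (math.exp(self.sd_log**2) - 1.0) * math.exp(2 * self.mean_log + self.sd_log**2)
        return math.sqrt(v)


@dataclass(frozen=True)
class BetaDist(Sampler):
    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ConfigurationError("beta sampler needs a, b > 0")

    def draw(self, rng, size=None):
        return rng.beta(self.a, self.b, size=size)

    @property
    def mean(self):
        return self.a / (self.a + self.b)

    @property
    def sd(self):
        s = self.a + self.b
        return math.sqrt(self.a * self.b / (s * s * (s + 1.0)))


@dataclass(frozen=True)
class Poisson(Sampler):
    lam: float

    def __post_init__(self):
        if self.lam < 0:
            raise ConfigurationError("poisson sampler needs lam >= 0")

    def draw(self, rng, size=None):
        return rng.poisson(self.lam, size=size)

    @property
    def mean(self):
        return float(self.lam)

    @property
    def sd(self):
        return math.sqrt(self.lam)


_DISTS = {
    "constant": (Constant, ("value",)),
    "uniform": (Uniform, ("low", "high")),
    "normal": (Normal, ("loc", "scale")),
    "lognormal": (LogNormal, ("mean_log", "sd_log")),
    "beta": (BetaDist, ("a", "b")),
    "poisson": (Poisson, ("lam",)),
}


def as_sampler(spec) -> Sampler:
    """Coerce a sampler spec to a :class:`Sampler`.

    Numbers become degenerate constants; dicts must carry a ``dist`` key
    naming one of: constant, uniform, normal, lognormal, beta, poisson.
    """
    if isinstance(spec, Sampler):
        return spec
    if isinstance(spec, (int, float)) and not isinstance(spec, bool):
        return Constant(float(spec))
    if isinstance(spec, dict):
        spec = dict(spec)
        name = spec.pop("dist", None)
        if name not in _DISTS:
            raise ConfigurationError(f"unknown sampler dist {name!r}; choose from {sorted(_DISTS)}")
        cls, fields = _DISTS[name]
        extra = set(spec) - set(fields)
        missing = set(fields) - set(spec)
        if extra or missing:
            raise ConfigurationError(
                f"sampler {name!r} takes parameters {fields}; got extra {sorted(extra)}, missing {sorted(missing)}"
            )
        return cls(**{k: float(spec[k]) for k in fields})
    raise ConfigurationError(f"cannot interpret sampler spec {spec!r}")
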