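"""Circular distributions: densities, seeded samplers, and named presets.

Families covered are the ones the simulation study needs: the circular
uniform, the von Mises, the wrapped skew normal, and finite mixtures of
those.  No wrapped Cauchy / cardioid / other families.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple, Union

import numpy as np
from scipy import special, stats

from .angles import TWO_PI, AngleSample, wrap_angles

RngLike = Union[int, np.random.Generator, np.random.SeedSequence, None]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WrappedSkewNormalSpec:
    """Wrapped skew normal parameters.

    location : xi, radians (location of the unwrapped skew normal)
    scale    : eta > 0 (linear scale of the unwrapped skew normal)
    shape    : alpha, skewness; alpha = 0 recovers the wrapped normal
    """

    location: float
    scale: float
    shape: float

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("wrapped skew normal scale must be > 0")


@dataclass(frozen=True)
class MixtureComponentSpec:
    """One component of a finite circular mixture.

    family is one of {"uniform", "von_mises", "wrapped_skew_normal"};
    parameters is the family-specific tuple: () for uniform,
    (mu, kappa) for von Mises, a WrappedSkewNormalSpec (or its
    (location, scale, shape) tuple) for the wrapped skew normal.
    """

    weight: float
    family: str
    parameters: Tuple = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("mixture weight must be in [0, 1]")
        if self.family not in ("uniform", "von_mises", "wrapped_skew_normal"):
            raise ValueError(f"unknown component family {self.family!r}")
        if self.family == "von_mises":
            _, kappa = self.parameters
            if kappa < 0:
                raise ValueError("von Mises concentration must be >= 0")


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def uniform_density(theta) -> np.ndarray:
    """Circular uniform density, ``1/(2*pi)`` everywhere."""
    theta = np.asarray(theta, dtype=float)
    return np.full_like(theta, 1.0 / TWO_PI)


def vonmises_density(theta, mu: float, kappa: float) -> np.ndarray:
    """von Mises density ``exp(kappa*cos(theta-mu)) / (2*pi*I0(kappa))``.

    Evaluated via exponentially scaled Bessel functions so that large
    concentrations (kappa up to several hundred) do not overflow.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    theta = np.asarray(theta, dtype=float)
    return np.exp(kappa * (np.cos(theta - mu) - 1.0)) / (TWO_PI * special.i0e(kappa))


def wrapped_skew_normal_density(theta, spec: WrappedSkewNormalSpec, wraps: int | None = None) -> np.ndarray:
    """Wrapped skew normal density by truncated wrapping sum.

    ``f(theta) = sum_k sn(theta + 2*pi*k; xi, eta, alpha)``; the number of
    wraps defaults to enough terms for the given scale (the unwrapped law
    has essentially no mass beyond ~6 scale units).
    """
    theta = np.asarray(theta, dtype=float)
    if wraps is None:
        wraps = max(2, int(np.ceil(6.0 * spec.scale / TWO_PI)) + 1)
    ks = np.arange(-wraps, wraps + 1)
    pts = theta[..., None] + TWO_PI * ks
    return stats.skewnorm.pdf(pts, spec.shape, loc=spec.location, scale=spec.scale).sum(axis=-1)


def mixture_density(theta, components: Sequence[MixtureComponentSpec]) -> np.ndarray:
    """Density of a finite mixture of circular components."""
    _check_weights(components)
    theta = np.asarray(theta, dtype=float)
    out = np.zeros_like(theta)
    for comp in components:
        if comp.family == "uniform":
            out += comp.weight * uniform_density(theta)
        elif comp.family == "von_mises":
            mu, kappa = comp.parameters
            out += comp.weight * vonmises_density(theta, mu, kappa)
        else:
            out += comp.weight * wrapped_skew_normal_density(theta, _as_wsn_spec(comp.parameters))
    return out


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def sample_uniform(n: int, rng_seed: RngLike = None) -> AngleSample:
    """``n`` i.i.d. draws from the circular uniform distribution."""
    _check_n(n)
    rng = _rng(rng_seed)
    return AngleSample(rng.uniform(0.0, TWO_PI, size=n))


def sample_vonmises(n: int, mu: float, kappa: float, rng_seed: RngLike = None) -> AngleSample:
    """``n`` i.i.d. draws from vM(mu, kappa); kappa = 0 is the uniform law."""
    _check_n(n)
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    rng = _rng(rng_seed)
    if kappa == 0.0:
        return AngleSample(rng.uniform(0.0, TWO_PI, size=n))
    # numpy's Generator.vonmises is the Best-Fisher rejection sampler
    return AngleSample(wrap_angles(rng.vonmises(mu, kappa, size=n)))


def sample_wrapped_skew_normal(n: int, spec: WrappedSkewNormalSpec, rng_seed: RngLike = None) -> AngleSample:
    """``n`` draws: skew-normal variates wrapped modulo ``2*pi``."""
    _check_n(n)
    rng = _rng(rng_seed)
    x = stats.skewnorm.rvs(spec.shape, loc=spec.location, scale=spec.scale, size=n, random_state=rng)
    return AngleSample(wrap_angles(x))


def sample_mixture(n: int, components: Sequence[MixtureComponentSpec], rng_seed: RngLike = None) -> AngleSample:
    """``n`` draws from a finite mixture: pick a component by weight, then sample it."""
    _check_n(n)
    _check_weights(components)
    rng = _rng(rng_seed)
    weights = np.array([c.weight for c in components], dtype=float)
    counts = rng.multinomial(n, weights / weights.sum())
    parts = []
    for comp, m in zip(components, counts):
        if m == 0:
            continue
        if comp.family == "uniform":
            parts.append(sample_uniform(m, rng).angles)
        elif comp.family == "von_mises":
            mu, kappa = comp.parameters
            parts.append(sample_vonmises(m, mu, kappa, rng).angles)
        else:
            parts.append(sample_wrapped_skew_normal(m, _as_wsn_spec(comp.parameters), rng).angles)
    out = np.concatenate(parts)
    rng.shuffle(out)
    return AngleSample(out)


# ---------------------------------------------------------------------------
# named presets: the study's alternative distributions
# ---------------------------------------------------------------------------

#: Unimodal von Mises power alternative: vM(pi, 1) (the cited mixture
#: generator's "model 2" preset).
VM_PRESET: Tuple[float, float] = (np.pi, 1.0)

#: Sharply skewed unimodal alternative.  The generator's preset is read as
#: shape alpha = 30 with a concentration of 2, i.e. linear scale
#: eta = 1/sqrt(2), centred at pi.  Overridable: it is just a spec value.
WSN_PRESET: WrappedSkewNormalSpec = WrappedSkewNormalSpec(
    location=np.pi, scale=1.0 / np.sqrt(2.0), shape=30.0
)

#: preset name -> sampler(n, rng) for the simulation study
def preset_sampler(name: str):
    """Return ``sampler(n, rng) -> AngleSample`` for a named distribution preset."""
    if name == "uniform":
        return lambda n, rng: sample_uniform(n, rng)
    if name in ("vm", "vonmises", "von_mises"):
        mu, kappa = VM_PRESET
        return lambda n, rng: sample_vonmises(n, mu, kappa, rng)
    if name in ("wsn", "wrapped_skew_normal"):
        return lambda n, rng: sample_wrapped_skew_normal(n, WSN_PRESET, rng)
    raise ValueError(f"unknown distribution preset {name!r}")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _check_n(n: int) -> None:
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError("n must be a positive integer")


def _check_weights(components: Sequence[MixtureComponentSpec]) -> None:
    if len(components) == 0:
        raise ValueError("mixture needs at least one component")
    total = sum(c.weight for c in components)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture weights must sum to 1 (got {total!r})")


def _as_wsn_spec(params) -> WrappedSkewNormalSpec:
    if isinstance(params, WrappedSkewNormalSpec):
        return params
    return WrappedSkewNormalSpec(*params)
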