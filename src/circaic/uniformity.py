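"""Traditional null-hypothesis tests of circular uniformity.

Five comparator tests: Rayleigh, Kuiper, Watson, Rao spacing, and
Hermans-Rasson.  Each returns a :class:`TestResult` with the statistic and
a p-value.  The Rayleigh test has a standard asymptotic p-value; the other
four use a seeded Monte Carlo engine (:func:`mc_pvalue`) simulating the
uniform null, with the add-one rule so that p is never exactly zero.

All statistic functions are vectorised over leading axes: they accept an
array of shape ``(..., n)`` holding one sample per row, which is what makes
Monte Carlo calibration and the simulation study affordable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .angles import TWO_PI, Angles, as_angle_sample
from .distributions import RngLike, _rng

#: pairwise-term constant of the Hermans-Rasson statistic (published value)
HR_BETA: float = 2.895

# cap on elements per vectorised chunk (keeps peak memory ~tens of MB)
_CHUNK_ELEMS = 4_000_000


@dataclass(frozen=True)
class TestResult:
    """Outcome of one uniformity test on one sample."""

    test_name: str
    statistic: float
    p_value: float
    n: int
    p_method: str  # "asymptotic" or "monte_carlo"
    mc_reps: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if (self.p_method == "monte_carlo") != (self.mc_reps is not None):
            raise ValueError("mc_reps must be present exactly when p_method is monte_carlo")


# ---------------------------------------------------------------------------
# statistics (vectorised over leading axes)
# ---------------------------------------------------------------------------

def rayleigh_statistic(theta: np.ndarray) -> np.ndarray:
    """Mean resultant length ``Rbar`` per sample (last axis)."""
    theta = np.asarray(theta, dtype=float)
    c = np.cos(theta).sum(axis=-1)
    s = np.sin(theta).sum(axis=-1)
    return np.hypot(c, s) / theta.shape[-1]


def kuiper_statistic(theta: np.ndarray) -> np.ndarray:
    """Kuiper ``Vn = D+ + D-`` from the uniform probability-integral transform.

    The transform uses the fixed origin 0 (``u = theta / (2*pi)``); the
    Monte Carlo null uses the same convention, so the test is exact even
    though ``Vn`` itself is origin-dependent.
    """
    theta = np.asarray(theta, dtype=float)
    n = theta.shape[-1]
    u = np.sort(theta, axis=-1) / TWO_PI
    j = np.arange(1, n + 1, dtype=float)
    d_plus = (j / n - u).max(axis=-1)
    d_minus = (u - (j - 1.0) / n).max(axis=-1)
    return d_plus + d_minus


def watson_statistic(theta: np.ndarray) -> np.ndarray:
    """Watson ``U^2`` statistic (rotation invariant)."""
    theta = np.asarray(theta, dtype=float)
    n = theta.shape[-1]
    u = np.sort(theta, axis=-1) / TWO_PI
    j = np.arange(1, n + 1, dtype=float)
    ubar = u.mean(axis=-1)
    dev = ((u - (2.0 * j - 1.0) / (2.0 * n)) ** 2).sum(axis=-1)
    return dev - n * (ubar - 0.5) ** 2 + 1.0 / (12.0 * n)


def rao_spacing_statistic(theta: np.ndarray) -> np.ndarray:
    """Rao spacing ``U = 0.5 * sum |T_i - 2*pi/n|`` over the n arc gaps (radians)."""
    theta = np.asarray(theta, dtype=float)
    n = theta.shape[-1]
    srt = np.sort(theta, axis=-1)
    gaps = np.diff(srt, axis=-1)
    wrap = TWO_PI - (srt[..., -1] - srt[..., 0])
    dev = np.abs(gaps - TWO_PI / n).sum(axis=-1) + np.abs(wrap - TWO_PI / n)
    return 0.5 * dev


def hermans_rasson_statistic(theta: np.ndarray, beta: float = HR_BETA) -> np.ndarray:
    """Hermans-Rasson pairwise statistic, normalised by n.

    ``T = (1/n) * sum_{i,j} [ |pi - |t_i - t_j|| - pi/2
    - beta * (|sin(t_i - t_j)| - 2/pi) ]``

    Both pairwise terms are centred at their uniform-null expectation, so
    concentrated samples push ``T`` up; uniformity is rejected for large
    ``T``.  Depends only on pairwise differences, hence rotation invariant.
    """
    theta = np.asarray(theta, dtype=float)
    n = theta.shape[-1]
    flat = theta.reshape(-1, n)
    out = np.empty(flat.shape[0])
    step = max(1, _CHUNK_ELEMS // (n * n))
    for lo in range(0, flat.shape[0], step):
        blk = flat[lo:lo + step]
        d = blk[:, :, None] - blk[:, None, :]
        term = np.abs(np.pi - np.abs(d)) - np.pi / 2.0
        term -= beta * (np.abs(np.sin(d)) - 2.0 / np.pi)
        out[lo:lo + step] = term.sum(axis=(-2, -1)) / n
    return out.reshape(theta.shape[:-1])


# ---------------------------------------------------------------------------
# Monte Carlo engine
# ---------------------------------------------------------------------------

def mc_pvalue(
    observed_stat: float,
    stat_fn: Callable[[np.ndarray], np.ndarray],
    n: int,
    reps: int = 10_000,
    seed: RngLike = None,
) -> float:
    """Monte Carlo tail p-value of ``observed_stat`` under the uniform null.

    Simulates ``reps`` uniform samples of size ``n`` and returns
    ``(1 + #{stat >= observed}) / (reps + 1)`` (add-one rule, so p is in
    ``(0, 1]`` and never exactly zero).  ``stat_fn`` should accept an array
    of shape ``(m, n)`` and return ``m`` statistics; a plain
    one-sample-at-a-time callable also works (slower fallback).

    Deterministic for a fixed integer seed.
    """
    if reps < 99:
        raise ValueError("reps must be >= 99")
    rng = _rng(seed)
    exceed = 0
    step = max(1, _CHUNK_ELEMS // max(n, 1))
    done = 0
    while done < reps:
        m = min(step, reps - done)
        nulls = rng.uniform(0.0, TWO_PI, size=(m, n))
        try:
            stats = np.asarray(stat_fn(nulls), dtype=float)
            if stats.shape != (m,):
                raise TypeError
        except Exception:
            stats = np.array([float(stat_fn(row)) for row in nulls])
        exceed += int((stats >= observed_stat).sum())
        done += m
    return (1 + exceed) / (reps + 1)


# ---------------------------------------------------------------------------
# public tests
# ---------------------------------------------------------------------------

def rayleigh_test(
    sample: Angles,
    p_method: str = "asymptotic",
    mc_reps: int = 10_000,
    seed: Optional[int] = None,
) -> TestResult:
    """Rayleigh test of uniformity (statistic: mean resultant length Rbar).

    The default p-value is the standard large-sample approximation
    ``p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n))`` with ``R = n*Rbar``;
    ``p_method="monte_carlo"`` switches to the simulation engine.
    """
    s = as_angle_sample(sample)
    _check_min_n(s.n, 2)
    rbar = float(rayleigh_statistic(s.angles))
    if p_method == "asymptotic":
        r_total = s.n * rbar
        p = np.exp(np.sqrt(1.0 + 4.0 * s.n + 4.0 * (s.n ** 2 - r_total ** 2)) - (1.0 + 2.0 * s.n))
        return TestResult("rayleigh", rbar, float(min(p, 1.0)), s.n, "asymptotic")
    if p_method == "monte_carlo":
        p = mc_pvalue(rbar, rayleigh_statistic, s.n, mc_reps, seed)
        return TestResult("rayleigh", rbar, p, s.n, "monte_carlo", mc_reps, seed)
    raise ValueError(f"unknown p_method {p_method!r}")


def kuiper_test(sample: Angles, mc_reps: int = 10_000, seed: Optional[int] = None) -> TestResult:
    """Kuiper test of uniformity (Vn = D+ + D-), Monte Carlo p-value."""
    s = as_angle_sample(sample)
    _check_min_n(s.n, 2)
    v = float(kuiper_statistic(s.angles))
    p = mc_pvalue(v, kuiper_statistic, s.n, mc_reps, seed)
    return TestResult("kuiper", v, p, s.n, "monte_carlo", mc_reps, seed)


def watson_test(sample: Angles, mc_reps: int = 10_000, seed: Optional[int] = None) -> TestResult:
    """Watson U^2 test of uniformity, Monte Carlo p-value."""
    s = as_angle_sample(sample)
    _check_min_n(s.n, 2)
    u2 = float(watson_statistic(s.angles))
    p = mc_pvalue(u2, watson_statistic, s.n, mc_reps, seed)
    return TestResult("watson", u2, p, s.n, "monte_carlo", mc_reps, seed)


def rao_spacing_test(sample: Angles, mc_reps: int = 10_000, seed: Optional[int] = None) -> TestResult:
    """Rao spacing test of uniformity, Monte Carlo p-value."""
    s = as_angle_sample(sample)
    _check_min_n(s.n, 4)
    u = float(rao_spacing_statistic(s.angles))
    p = mc_pvalue(u, rao_spacing_statistic, s.n, mc_reps, seed)
    return TestResult("rao", u, p, s.n, "monte_carlo", mc_reps, seed)


def hermans_rasson_test(sample: Angles, mc_reps: int = 9_999, seed: Optional[int] = None) -> TestResult:
    """Hermans-Rasson test of uniformity, Monte Carlo p-value.

    Powerful over a broad range of alternatives, including multimodal
    ones; simulation-based by construction.
    """
    if mc_reps < 999:
        raise ValueError("mc_reps must be >= 999 for the Hermans-Rasson test")
    s = as_angle_sample(sample)
    _check_min_n(s.n, 2)
    t = float(hermans_rasson_statistic(s.angles))
    p = mc_pvalue(t, hermans_rasson_statistic, s.n, mc_reps, seed)
    return TestResult("hr", t, p, s.n, "monte_carlo", mc_reps, seed)


ALL_TESTS = ("rayleigh", "kuiper", "watson", "rao", "hr")


def run_test(name: str, sample: Angles, mc_reps: int = 10_000, seed: Optional[int] = None) -> TestResult:
    """Dispatch a uniformity test by name."""
    if name == "rayleigh":
        return rayleigh_test(sample)
    if name == "kuiper":
        return kuiper_test(sample, mc_reps, seed)
    if name == "watson":
        return watson_test(sample, mc_reps, seed)
    if name == "rao":
        return rao_spacing_test(sample, mc_reps, seed)
    if name == "hr":
        return hermans_rasson_test(sample, max(mc_reps, 999), seed)
    raise ValueError(f"unknown test {name!r}")


def _check_min_n(n: int, minimum: int) -> None:
    if n < minimum:
        raise ValueError(f"test requires at least {minimum} angles (got {n})")
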