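"""Von Mises mixture model suite, constrained ML fitting, and delta-AIC.

The family is the two-component von Mises mixture

    f(theta) = lam * vM(theta; q1, k1) + (1 - lam) * vM(theta; q2, k2)

with mean directions ``q1, q2``, concentrations ``k1, k2 >= 0`` and mixing
weight ``lam`` in ``[0, 1]``.  Ten hypotheses are obtained by constraining
the five parameters (the model registry below); the evidence against
circular uniformity is the AIC difference

    delta_aic = AIC(M1) - min over alternative models of AIC,

large positive values meaning the uniform model M1 loses badly to some
alternative.

The registry is declarative (free parameters + fixed values + ties), so a
constraint pattern can be corrected by editing one table entry without
touching the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, special

from .angles import (
    TWO_PI,
    Angles,
    as_angle_sample,
    axial_mean,
    circular_mean,
    resultant_length,
)

#: upper bound for concentrations during fitting; unbounded kappa diverges
#: on degenerate (all-identical) samples, and 500 exceeds any biologically
#: plausible concentration.
KAPPA_MAX: float = 500.0

PARAM_NAMES: Tuple[str, ...] = ("q1", "k1", "q2", "k2", "lam")


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixture-model hypothesis.

    free  : names of freely estimated parameters (their count is ``k``)
    fixed : parameter -> constant value
    ties  : parameter -> (source parameter, additive offset)
    """

    name: str
    free: Tuple[str, ...]
    fixed: Mapping[str, float] = field(default_factory=dict)
    ties: Mapping[str, Tuple[str, float]] = field(default_factory=dict)
    description: str = ""

    @property
    def k(self) -> int:
        """Number of free parameters (AIC penalty)."""
        return len(self.free)

    def full_params(self, x: Sequence[float]) -> Dict[str, float]:
        """Expand a free-parameter vector into all five mixture parameters."""
        p: Dict[str, float] = dict(self.fixed)
        p.update(zip(self.free, x))
        for name, (src, off) in self.ties.items():
            p[name] = p[src] + off
        return p


def _m(name, free, fixed=None, ties=None, desc=""):
    return ModelSpec(name, tuple(free), dict(fixed or {}), dict(ties or {}), desc)


#: The ten-model suite, in canonical (registry) order.  M1 is the uniform
#: null; for single-component models the second component is tied to the
#: first so that warm starts project cleanly between nested models.
MODELS: Dict[str, ModelSpec] = {
    m.name: m
    for m in [
        _m("M1", [], {"q1": 0.0, "k1": 0.0, "lam": 1.0},
           {"q2": ("q1", 0.0), "k2": ("k1", 0.0)}, "uniform (random)"),
        _m("M2A", ["q1", "k1"], {"lam": 1.0},
           {"q2": ("q1", 0.0), "k2": ("k1", 0.0)}, "unimodal von Mises"),
        _m("M2B", ["q1", "k1", "lam"], {"k2": 0.0},
           {"q2": ("q1", 0.0)}, "unimodal von Mises + uniform"),
        _m("M2C", ["q1", "k1", "k2", "lam"], {},
           {"q2": ("q1", 0.0)}, "two same-direction von Mises"),
        _m("M3A", ["q1", "k1"], {"lam": 0.5},
           {"q2": ("q1", np.pi), "k2": ("k1", 0.0)}, "axial bimodal, equal weights"),
        _m("M3B", ["q1", "k1", "lam"], {},
           {"q2": ("q1", np.pi), "k2": ("k1", 0.0)}, "axial bimodal, free weights"),
        _m("M4A", ["q1", "k1", "q2"], {"lam": 0.5},
           {"k2": ("k1", 0.0)}, "bimodal, shared concentration, equal weights"),
        _m("M4B", ["q1", "k1", "q2", "lam"], {},
           {"k2": ("k1", 0.0)}, "bimodal, shared concentration, free weights"),
        _m("M5A", ["q1", "k1", "q2", "k2"], {"lam": 0.5}, {},
           "bimodal, free concentrations, equal weights"),
        _m("M5B", ["q1", "k1", "q2", "k2", "lam"], {}, {},
           "bimodal, fully free"),
    ]
}

MODEL_ORDER: Tuple[str, ...] = tuple(MODELS)

SUITES: Dict[str, Tuple[str, ...]] = {
    "S2": ("M1", "M2A"),
    "S4": ("M1", "M2A", "M2B", "M2C"),
    "S10": MODEL_ORDER,
}

#: nested submodels used as warm starts when fitting a whole suite
_WARM_PARENTS: Dict[str, Tuple[str, ...]] = {
    "M2B": ("M2A",),
    "M2C": ("M2B", "M2A"),
    "M3A": ("M2A",),
    "M3B": ("M3A",),
    "M4A": ("M3A", "M2A"),
    "M4B": ("M4A", "M3B"),
    "M5A": ("M4A",),
    "M5B": ("M4B", "M5A"),
}


def model_registry(suite_name: str) -> List[ModelSpec]:
    """The models of one suite: S2 (uniform vs von Mises), S4 (+ the other
    unimodal variants), or S10 (all ten)."""
    if suite_name not in SUITES:
        raise ValueError(f"unknown suite {suite_name!r}; choose from {sorted(SUITES)}")
    return [MODELS[name] for name in SUITES[suite_name]]


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _bessel_ratio(kappa: float) -> float:
    """A(kappa) = I1(kappa) / I0(kappa), computed with scaled Bessels."""
    return float(special.i1e(kappa) / special.i0e(kappa))


def kappa_mle(rbar: float) -> float:
    """Invert A(kappa) = rbar: the classical von Mises concentration MLE.

    Clipped to ``[0, KAPPA_MAX]``; ``rbar`` at or beyond ``A(KAPPA_MAX)``
    (degenerate, near-point samples) returns the bound.
    """
    if rbar <= 0.0:
        return 0.0
    if rbar >= _bessel_ratio(KAPPA_MAX):
        return KAPPA_MAX
    if rbar < 1e-8:
        return 2.0 * rbar  # small-kappa expansion A(kappa) ~ kappa/2
    return float(optimize.brentq(lambda k: _bessel_ratio(k) - rbar, 1e-12, KAPPA_MAX))


def _loglik_and_grad(theta: np.ndarray, p: Mapping[str, float]):
    """Log-likelihood of the full five-parameter mixture and its gradient
    with respect to (q1, k1, q2, k2, lam)."""
    q1, k1, q2, k2, lam = (p[name] for name in PARAM_NAMES)
    c1 = np.cos(theta - q1)
    c2 = np.cos(theta - q2)
    # scaled form exp(k*(cos-1)) / (2*pi*i0e(k)) never overflows
    g1 = np.exp(k1 * (c1 - 1.0)) / (TWO_PI * special.i0e(k1))
    g2 = np.exp(k2 * (c2 - 1.0)) / (TWO_PI * special.i0e(k2))
    # floor protects against underflow at extreme concentrations (e.g. a
    # boundary weight with the live component's density vanishing at some
    # observation); the true density is strictly positive
    f = np.maximum(lam * g1 + (1.0 - lam) * g2, 1e-300)
    logl = float(np.log(f).sum())
    w1 = lam * g1 / f
    w2 = (1.0 - lam) * g2 / f
    grad = {
        "q1": float((w1 * k1 * np.sin(theta - q1)).sum()),
        "k1": float((w1 * (c1 - _bessel_ratio(k1))).sum()),
        "q2": float((w2 * k2 * np.sin(theta - q2)).sum()),
        "k2": float((w2 * (c2 - _bessel_ratio(k2))).sum()),
        "lam": float(((g1 - g2) / f).sum()),
    }
    return logl, grad


def mixture_loglik(sample: Angles, params: Sequence[float]) -> float:
    """Log-likelihood of the full mixture at ``params = (q1, k1, q2, k2, lam)``."""
    s = as_angle_sample(sample)
    q1, k1, q2, k2, lam = (float(v) for v in params)
    if k1 < 0 or k2 < 0:
        raise ValueError("concentrations must be >= 0")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("mixing weight must be in [0, 1]")
    logl, _ = _loglik_and_grad(s.angles, dict(zip(PARAM_NAMES, (q1, k1, q2, k2, lam))))
    return logl


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one model on one sample."""

    model: ModelSpec
    estimates: Dict[str, float]  # all five parameters after constraints
    logL: float
    aic: float
    converged: bool
    n_starts_used: int

    @property
    def name(self) -> str:
        return self.model.name


@dataclass(frozen=True)
class SuiteComparison:
    """All fits of one suite on one sample, plus the delta-AIC statistic."""

    suite_name: str
    fits: Dict[str, FitResult]
    best_model: str
    delta_aic: float

    def table(self):
        """Per-model summary as a pandas DataFrame (name, k, logL, AIC, ...)."""
        import pandas as pd

        rows = []
        for name, fr in self.fits.items():
            row = {"model": name, "k": fr.model.k, "logL": fr.logL, "AIC": fr.aic,
                   "converged": fr.converged}
            row.update({p: fr.estimates[p] for p in PARAM_NAMES})
            rows.append(row)
        return pd.DataFrame(rows)


def _bounds_for(model: ModelSpec) -> List[Tuple[Optional[float], Optional[float]]]:
    out: List[Tuple[Optional[float], Optional[float]]] = []
    for name in model.free:
        if name.startswith("q"):
            # mean directions are periodic: leave them unbounded and wrap
            # the estimate afterwards (no 0/2pi seam for the optimizer)
            out.append((None, None))
        elif name.startswith("k"):
            out.append((0.0, KAPPA_MAX))
        else:  # lam
            out.append((0.0, 1.0))
    return out


def _start_points(model: ModelSpec, theta: np.ndarray, n_starts: int) -> List[np.ndarray]:
    """Deterministic multi-start grid for one model.

    Smart starts come first: the closed-form von Mises MLE direction /
    concentration, the axial (angle-doubling) estimate for bimodal models,
    and an antipodal second mode.  A coarse direction x concentration grid
    pads the list up to ``n_starts``.
    """
    mu = circular_mean(theta)
    rbar = resultant_length(theta)
    khat = min(kappa_mle(rbar), 50.0)
    mu_ax = axial_mean(theta)
    a2 = np.hypot(np.sin(2 * theta).sum(), np.cos(2 * theta).sum()) / theta.size
    khat_ax = min(kappa_mle(a2), 50.0)

    base = {"q1": mu, "k1": max(khat, 0.05), "q2": np.mod(mu + np.pi, TWO_PI),
            "k2": max(khat, 0.05), "lam": 0.5}
    axial = {"q1": mu_ax, "k1": max(khat_ax, 0.05), "q2": np.mod(mu_ax + np.pi, TWO_PI),
             "k2": max(khat_ax, 0.05), "lam": 0.5}

    smart: List[Dict[str, float]] = []
    if model.name in ("M2A", "M2B", "M2C"):
        smart.append(dict(base, lam=0.9))
        smart.append(dict(base, lam=0.5, k2=0.05))
    elif model.name in ("M3A", "M3B"):
        smart.append(axial)
        smart.append(base)
    else:  # M4/M5 families
        smart.append(axial)
        smart.append(base)
        smart.append(dict(axial, k2=0.5))

    grid: List[Dict[str, float]] = []
    for q in (mu, np.mod(mu + np.pi, TWO_PI), mu_ax):
        for kap in (0.5, 2.0, 10.0):
            grid.append({"q1": q, "k1": kap, "q2": np.mod(q + np.pi, TWO_PI),
                         "k2": kap, "lam": 0.5})

    starts: List[np.ndarray] = []
    seen = set()
    for cand in smart + grid:
        x = np.array([cand[name] for name in model.free], dtype=float)
        key = tuple(np.round(x, 6))
        if key not in seen:
            seen.add(key)
            starts.append(x)
        if len(starts) >= max(n_starts, 1):
            break
    return starts


def _clip_to_bounds(x: np.ndarray, model: ModelSpec) -> np.ndarray:
    out = x.copy()
    for i, name in enumerate(model.free):
        if name.startswith("k"):
            out[i] = np.clip(out[i], 0.0, KAPPA_MAX)
        elif name == "lam":
            out[i] = np.clip(out[i], 0.0, 1.0)
    return out


def _finish(model: ModelSpec, x: np.ndarray, logl: float, converged: bool,
            n_starts_used: int, n: int) -> FitResult:
    p = model.full_params(x)
    est = {name: float(p[name]) for name in PARAM_NAMES}
    est["q1"] = float(np.mod(est["q1"], TWO_PI))
    est["q2"] = float(np.mod(est["q2"], TWO_PI))
    aic = 2.0 * model.k - 2.0 * logl
    return FitResult(model, est, float(logl), float(aic), converged, n_starts_used)


def fit_model(
    sample: Angles,
    model: ModelSpec | str,
    n_starts: int = 5,
    seed: int = 0,
    extra_starts: Sequence[Sequence[float]] = (),
) -> FitResult:
    """Fit one mixture model by bounded quasi-Newton ML with multiple starts.

    Mean directions are optimised unbounded (the likelihood is periodic in
    them) and wrapped into ``[0, 2*pi)`` afterwards; concentrations are
    bounded to ``[0, KAPPA_MAX]`` and the weight to ``[0, 1]``.  The best
    local optimum over all starts is returned; if no start converges the
    best evaluated point is still returned with ``converged=False`` (never
    an exception).

    ``extra_starts`` are additional free-parameter vectors (used by
    :func:`fit_suite` to warm-start a model from its nested submodels).
    ``seed`` only matters when ``n_starts`` exceeds the deterministic grid:
    surplus starts are drawn at random.
    """
    if isinstance(model, str):
        model = MODELS[model]
    s = as_angle_sample(sample)
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if model.k == 0:
        # uniform model: closed form, no optimisation
        logl = -s.n * np.log(TWO_PI)
        return _finish(model, np.empty(0), logl, True, 0, s.n)
    if s.n < 2:
        raise ValueError("models with free parameters need n >= 2")

    theta = s.angles

    def neg(x: np.ndarray):
        p = model.full_params(x)
        # guard: ties never violate bounds, but optimizer steps are clipped
        # by L-BFGS-B itself for bounded coordinates
        logl, grad = _loglik_and_grad(theta, p)
        g = np.zeros_like(x)
        acc = {name: grad[name] for name in PARAM_NAMES}
        for name, (src, _off) in model.ties.items():
            acc[src] = acc[src] + acc[name]
        for i, name in enumerate(model.free):
            g[i] = acc[name]
        return -logl, -g

    starts = _start_points(model, theta, n_starts)
    rng = np.random.default_rng(seed)
    while len(starts) < n_starts:
        x = np.empty(model.k)
        for i, name in enumerate(model.free):
            if name.startswith("q"):
                x[i] = rng.uniform(0.0, TWO_PI)
            elif name.startswith("k"):
                x[i] = rng.uniform(0.0, 20.0)
            else:
                x[i] = rng.uniform(0.0, 1.0)
        starts.append(x)
    for xs in extra_starts:
        starts.append(_clip_to_bounds(np.asarray(xs, dtype=float), model))

    bounds = _bounds_for(model)
    best_x, best_f, any_ok = None, np.inf, False
    for x0 in starts:
        res = optimize.minimize(
            neg, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-11, "gtol": 1e-7, "maxiter": 200},
        )
        any_ok = any_ok or bool(res.success)
        if res.fun < best_f:
            best_f, best_x = float(res.fun), np.asarray(res.x, dtype=float)
    return _finish(model, best_x, -best_f, any_ok, len(starts), s.n)


def fit_suite(sample: Angles, suite_name: str, n_starts: int = 3, seed: int = 0) -> SuiteComparison:
    """Fit every model of a suite and form the delta-AIC statistic.

    Models are fitted in registry order; each model additionally starts
    from the projected estimates of its already-fitted nested submodels,
    which both speeds the search up and enforces the nesting monotonicity
    of the fitted log-likelihoods.

    ``delta_aic = AIC(M1) - min over alternatives of AIC``; the best model
    is the overall AIC minimiser (ties: fewest parameters, then registry
    order).
    """
    s = as_angle_sample(sample)
    specs = model_registry(suite_name)
    fits: Dict[str, FitResult] = {}
    for spec in specs:
        warm: List[np.ndarray] = []
        for parent in _WARM_PARENTS.get(spec.name, ()):
            if parent in fits:
                full = fits[parent].estimates
                warm.append(np.array([full[name] for name in spec.free], dtype=float))
        fits[spec.name] = fit_model(s, spec, n_starts=n_starts, seed=seed, extra_starts=warm)

    alt_aics = [fr.aic for name, fr in fits.items() if name != "M1"]
    delta = float(fits["M1"].aic - min(alt_aics))
    order = {name: i for i, name in enumerate(SUITES[suite_name])}
    best = min(fits.values(), key=lambda fr: (fr.aic, fr.model.k, order[fr.name]))
    return SuiteComparison(suite_name, fits, best.name, delta)
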