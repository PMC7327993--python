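import numpy as np
import pytest

from circaic.angles import TWO_PI, circular_dist, circular_mean, resultant_length
from circaic.distributions import sample_uniform, sample_vonmises, vonmises_density
from circaic.models import (
    MODELS,
    SUITES,
    fit_model,
    fit_suite,
    kappa_mle,
    mixture_loglik,
    model_registry,
)

# nested (smaller, larger) model pairs: the larger contains the smaller
NESTED_PAIRS = [
    ("M1", "M2A"), ("M2A", "M2B"), ("M2B", "M2C"), ("M3A", "M3B"),
    ("M2A", "M4A"), ("M3A", "M4A"), ("M4A", "M4B"), ("M4A", "M5A"),
    ("M5A", "M5B"), ("M4B", "M5B"),
]


class TestRegistry:
    def test_suite_contents(self):
        s2 = model_registry("S2")
        assert [m.name for m in s2] == ["M1", "M2A"]
        assert s2[0].k == 0 and s2[1].k == 2
        assert [m.name for m in model_registry("S4")] == ["M1", "M2A", "M2B", "M2C"]
        s10 = model_registry("S10")
        assert len(s10) == 10
        assert len({m.name for m in s10}) == 10

    def test_parameter_counts_bounded(self):
        for m in model_registry("S10"):
            assert 0 <= m.k <= 5
        assert MODELS["M5B"].k == 5  # fully free two-component mixture

    def test_unknown_suite_rejected(self):
        with pytest.raises(ValueError):
            model_registry("S3")

    def test_constraints_expand_consistently(self):
        # axial models put the second mode exactly opposite the first
        p = MODELS["M3A"].full_params([1.0, 2.5])
        assert p["q2"] == pytest.approx(1.0 + np.pi)
        assert p["k2"] == pytest.approx(2.5)
        assert p["lam"] == 0.5


class TestLoglik:
    def test_uniform_closed_form(self):
        s = sample_uniform(10, 1)
        expected = -10.0 * np.log(TWO_PI)
        assert mixture_loglik(s, (0.0, 0.0, 0.0, 0.0, 1.0)) == pytest.approx(expected)
        assert expected == pytest.approx(-18.37877066, abs=1e-6)

    def test_zero_concentrations_collapse_to_uniform(self):
        s = sample_uniform(25, 2)
        base = -25.0 * np.log(TWO_PI)
        for lam in (0.0, 0.3, 1.0):
            assert mixture_loglik(s, (1.0, 0.0, 4.0, 0.0, lam)) == pytest.approx(base)

    def test_matches_brute_force_sum_of_log_densities(self):
        rng = np.random.default_rng(3)
        s = sample_uniform(40, 4)
        for _ in range(10):
            q1, q2 = rng.uniform(0, TWO_PI, 2)
            k1, k2 = rng.uniform(0, 20, 2)
            lam = rng.uniform(0, 1)
            direct = float(np.log(
                lam * vonmises_density(s.angles, q1, k1)
                + (1 - lam) * vonmises_density(s.angles, q2, k2)
            ).sum())
            assert mixture_loglik(s, (q1, k1, q2, k2, lam)) == pytest.approx(direct, abs=1e-10)

    def test_out_of_bound_parameters_rejected(self):
        s = sample_uniform(5, 5)
        with pytest.raises(ValueError):
            mixture_loglik(s, (0.0, -1.0, 0.0, 0.0, 1.0))
        with pytest.raises(ValueError):
            mixture_loglik(s, (0.0, 1.0, 0.0, 0.0, 1.5))


class TestFitModel:
    def test_uniform_model_closed_form(self):
        s = sample_uniform(10, 6)
        fr = fit_model(s, "M1")
        assert fr.logL == pytest.approx(-10.0 * np.log(TWO_PI))
        assert fr.aic == pytest.approx(20.0 * np.log(TWO_PI))
        assert fr.aic == pytest.approx(36.7575413, abs=1e-6)
        assert fr.converged

    def test_m2a_recovers_vonmises_parameters(self):
        s = sample_vonmises(10_000, 2.0, 3.0, 7)
        fr = fit_model(s, "M2A")
        assert circular_dist(fr.estimates["q1"], 2.0) < 0.05
        assert abs(fr.estimates["k1"] - 3.0) < 0.15

    def test_aic_identity(self):
        s = sample_vonmises(60, 1.0, 2.0, 8)
        for name in SUITES["S10"]:
            fr = fit_model(s, name, n_starts=2)
            assert fr.aic == pytest.approx(2.0 * fr.model.k - 2.0 * fr.logL, abs=1e-9)

    def test_m2a_never_below_uniform_likelihood(self):
        # nesting: M2A contains the uniform at k1 = 0
        for seed in range(8):
            s = sample_uniform(12, 100 + seed)
            fr = fit_model(s, "M2A")
            assert fr.logL >= -12.0 * np.log(TWO_PI) - 1e-9

    def test_free_parameter_models_need_two_points(self):
        with pytest.raises(ValueError):
            fit_model([1.0], "M2A")
        fr = fit_model([1.0], "M1")  # uniform fits a single angle
        assert fr.logL == pytest.approx(-np.log(TWO_PI))


class TestFitSuite:
    def test_concentrated_sample_selects_vonmises(self):
        s = sample_vonmises(100, np.pi, 5.0, 9)
        comp = fit_suite(s, "S2")
        assert comp.best_model == "M2A"
        assert comp.delta_aic > 2.0

    def test_evenly_spaced_sample_collapses_to_penalty(self):
        # every alternative degenerates to the uniform fit; only the AIC
        # penalty of the smallest alternative (k = 2) remains
        theta = TWO_PI * (np.arange(1, 13) - 0.5) / 12
        comp = fit_suite(theta, "S2")
        assert comp.delta_aic == pytest.approx(-4.0, abs=1e-4)
        assert comp.best_model == "M1"

    def test_delta_aic_rotation_equivariant(self):
        s = sample_vonmises(50, 1.0, 2.0, 10)
        base = fit_suite(s, "S4")
        for shift in (0.7, np.pi, 5.1):
            rot = fit_suite(np.mod(s.angles + shift, TWO_PI), "S4")
            assert rot.delta_aic == pytest.approx(base.delta_aic, abs=1e-6)

    @pytest.mark.parametrize("seed,n,maker", [
        (11, 40, lambda n, seed: sample_vonmises(n, 2.0, 4.0, seed)),
        (12, 40, lambda n, seed: sample_uniform(n, seed)),
    ])
    def test_nesting_monotonicity_of_fitted_likelihoods(self, seed, n, maker):
        comp = fit_suite(maker(n, seed), "S10")
        for small, large in NESTED_PAIRS:
            assert comp.fits[large].logL >= comp.fits[small].logL - 1e-6, (small, large)

    def test_best_model_attains_minimum_aic(self):
        comp = fit_suite(sample_vonmises(60, 0.5, 3.0, 13), "S10")
        best_aic = min(fr.aic for fr in comp.fits.values())
        assert comp.fits[comp.best_model].aic == pytest.approx(best_aic)


class TestKappaMle:
    def test_round_trip_through_bessel_ratio(self):
        from scipy import special
        for kappa in (0.3, 1.0, 5.0, 60.0):
            rbar = special.i1e(kappa) / special.i0e(kappa)
            assert kappa_mle(float(rbar)) == pytest.approx(kappa, rel=1e-6)
        assert kappa_mle(0.0) == 0.0
        assert kappa_mle(1.0) == 500.0  # degenerate samples hit the bound


def test_s2_null_exceedance_matches_boundary_lrt_theory(null_study):
    """Under uniformity, delta_aic(S2) > 0 iff the von Mises LRT exceeds 4;
    the LRT is asymptotically the Rayleigh statistic 2*n*Rbar^2 ~ chi2(2),
    so the exceedance proportion should sit near exp(-2) ~ 0.135."""
    for n in (20, 50, 100):
        frac = float(np.mean(null_study[n]["S2"] > 0.0))
        assert 0.08 <= frac <= 0.20, (n, frac)
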