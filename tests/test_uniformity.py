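import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circaic.angles import TWO_PI
from circaic.distributions import MixtureComponentSpec, sample_mixture, sample_vonmises
from circaic.uniformity import (
    TestResult as UniformityTestResult,
    hermans_rasson_statistic,
    hermans_rasson_test,
    kuiper_statistic,
    kuiper_test,
    mc_pvalue,
    rao_spacing_statistic,
    rao_spacing_test,
    rayleigh_statistic,
    rayleigh_test,
    watson_statistic,
    watson_test,
)


def evenly_spaced(n):
    return TWO_PI * (np.arange(1, n + 1) - 0.5) / n


@pytest.mark.parametrize("n", [4, 7, 20, 51])
def test_evenly_spaced_angles_closed_forms(n):
    theta = evenly_spaced(n)
    assert abs(float(kuiper_statistic(theta)) - 1.0 / n) < 1e-10
    assert abs(float(watson_statistic(theta)) - 1.0 / (12.0 * n)) < 1e-10
    assert abs(float(rao_spacing_statistic(theta))) < 1e-10
    assert abs(float(rayleigh_statistic(theta))) < 1e-10


def test_identical_angles_closed_forms():
    n = 10
    theta = np.full(n, 1.0)
    # point mass: Rbar maximal, one circular gap of 2*pi
    assert float(rayleigh_statistic(theta)) == pytest.approx(1.0)
    assert float(rao_spacing_statistic(theta)) == pytest.approx(TWO_PI * (n - 1) / n)
    # ECDF jumps 0 -> 1 at the atom: D+ = 1-u, D- = u, Vn = 1 exactly
    assert float(kuiper_statistic(theta)) == pytest.approx(1.0)
    r = rayleigh_test(theta)
    assert r.statistic == pytest.approx(1.0)
    assert r.p_value < 1e-3


def test_gaps_always_sum_to_full_circle():
    rng = np.random.default_rng(0)
    for _ in range(20):
        theta = np.sort(rng.uniform(0, TWO_PI, 17))
        gaps = np.append(np.diff(theta), TWO_PI - (theta[-1] - theta[0]))
        assert gaps.sum() == pytest.approx(TWO_PI, abs=1e-10)


@settings(derandomize=True, deadline=None, max_examples=40)
@given(
    st.lists(st.floats(0, TWO_PI, exclude_max=True), min_size=5, max_size=25),
    st.floats(-10, 10),
)
def test_rotation_invariance_of_statistics(angles, shift):
    theta = np.asarray(angles)
    rotated = np.mod(theta + shift, TWO_PI)
    assert float(rayleigh_statistic(rotated)) == pytest.approx(
        float(rayleigh_statistic(theta)), abs=1e-9)
    assert float(watson_statistic(rotated)) == pytest.approx(
        float(watson_statistic(theta)), abs=1e-9)
    assert float(rao_spacing_statistic(rotated)) == pytest.approx(
        float(rao_spacing_statistic(theta)), abs=1e-9)
    assert float(hermans_rasson_statistic(rotated)) == pytest.approx(
        float(hermans_rasson_statistic(theta)), abs=1e-8)


def test_mc_pvalue_extremes_and_add_one_rule():
    reps = 199
    assert mc_pvalue(-np.inf, rayleigh_statistic, 10, reps, seed=1) == 1.0
    assert mc_pvalue(np.inf, rayleigh_statistic, 10, reps, seed=1) == 1.0 / (reps + 1)
    with pytest.raises(ValueError):
        mc_pvalue(0.0, rayleigh_statistic, 10, reps=50, seed=1)


def test_mc_pvalue_stabilises_with_more_replicates():
    obs = float(rayleigh_statistic(sample_vonmises(20, np.pi, 1.0, 5).angles))
    p1 = mc_pvalue(obs, rayleigh_statistic, 20, reps=4_000, seed=2)
    p2 = mc_pvalue(obs, rayleigh_statistic, 20, reps=8_000, seed=3)
    assert abs(p1 - p2) < 3.0 * np.sqrt(p1 * (1 - p1) / 4_000)


def test_mc_pvalue_accepts_scalar_statistic_callable():
    # non-vectorised callables take the (slow) row-by-row fallback
    obs = 0.9
    p_vec = mc_pvalue(obs, rayleigh_statistic, 10, reps=299, seed=4)
    p_scalar = mc_pvalue(obs, lambda row: float(rayleigh_statistic(row)), 10, reps=299, seed=4)
    assert p_vec == p_scalar


def test_rayleigh_asymptotic_p_matches_monte_carlo():
    s = sample_vonmises(20, np.pi, 1.0, 5)
    p_asym = rayleigh_test(s).p_value
    p_mc = rayleigh_test(s, p_method="monte_carlo", mc_reps=100_000, seed=1).p_value
    assert abs(p_asym - p_mc) < 0.01


def test_minimum_sample_sizes_enforced():
    with pytest.raises(ValueError):
        rayleigh_test([1.0])
    with pytest.raises(ValueError):
        kuiper_test([1.0])
    with pytest.raises(ValueError):
        rao_spacing_test([1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        hermans_rasson_test([1.0, 2.0], mc_reps=500)


def test_testresult_validation():
    with pytest.raises(ValueError):
        UniformityTestResult("x", 0.0, 1.5, 10, "asymptotic")
    with pytest.raises(ValueError):
        UniformityTestResult("x", 0.0, 0.5, 10, "monte_carlo")  # mc_reps missing


def _mc_power(sample_fn, stat_fn, reps=400, inner=999, n=20):
    hits = 0
    for i in range(reps):
        s = sample_fn(i)
        nulls = np.random.default_rng(1_000_000 + i).uniform(0, TWO_PI, (inner, n))
        p = (1 + int((stat_fn(nulls) >= float(stat_fn(s.angles))).sum())) / (inner + 1)
        hits += p < 0.05
    return hits / reps


def test_hr_power_comparable_on_unimodal_and_superior_on_axial_data():
    """The Hermans-Rasson statistic weights odd and even harmonics, so it
    concedes a little power to Rayleigh against a pure von Mises but keeps
    high power against axial data, where Rayleigh is essentially blind."""
    vm = lambda i: sample_vonmises(20, np.pi, 1.0, 50_000 + i)
    p_hr = _mc_power(vm, hermans_rasson_statistic)
    p_ray = np.mean([rayleigh_test(vm(i)).p_value < 0.05 for i in range(400)])
    assert p_hr >= 0.5
    assert p_hr >= p_ray - 0.25

    comps = [MixtureComponentSpec(0.5, "von_mises", (0.0, 4.0)),
             MixtureComponentSpec(0.5, "von_mises", (np.pi, 4.0))]
    axial = lambda i: sample_mixture(20, comps, 90_000 + i)
    p_hr_ax = _mc_power(axial, hermans_rasson_statistic, reps=300)
    p_ray_ax = np.mean([rayleigh_test(axial(i)).p_value < 0.05 for i in range(300)])
    assert p_hr_ax > 0.7
    assert p_ray_ax < 0.2


def test_watson_test_returns_monte_carlo_result():
    s = sample_vonmises(30, 1.0, 2.0, 7)
    r = watson_test(s, mc_reps=999, seed=3)
    assert r.p_method == "monte_carlo"
    assert r.mc_reps == 999
    assert 0 < r.p_value <= 1
    # concentrated sample: all tests should find it
    assert r.p_value < 0.05
    assert kuiper_test(s, mc_reps=999, seed=3).p_value < 0.05
    assert rao_spacing_test(s, mc_reps=999, seed=3).p_value < 0.05
    assert hermans_rasson_test(s, mc_reps=999, seed=3).p_value < 0.05
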