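# Methods

This note records the statistical model, the numerical choices, and the
limits of what the package's simulations can show.

## The testing problem

A sample θ₁…θₙ of angles is tested against the null of circular
uniformity, density 1/(2π). Two families of procedures are implemented:

1. **Traditional tests** — Rayleigh, Kuiper, Watson U², Rao spacing, and
   Hermans–Rasson — each reducing the sample to a scalar statistic whose
   null distribution is known (Rayleigh) or simulated (the rest).
2. **The delta-AIC rule** — fit a suite of von Mises mixture models plus
   the uniform model M1 by maximum likelihood and reject uniformity when
   ΔAIC = AIC(M1) − min AIC(alternatives) exceeds a cut-off.

The package's contribution is making route 2 a calibrated test: the
cut-off Z is derived by simulation so that the rule's type I error equals
the nominal level for the given sample size and suite.

## Model suite

All models are constraints of f(θ) = λ·vM(θ;q₁,k₁) + (1−λ)·vM(θ;q₂,k₂):

| model | free parameters | constraints | k |
|-------|-----------------|-------------|---|
| M1  | —                | k₁=0, λ=1           | 0 |
| M2A | q₁,k₁            | λ=1                 | 2 |
| M2B | q₁,k₁,λ          | q₂=q₁, k₂=0         | 3 |
| M2C | q₁,k₁,k₂,λ       | q₂=q₁               | 4 |
| M3A | q₁,k₁            | q₂=q₁+π, k₂=k₁, λ=½ | 2 |
| M3B | q₁,k₁,λ          | q₂=q₁+π, k₂=k₁      | 3 |
| M4A | q₁,k₁,q₂         | k₂=k₁, λ=½          | 3 |
| M4B | q₁,k₁,q₂,λ       | k₂=k₁               | 4 |
| M5A | q₁,k₁,q₂,k₂      | λ=½                 | 4 |
| M5B | q₁,k₁,q₂,k₂,λ    | —                   | 5 |

M2-x are unimodal (M2B mixes in a uniform "background", M2C a second
same-direction component), M3-x are axial (antipodal modes, shared
concentration), M4/M5 progressively free the second mode. The registry is
a declarative table (free + fixed + tied parameters), so a pattern can be
corrected in one line without touching the optimizer. Suites: S2 =
{M1, M2A}, S4 = {M1, M2A–C}, S10 = all ten.

## Maximum likelihood fitting

- **Parameter space.** Mean directions are optimised unbounded — the
  likelihood is 2π-periodic in them, so no seam exists for the optimizer —
  and wrapped into [0, 2π) afterwards. Concentrations live in
  [0, k_max] with k_max = 500 (unbounded κ diverges on near-degenerate
  samples; 500 is far beyond any biologically plausible concentration);
  weights in [0, 1].
- **Objective.** The log-likelihood and its analytic gradient are
  evaluated with exponentially scaled Bessel functions,
  vM = exp(k(cosΔ−1))/(2π·I0e(k)), so large κ cannot overflow; the mixture
  density is floored at 1e-300 against underflow at extreme parameters.
- **Optimizer.** L-BFGS-B, ftol 1e-11 / gtol 1e-7, per start; the best of
  all starts wins. If no start converges the best evaluated point is
  returned flagged `converged=False` — never an exception, since the
  simulation loops must not die on a pathological replicate.
- **Starts.** Deterministic: the closed-form von Mises estimate (circular
  mean, A⁻¹(R̄)) for unimodal models, the angle-doubling axial estimate
  with its antipode for bimodal ones, padded by a coarse direction ×
  concentration grid ({0.5, 2, 10}); `fit_suite` additionally warm-starts
  every model from its already-fitted nested submodels. Warm starts are
  what make the nesting monotonicity (larger model never fits worse) hold
  to 1e-6 in practice, and they cut the cost of a full S10 fit to a few
  dozen milliseconds per sample.
- **Ties.** Best model = lowest AIC, then fewest parameters, then
  registry order — deterministic output.

## Calibration of Z

`calibrate_Z(n, suite, alpha, reps, seed)` simulates `reps` uniform
samples of size n, computes the null ΔAIC for the suite on each, and
returns the order statistic such that exactly ⌊alpha·reps⌋ null draws
exceed Z (rejection is by strict inequality; the strict/non-strict choice
matters only at O(1/reps)). Consequences, all tested:

- on the calibration draws, the exceedance fraction is *exactly*
  ⌊alpha·reps⌋/reps;
- Z is nonincreasing in alpha;
- on shared null draws Z(S10) ≥ Z(S4) ≥ Z(S2), because the minimum over
  more models can only grow ΔAIC.

For S2, asymptotic theory pins the answer: ΔAIC > z iff the likelihood
ratio exceeds z + 4, and the vM-vs-uniform LRT is asymptotically the
Rayleigh statistic 2nR̄² ~ χ²₂, giving Z ≈ q₉₅(χ²₂) − 4 = 1.99 and a
null P(ΔAIC > 0) ≈ e⁻² ≈ 0.135. The simulated values (Z ≈ 1.9–2.3 for
n ≥ 20, exceedance ≈ 0.13) agree; this closed form is used as an
independent oracle in the tests, never as the implementation.

Default `reps` is 10,000 (the full-scale protocol); the package's own test
suite and the acceptance script use 1,000–2,000, which locates Z to about
±0.1 AIC units and rates to ±0.01–0.016 — the Monte Carlo standard errors
are carried in every result table.

## Traditional tests

- **Rayleigh**: statistic R̄; p-value from the standard large-sample
  approximation exp(√(1+4n+4(n²−R²)) − (1+2n)), R = nR̄, cross-checked
  against Monte Carlo to ±0.01 in the tests.
- **Kuiper Vₙ, Watson U², Rao spacing U**: order-statistic formulas on the
  probability-integral transform u = θ/2π (Kuiper uses the fixed origin 0;
  the Monte Carlo null uses the same convention, so the test stays exact).
  P-values by simulation, default 10,000 replicates, add-one rule
  (1 + #{null ≥ obs})/(reps + 1) so p is never exactly 0.
- **Hermans–Rasson**: the pairwise statistic
  T = (1/n)·Σᵢⱼ [ |π−|θᵢ−θⱼ|| − π/2 − 2.895·(|sin(θᵢ−θⱼ)| − 2/π) ],
  diagonal included, rejected for large T. Both terms are centred at their
  uniform expectation; in the Fourier domain the first term loads the odd
  harmonics and the (negative) sine term the even ones, which is why the
  test keeps high power against axial data (where Rayleigh is blind) at
  the cost of some power against a pure von Mises. Tie handling: none —
  duplicate angles are legitimate and simply enter the double sum.

All Monte Carlo machinery is vectorised over replicates in memory-bounded
chunks (a few million elements), which is what keeps the full simulation
study on one core tractable.

## Simulation study

`type1_experiment` / `power_experiment` implement the shared-sample
design: per sample size, one set of simulated samples feeds every rule
(the five tests and each suite × cut-off combination), so rules are
compared on identical data. Replicate i at size index j draws all its
randomness from `SeedSequence(seed, spawn_key=(j, i))`; results are
therefore bit-identical whether the loop runs serially, chunked, or under
joblib — a property the tests assert.

Alternatives for power are the named presets: von Mises vM(π, 1) and the
wrapped skew normal with location π, scale 1/√2, shape 30 (a sharply
right-skewed unimodal law). Both presets are interpretations of a
generator convention (the upstream mixture generator's "model 2" and its
"κ=30, con=2" wrapped-skew-normal, read as shape 30 with the linear scale
1/√con); they are plain config values a user can override, and nothing in
the calibration or testing machinery depends on the particular preset.
Power is only computed for the calibrated cut-off Z — the fixed cut-offs
0 and 2 have inflated type I error, so their "power" would not be
comparable and the API refuses to compute it.

## What the synthetic data does and does not show

The generators produce i.i.d. draws from clean parametric laws with full
angular resolution. Real orientation data frequently violate this:
readings rounded to 5° or 10° (which inflates spacing-type tests), serial
dependence within an animal, and axial ambiguity of the recording method.
None of these are modelled; passing tests demonstrate correctness of the
procedures under their stated assumptions, not robustness to those
artefacts. Rounded-data corrections and axial preprocessing (angle
doubling) are deliberately out of scope.

## Problem sizes used by the validation suite

The test suite runs the study at desk scale — 1,000–2,000 replicates per
condition, sample sizes {10, 20, 50, 100}, inner Monte Carlo 999–2,000 —
chosen so the whole suite completes in roughly a quarter hour on one core
while keeping every check's Monte Carlo standard error well inside its
assertion band. The acceptance script uses 1,000–2,000 replicates per
target for the same reason. Full-scale (10,000-replicate) runs are a
single flag away in the CLI and library defaults.

## Known limitations

- The ΔAIC rule is reported as reject/retain with the statistic and the
  cut-off, deliberately not as a p-value; interpolating a p-value from the
  null draws would overstate the resolution of a 10³–10⁴-replicate null.
- Calibration depends (weakly) on the optimizer: a fitter that finds
  deeper likelihood optima shifts the null ΔAIC distribution slightly
  upward — and Z with it. Z values regenerated under this package are
  internally consistent, which is what the validity of the test requires;
  they are not guaranteed to match tables produced by other software to
  the second decimal.
- Mixture likelihoods are multimodal; with the default start policy a
  global optimum is not provable, only (as tested) reliably attained for
  the model scales at hand.
- No three-or-more-component mixtures, no BIC, no confidence intervals on
  fitted parameters.
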