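# circaic

Model selection as a test of circular uniformity — with the type I error
under control.

Many biological measurements live on a circle: animal headings, times of
day, phases of an annual cycle. The first question asked of such data is
almost always *is there any directional preference at all?*, classically
answered by a null-hypothesis test (Rayleigh, Kuiper, Watson, Rao spacing,
Hermans–Rasson). An increasingly popular alternative is model comparison:
fit a suite of von Mises mixture models together with the uniform model M1
and ask whether any alternative beats M1 by AIC. `circaic` implements both
routes and, crucially, the Monte Carlo calibration that makes the AIC route
a *valid* test.

## The method

The model family is the two-component von Mises mixture

```
f(θ) = λ·vM(θ; q₁, k₁) + (1−λ)·vM(θ; q₂, k₂),
```

constrained into ten hypotheses `M1, M2A–M2C, M3A–M3B, M4A–M4B, M5A–M5B`
(uniform; unimodal variants; axial and general bimodal variants). Three
nested suites are used: **S2** = {M1, M2A}, **S4** = {M1, M2A, M2B, M2C},
**S10** = all ten. Each model is fitted by constrained maximum likelihood
(multi-start bounded quasi-Newton), and the evidence against uniformity is

```
ΔAIC = AIC(M1) − min over alternative models of AIC.
```

Rejecting uniformity whenever ΔAIC > 0 is badly anticonservative — with
S10 at n = 10 the false-positive rate approaches 40% — and the textbook
cut-off of 2 is only adequate for the two-model suite. `circaic` therefore
derives, by simulating the uniform null, the critical value **Z** such that
ΔAIC > Z has exactly the nominal 5% type I error for a given sample size
and suite. (For S2, asymptotic theory says Z ≈ q₉₅(χ²₂) − 4 ≈ 2, which the
simulation reproduces.) The five traditional tests are included as
comparators, with exact Monte Carlo p-values where no reliable closed form
exists.

## Worked example

```python
import numpy as np
from circaic import (sample_vonmises, rayleigh_test, fit_suite,
                     calibrate_Z, CalibrationTable, analyze)

bearings = sample_vonmises(100, mu=np.pi, kappa=5.0, rng_seed=1)

print(rayleigh_test(bearings))
# TestResult(test_name='rayleigh', statistic=0.8837..., p_value=1.89e-46,
#            n=100, p_method='asymptotic', ...)

comp = fit_suite(bearings, "S10")
print(comp.best_model, round(comp.delta_aic, 2))
# M2A 219.17

entry = calibrate_Z(n=100, suite_name="S2", alpha=0.05, reps=2000, seed=0)
report = analyze(bearings, suite_name="S2",
                 ztable=CalibrationTable([entry]))
print(report.summary())
# n = 100
#  rayleigh: statistic = 0.8837, p = 1.895e-46
# AIC rule (S2): delta AIC = 219.166, Z = 1.990, best model = M2A -> REJECT uniformity
```

Both detectors agree emphatically: the mean resultant length R̄ = 0.88 is
enormous for n = 100 (Rayleigh p ≈ 10⁻⁴⁶), and the unimodal von Mises
model beats the uniform by 219 AIC units, far above the calibrated cut-off
Z ≈ 2.0.

The same workflow from the shell, e.g. for a file of homing-pigeon
bearings in degrees (one per line; such data ship with the R package
`circular`):

```sh
circaic calibrate --n 23 --suite S10 --reps 10000 --seed 0 --out ztable.csv
circaic analyze --file pigeons_control.txt --units deg --suite S10 --ztable ztable.csv
```

Other subcommands: `simulate` (seeded samples from the built-in circular
distributions), `test` (the five traditional tests), `mle` (the per-model
fit table), `type1` and `power` (the full simulation study, CSV output).

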