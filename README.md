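# doserr

A simulation laboratory for **dose measurement-error correction in
radiation epidemiology**.  It generates synthetic grouped cohorts whose
doses carry shared and unshared Berkson and classical lognormal errors,
fits excess-relative-risk (ERR) Poisson models with six correction
strategies, and scores each strategy by the coverage probability of its
95% intervals and the bias of its predicted ERR.

It is aimed at biostatisticians and radiation epidemiologists who want
to reproduce, probe or extend coverage/bias comparisons of dose-error
corrections — in particular the failure mode of ensemble
model-averaging estimators under heavy *shared* dose error.

## The model

Cohorts are grouped by dose (five groups shaped like bone-marrow-dose
strata of an atomic-bomb-survivor cohort).  True and surrogate doses
for individual *i* of group *k* in dose realization *j* are

    D_true,ij = D_cent,k · e^{−(σ²_sB+σ²_uB)/2} · e^{σ_sB ε_j + σ_uB δ_ij}
    D_surr,ij = D_cent,k · e^{−(σ²_sC+σ²_uC)/2} · e^{σ_sC μ_j + σ_uC κ_ij}

(s/u = shared/unshared, B/C = Berkson/classical; ε, δ, μ, κ i.i.d.
N(0,1)).  Cancer cases (N = 250 per ensemble) are drawn from grouped
Poisson rates

    λ_g = T_g · e^κ · (1 + α d_g + β d_g²)

with person-year offsets T_g, under a linear-quadratic truth
(α = 0.25/Gy, β = 2/Gy²) or a linear truth (α = 3/Gy).  The estimators:

| method | dose input | interval |
|---|---|---|
| unadjusted | one surrogate realization | profile likelihood |
| regression calibration (RC) | mean of true-dose realizations | profile likelihood |
| extended RC (ERC) | as RC | profile, inflated by refit spread |
| MCML | all m realizations | profile of the averaged likelihood |
| quasi-2DMC with BMA | all m realizations | equal-tail 95% posterior |
| FMA | all m realizations | AIC-weighted sample centiles |

See `docs/methods.md` for the full model, sampler and design notes.

## Worked example

One meta-ensemble under heavy shared Berkson error (unshared 20%,
shared 50%, classical 20%/20%), linear-quadratic truth:

```python
import numpy as np
from doserr import (ErrorConfig, LINEAR_QUADRATIC_TRUTH, DoseVectorSet,
                    build_ensemble, default_groups, dose_correlation,
                    fit_regression_calibration, fit_erc, run_quasi_2dmc_bma)

groups = default_groups()
errors = ErrorConfig(sigma_share_berkson=0.5, sigma_unshare_berkson=0.2,
                     sigma_share_class=0.2, sigma_unshare_class=0.2)
ens = build_ensemble(groups, errors, LINEAR_QUADRATIC_TRUTH,
                     m=1000, n_cases=250, seed=11)
print("cases per group:", ens.cohort.cases)
print("dose correlation:", round(dose_correlation(ens.dose_ensemble.true_doses, seed=0), 3))

doses = DoseVectorSet(ens.group_dose_vectors)
rc   = fit_regression_calibration(ens.cohort, doses, "linear-quadratic")
erc  = fit_erc(ens.cohort, doses, "linear-quadratic")
_, bma = run_quasi_2dmc_bma(ens.cohort, doses, "linear-quadratic", seed=1)
for f in (rc, erc, bma):
    print(f"{f.method:18s} alpha {f.alpha_hat:6.3f} ({f.ci_alpha.lo:6.3f}, {f.ci_alpha.hi:6.3f})"
          f"   beta {f.beta_hat:6.3f} ({f.ci_beta.lo:6.3f}, {f.ci_beta.hi:6.3f})")
```

prints

```
cases per group: (126, 26, 31, 50, 17)
dose correlation: 0.849
regression_calibration alpha  0.344 (-1.325,  2.772)   beta  2.289 ( 0.868,  3.612)
erc                alpha  0.344 (-1.382,  2.855)   beta  2.289 (-11.621, 15.250)
quasi_2dmc_bma     alpha  3.982 ( 2.487,  5.536)   beta -0.133 (-0.529,  0.453)
```

Read it as: the 50% shared error makes individual true doses almost
perfectly correlated (0.849 here; the lognormal closed form gives
0.844).  RC lands near the truth (0.25, 2) and ERC keeps its point
estimate while widening the intervals for the shared dose uncertainty.
The BMA sampler, forced to compromise one parameter vector across a
thousand dose ensembles that differ by a common scale factor, flattens
the curvature (β ≈ −0.13) and inflates the linear term (α ≈ 4.0) —
with a deceptively tight posterior whose intervals miss both true
coefficients.  Over many ensembles that tightness turns into coverage
probabilities near zero, which is the headline failure this package
quantifies.

Full studies (scenario grids × n ensembles × methods, written as CSV
tables of coverage, mean coefficients and percent ERR bias) run from
the command line via plain-text steering files:

```sh
doserr study --steering run.steer --out results/
doserr simulate --m-sub 1000 --seed 3 --out cohort.csv
doserr fit --cohort cohort.csv --method erc --form linear-quadratic
```

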