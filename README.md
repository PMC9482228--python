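# volnorm

Size-effect normalization for metabolomics time-series measurements.

When biofluid samples (finger sweat, blood plasma, ...) are collected
repeatedly over time, the measured abundance of every metabolite is the
product of its concentration and an unknown, highly variable sample
volume: `M̃(t) ≈ C(t) · V(t)`.  This *size effect* obscures the
concentration dynamics one actually cares about.  `volnorm` estimates
the latent volume profile `V(t)` — and thereby the concentrations —
with three related methods:

* **PQN** (probabilistic quotient normalization): the dilution factor of
  each sample is the median of its abundance ratios to a reference
  profile, `Q(t) = median_j { M̃_j(t) / M_ref_j }` with a metabolite-wise
  median reference.  Scale-free: it recovers relative volume changes
  only.
* **PKM** (pharmacokinetic normalization): for `ℓ ≥ 2` metabolites with
  known kinetics (a modified Bateman curve
  `F(t) = c₀ k_a/(k_e − k_a) (e^{−k_a(t−lag)} − e^{−k_e(t−lag)}) + d`,
  clamped to the baseline `d`, or a first-order mass-action cascade),
  kinetic parameters and per-time-point volumes are fitted jointly under
  physical bounds, yielding *absolute* volumes.
* **MIX**: both at once.  The objective adds to the PKM term a penalty
  `L[(1−λ)(ZT(V)_i − ZT(Q)_i)² Var(T(V))]` that pulls the fitted volume
  profile toward the PQN quotients computed from *all* metabolites, with
  `λ = 1/(ℓ+1)`, log10 transform `T`, standard scaling `Z` and a robust
  Cauchy loss `L`.  MIX matches PQN in relative accuracy, estimates
  absolute volumes like PKM, and degrades gracefully when untargeted
  features are contaminated.

Optimization is bounded trust-region nonlinear least squares restarted
from random initial points (Monte-Carlo multistart).  The package also
ships the synthetic benchmark that characterizes the methods (kinetic,
random and resampled concentration profiles; truncated log-normal
volumes; 20 % CV multiplicative error; adjustable contamination
fraction), RMSE/rRMSE goodness measures with paired Wilcoxon
comparisons, and LC-MS feature-table pre-filtering (retention-time,
blank and isomer rules).

## Worked example

```python
import numpy as np
from volnorm import MIXNormalizer, rrmse, rmse
from volnorm import synthetic as syn

# one benchmark replicate: 60 metabolites (first 4 = caffeine-like toy
# kinetics), 20 time points, log-normal volumes, 20 % CV error
ds = syn.simulate_v1(n_metabolites=60, seed=7)

est = MIXNormalizer(ell=4, known_params=syn.toy_known_params(),
                    n_starts=20, random_state=1)
est.fit(ds.M, t=ds.t)

print("rRMSE", round(rrmse(ds.V, est.V_), 4))
print("RMSE ", round(rmse(ds.V, est.V_), 4), "uL")
caffeine = est.kinetic_params_[0]
print("caffeine-analogue k_a", round(caffeine.k_a, 3),
      "k_e", round(caffeine.k_e, 3))
```

prints

```
rRMSE 0.0759
RMSE  0.05 uL
caffeine-analogue k_a 2.438 k_e 0.102
```

i.e. on this noisy replicate the fitted volumes track the true ones to
~8 % relative spread and 0.05 µL absolute error.  The elimination rate
of the caffeine-like metabolite (true 0.12 h⁻¹) comes back closely; the
absorption rate (true 1.5 h⁻¹) is less tightly determined on a single
20 %-CV replicate — across replicates its median error is a few percent
when the error is switched off (see the recovery experiment below).
`est.V_` holds the fitted volumes, `est.transform_volumes(ds.M)` the
normalized concentrations.

The same functionality is exposed on the command line:

```sh
volnorm simulate --version v1 --n-metabolites 60 --replicates 10 --seed 1 --out sim/
volnorm fit --model mix --ell 4 --mc 100 --seed 1 --data sim/replicate_000/M.tsv --out fit/
volnorm evaluate --truth sim/replicate_000 --fits fit/ --out report.tsv
volnorm benchmark --versions v1 --n-metabolites 4,20,60 --replicates 20 --out bench.tsv
volnorm filter --table features.tsv --sample-cols s1,s2,s3 --blank-cols b1,b2 --out kept.tsv
```

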