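# Methods

## The measurement model

A time series of mass-spectrometric abundances is modelled as
`M̃_ij = C_j(t_i) · V_i · ε_ij`: the concentration of metabolite `j` at
time `t_i`, times the unknown sample volume `V_i` collected at that
time, times a multiplicative measurement error.  All three estimators
in this package target `V`:

* **PQN** assumes the median concentration fold change between samples
  is ≈ 1, so the median abundance ratio to a reference profile is
  proportional to the volume.  The reference is the metabolite-wise
  median over the time series (robust to errors; alternatives `mean`
  and `first` are available but not default).  PQN needs strictly
  positive, complete data — missing values are rejected rather than
  imputed.
* **PKM** fits, for `ℓ` metabolites with known kinetic form, the kinetic
  parameters θ and the volume vector jointly so that `C(t; θ) · V`
  matches the measured masses, under physical bounds on both.  `ℓ ≥ 2`
  is required, otherwise there are more parameters than data points per
  time point.
* **MIX** minimizes `L_PKM + L_PQN` where

      L_PKM = Σ_ij L[ λ (T(M̃_ij) − T(C_ij V_i))² ]
      L_PQN = Σ_i  L[ (1−λ) (ZT(V)_i − ZT(Q)_i)² · Var(T(V)) ]

  with `λ = 1/(ℓ+1)`, which weights the two terms equally per time
  point (ℓ modelled data points against one quotient).  At `λ = 1` the
  PQN term vanishes and MIX is exactly PKM (bit-for-bit at equal seed;
  the residual block is omitted rather than zero-weighted).

## Kinetic models

The default concentration curve is a modified Bateman function with
parameters `(k_a, k_e, c_0, lag, d)`: absorption and elimination rates
(1/h), absorbed amount over the volume of distribution, absorption
start time (h) and a baseline offset.  The two-exponential core is
clamped at the baseline where it is negative (hence `F(t) = d` before
`lag`), and the analytic limit `c_0 k_a (t−lag) e^{−k_a(t−lag)}` is
used when `|k_e − k_a| < 1e-9`, removing the pole without constraining
the optimizer.  A two-metabolite first-order cascade
(`A → Caf → M` with elimination from both pools, closed-form solution
verified against adaptive ODE integration to ≤ 1e-7) is available for
modelling a parent compound together with one degradation product; its
derived identities are `k_a = k₁'` and `k_e = k₂' + k₃'`.

Note that Bateman-type curves carry the classic "flip-flop"
ambiguity — swapping `k_a` and `k_e` reproduces the same shape with a
rescaled amplitude, which a free volume vector can absorb.  Absolute
volume inference therefore requires fixing what is genuinely known;
in the benchmark the first four (targeted) metabolites have `c_0`,
`lag` and `d` fixed and only their rates free, mirroring a caffeine
experiment where the ingested dose and absence of endogenous synthesis
are known.

## Loss, transform, scaling

* Losses: `cauchy` applies `ρ(z) = ln(1+z)` to the squared weighted
  residual; `max_cauchy` applies it to the squared maximum of the
  absolute and the relative residual, the latter defined as
  `(T(M̃)−T(CV))/T(M̃)` guarded at `|T(M̃)| < 1e-12`; `max_linear` is the
  unrobustified variant.  Defaults: `max_cauchy` for PKM, `cauchy` for
  MIX.
* Transforms: identity (PKM default) or `log10(x + 1e-8)` (MIX
  default) — the additive guard is the size of the optimizer precision
  and keeps zero concentrations finite.
* Scalings (PQN term only): `standard` `(x−mean)/std` (default) or
  `mean` (centering on log data, division otherwise).  The
  standard-scaled difference is multiplied by `Std(T(V))`, recomputed
  from the current volume iterate at every evaluation; this is what
  couples the quotient term's scale to the kinetic term and lets the
  degenerate constant-volume case vanish smoothly instead of dividing
  by zero.  A fit whose volume vector comes back (near-)constant is
  reported with a warning flag (`size_effect_detected_ = False`), not
  an error: it signals that size effects may simply be absent.

## Optimization

Bounded trust-region nonlinear least squares (`scipy.optimize.
least_squares`, method `trf`, tolerances 1e-8) with the robust loss
applied through the residual-weighting contract, restarted from
`n_starts` initial points drawn uniformly within the bounds.  Child
seeds are spawned per start index from the parent seed, so the best
loss is non-increasing in the number of starts and results are
reproducible.  The best start by final (spec-semantics) loss wins; ties
keep the lowest index.  For models with many free parameters the
Jacobian sparsity pattern (each residual touches one metabolite's
parameters and one volume) is exploited via grouped finite differences.
Full-model fits in the shipped benchmarks cap iterations at 200
residual evaluations per start — convergence beyond that changes the
loss but not the conclusions, and keeps a 60-metabolite fit under a
second per start.  An optional unit-max column pre-scaling (`prescale`)
improves convergence for data spanning orders of magnitude; the factor
is folded back into the reported `c_0` and `d`.

## Synthetic benchmark

Generators build `M = diag(C V) ε` from known truth:

* volumes: log-normal with untruncated median 0.3 µL and geometric SD
  2.5, truncated to [0.05, 4] µL by rejection — a realistic finger-sweat
  volume range;
* error: `Normal(1, 0.2)` per metabolite and time point (20 % CV),
  truncated at 0.01 to preserve positivity;
* concentrations: four fixed caffeine-like toy curves (fast absorption,
  slow elimination, small baselines; all within the fitting bounds
  `(0,0,0,0,0) ≤ (k_a,k_e,c_0,lag,d) ≤ (3,3,5,15,3)`), plus untargeted
  columns that are (v1) Bateman curves with uniformly drawn parameters,
  (v2) i.i.d. log-normal draws whose mean/SD come from log-normal
  meta-distributions, or (v3) columns resampled without replacement
  from a ground-truth matrix.  The shipped v3 ground truth is a
  synthetic stand-in regenerated deterministically from a fixed seed —
  a half/half mixture of Bateman-shaped and random profiles emulating
  quotient-normalized real sweat data; a real matrix can be substituted
  via the CLI.
* contamination: `apply_noise_fraction` flags `round(f_n · n)`
  untargeted columns as volume-independent (their masses are `C ε`);
  targeted columns are never flagged.

The default grid is 20 equidistant time points on [0, 15] h and 100
replicates per condition.

What the generators deliberately do **not** emulate: missing values,
chromatographic artefacts, batch effects, and — importantly —
cross-feature correlation (adducts, isotopologues, shared kinetics).
Real untargeted data is strongly correlated; the independent columns
here make the quotient estimator decorrelate from the volumes faster as
the contamination fraction grows than correlated real data would.  At
extreme contamination (`f_n = 0.95`) this flips the mean-vs-standard
scaled-error comparison: once the standardized quotients are nearly
uncorrelated with the true volumes, standardization amplifies pure
noise and the standard-scaled error exceeds the mean-scaled one (it is
smaller throughout `f_n ≤ 0.9`).  Passing tests on this benchmark show
the estimators behave correctly under the stated error model, not that
they are robust to structure the generators omit.

## Goodness measures

`rmse` is the population standard deviation of `V_true − V_fit`
(absolute accuracy; undefined for PQN, which has no volume scale);
`rrmse` is `std/mean` of the ratio `V_true / V_fit` (relative accuracy;
scale-free, so PQN quotients can be scored).  Population
(n-denominator) standard deviations are used throughout, consistently
for every method, so relative comparisons are unaffected by the
convention.  The scaled-error diagnostics compare mean- and
standard-scaled log-quotients against log-volumes; because both
scalings center their argument the signed sums cancel identically, so
the reported error size is the sum of absolute per-time-point residuals
(signed vectors are available).  Method comparisons use the paired
Wilcoxon signed-rank test (zeros discarded, exact null for ≤ 25 pairs)
with stars at p ≤ 0.05 / 0.01 / 0.001.

## Feature-table pre-filtering

Before normalizing real LC-MS exports, three per-time-series rules
remove likely background: retention time > 5.5 min; minimum sample
abundance < 5× the maximum blank abundance (spike-ins / internal
standards exempt); and isomer deduplication (pairs within 0.001 Da
*and* 0.5 min, keeping the member with the higher maximum abundance —
the better-quantified peak).  The isomer rule runs last, on survivors;
filtering is idempotent.  Blank subtraction is deliberately not
performed.

## Problem sizes of the shipped checks

The benchmark tests use 100 replicates per condition (20 for the
all-metabolite model at 60 metabolites), 20 Monte-Carlo starts for
minimal models (25 and 50 starts give identical replicate means) and 25
iteration-capped starts for full models; `scripts/acceptance.py` uses
40 and 12 replicates respectively.  These sizes give replicate-mean
standard errors well below the effect sizes being checked.
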