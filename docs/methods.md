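# Methods

## The FD2 release model

One active zone is modelled as `N_T` vesicle docking sites (default 7,
the anatomical docked-vesicle count reported for climbing-fiber active
zones; valid range 1–10). Each site holds a release-competent vesicle with
probability `P_occ`. Occupancy is treated as set by the phosphorylation
state of vesicle-associated proteins (PKA/synapsin signalling) and is held
constant within a simulated train; all within-train dynamics are carried by
the facilitation/depression variables. The readily-releasable pool per
active zone is `RRP = N_T · P_occ`, and expected release per stimulus is
`V_released = RRP · P_succ` with `P_succ = F · D`.

### Dynamics

Two dimensionless calcium sensors follow each stimulus:

| symbol | meaning | default | units |
|---|---|---|---|
| `ΔF`, `ΔD` | per-stimulus increments of `CaX_F`, `CaX_D` | 5, 0.001 | — |
| `τ_F`, `τ_D` | sensor decay time constants | 0.1, 0.05 | s |
| `K_F`, `K_D` | sensor half-saturation constants | 2, 2 | — |
| `k_0`, `k_max` | baseline / maximal recovery rate | 0.7, 20 | s⁻¹ |
| `F_base` | facilitation probability at rest | scenario-dependent | — |
| `N_T` | docking sites per active zone | 7 | count |
| `P_occ` | site occupancy probability | scenario-dependent | — |

Facilitation is the saturable form
`F = F_base + (1 − F_base)·CaX_F/(CaX_F + K_F)` — the minimal expression
with baseline `F_base`, monotone growth, saturation at 1, and `K_F` as the
half-saturation constant. Recovery from the post-release refractory state
follows `dD/dt = (1 − D)·k(CaX_D)` with
`k(c) = k_0 + (k_max − k_0)·c/(c + K_D)`.

At a stimulus, release is computed from the pre-pulse state; then the
released fraction of ready sites becomes refractory (`D ← D·(1 − F)`) and
both sensors are incremented (increments are defined to occur after the
stimulus). `ΔD` increments once per stimulus, not per released vesicle.

### Integration

Between stimuli the sensors decay exactly (`c·e^(−dt/τ)`), and the `D`
equation is integrated in closed form: with `CaX_D(t) = c₀e^(−t/τ_D)`,

```
∫₀^dt k dt = k₀·dt + (k_max − k₀)·τ_D·ln[(c₀ + K_D)/(c₀e^(−dt/τ_D) + K_D)]
D(dt) = 1 − (1 − D₀)·e^(−∫k dt)
```

so the event-driven simulator is exact to machine precision — there is no
step-size parameter. The test suite cross-checks it against an independent
two-pulse calculation that integrates `k(CaX_D(t))` with adaptive
quadrature (agreement ≤ 1e−6 over a grid of `F_base` × interstimulus
interval).

A structural consequence used throughout: `P_occ` multiplies every
`V_released` identically, so all amplitude *ratios* (paired-pulse ratio,
train profiles) are exactly invariant to occupancy. The documented
operating points (`data/model_points.yaml`) exploit this: points a/b and
c/d differ only in occupancy and have bitwise-identical PPRs.

`τ_F` is taken as 0.1 s (facilitation decaying over ~100 ms, consistent
with paired-pulse ratios returning to ~1 by multi-second intervals); with
this value the low-success operating point yields a 50 ms PPR of 1.169.

Stochastic release counts are drawn as a single-stage
`Binomial(N_T, P_occ·F·D)` per stimulus. A nested draw (occupancy first,
then fusion) has the same mean; only means are constrained by the
deterministic model, so the simpler sampler is used.

## Multivesicular-release exceedance geometry

With `(P_occ, P_succ)` unknown and treated as uniform on the unit square,
`P(V > z)` for a `v`-site active zone is the area fraction where
`v·x·y > z`, which integrates to `1 + (z/v)(ln(z/v) − 1)` for
`0 < z/v ≤ 1` (natural logarithm). The formula is extended by continuity:
1 at `z = 0`, 0 for `z ≥ v`. `v` may be real-valued so curves over site
counts are smooth. A seeded uniform Monte-Carlo estimator provides the
independent cross-check; tests require agreement within binomial standard
errors (family-corrected across grid points).

## Pool and release-probability estimators

* **Cumulative-train method** — cumulative EPSC amplitude vs stimulus
  number; ordinary least squares through the last `n_last = 5` points; the
  y-intercept estimates `RRP` (amplitude units) and the slope the steady
  replenishment per stimulus. Assumes constant replenishment late in the
  train. Bias on a finite pure-depletion train is the residual tail mass
  `(1 − p_r)^n` (≤ 2% for the test conditions).
* **Elmqvist–Quastel method** — amplitude `A_k` vs prior cumulative
  amplitude `C_{k−1}`; a line through the first `n_first = 2` points is
  extrapolated to its x-intercept. Exact on pure-depletion trains, where
  `A_k = p_r(RRP − C_{k−1})` is exactly linear. `n_first` is exposed
  because variants of the method use more points.
* Both define `Pr = A₁ / RRP`; both are plain OLS with no weighting;
  amplitude units pass through unchanged. Degenerate inputs (no
  depression, nonpositive intercept) return failure flags rather than
  numbers.
* **Depletion-model Pr from paired-pulse depression** —
  `A₂/A₁ = 1 − Pr·(1 − r)` where `r` is the fraction of the pool recovered
  by the second stimulus, so `Pr = (1 − PPR)/(1 − r)`, clamped to [0, 1].
  `r` defaults to 0, appropriate at ~10 ms intervals where measured
  recovery is a few percent; a measured `r` can be supplied.
* **Exponential fits** — single-exponential recovery
  (`1 − (1 − floor)e^(−Δt/τ)`) and train-decay
  (`plateau + (initial − plateau)e^(−t/τ)`) fits via
  Levenberg–Marquardt; single exponentials only. For a geometric
  depletion train the decay constant is analytically
  `Δt/(−ln(1 − p_r))`, which the tests use as ground truth.

## Quantal statistics

* **CV ratio** (treated/control, as %) is exactly 100% under uniform
  amplitude scaling — the diagnostic for purely postsynaptic changes —
  while a change in binomial release probability predicts
  `CV = √((1−p)/(Np))`.
* **Variance–mean** fits `σ² = qμ − μ²/N` (least squares in the basis
  `{μ, μ²}`, Bessel-corrected sample variances). Nonpositive fitted `q` or
  `N`, or any condition lying far off the parabola (relative residual
  > 50%, which a supra-binomial condition produces), flags the data as
  non-binomial.
* **Release-mode classification** uses the five-stimulus potency protocol:
  potency = mean amplitude of *successful* responses per stimulus
  (unweighted across stimuli within each group); the ratio of late (S3–5)
  to early (S1–2) group potency classifies a synapse as UVR in
  [0.8, 1.2], MVR above 1.3, otherwise unclassified (including the
  excluded 1.2–1.3 gap and ratios below 0.8). The bands are a total,
  mutually exclusive partition by construction.
* **Event detection** is threshold-on-smoothed-trace with a refractory
  lockout and a prominence requirement equal to the threshold (without
  which noise ripples on the 5–6 ms decay tail of a large event register
  as spurious events). Amplitudes are measured against a pre-event median
  baseline, either as a smoothed peak or — when the EPSC time constant is
  supplied — as the least-squares scale of the unit EPSC template with
  correlation-based alignment, which cuts the single-event amplitude
  noise by roughly the square root of the template support (~10× at
  50 kHz). Events closer than the refractory interval are reported as
  one; the detection benchmark therefore scores against resolvable
  (≥ refractory-separated) ground-truth events.
* **Dose–response** is a four-parameter logistic on log10 concentration
  with unconstrained slope sign; since `(bottom, top, slope)` and
  `(top, bottom, −slope)` describe the same curve, output is canonicalized
  to `bottom ≤ top`.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume — not
the biophysics of a slice recording:

* **EPSC kernel** `(t/τ_E)·e^(1−t/τ_E)`, peak 1 at `t = τ_E` (default
  1.5 ms). Amplitudes are peak scalings (pA); charge is not modelled.
* **Depletion trains**: pool `N0`, per-vesicle release probability `p_r`,
  deterministic replenishment `R` per interval (the constant-replenishment
  assumption of the cumulative-train method; stochastic replenishment is
  out of scope).
* **Noisy sweeps**: per sweep, integer pool propagation with
  `Binomial(N_k, p_r)` release, lognormal quantal amplitudes (positive
  support; mean `q` = 55 pA, CV 0.3 by default — the distribution shape is
  a package choice, only the mean is constrained by typical asynchronous
  EPSC data) and additive Gaussian baseline noise.
* **Asynchronous events**: homogeneous Poisson times (default settings in
  tests use 1.3–3.5 Hz, spanning reported asynchronous-EPSC rates) with
  lognormal amplitudes; continuous traces are linear superpositions of the
  kernel sampled at 50 kHz (`dt = 0.02` ms) plus Gaussian noise.

Every stochastic generator takes an explicit seed and is reproducible
bit-for-bit. What passing tests show is that the estimators and detectors
are correct *for data that satisfy their assumptions* (binomial quanta,
constant replenishment, stationary noise); real recordings add receptor
saturation/desensitization, series-resistance and filtering artifacts,
and nonstationary vesicle dynamics that the generator deliberately omits.

## Numerical choices and problem sizes

* OLS via `numpy.polyfit`/`lstsq`; nonlinear fits via
  `scipy.optimize.curve_fit` (bounded where parameters are physical;
  failure flags instead of exceptions on non-convergence or degenerate
  data).
* Two-sample KS via `scipy.stats.ks_2samp` (asymptotic p for large
  samples).
* Statistical test sizes: Monte-Carlo cross-checks use 10⁵ draws per grid
  point; sampler-moment checks 10⁵ draws; noise-robustness suites use
  20-sweep replicates (40 replicate fits) and variance–mean simulations
  200 sweeps × 100 replicates. These sizes give standard errors a factor
  of several below the asserted tolerances while keeping the default test
  run fast.
* Scenario reports print floats at 6 significant digits so repeated runs
  with one seed are byte-identical.

## Known limitations

* `P_occ` is static within a train; occupancy refill on the train
  timescale, if present at a synapse, is absorbed into `D`'s recovery.
* Calcium-sensor recovery acts on `D` only; it does not refill occupancy.
* The exceedance geometry assumes a uniform prior over
  `(P_occ, P_succ)`; no other priors are implemented.
* Estimators return amplitude-unit pools; conversion to vesicle counts
  requires an externally supplied quantal size.
* Single-exponential fits only; multi-pool models and deconvolution-based
  pool estimates are out of scope.
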