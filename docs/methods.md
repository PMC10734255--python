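# Methods

## Model

`thermguts` implements a toxicokinetic–toxicodynamic (TK–TD) survival model
in which temperature, rather than a chemical, is the stressor. The model
carries the damage-plus-hazard structure of the GUTS stochastic-death (SD)
family over to thermal stress.

A dimensionless latent damage state `D_T` (with `D_T = 1` meaning "no
damage") relaxes as a first-order process towards a temperature-dependent
accrual target:

    dD_T/dt = k_T · (F(T(t)) − D_T),      F(T) = max(1, exp(α (T − T_c)))

Above the critical temperature `T_c` the target grows exponentially with
temperature; at or below `T_c` the target clamps at the baseline 1, so any
existing damage is repaired back towards 1 with the same dominant rate
`k_T`. `F` is continuous at `T_c`, so the right-hand side has only a kink
there, never a jump in state. Damage never falls below 1: the baseline is
both the starting condition and the hazard threshold.

Damage in excess of the baseline kills at a rate proportional to the
excess, and a constant background hazard `h_b` acts independently:

    h(t) = b_T · max(0, D_T(t) − 1) + h_b
    S_T(t) = exp(−∫₀ᵗ h(s) ds),      S_T(0) = 1

Survival is therefore the survival function of a single stochastic-death
hazard (GUTS-SD mechanics); there is no individual tolerance distribution
(GUTS-IT), and no cold-stress limb — only heating stress is modelled.

Key structural decisions where the formulation was genuinely open:

* **Accrual target below `T_c`.** The target is clamped at 1 rather than
  allowed below it, so repair stops exactly at "no damage". This keeps
  `D_T ≥ 1` invariant and makes recovery after a hot spell an exponential
  relaxation to baseline with rate `k_T`.
* **Hazard threshold.** The hazard is proportional to `D_T − 1`, not to
  `D_T` itself. With hazard ∝ `D_T` an undamaged organism at its optimum
  temperature would experience a permanent thermal hazard `b_T`, which
  contradicts the construction of `D_T = 1` as the no-effect state; the
  external threshold role is played by `T_c`.
* **Constant parameters.** The organism is assumed not to change over the
  exposure (no acclimation, ageing or life-stage effects).

## Parameters

| symbol | meaning | unit | default |
|---|---|---|---|
| `k_T` | dominant rate of damage accrual and repair | 1/day | 5.76 |
| `α` (`alpha`) | temperature scaling of the accrual target | 1/K | 0.033 |
| `T_c` | critical temperature where accrual starts | K | 284.15 (11 °C) |
| `h_b` | background hazard rate | 1/day | 0.004 |
| `b_T` | killing rate (damage → hazard) | 1/day | 0.127 |

The defaults are the reference calibration for *Gammarus pulex* exposed to
constant 10/15/20/25 °C water for 8 days (`GAMMARUS_PULEX_PARAMS`). `T_c`
is a *set* value (chosen from rearing temperature and the absence of
mortality at 10 °C), not an estimated one; a 14 °C variant is available as
a sensitivity configuration (`--tc-celsius 14`). `h_b` is fitted during
calibration but conventionally set to 0 for forward scenario simulation, so
that predicted mortality isolates the thermal effect; both switches are
explicit in the API and CLI. All user-facing temperatures are °C and are
converted internally to kelvin; all times are days.

## Temperature scenarios

Three forcing families:

* **constant** — `T(t) = base_mean`;
* **daily_fluctuation** — `T(t) = base_mean + amplitude · sin(2π t)`.
  The waveform and phase of the daily cycle are not dictated by the data
  the model targets, so a sine with period exactly 1 day and `T = mean,
  rising` at `t = 0` was chosen; `amplitude` is the half-range ("12 ± 4 °C"
  oscillates between 8 and 16 °C). An optional `phase` key shifts the
  waveform if another convention is needed.
* **heatwave** — the daily fluctuation plus a rectangular additive offset
  `hw_intensity` over the half-open window `[hw_start, hw_start +
  hw_duration)`.

Scenarios are YAML/JSON documents validated strictly (unknown keys are
errors) and round-trip losslessly.

## Numerics

Damage and cumulative hazard are co-integrated as one ODE system with
`scipy`'s LSODA (rtol 1e-8, atol 1e-10), which avoids post-hoc quadrature
error in the survival integral. For time-varying forcings the maximum step
is capped at 1/48 day so the daily sinusoid and rectangular heatwave edges
cannot be stepped over. For constant forcing the linear ODE has a closed
form — `D(t) = F + (1 − F) e^{−k_T t}` and an analytic cumulative hazard —
which serves two roles: it is the independent oracle the integrator is
tested against (relative tolerance 1e-6 for damage, 1e-5 for survival), and
it is the fast path used by the calibration likelihood, whose data are
constant-temperature treatments. Solver output is clipped to the invariants
(`D ≥ 1`, cumulative hazard nondecreasing) to remove tolerance-level noise.

The heatwave sweep evaluates hundreds of 200-day scenarios; running the
adaptive solver per cell would be needlessly slow. The default sweep method
advances **all grid cells simultaneously** with a fixed-step exponential
integrator (96 steps/day): over one step the ODE is linear in `D` with an
approximately constant target, so `D ← F_mid + (D − F_mid) e^{−k_T h}` with
the target evaluated at the step midpoint, and the hazard integral is
accumulated by the trapezoidal rule. Against the adaptive solver this
agrees to about 1e-4 in cumulative hazard (log-survival); the adaptive
path is retained as `method="ode"` and the agreement is asserted in tests.

## Calibration

The likelihood is the conditional multinomial standard in GUTS practice:
per replicate cohort, interval death counts plus final survivors are
multinomial with cell probabilities `S(t_{j−1}) − S(t_j)` and `S(t_m)`.
Replicates are independent cohorts (not pooled). By default the
parameter-independent multinomial coefficient is omitted — the value is
then invariant under splitting a cohort — and `include_combinatorial=True`
adds it back, giving the exact log-probability of the counts (this form is
tested against exhaustive enumeration over per-individual death-time
assignments on 3-individual cohorts). Cell probabilities are floored at
1e-12 before logs so impossible observations stay finite.

Fitting searches `{k_T, α, h_b, b_T}` (with `T_c` fixed) on the log10 scale
inside a box (`k_T, b_T ∈ [1e-3, 100]`, `α, h_b ∈ [1e-6, 1]`): a Latin
hypercube of 6000 points, Nelder–Mead polishing from the 6 best, a
shrinking Gaussian refinement cloud around the optimum, and
profile-likelihood scans per parameter (re-optimizing the others at fixed
values stepping outward until the profile falls well below the cutoff).
Every evaluated parameter set is stored. Confidence intervals are
likelihood-ratio intervals: the min/max per parameter over all stored sets
with log-likelihood within `χ²(1, level)/2` of the maximum (1.92 at 95%).
The profile scans guarantee those extremes are sharp, and with one free
parameter the interval provably matches the points where the
log-likelihood itself drops by 1.92 (checked against root-finding in
tests). A CI endpoint within 0.02 dex of the search box is flagged
"at boundary".

This boundary flag is not a numerical nuisance but a finding the model
reproduces: on sub-daily observation grids the data cannot distinguish
fast from very fast kinetics, so `k_T` and `b_T` lack well-defined upper
limits and their CI upper bounds run to the box edge, while `α` and `h_b`
remain well identified. The same ridge makes the joint likelihood bimodal
in practice: a fraction of synthetic refits collapse to the box corner
(`b_T` at 100 with a compensating small `α`, where the hazard becomes
effectively linear in `T − T_c`), which is why point estimates of `α`
scatter widely even though its likelihood-ratio interval covers the
generating value at the nominal rate.

Goodness of fit follows EFSA-style reporting on observed vs predicted
survivor counts pooled over treatments, replicates and times:
`R² = 1 − SSE/SStot`, `NRMSE = RMSE / mean(observed)`, and
`AIC = 2k − 2 logL` with `k` the number of free parameters. Observed
survival fractions are summarized with Wilson score intervals.

## Synthetic data

The generator reproduces the calibration study design: by default 4
constant-temperature treatments (10, 15, 20, 25 °C), 3 replicates × 10
individuals, observations every 0.5 day over 8 days (17 time points
including `t = 0`, full cohorts at start). Deaths are drawn sequentially
per replicate as `alive(t_j) ~ Binomial(alive(t_{j−1}), S(t_j)/S(t_{j−1}))`
— exactly the process the multinomial likelihood assumes, distributionally
identical to per-individual death-time sampling but cheaper. All
randomness flows through one explicit `numpy` Generator seed; the same
seed reproduces the dataset byte for byte.

What the generator does *not* emulate: individual tolerance heterogeneity
(GUTS-IT mechanics), overdispersion between replicates beyond binomial
sampling, handling losses or censoring, and measurement error in
temperature. Passing recovery tests therefore demonstrate internal
consistency of likelihood and generator under the model's own assumptions,
not robustness to the ways real assay data violate them.

## Heatwave analysis

The sweep covers intensities 3–6 °C and durations 7–100 days (projected
lake heatwave ranges under a high-emission pathway), applied on a 12 ± 4 °C
daily cycle starting at day 10, evaluated at `t = 200` days with `h_b = 0`;
grid steps default to 0.25 °C × 3 days and are configurable. End survival
is monotone nonincreasing along both axes. On a per-unit basis the
intensity axis is the steeper one — one extra °C of intensity costs more
log-survival than one extra day of duration (≈0.035 vs ≈0.010 at the mild
corner with the reference parameters) — reflecting the exponential
temperature dependence of damage accrual against the linear accumulation of
exposure time. Over the full swept ranges the 93-day duration span
nevertheless moves end survival further than the 3 °C intensity span; both
facts are asserted where relevant and the per-unit comparison is the
qualitative "intensity dominates" statement this package stands behind.

## Problem sizes and determinism

Test and verification runs use: 50 synthetic refits of the reference assay
scaled to 200 individuals per treatment for the α-recovery study (one
replicate of 200 — the likelihood is invariant to how a cohort is
partitioned); a 1000-individual, 100-day below-`T_c` cohort for background
hazard recovery; 10⁴-individual cohorts for distributional checks of the
generator; and the default 13 × 32 heatwave grid. Every stochastic step
takes an explicit integer seed; there is no global random state.

## Known limitations

* `T_c` is not estimable from survival data of this design and must be set
  from biological knowledge; results are conditional on that choice (the
  14 °C sensitivity variant is one keystroke away).
* Point estimates of `k_T` and `b_T` are upper-boundary artifacts whenever
  kinetics are fast relative to the observation grid; only their lower CI
  limits are data-driven.
* The model addresses heating stress only; no cold-stress hazard exists
  below any lower critical temperature.
* Damage is dimensionless and latent — trajectories are comparable across
  scenarios but have no measurable physiological unit.
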