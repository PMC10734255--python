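# thermguts

Toxicokinetic–toxicodynamic (TK–TD) modelling of **thermal stress on
ectotherm survival**, in the style of the GUTS (General Unified Threshold
model of Survival) framework used for chemical stressors. The package is
for ecotoxicologists and ecological risk modellers who want to predict
mortality of aquatic invertebrates under arbitrary water-temperature
regimes — constant exposures, daily cycles, heatwaves — and to calibrate
the model to replicated survival count data.

## The model

A dimensionless latent damage state D_T (D_T = 1 ⇔ no damage) follows
first-order dynamics towards a temperature-dependent accrual target, and
damage above baseline translates into a hazard:

    dD_T/dt = k_T (F(T) − D_T),       F(T) = max(1, e^{α (T − T_c)})
    h(t)    = b_T max(0, D_T − 1) + h_b
    S_T(t)  = exp(−∫₀ᵗ h(s) ds)

Above the critical temperature T_c damage accrues exponentially with
temperature (coefficient α, dominant rate k_T); below T_c it is repaired
back towards baseline at the same rate. `b_T` is the killing rate and
`h_b` a background hazard. The bundled reference calibration
(`GAMMARUS_PULEX_PARAMS`) describes *Gammarus pulex* under acute heat
stress: k_T = 5.76 d⁻¹, α = 0.033 K⁻¹, T_c = 284.15 K (11 °C, a set
value), h_b = 0.004 d⁻¹, b_T = 0.127 d⁻¹.

Calibration maximizes the conditional multinomial likelihood of interval
death counts (the standard GUTS form), explores the parameter space on a
log-scaled Latin hypercube with profile-likelihood refinement, and reports
likelihood-ratio confidence intervals with explicit flags when a bound
runs into the search box — which is the expected outcome for k_T and b_T,
whose upper limits are not identifiable from sub-daily survival counts.

## Worked example

```python
import numpy as np
from thermguts import (GAMMARUS_PULEX_PARAMS, TemperatureScenario,
                       simulate_survival)

params = GAMMARUS_PULEX_PARAMS.with_(h_b=0.0)   # isolate the thermal effect
for T in (10, 15, 20, 25):
    scenario = TemperatureScenario(kind="constant", base_mean=T, t_end=8.0)
    curve = simulate_survival(scenario, params,
                              output_grid=np.array([0.0, 8.0]))
    print(T, round(curve.survival[-1], 3))
```

prints the 8-day survival probabilities of the calibration treatments:

```
10 1.0
15 0.869
20 0.709
25 0.558
```

At 10 °C the forcing never exceeds T_c, so no damage accrues and survival
stays at 1; above T_c survival drops the faster the hotter the water. A
heatwave scenario — a 12 ± 4 °C daily cycle with a +4 °C, 10-day heatwave
starting at day 10 —

```python
hw = TemperatureScenario(kind="heatwave", base_mean=12, amplitude=4,
                         hw_start=10, hw_duration=10, hw_intensity=4,
                         t_end=200)
print(round(simulate_survival(hw, params,
            output_grid=np.array([0.0, 200.0])).survival[-1], 3))
```

gives `0.169`: the damage peaks at about 1.29 during the heatwave and
relaxes back to baseline within a day of it ending, but the accumulated
hazard (plus the mildly stressful fluctuating baseline itself) has cost
most of the cohort.

The same machinery is scriptable from the shell:

```bash
thermguts synth --seed 1 --out runs/data          # synthetic survival assay
thermguts calibrate --data runs/data/survival.csv --seed 0 --out runs/fit
thermguts heatmap --out runs/hw                   # intensity × duration grid
```

`calibrate` writes a JSON report (best fit, CI bounds with boundary flags,
log-likelihood, R², NRMSE, AIC) and fitted survival curves with CI bands;
`heatmap` writes the long-format end-survival grid over heatwave
intensities 3–6 °C and durations 7–100 days.

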