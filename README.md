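# hpaxis — stoichiometric model of rat HPA-axis dynamics under kindling

`hpaxis` is an in-silico laboratory for the hypothalamic–pituitary–adrenal
(HPA) axis of the rat: a mass-action ODE model of the hormone network, a
circadian drive on CRH production, a pulse-perturbation protocol emulating
lateral-hypothalamic kindling (LHK, an electrical-stimulation model of
manic-like states), oscillation analytics, a synthetic blood-sampling/ELISA
data generator, and least-squares calibration of the perturbation parameters
from sampled corticosterone. It is aimed at computational neuroendocrinology:
exploring how ultradian (20 min–2 h) and circadian (24 h) glucocorticoid
rhythms respond to acute and sustained stimulation, and testing whether those
responses are identifiable from realistically sparse blood samples.

## The model

Eleven species — CHOL, CRH, ACTH, PNN (pregnenolone), PGS (progesterone),
DCTS (deoxycorticosterone), CTS (corticosterone), ALDO (aldosterone),
HPNN, HPGS (17α-hydroxy intermediates) and CORT (cortisol) — interact through
25 lumped reactions R1–R25 with mass-action kinetics,

dc/dt = S · v(c),  v_j = k_j · Π_i c_i^{s_ij},

where S is the stoichiometry matrix and the k_j span 17 orders of magnitude
(the system is stiff). The rhythm-generating core is corticosterone's twin
feedback: cubic autocatalysis DCTS + 2 CTS → 3 CTS and quadratic
autoinhibition ALDO + 2 CTS → CTS, with CRH→ACTH acting catalytically
(CRH triggers pituitary release without being consumed by the step). The
fixed point of the frozen-forcing system is an unstable focus
(λ ≈ +0.030 ± 0.074i min⁻¹), so sustained ultradian oscillations emerge
without any imposed pulse generator.

CRH production is modulated by an asymmetric 24 h drive

D(t) = d₁ − 0.079145093·d₂ + {0.064·sin(2π(t−840)/1440) + 0.12·|sin(π(t−840)/1440)|}·d₂,

d₁ = 0.2662, d₂ = 2.5, t in minutes from midnight. Experimental conditions:

* **control** — the model as is;
* **sham** — CRH production constant ×1.1765 (surgical-stress elevation);
* **kindled** — sham background plus additive CRH pulses of 5×10⁻⁸ M
  applied by stop-and-restart every 40 s for 50 min (21:12–22:02).

## Worked example

```python
import hpaxis

traj = hpaxis.integrate(hpaxis.control_scenario(days=5))   # strict stiff solve
m = hpaxis.detect_ultradian(traj.times, traj.series("CTS"),
                            window=(1440.0, 7200.0))       # discard day 1
print(round(m.ultradian_period_min), round(m.ultradian_frequency_per_day))
print(round(hpaxis.circadian_period_estimate(*traj.window(1440.0, 7200.0)), 2))
print(round(hpaxis.molar_to_ng_per_ml(traj.day_mean(2)), 1))
```

prints

```
57 21
24.0
81.7
```

— corticosterone pulses every ~57 min (21 peaks/day, inside the
physiological 20 min–2 h band), entrains exactly to the 24 h drive, and
averages ~82 ng/mL per day, the right order for control rats. The same
pipeline from a shell:

```sh
hpaxis simulate --condition lhk --days 3 --out kindled.csv
hpaxis sample   --traj kindled.csv --variant B --seed 7 --out animal.csv
hpaxis metrics  --traj kindled.csv --window day2:day3 --out metrics.json
hpaxis run      --out pipeline_out/        # full simulate→sample→metrics→calibrate
```

The numbered scripts under `analysis/` run the study end to end (scenario
comparison, oscillation metrics, 72 h kindling dose–response, synthetic
cohort + ANOVA, parameter calibration) and write their tables under
`results/`.

## Layout

* `src/hpaxis/` — the library: `network` (reactions, rate law), `forcing`
  (circadian drive), `simulate` (stiff integration, pulse schedules),
  `metrics` (oscillation analytics, unit/dosing calculators), `sampling`
  (synthetic blood draws + assay noise), `calibrate` (parameter recovery,
  ANOVA), `pipeline`/`cli` (configuration, end-to-end runs).
* `analysis/` — numbered narrative drivers over the library.
* `docs/methods.md` — modeling and numerical choices, in detail.
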