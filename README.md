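# stovewedge

A toolkit for designing, simulating, and analysing a community stepped-wedge
trial of alternative biomass cookstoves — built around the question of whether
replacing open indoor biomass burning with a chimney stove lowers rates of
acute lower respiratory infection (ALRI) in children under 36 months and
raises birthweight, in a setting (rural southern Nepal) where indoor PM2.5
routinely reaches thousands of μg/m³ during cooking.

It is aimed at trial biostatisticians and exposure scientists who need the
whole computational chain in one place:

- **Trial structure & randomization** — a 12-group stepped wedge (4 sectors
  per group, 6 pre-installation months + 12 monthly wedge steps + 6 post
  months), the hat-draw wedge-order randomization, and stratified balanced
  individual randomization for the follow-on stove-type trial.
- **Synthetic data generators** — cohorts (Poisson children per sector),
  child-period ALRI panels from the generative logistic model, daily symptom
  diaries with planted episodes, 10-second PM2.5/CO logger traces with known
  cooking-event windows, and clustered birthweights. Each generator's
  defaults are the study's stated conditions, and each emits ground truth
  for round-trip testing.
- **Episode detection** — the diary ALRI case definition (≥2 days of fever +
  fast/difficult breathing with co-occurrence on ≥1 day, episodes separated
  by ≥7 symptom-free days) and severity grading from case examinations.
- **Exposure metrics** — 3%-trimmed 10-minute means, length-5 running
  medians, the 10th-percentile daily baseline, Stove Influenced Time (SIT,
  filtered value > 1.2× baseline), and the integrated excess concentration
  SIP/SIC, plus mixed-model before/after stove contrasts.
- **Analysis model** — the logistic mixed model

  ```
  logit Pr(Y_ijt = 1) = α₀ + b_i + c_ij + s(t, v) + θ·X_it,
  b_i ~ N(0, σ²_village),  c_ij ~ N(0, σ²_child)
  ```

  for child *j* in village/sector *i* at month *t*, with a natural cubic
  spline time function *s(t, v)* and the stove effect θ, estimated by
  Laplace-approximated maximum likelihood with model-based and
  cluster-robust (sandwich) standard errors and a v = 4…12 sensitivity
  sweep.
- **Power & sample size** — the simulation-based power grid over
  (θ, secular trend, v), and closed-form birthweight minimum-detectable-
  difference and low-birthweight power calculators with explicit ICC /
  design-effect assumptions.

## Worked example

```python
import numpy as np
from stovewedge import (
    StepWedgeDesign, SimulationParams, SteppedWedgeLogit,
    randomize_wedge_order, generate_cohort, simulate_panel,
)

order = randomize_wedge_order(12, seed=2014)
design = StepWedgeDesign.from_wedge_order(order)
params = SimulationParams(theta=-0.2, seed=2014)   # 20% odds reduction
cohort = generate_cohort(design, params)
panel = simulate_panel(design, cohort, params)
result = SteppedWedgeLogit.from_dataframe(panel, v=8).fit()
print(result.summary())
```

prints (1,748 children; 41,952 child-period observations):

```
Stepped-wedge logistic mixed model (Laplace ML)
========================================================
Observations: 41952   Converged: True
Spline df (v): 8   Cluster level: sector
log-likelihood: -11481.89
--------------------------------------------------------
theta (stove effect): -0.1800
  SE (model-based):   0.0700
  SE (robust):        0.0567   ratio 0.81   -> use model-based
  Wald z: -2.57   p = 0.01011
  95% CI: (-0.3172, -0.0428)
  odds ratio: 0.835
--------------------------------------------------------
alpha0 (baseline log-odds): -2.3974
sigma2 village: 0.0291   sigma2 child: 0.0628
```

The simulated stove effect θ = −0.2 is recovered (−0.18 ± 0.07, odds ratio
0.835): the intervention is detected at the 5% level, the robust/model-based
SE ratio near 1 indicates the assumed correlation structure is adequate, and
the variance components are close to the generating values 0.025 and 0.10
(these two parameters have a flat likelihood at this scale).

The same machinery is exposed on the command line:

```bash
stovewedge simulate --seed 1 --out data/         # full synthetic dataset
stovewedge fit --panel data/panel.csv --v 8 --sensitivity
stovewedge sample-size --n-per-group 1175
# minimum detectable birthweight difference: 50.5 g (n/arm=1175, SD=437.0 g, ICC=0.03357, m=1)
# power for LBW relative reduction 20% (p0=0.29, DEFF=2.36): 54.9%
```

## Layout

```
src/stovewedge/
  design.py     trial structure, wedge-order and phase-two randomization
  simulate.py   all synthetic-data generators + rate calibration
  episodes.py   diary ALRI episode detection and severity grading
  exposure.py   trimmed means, running medians, baseline, SIT/SIP/SIC
  glmm.py       spline basis, Laplace GLMM engine, robust SEs, birthweight
  power.py      power-simulation grid and sample-size calculators
  cli.py        command-line entry points
  io.py         delimited-text file contracts
docs/methods.md   modelling and numerical choices in detail
```
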