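# socflux

Does adding fresh carbon to soil build up soil organic carbon (SOC), or does
it prime away more old carbon than it adds? `socflux` answers this the way
the isotope-incubation literature does: it calibrates compartmental
decomposition models to labeled-CO₂ time series, standardizes the resulting
carbon fluxes to a common one-year horizon, and pools them across studies
with a weighted meta-analysis. It is a library for biogeochemists and
modelers working with soil incubation data, plus a small pipeline CLI.

## What is inside

* **Four decomposition models** with exact isotope bookkeeping —
  conventional first-order (new → labile/recalcitrant), an interactive
  two-pool model in which the old-C decay rate is `K_O + K_p·N^p` (the
  priming term, driven by the standing new-C pool `N`), and
  Michaelis–Menten / reverse Michaelis–Menten microbial models — integrated
  with fixed-step RK4 and validated against matrix-exponential and
  closed-form oracles.
* **Bayesian calibration** of any model to a study's three cumulative CO₂
  series (old-C control, old-C under addition, added-C) with a Gaussian
  likelihood `−Σ (Z−X)²/2σ²`, uniform priors, and an adaptive Metropolis
  sampler (MAP-screened start, covariance-adapted Gaussian proposals frozen
  after burn-in, reflection at the prior bounds).
* **Model selection** by the deviance information criterion:
  `DIC = D̄ + p_D`, pooled across studies as `DIC_w = Σ DIC_i n_i / Σ n_i`,
  compared through `L = exp(−0.5·(DIC_w − DIC_min))` with threshold 0.5;
  plus within-sample OLS agreement and fixed/random out-of-sample
  validation modes.
* **Flux accounting**: replenishment (labeled C left in soil pools),
  priming (treatment-minus-control old-C CO₂), and net change
  (replenishment − priming), each as % of added C at a standardized
  horizon, with posterior credible bands.
* **A scenario engine** for continuous inputs: spin-up to steady state at
  0.8 mg C kg⁻¹ d⁻¹, one-year runs under a 10% step or a gradual ramp (both
  injecting exactly 29.2 mg C kg⁻¹ extra), and warming/drying/wetting as
  ±10–15% rate rescalings.
* **Weighted-effect-size synthesis** (`M = ΣW*M/ΣW*`, `V = 1/ΣW*`,
  `CI = M ± 1.96√V`, weights `W* = n/s²`) with substrate N:C grouping and
  CI-based significance.
* **A synthetic-data generator** that emulates the incubation literature's
  structure (one-time labeled addition, mostly <10% of the SOC stock, ≥3
  time points over ≥28 days, reported SDs, N:C categories with an embedded
  high > low > none net-change ordering) so every stage is testable against
  known truth.

## A worked example

```python
import numpy as np
from socflux import MCMCConfig, run_mcmc, standardized_summary
from socflux.synthetic import SynthConfig, generate_collection

study = generate_collection(SynthConfig(n_studies=1, noise_cv=0.05, seed=3))[0]
obs = study.observations
chain = run_mcmc("interactive", obs, MCMCConfig(n_iterations=10_000, seed=5))
summary = standardized_summary(chain, "interactive", obs, horizon_days=365.0)
for metric, (mean, lo, hi) in summary.percent_of_added.items():
    print(f"{metric:14s} {mean:6.1f} [{lo:6.1f}, {hi:6.1f}] % of added C")
```

prints (seeds fixed, so exactly reproducible):

```
replenishment    41.2 [  38.7,   43.8] % of added C
priming           7.6 [   4.6,   13.0] % of added C
net              33.7 [  29.2,   37.8] % of added C
loss             58.8 [  56.2,   61.3] % of added C
```

Reading: a year after adding substrate worth ~15% of this soil's carbon
stock, about 41% of the added carbon remains in the soil, priming released
old carbon worth ~8% of the addition, so the soil ends up ~34% of the
addition richer — replenishment outweighs priming. The `examples/`
directory has one short script per capability (simulation, fitting,
selection, fluxes, scenarios, synthesis); each prints its numbers with a
line on what they mean. The same stages are scriptable from the shell:

```bash
socflux all --seed 1 --out runs/demo        # synthetic collection, end to end
socflux all --input-dir my_studies/ --out runs/real
```

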