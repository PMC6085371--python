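# Methods

`socflux` implements a data–model synthesis of soil organic carbon (SOC)
dynamics after fresh carbon additions: how much of the added carbon is
retained in the soil (replenishment), how much extra old SOC is respired
because of it (priming), and the resulting net SOC change. This note
documents the models, the calibration machinery, the numerical choices, and
what the synthetic-data experiments do and do not demonstrate.

## The experimental template

Every study is a paired laboratory incubation: a soil containing `SOC`
mg C g⁻¹ of old (unlabeled) organic carbon receives, at t = 0, a one-time
addition of isotope-labeled substrate (`added_c` mg C g⁻¹; in most studies
below 10% of the stock). Three cumulative CO₂ series are observed over at
least 28 days at more than two time points: old-C CO₂ in the control jar,
old-C CO₂ under addition, and CO₂ from the added substrate. The isotope
label makes the source attribution observable.

Definitions used throughout, all evaluated at a standardized horizon
(default 365 d) and normalized by the added amount:

* **replenishment** — labeled C still in any soil pool, equivalently
  `added − cumulative labeled CO₂`;
* **priming** — cumulative unlabeled (old-C) CO₂ in the treatment minus the
  control;
* **net change** — replenishment − priming, exactly;
* **loss** — 100% − replenishment.

## The four decomposition models

All models resolve each compartment into a labeled and an unlabeled mass and
ledger cumulative CO₂ per label; every right-hand side conserves each label
exactly (pools + CO₂ − inputs is constant), which is both a physical
requirement and the identity the flux accounting relies on.

1. **Conventional** (first-order, pools N → {L, R} with L↔R exchange).
   Respiration from a pool is (1 − outgoing transfer coefficients) of its
   decay flux. Priming cannot arise mechanistically; the model represents it
   by giving the treatment and control *different* rate parameters. The
   fit-level vector therefore has 12 entries: shared {K_N, a_LN, a_RN, f_L}
   plus per-condition {K_L, K_R, a_LR, a_RL}, fitted jointly against all
   three series.
2. **Interactive** (two pools; an extension of the introductory carbon
   balance model, ICBM). New C decays at K_N; a fraction r replenishes the
   old pool; the old pool decays at `K_O + K_p·N^p` — the second term is the
   priming mechanism, switched on by the standing new-C pool N. With
   N = 0 the old pool is a pure exponential.
3. **Michaelis–Menten**: explicit microbial biomass B; uptake of each
   substrate is Michaelis–Menten in the substrate and proportional to B;
   a fraction ε of uptake becomes biomass, (1 − ε) is respired; biomass
   turns over into the old pool at μ_B.
4. **Reverse Michaelis–Menten**: uptake is first-order in the substrate and
   saturating in biomass, B/(B + K_B).

Isotope bookkeeping in the microbial models follows the label through every
flux: uptake of labeled substrate is the labeled share of the pool's uptake,
assimilation routes ε of the *labeled* uptake into labeled biomass, and dead
labeled biomass feeds the labeled old pool. (Bookkeeping that instead scales
microbial terms by total biomass would create or destroy label; we keep the
label-conserving form, which changes nothing for totals.)

Initial conditions come from the study metadata and the initial-fraction
parameters: the native stock is unlabeled and split by f_L (conventional:
labile share) or f_N/f_B (fast-pool and biomass shares); the added substrate
is fully labeled and enters N.

## Integration

Fixed-step classical RK4 (default dt = 0.05 d), states linearly
interpolated onto the requested output times. The scheme is deterministic
and, because every right-hand side sums to the input rate, preserves mass
balance to round-off; the linear models are cross-checked against
`scipy.linalg.expm` to < 10⁻⁶ mg C g⁻¹. Parameter sets whose effective
rates exceed the stable step (possible in the Michaelis–Menten corner of
the prior box) are flagged as divergent and rejected by the calibration
rather than silently integrated.

The calibration hot path (likelihood evaluations inside the sampler, flux
and scenario posterior sweeps) uses dt = 0.25 d. For the rate magnitudes in
these priors, RK4 at 0.25 d agrees with 0.05 d to many digits below the
observation noise (asserted by a test); the coarser step keeps the
Monte-Carlo experiments at desk scale. All reported point simulations and
all oracle tests use dt = 0.05.

Continuous inputs are piecewise-linear rate schedules integrated exactly by
RK4 (degree ≤ 1 in t); one-time additions at t = 0 are initial conditions,
and mid-run impulses split the integration at the impulse time.

## Likelihood and sampler

The likelihood is Gaussian in the cumulative values:
`log L = −Σ_series Σ_t (Z − X)² / (2σ²)` with the reported per-point SDs;
missing or zero SDs fall back to `max(5% of Z, 1% of added C)` with a
warning. Priors are independent uniforms over the parameter boxes (decay
and turnover rates 10⁻⁵–1 d⁻¹; maximum assimilation rates 10⁻³–10 d⁻¹;
Michaelis constants 10⁻³–100 mg C g⁻¹; fractions 0–1; p 0.01–2; K_p 0–1),
so the Metropolis ratio reduces to the likelihood ratio. Joint constraints
(a_LN + a_RN ≤ 1, f_N + f_B ≤ 1) are enforced as zero prior mass.

The sampler is an adaptive Metropolis with three ingredients, all frozen at
the end of burn-in (first half of the chain, discarded) so the retained
chain is a valid Metropolis sample:

* **a MAP start** — a batch of prior draws (half uniform, half log-uniform
  for parameters spanning decades, floored at 10⁻⁶ of the upper bound when
  the lower bound is 0) is screened by likelihood and the best few are
  polished by Nelder–Mead in log-transformed coordinates. Without this,
  short chains reliably freeze in a mirror mode in which a large native
  fast pool (f_N ≈ 1) imitates the old pool;
* **covariance-adaptive Gaussian proposals** — steps `scale·L·z` with L
  refreshed every window from the Cholesky factor of the accumulated
  burn-in history (first quarter dropped as transient), scaled by
  2.38/√k, and reflected into the prior box;
* **acceptance-tuned global scale** — halved/doubled per window to keep the
  windowed acceptance rate inside [0.2, 0.5], with a harder cut when a
  window accepts almost nothing.

The classical uniform-window proposal
(θ_new = θ_old + d·(θ_max − θ_min)/D, d ~ U(−0.5, 0.5), reflected at the
bounds) is exposed as `propose` and used as the reference for its own
distributional tests; it is not robust enough as the production proposal
when posterior scales span four orders of magnitude.

Defaults: 50 000 iterations (the desk-scale experiments use 5–10 thousand),
burn-in fraction 0.5, adaptation window 250 iterations (shrunk so short
chains still get a dozen windows), acceptance-diagnostic error below 1%.
Chains are exactly reproducible from the configured seed.

## Model selection

Per study, `DIC = D̄ + p_D` with `D̄` the posterior mean of −2 log L and
`p_D = D̄ + 2 log L(θ̄)` at the posterior-mean parameters (evaluated, with a
warning, even when θ̄ falls outside the joint support — possible for
bounded, non-convex posteriors). Study DICs pool across a collection
weighted by data-point counts, and models are compared by
`L = exp(−0.5·(DIC_w − DIC_min))` with 0.5 as the selection threshold; ties
all score 1. The posterior-mean plugin is known to misbehave on strongly
ridged posteriors (p_D can go negative); the selection experiments in the
acceptance suite report the criterion exactly as defined here.

Within-sample evaluation regresses observed on modeled cumulative CO₂
pooled over studies and series (ordinary least squares; slope, R², and the
two-sided t-test P for the slope). Fixed-mode validation fits one substrate
amount and predicts the same soil under a different amount with parameters
held fixed. Random-mode validation half-splits the collection stratified by
added-C fraction quartile (simple split with a warning below 8 studies),
tunes only the prior boxes on the training half (envelope of the training
point estimates, widened 2× each way), refits the held-out studies under
those boxes, and reports the same agreement statistics.

## Flux accounting

Fluxes are computed from paired treatment/control simulations at the
standardized horizon and normalized by the added amount; posterior
uncertainty comes from re-simulating a posterior subsample (default 200
draws) and reporting the mean and the 2.5th/97.5th percentiles. The 1-year
horizon generally extrapolates beyond the incubation span using the fitted
model — that is the point of model-based standardization, and it is why the
validation modes matter. Replenishment includes labeled microbial biomass
where the model has one. The traditional "percent increase over control"
priming expression is available as a diagnostic only.

## Scenario engine

For the continuous-input experiment the interactive model is spun up to its
exact algebraic steady state under 0.8 mg C kg⁻¹ d⁻¹ (N* = I/K_N,
O* = r·I/(K_O + K_p·N*^p); ≈ 378 g C m⁻² yr⁻¹ for a 1-m topsoil at
1.3 g cm⁻³), then run for a year under: constant 0.80; a 10% step to 0.88;
or a gradual ramp. The ramp is linear from 0.8004 at t = 0 to 0.9596 at
t = 365, the continuous schedule whose integral of increments equals the
discrete daily ramp's total of exactly 29.2 mg C kg⁻¹ — the same extra
carbon the step injects. The response is the end-of-year SOC difference
against the continued-constant baseline (identical to the initial stock at
steady state), as a percent of the extra input. Warming multiplies the
three rate parameters (K_N, K_O, K_p) by 1.15 — the conventional rounding
of Q10 = 2 over +2 °C; `exact_q10=True` uses 2^0.2 ≈ 1.1487 — drying by
0.9 and wetting by 1.1, applied before the spin-up so each climate is
internally consistent. Per study, the response is averaged over a posterior
subsample and pooled by the weighted-mean synthesis.

## Synthesis

Study effects (fluxes or scenario responses) are pooled by a fixed-form
weighted mean: `M = ΣW*M / ΣW*`, `V = 1/ΣW*`, `CI = M ± 1.96·√V`. The
weighting factor is `W* = n / s²` — replicate count over squared posterior
SD, an inverse squared standard error — chosen to honor weighting by both
the variation and the sample size of individual studies; the per-study
uncertainty entering the weight is the posterior spread. Significance uses
only the 95% CIs: an effect is significant when its CI excludes zero, and
two N:C groups differ when their CIs do not overlap. No random-effects
heterogeneity model is fitted.

## Synthetic data

The generator emulates the collected studies' statistical structure so
every stage is testable with known truth: SOC uniform on 5–30 mg C g⁻¹;
added C mostly (probability 0.75) 1–8% of the stock, otherwise 8–20%, so
over two-thirds of studies sit under 10%; weekly observations to day 70;
substrate N:C categories {none, low, high} in configurable proportions.

True interactive-model parameters are drawn from field-realistic interior
ranges rather than the (deliberately vague) prior boxes: K_N 0.02–0.08 d⁻¹,
K_O 5×10⁻⁵–5×10⁻⁴ d⁻¹, p 0.8–1.2, f_N 0.005–0.02; r rises with the
substrate N:C category (0.30–0.40 / 0.40–0.50 / 0.50–0.60) and the priming
strength falls with it (K_p = c_p/SOC with c_p 3–6×10⁻³ / 1.5–3×10⁻³ /
0.5–1.5×10⁻³), so the category ordering of the true net change
(high > low > none) is embedded as known truth. The priors' midpoints were
rejected as truth ranges because they imply old SOC turning over in days.

Noise is multiplicative on the *increments* of each cumulative series
(clipped at zero, re-accumulated), which preserves monotonicity without the
upward bias of noising-then-sorting cumulative values. The emitted series
is what published tables contain: the mean of `n_replicates` jars, so its
increments carry noise CV/√R, while the SD column reports the
across-replicate SD of a single jar's cumulative value, √(Σ increment²)·CV,
floored at 1% of the added C. Default CV 5% per jar, R = 3. Because the
calibration treats the cumulative points as independent although their
accumulated noise is correlated, the replicate-SD σ being larger than the
mean-series noise is what keeps the posteriors approximately calibrated
(measured per-parameter coverage 0.83–1.0 at nominal 95%); it also makes
the reported errors conservative, which narrows the deviance gap between
the generating model and its closest competitor in selection experiments.
Per-study generators are spawned from the master seed, so study i is
identical regardless of how many studies are requested.

What passing the synthetic experiments shows: the pipeline recovers what
the interactive model generated, under the noise model above. What it does
not show: robustness to structural error (real soils are not two pools),
to correlated or systematically biased measurements, to the between-study
heterogeneity of real collections, or to the field conditions the
incubation template itself abstracts away.

## Problem sizes in the shipped experiments

The test and acceptance experiments run, per choice, at desk scale: chains
of 10 000 iterations for recovery and coverage (20 studies / 20
replicates), 5 000 for the model-selection race (10 seeded runs of 3
studies × 4 models), posterior subsamples of 100–200 for flux and scenario
sweeps. Production analyses should use the 50 000-iteration default and as
many studies as are available.

## Known limitations

* The likelihood treats cumulative observations as independent across time
  points although cumulative noise is autocorrelated by construction; this
  is the standard simplification for this data type and slightly
  miscalibrates posterior widths.
* DIC with the posterior-mean plugin can produce negative effective
  parameter counts on ridged posteriors (overparameterized models fitted to
  data they can interpolate); the model-selection experiments inherit this
  behavior of the criterion itself.
* The (K_p, p) priming pair is identified mostly through its product over
  the incubation span; one-year extrapolations of priming therefore carry
  the widest posterior bands.
* Steady-state solving is implemented for the interactive model only (the
  scenario experiment uses nothing else).
* Environmental modifiers are static rate rescalings; no temperature or
  moisture time series are modeled.
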