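# gcjoint

Joint modelling of longitudinal fecal glucocorticoid (fGC) trajectories and
adult survival in wild female baboons.

## The problem

Whether sustained activation of the HPA (hypothalamic–pituitary–adrenal)
axis shortens life in natural populations is hard to test: it needs
repeated hormone measurements across adult lives, survival follow-up, and a
model that links the two without treating noisy samples as the true
hormonal state. `gcjoint` implements that analysis for the study design of
a long-term baboon field project — sparse, irregular fecal glucocorticoid
samples (median 7 per female-year), environmental and social covariates
built from raw field tables, and all-cause adult mortality with staggered
entry and right censoring — as a reusable, tested pipeline driven entirely
by a synthetic-data generator. It is aimed at behavioral ecologists and
biostatisticians who want to fit or power such shared-parameter models
without access to the original field data.

## The model

A linear mixed submodel for log fGC,

    y_i(t) = m_i(t) + eps_i(t) = X_i(t) beta + b0_i + b1_i t + eps_i(t)

(fixed effects: age, reproductive state, season, rainfall anomaly,
temperature, group size and its square, dominance rank, alpha status,
sample-storage times), is coupled to a proportional-hazards submodel with a
B-spline log-baseline, left truncation at adult entry, and yearly
time-varying covariates (social-bond strength DSI_F / DSI_M, annual
rainfall anomaly):

    h_i(t) = h0(t) exp( gamma' w_i(t) + f(alpha, M_i(t)) )

The association `f` is the current value `alpha * m_i(t)`, the current
slope `alpha * m_i'(t)`, the cumulative exposure
`alpha * integral_5^t m_i(u) du`, or absent. Estimation is
Laplace-marginal MAP with Gaussian-curvature posterior draws (no MCMC
backend is assumed); dynamic prediction gives conditional survival curves
for hypothetical females holding any chosen fGC percentile. See
`docs/methods.md` for assumptions, priors and numerical choices.

## Worked example

```python
import numpy as np
from gcjoint import (AssociationSpec, MCMCConfig, SimConfig, build_joint_data,
                     conditional_survival, fit_joint, fit_lmm,
                     median_survival_age, percentile_trajectory, r2_nakagawa,
                     simulate_all)

cfg = SimConfig(seed=5, assoc=AssociationSpec("auc", 0.115))
sim = simulate_all(cfg)                      # 242 females, 19.5-year window

lmm = fit_lmm(sim.fgc.design)
marg, cond = r2_nakagawa(lmm, sim.fgc.design)
print(f"samples {len(sim.fgc.design.y)}, deaths {int(sim.survival.event.sum())}")
print(f"marginal R2 {marg:.3f}, conditional R2 {cond:.3f}")

data = build_joint_data(sim.fgc.design, sim.fgc.year_table, sim.records,
                        assoc_mode="auc")
fit = fit_joint(data, mcmc_config=MCMCConfig.test_preset(seed=5), init=lmm)
lo, hi = fit.posterior_interval("alpha")
print(f"AUC association alpha: posterior mean {fit.draws['alpha'].mean():.3f}, "
      f"90% CI ({lo:.3f}, {hi:.3f})  [truth 0.115]")

grid = np.arange(14.0, 27.01, 0.25)
for pct in (90, 10):
    spec = percentile_trajectory(sim.fgc.samples, pct, t0=14.0,
                                 design=sim.fgc.design)
    curve = conditional_survival(fit, spec, grid,
                                 rng=np.random.default_rng(pct))
    print(f"p{pct} female: median survival age {median_survival_age(curve):.1f}")
```

prints

```
samples 14321, deaths 142
marginal R2 0.136, conditional R2 0.206
AUC association alpha: posterior mean 0.091, 90% CI (-0.001, 0.180)  [truth 0.115]
p90 female: median survival age 19.6
p10 female: median survival age 22.0
```

Reading the output: the mixed submodel explains ~14% of log-fGC variance
through measured covariates and ~21% adding individual identity, matching
the study's variance decomposition. The cumulative-exposure coefficient is
recovered near its true value with an interval of realistic width, and a
hypothetical female holding the 90th fGC percentile from adulthood
(conditioned alive at age 14) reaches median survival ~2.4 years before
one holding the 10th percentile — the qualitative life-expectancy gap a
positive cumulative association implies.

The same analysis runs end-to-end from the command line with a YAML config
(`gcjoint run examples/config.yaml`), with subcommands `simulate`, `covariates`,
`dsi`, `fit-longitudinal`, `fit-joint`, `predict` and `report` for the
dependency-ordered stages, CSV outputs with documented headers, and a
manifest with row counts, seed and config hash.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the generator and the longitudinal submodel from scratch at their
default settings and writes the package's self-contained calibration
quantities as JSON: the median number of fGC samples per female-year, the
marginal and conditional Nakagawa R2 of the mixed submodel on a default
cohort, and the size of one log-fGC unit in SDs of the simulated
distribution. Each value is computed at run time from a fresh simulation
under the given seed.
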