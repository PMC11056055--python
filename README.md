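# stcar

Bayesian spatio-temporal Poisson models with Leroux conditional
autoregressive (CAR) priors: synthetic panel-count generation under
controlled spatial and temporal correlation, posterior sampling by a
No-U-Turn Hamiltonian Monte Carlo sampler, and model comparison by WAIC,
RMSE, MAE and predictive-interval coverage.

## Who this is for

Researchers comparing areal spatio-temporal count models — disease mapping,
food-security surveillance, small-area epidemiology — who want a tested,
reproducible harness for asking: *which space-time decomposition of the
random effect holds up as the strength of spatial and temporal correlation
varies?*

## The models

All four models share a Poisson observation layer with log link and offset,

```
y_it ~ Poisson(mu_it),    log(mu_it) = x_it' beta + log(n_it) + v_it,
```

for unit `i = 1..N` and time `t = 1..T`, and differ in the decomposition of
the spatio-temporal random effect `v_it`:

| Model | `v_it` | Priors on the pieces |
|-------|--------|----------------------|
| SPLTM | `w1 + a_i + (w2 + b_i)(t - tbar)/T`, `tbar = (T+1)/2` | `a, b ~ CAR(rho, k2, W)`; `w1, w2` flat |
| SPAM  | `a_i + b_t + c_it` | `a ~ CAR(W)`, `b ~ CAR(Z)`, `c_it ~ N(0, k2_I)` |
| STSM  | `a_it + b_t` | `a_.t ~ CAR(rho_s, k2_t, W)` per `t`; `b ~ CAR(rho_T, k2, Z)` |
| TMS   | `a_it` | `a_.t | a_.(t-1) ~ N(rho_T a_.(t-1), k2 Q(W, rho_s)^-1)` |

`CAR(rho, k2, W)` is the Leroux Gaussian Markov random field with precision
`Q(W, rho) = rho (W_d - W) + (1 - rho) I`, where `W` is the binary symmetric
spatial adjacency, `W_d` its degree diagonal, and `Z` the tridiagonal lag-one
temporal adjacency. Every `rho` has a uniform(0, 1) prior and every variance
an inverse-gamma prior; `beta` is flat.

Models are fitted by NUTS with dual-averaging step-size adaptation and a
diagonal mass matrix learned during burn-in; the study-scale chain profile
(120,000 iterations, 20,000 burn-in, thinning 10, i.e. 10,000 retained
draws) and a desk-scale profile (6,000 / 1,000 / 5) are built in. Goodness
of fit is `WAIC = -2(lpd - pWAIC)` from the per-draw pointwise
log-likelihoods, bias is RMSE and MAE of the posterior-mean intensities, and
validation is the coverage percentage of equal-tailed 95%
posterior-predictive intervals on a held-out 30% of records.

## Worked example

```python
import numpy as np
from stcar import (Scenario, generate_panel, PanelData, temporal_adjacency,
                   build_model, run_chain, chain_profile, waic,
                   point_predictions, rmse, mae)

scenario = Scenario(sp=0.5, tm=0.5, n_units=15, n_times=8, seed=11)
panel = generate_panel(scenario)                  # zero-truncated counts
data = PanelData(y=panel.y, offset=panel.offset, X=panel.X,
                 graph=panel.graph, tgraph=temporal_adjacency(8))

for name in ("SPLTM", "SPAM"):
    model = build_model(name, data)
    draws = run_chain(model, chain_profile("desk", seed=11))
    w = waic(draws.pointwise_loglik)
    yhat = point_predictions(draws, model)
    print(f"{name}: WAIC={w.waic:7.1f} pWAIC={w.p_waic:5.1f} "
          f"RMSE={rmse(panel.y, yhat):.3f} MAE={mae(panel.y, yhat):.3f}")
```

prints (numbers from this exact script):

```
SPLTM: WAIC=  338.4 pWAIC=  5.6 RMSE=0.803 MAE=0.636
SPAM: WAIC=  343.0 pWAIC=  7.5 RMSE=0.787 MAE=0.609
```

The ANOVA-type decomposition (SPAM) tracks the data more closely — lower
RMSE and MAE — because the generating process has exactly a unit-level plus
time-level latent structure that the linear time trend of SPLTM cannot
absorb. Its WAIC pays a visibly larger complexity correction (pWAIC), so on
a single small replication the WAIC race can go either way; averaged over
replications and scenarios SPAM's mean WAIC falls below SPLTM's in the
majority of correlation settings, which is the experiment's headline
ordering and what the acceptance suite reproduces.

The same pipeline is scriptable from the shell: `stcar simulate`,
`stcar fit`, `stcar run-grid`, `stcar validate`, `stcar report`
(see `stcar --help`).

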