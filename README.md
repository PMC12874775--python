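# dcbnet — dynamic copula Bayesian networks for longitudinal panels

`dcbnet` models time-varying dependence among ordinal/binary household
outcomes — program participation, food security, wealth, mother wellbeing,
child undernutrition — as a **dynamic copula Bayesian network**: a
time-sliced Bayesian network whose conditional dependencies are bivariate
copulas with slice-specific parameters.  It is aimed at biostatisticians and
epidemiologists who need a probabilistic, rank-based dependence map across
several interrelated ordinal outcomes over survey waves, where linear or
Gaussian assumptions do not hold and one-exposure/one-outcome designs fall
short.

## Model

The joint density of a panel sequence factorizes as

    P(x^(0:T)) = P(x^(0)) · Π_t P(x^(t) | x^(t−1))

with an initial graph **G₀** over the slice-0 variables and a transition
graph **G→** whose edges are contemporaneous (within slice *t*) or
autoregressive (slice *t−1* → *t*).  Each node's conditional is its marginal
density times bivariate copula densities linking it to its parents, with
per-slice parameters θ_t.  The toolkit provides:

* a registry of ten bivariate copula families (Gaussian, Clayton, Frank,
  Gumbel, Joe, AMH, Raftery, Marshall–Olkin, Roch–Alegre, independence)
  with CDF, density, conditional h-function h(v|u) = ∂C/∂u, exact samplers,
  and closed-form or numerical Kendall-τ ↔ θ maps;
* probability-integral and distributional transforms with correct tie
  handling for ordinal data;
* tie-corrected Kendall τ-b (optionally observation-weighted) with per-wave
  edge trajectories and significance stars;
* structure learning for (G₀, G→) by greedy hill-climbing under the score
  ℓ − 0.5·log(K)·|Θ| with time-slice constraints, restarts and an
  AIC-penalty variant;
* per-edge estimation by τ-initialized multi-restart local optimization and
  by random-walk Metropolis MCMC (posterior medians, 95% CrI, split-R̂ /
  ESS diagnostics, posterior predictive τ checks), plus family selection by
  log-likelihood/AIC/BIC;
* a goodness-of-fit panel (likelihood, AIC, BIC, RMSE, NSE, NRMSE, MAE/SD)
  with conditional-mean edge prediction;
* selection/spillover tools: stabilized inverse-probability weights,
  standardized-mean-difference balance diagnostics, leave-one-out community
  program intensity (CPI), community-block bootstrap;
* a synthetic longitudinal panel generator reproducing the reference
  scenario (8-level participation margins per wave, copula-linked ordinal
  outcomes, persistence, communities, baseline waves) so the whole pipeline
  is testable without any external data.

## Worked example

```python
from dcbnet.synthetic_data import default_config, generate_panel
from dcbnet.dynamic_graph import study_fixture
from dcbnet.structure_learning import learn_dynamic_structure
from dcbnet.parameter_learning import fit_edge
from dcbnet.dependence import trajectory_table

cfg = default_config(n_units=1000, seed=42)
panel = generate_panel(cfg)
waves = ["2009", "2013", "2016"]

graph, reports = learn_dynamic_structure(
    panel, study_fixture(with_cpi=False), restarts=3, seed=42, waves=waves)
print(sorted(graph.g0_edges))
print(trajectory_table(panel, [("PS", "FS"), ("FS", "CUS")], waves))

fit = fit_edge(panel, ("PS", "FS"), waves, seed=42, restarts=10,
               n_chains=4, n_draws=1000, n_adapt=500)
```

prints

```
[('FS', 'CUS'), ('MSW', 'CUS'), ('PS', 'FS'), ('PS', 'MSW'),
 ('PS', 'WQ'), ('WQ', 'CUS'), ('WQ', 'FS')]
     edge      2009      2013      2016
 PS -> FS  0.570***  0.738***  0.723***
FS -> CUS -0.140*** -0.205*** -0.249***
best family: frank
theta local: 5.1817   posterior median: 5.1894  95% CrI: (4.9337, 5.4270)
tau: 0.469***  NSE: 0.433  RMSE: 0.218  R-hat: 1.0074
```

The learned initial graph recovers all seven planted within-slice edges.
The τ trajectory shows participation→food-security dependence strengthening
over waves and the protective (negative, strengthening) food-security→
undernutrition edge, with *** marking 1% significance.  For the PS→FS edge
the AIC-selected family's local estimate sits inside the MCMC 95% credible
interval, R̂ < 1.01 indicates converged chains, and NSE/RMSE summarize the
skill of the conditional-mean predictor on the pseudo-observation scale.

The same pipeline is available from the shell:

```bash
dcbn report --n-units 1000 --seed 42 --outdir out/
# writes panel.csv, graph.json, edge_fits.csv, tau_edges.csv, tau_self_loops.csv
```

Real panels enter as a CSV with a JSON sidecar schema (variable scales,
ordered levels, orientation flags); see `dcbnet.panel.PanelDataset`.

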