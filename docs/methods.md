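# Methods

## Model

`dcbnet` implements a dynamic copula Bayesian network (DCBN): a Bayesian
network replicated over time slices whose conditional dependencies are
bivariate copulas with slice-specific parameters.  The joint density of a
panel sequence factorizes as

    P(x^(0:T)) = P(x^(0)) · Π_{t=1..T} P(x^(t) | x^(t-1)),

with the initial density built from a graph G0 over the slice-0 variables
and the transition density from a two-replication graph G→ whose edges are
either contemporaneous (within slice t) or autoregressive (slice t−1 → t).
Each node's conditional is the product of its marginal density and bivariate
copula densities linking it to its parents — the edge-wise composition under
which every dependency is a named bivariate family with its own parameters
θ_t per slice.  Feedback is allowed across time; each slice is acyclic.

### Edge-wise composition for multi-parent nodes

A node with several parents is modeled as a *product of bivariate copula
densities*, one per edge, rather than a joint (d+1)-dimensional copula or a
copula-ratio with a multivariate denominator.  This matches the per-edge
reporting surface (one family, one θ, one τ per edge) and keeps estimation
local, at the cost of not being an exact joint density when parents are
mutually dependent.  The alternative — a full multivariate copula ratio per
node — is deliberately out of scope; swapping it in would only change
`structure_learning`'s score accumulation and `parameter_learning`'s
composition rule.

## Marginals and pseudo-observations

Discrete/ordinal variables (all of the reference-scenario variables) use empirical
category masses and the **distributional transform**
U = F(x−) + V·(F(x) − F(x−)), V ~ U(0,1), which maps tied data to exact
uniforms when the marginal is correct.  V-streams are independent per
(variable, wave, seed).  Continuous variables use the empirical CDF with
rank/(n+1) rescaling so transforms never reach 1 (downstream densities are
undefined at the boundary).  Ordered-logit marginals are not implemented —
the empirical CDF covers every ordinal use here; this is a deliberate
simplification.  Rows with missingness in either member of an edge are
dropped pairwise with a logged count; no imputation.

Densities evaluated at empirical boundary values are clamped 1e-10 into the
interior by the likelihood layer (`edge_loglik`); the copula layer itself
rejects exact-boundary density evaluation.

## Copula registry

Ten families ship by default: independence, Gaussian, Clayton, Frank,
Gumbel, Joe, AMH, Raftery, Marshall–Olkin, Roch–Alegre.  Archimedean
families are implemented through their generators (density
c = −φ''(C)φ'(u)φ'(v)/φ'(C)³, conditional h = φ'(u)/φ'(C)).  The
Roch–Alegre family is the two-parameter Archimedean generator
φ(t) = ((1 − ln t)^θ1 − 1)^θ2, θ1 > 0, θ2 ≥ 1.  The Marshall–Olkin copula
C(u,v) = min(v·u^{1−θ1}, u·v^{1−θ2}) has a singular component of mass τ on
the curve u^θ1 = v^θ2; its density is the absolutely continuous part, its
sampler the exact exponential-shock construction, and maximum-likelihood
fits to data carrying that singular mass are intrinsically ill-posed — it is
fit only to smeared (distributionally transformed) data in practice, and it
is excluded from the estimator-recovery guarantees for that reason.

Kendall's τ uses closed forms where available (Gaussian (2/π)asin ρ,
Clayton θ/(θ+2), Gumbel 1−1/θ, AMH, Raftery 2θ/(3−θ), Marshall–Olkin
θ1θ2/(θ1+θ2−θ1θ2)), the generator integral τ = 1 + 4∫φ/φ' for Frank and
Roch–Alegre, and a series for Joe.  τ-inversion is Brent root-finding on
θ1; two-parameter families anchor θ2 at a fixed default — the domain
midpoint for Marshall–Olkin (τ range (0, 0.5)) and θ2 = 1 for Roch–Alegre,
where the second generator transform is inactive and the attainable τ range
spans ≈ (0, 1) (the midpoint would restrict it to τ ≳ 0.75).

Numerical notes: generators are evaluated with `log1p`/`expm1` branches so
that φ never underflows to zero near t = 1 (underflow there makes the
density ratio explode); conditional inversion uses 60-step vectorized
bisection on the h-function, which also handles h-jumps from singular
components correctly (generalized inverse).

## Dependence screening

Tie-corrected Kendall τ-b with the pairwise weight-product extension for
observation weights (exactly τ-b at unit weights).  Significance for
unweighted τ uses z = 3τ√(n(n−1))/√(2(2n+5)) with 10/5/1% stars; weighted τ
gets its uncertainty from the community-block bootstrap because weights
invalidate that variance.  Orientation harmonization (higher FS/WQ = better,
higher CUS = more undernutrition) is a declarative per-variable flag applied
once at load, never inside τ computation.

**τ-b on grouped data is not the latent copula τ.**  For ordinal variables
the tie-corrected τ-b of the discretized pair sits systematically above the
latent τ (≈ +0.04–0.06 at τ = 0.4–0.6 with the margins used here).  Tests
therefore compare empirical τ-b against the *exact population τ-b* of the
discretized pair (computable from the copula CDF and the margins), not
against the latent target directly.

## Structure learning

Greedy hill-climbing (add/delete/reverse) over a constraint template with
the score ℓ − 0.5·log(K)·|Θ| (higher is better), where ℓ is the maximized
edge-wise copula log-likelihood plus graph-independent marginal terms, K is
the number of sequences (initial part) or transitions (transition part), and
|Θ| counts free copula parameters (not edges — this matters for
two-parameter families).  An AIC-penalty variant (one unit per parameter) is
available for sensitivity.  G0 and G→ are learned separately
(decomposability) and merged; the total score is the sum of the parts.

Choices: maximum in-degree 3; screening catalogue {Gaussian, Frank} during
search (one parameter each, full ±τ range) with the full catalogue reserved
for post-hoc family selection; restarts start from random subgraphs of the
template with edge probability 0.3 (the first restart from the empty
graph); deterministic for a given seed.  Because bivariate copula
likelihoods are exchangeable, edge *direction* cannot be identified from
data — the template supplies orientation, and reverse moves are admitted
only when the reversed edge is itself in the template.

## Parameter estimation

Per edge, two estimators:

* **Local**: L-BFGS-B on the log-likelihood, first start at the τ-inverted
  parameter, remaining starts uniform over the domain (default 100 restarts
  at the library surface; structure search uses 3, edge reports 30 — the
  likelihoods here are low-dimensional and nearly unimodal).  The objective
  is re-evaluated at the optimizer's solution because the failure-penalty
  cliff used to guard invalid parameters can corrupt the reported optimum.
* **MCMC (primary)**: random-walk Metropolis, componentwise Gaussian
  proposals on the logit-transformed parameter scale, uniform prior over the
  (numerically truncated) domain with the transform Jacobian included.
  Defaults: 4 chains × 2000 draws after 1000 adaptation steps, step sizes
  adapted toward ≈30% acceptance in 50-iteration windows.  Reports posterior
  medians and central 95% credible intervals.

Diagnostics: rank-normalized split-R̂ and ESS (arviz) drive the
`converged` flag at R̂ < 1.01; a classic whole-chain Gelman–Rubin variant
(`classic_rhat`, floored at 1) is exposed for the identical-chains identity.
Posterior predictive τ checks draw θ from the posterior, simulate n pairs
and ask whether the observed τ falls in the central 95% predictive interval.
Two-parameter posteriors (notably Roch–Alegre, whose θ1/θ2 trade off along a
τ-level ridge) mix slowly under componentwise proposals; low ESS there is
flagged, not fatal, and interpreted cautiously.

Family selection fits every catalogue family locally and ranks by
log-likelihood, AIC or BIC; ties break toward fewer parameters, then name.

## Fit metrics

AIC = −2ℓ + 2k and BIC = −2ℓ + k·log(n) (the log-likelihood reading — the
literal "likelihood" in those formulas would be dimensionally inconsistent).
Edge-level predictive skill uses the conditional-mean rule
ŷ = E[V | U = u] = 1 − ∫ h(v|u) dv (64-point Gauss–Legendre) on the
pseudo-observation scale, then RMSE, NSE = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²,
NRMSE = RMSE/SD(y) and MAE/SD with the n−1 SD.  The conditional-mean rule
and the pseudo-scale are package choices (a conditional-median alternative
would swap in behind `predict_edge`); they fix conventions that a bare
RMSE/NSE report leaves open.

## Selection and spillover adjustment

* Stabilized IPW: main-effects logistic propensity on baseline covariates,
  weight P(A=a)/P(A=a|X); optional symmetric percentile truncation (default
  none, (1,99) available).  Perfect separation raises with advice.
* Balance: SMD = (mean₁−mean₀)/pooled SD (pooled SD always unweighted so
  weighted and unweighted SMDs share a scale), plus Wilcoxon rank-sum tests.
* CPI: leave-one-out share of other households in the community
  participating in any initiative (participation ≠ control); missing for
  singleton communities; program-specific variants via a different
  indicator column.
* Community-block bootstrap: resample communities with replacement, keep
  whole blocks, percentile 95% CI (BCa not implemented — percentile is the
  simplest defensible default).  Failed replicates are dropped with a logged
  count; >10% failures abort.

## Synthetic panel generator

The generator emulates the statistical structure the DCBN assumes, not any
real survey: 2 baseline + 3 analysis waves; an 8-level participation
variable with per-wave margins fixed to the printed participation table
(cells stored verbatim; the 2013/2016 printed aggregate rows are internally
inconsistent with their cells by rounding, so aggregates are recomputed from
cells and asserted only where exact — 2009); ordinal FS (4 levels), WQ
(5 quintiles), MSW (5), and an 8-state CUS collapsible to binary
(normal vs any undernourished state); uniform community assignment
(default 25 communities).

Children are generated by **sequential conditional inversion**: a uniform
draw is pushed through the inverse h-function for each conditioner in turn —
own past (persistence) first, then contemporaneous parents in declared
order — and finally discretized through the declared margins.  Stated τ
targets are exact for single-conditioner children and attenuated/compounded
for multi-conditioner ones (e.g. CUS with three parents plus persistence);
recovery tests therefore use single-edge configurations, while the full
default configuration is used for structure recovery, where only edge
presence matters.  Negative-τ edges under positive-only families use a 180°
rotation of the conditioning argument; Marshall–Olkin uses the symmetric
α = β = 2τ/(1+τ) parameterization so the full τ ∈ (0,1) range is reachable.

Default dependence ladders follow the reference scenario's per-wave τ trajectories
(e.g. participation→food security 0.392/0.517/0.624 under Joe;
food security→undernutrition −0.33/−0.418/−0.60 under rotated Raftery;
wealth→undernutrition negative Gaussian).  Where a scenario's nominal
per-edge family cannot attain its target τ (AMH saturates at
τ = 1/3), the Gaussian family carries the target instead — the τ ladder,
not the family label, is treated as the generative condition.  Baseline
waves carry persistence only (no contemporaneous edges), acting as
pre-program conditioning variables; baseline-covariate confounding is dialed
by a target SMD (default 0.18) realized exactly in expectation by mean
shifts between later participants and non-participants.

What passing tests on these panels do **not** show: robustness to survey
attrition, informative sampling weights, real geography/interference
structure, or misspecified marginals — none of which the generator emulates.

## Problem sizes and runtimes

Test and acceptance runs use n = 1000–5000 units, 10 seeds for recovery
statements, 4×2000-draw chains, B = 120 bootstrap replicates over 10–20
trials — sizes at which every asymptotic property checked here is
comfortably in regime (e.g. bootstrap coverage is checked at n = 1000
because at n = 400 the finite-sample bias of τ-b under heavy ties, not
bootstrap validity, dominates the miss rate).  The full suite runs in
roughly ten minutes on one core.

## Known limitations

* Edge-wise composition is not an exact joint density for dependent parents.
* Edge directions come from the template, not the data (bivariate
  exchangeability).
* Marshall–Olkin maximum likelihood ignores the singular component.
* Componentwise Metropolis mixes slowly on two-parameter τ-ridges.
* The weighted-τ estimator's finite-sample distribution is unknown;
  inference for it is bootstrap-only.
* Vine constructions, latent slices, continuous-time dynamics and
  goodness-of-fit tests beyond the reported metric panel are out of scope.
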