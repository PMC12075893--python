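# Methods

## Setting and model

`baskex` targets single-arm basket trials with binary endpoints: one
treatment tested across `K` disease-defined baskets, with responses
`Y_k ~ Binomial(n_k, p_k)`.  A basket trial that adds baskets mid-study
splits into `K0` *existing* baskets and `K' = K - K0` *new* baskets,
typically smaller because of the shorter recruitment window.  For each
basket the hypotheses are `H0: p_k <= q0` versus `Ha: p_k > q0`, decided by
the rule "declare efficacy when `P(p_k > q0 | data) > Delta_k`", with
strict inequalities throughout.

Information borrowing uses the exchangeability–nonexchangeability (EXNEX)
mixture.  On the log-odds scale `theta_k = logit(p_k)`:

- with prior probability `pi_k` the basket is exchangeable:
  `theta_k ~ N(mu, sigma^2)`, `mu ~ N(logit(q0), nu_mu^2)`,
  `sigma ~ half-normal(0, 1)`;
- otherwise it is non-exchangeable: `theta_k ~ N(m_k, nu_k^2)` with
  `m_k = logit(rho_k)` and `nu_k^2 = 1/rho_k + 1/(1 - rho_k)`, the
  log-odds variance of a single observation at the plausible rate `rho_k`.

Mixture membership is carried by `delta_k ~ Bernoulli(pi_k)`.  The
*independent* analysis model drops all cross-basket structure and places
`theta_k ~ N(logit(q0), 10^2)` on each basket alone.

Default hyperparameters (the default design's values): `q0 = 0.2`,
`q1 = 0.4`, `pi_k = 0.5`, `rho_k = 0.3` (a marginally effective rate
between null and target), `nu_mu = 10`, half-normal scale 1.

## Posterior computation

Inference is Metropolis-within-Gibbs:

- each `theta_k`: Gaussian random-walk proposal, accepted against the
  binomial likelihood times the `delta_k`-selected normal prior;
- `delta_k`: exact Gibbs draw from its Bernoulli full conditional
  (the EX and NEX components are structurally distinct densities at the
  current `theta_k`, so no label switching arises);
- `mu`: exact Gibbs draw from its normal full conditional over the
  currently-exchangeable baskets;
- `log sigma`: Gaussian random walk with the half-normal prior and
  log-scale Jacobian.

Proposal scales adapt toward 44% acceptance by Robbins–Monro during warmup
and are frozen afterwards, so retained draws target the exact posterior.
Defaults for a single analysis are 4 chains of 2,500 warmup plus 2,500 kept
iterations.  Convergence is summarised by a between/within-chain ratio and
an autocorrelation-based effective sample size; `R-hat > 1.05` or
`ESS < 400` logs a warning and is recorded in the result's diagnostics,
never silently altering output.

The sampler is *batched*: all chain state carries a leading replicate axis,
so a calibration or operating-characteristic study advances thousands of
simulated datasets in lock-step through vectorised updates.  Batched fits
accumulate exceedance counts and moments online instead of storing draws.
Simulation-loop fits default to 2 chains of 750 warmup plus 2,500 kept
iterations per dataset (5,000 kept draws, exceedance Monte Carlo sd roughly
0.005–0.01), a deliberate throughput/precision trade-off; single-trial
analyses keep full draws at the longer defaults.

Correctness of the sampler was established against brute-force nested
quadrature (`tests/oracle.py`): the posterior is summed analytically over
the `2^K` membership configurations, each factorising into 1-D theta
integrals and a 2-D `(mu, sigma)` integral, on threshold-aligned grids.
Exceedance probabilities agree within 0.01 for small-`K` cases, and the
degenerate limits (`pi = 0`: independent; `pi = 1`: one hierarchical
component) match closed-form or importance-sampling cross-checks.

## Decision approaches for added baskets

- **IND** — existing baskets: EXNEX over the `K0` existing; new baskets:
  independent model, one basket at a time.  Quarantines the new baskets:
  their addition cannot move existing-basket inference, and their type I
  error is controlled by construction.
- **UNPL** — unplanned addition: cut-offs calibrated on the existing
  baskets only; at analysis time one EXNEX over all `K`.  New baskets
  inherit the cut-off of the existing basket with the nearest sample size
  (ties to the smallest index — a deterministic choice where any rule is
  defensible).
- **PL1(a)** — planned addition, one model: a single EXNEX over all `K`
  baskets for both calibration and analysis (timing of addition known, so
  all sample sizes are fixed at calibration).
- **PL2(a)** — planned addition, two models: existing-basket decisions from
  EXNEX over the `K0` existing; new-basket decisions from EXNEX over all
  `K`.  The all-`K` fit's existing-basket posteriors are retained in the
  decision's diagnostics for transparency but never feed decisions.

UNPL and PL1(a) share the analysis model, so at a common seed they produce
identical exceedance probabilities and differ only through cut-offs;
IND and PL2(a) likewise share the existing-basket model.  These identities
are asserted as tests.

## Cut-off calibration

Classical calibration simulates the global null (`p_k = q0` everywhere),
computes `Q = P(p_k > q0 | data)` per dataset, and sets `Delta` to the
empirical `(1 - alpha)` quantile of the null `Q` values.

The robust procedure generalises to `M` weighted scenarios: for each
scenario `R` datasets are simulated and fitted; every truly-null basket
(`p_mk == q0`, exact comparison) contributes `omega_m` copies of its `Q` to
a pooled store.  Stores are pooled across baskets sharing a sample size
within the same calibration model, and each sample-size class takes the
`(1 - alpha)` quantile of its pooled store — guaranteeing equal-sized
baskets identical cut-offs and controlling the error rate *on average*
across scenarios.  Scenarios with no null basket are legal inputs and are
skipped with a log note.  Weights must be positive integers because they
are literally replication counts of stored values.

Numerical conventions, chosen where the procedure is genuinely open:

- the quantile is the order statistic at rank `ceil((1 - alpha) N)`, no
  interpolation — reproducible, and with the strict rejection rule at most
  `alpha * N` stored values would reject;
- equal-`n` stores are concatenated before taking the quantile rather than
  averaging per-basket quantiles, which uses the information symmetrically
  and enforces the equal-cut-off requirement exactly;
- integer weights are implemented as value replication, not extra
  simulation: listing a scenario `w` times with a shared seed key is
  bit-identical to weighting it by `w` (tested);
- one master seed spawns a recorded substream per (scenario key,
  replicate), so any single simulated dataset can be regenerated, and
  model-fit seeds are derived per (scenario, model) from disjoint tags.

Replaying the calibration scenarios against the calibrated cut-offs
recovers the nominal level on weighted average (tested within 3 Monte
Carlo standard errors).

## Simulation studies

The fixed-scenario study simulates each scenario once and analyses every
dataset under all requested approaches (common random numbers), fitting
each distinct model once per scenario and sharing it.  Reported metrics:
per-basket rejection percentage (type I error at null baskets, power at
target-rate baskets), family-wise error among null baskets, the proportion
of datasets with all `K` decisions correct, and estimation summaries.

The random-scenario study fixes existing-basket rates, draws the new
basket's true rate uniformly from an interval (one dataset per draw), and
tabulates basket-level decision disagreements between approach pairs.
Truth is "reject iff `p_k > q0`", so rates inside `(q0, q1)` count
rejection as correct — the only labelling consistent with the hypotheses —
and in any disagreement exactly one side is correct; a both-wrong exclusion
is implemented as a safeguard but is a no-op under this labelling.
Decisions near a cut-off can flip on per-fit Monte Carlo noise, which
dilutes the observed asymmetry between approaches; discrepancy studies
therefore use substantially longer chains (tests use 48,000 kept draws per
fit at 2,000 draws) than rejection-rate studies, where such flips average
out.

## Problem sizes and reproduction scale

The packaged studies run at 1,500–2,000 replicates per scenario (the
original design used 10,000); at 2,000 replicates the Monte Carlo standard
error of a rejection proportion near 10% is about 0.7 percentage points,
and calibrated cut-offs are stable to roughly ±0.01.  These sizes are the
package's default desk-scale protocol and are what `scripts/acceptance.py`
and the test suite use.

## Known limitations

- The simulated data are exactly binomial with independent baskets: no
  overdispersion, no drift over accrual, no interim looks, and no
  patient-level covariates.  Passing tests demonstrate calibration and
  error control *under the model*, not robustness to real-data violations.
- A new basket's decision depends on its response count through a discrete
  set of posterior values; when a calibrated cut-off falls essentially on
  one of those atoms (for the default design, the independent model's
  exceedance at 5/14 responders is 0.9005, next to published cut-offs
  0.890/0.900), rejection rates at that basket are knife-edge quantities:
  arbitrarily small analysis-stage Monte Carlo differences move them by the
  full probability mass of the atom (8.6 points at the null rate).
  Cut-offs calibrated and applied within one pipeline are self-consistent;
  mixing externally calibrated cut-offs with a differently-precise
  analysis is not, and such cells should be interpreted accordingly.
- Only the basket-wise type I error metric ships for calibration; the
  condition/quantity hooks generalise to other metrics (FWER, power) but
  those paths are untested.
- Multi-arm extensions, continuous endpoints and futility stopping are out
  of scope.
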