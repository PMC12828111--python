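# Methods

## The design in one paragraph

`dosesched` finds the subgroup-specific optimal dose–schedule combination of
an immunotherapeutic agent by jointly modelling a continuous immune response,
binary dose-limiting toxicity (DLT) and ordinal tumour response across a
`J × K` dose–schedule grid and two biomarker subgroups. Combinations are
ranked by an elicited risk–benefit utility and explored adaptively: a fast,
toxicity-only escalation stage followed by model-based adaptive randomization
restricted to combinations with acceptable posterior safety and efficacy.

## Outcome models

For a patient in subgroup `M ∈ {0, 1}` treated at combination `(j, k)`:

* `Z ~ N(μ_Z((j,k),M), σ_Z²)` with plateau mean
  `μ_Z = α_k e^{δM} (1 − e^{−ν d_j})`. The mean is zero at dose zero, rises
  and saturates at `α_k e^{δM}`; `δ > 0` encodes that marker-positive patients
  reach higher maxima, `ν > 0` a common dose rate.
* `X ~ Bernoulli(p_(j,k))`, `logit p = β_{0,k} + β_1 d_j`. One intercept per
  schedule and an unconstrained common slope accommodate both complete and
  partial toxicity orderings across schedules; toxicity is shared across
  subgroups.
* `Y ∈ {0, 1, 2}` (PD / SD / CR-PR) with `logit q_2 = ζ_{(j,k),M}` and
  `logit(q_1 + q_2) = λ + ζ_{(j,k),M}`, `λ > 0` a proportional-odds-style
  shift shared across the grid.

The `ζ` array carries the cross-grid structure instead of a rigid parametric
dose–efficacy curve: `ζ_{(j,k),0}` is centred on `ζ_{(j−1,k),0}` plus
`γ · Δμ̃_Z` (the standardized marker-negative immune-response increment), with
innovation variance `σ_{E,0}²`; the lowest dose is anchored by
`ζ_{(1,k),0} ~ N(ζ_{(0,k),0}, τ²)`. Marker-positive logits borrow strength via
`ζ_{(j,k),1} ~ N(ζ_{(j,k),0}, σ_{E,1}²)` truncated to
`ζ_{(j,k),1} > ζ_{(j,k),0}`, which forces better marker-positive efficacy cell
by cell. The truncated term is applied at every dose level `j = 1..J`
(the joint-posterior formulation; the anchored lowest dose needs it too, and
dropping it at `j = 1` would leave `ζ_{(1,k),1}` without its ordering
constraint). Toxicity and efficacy are modelled independently given the
parameters; estimating their residual dependence is hopeless at phase I/II
sample sizes and ignoring it is known to cost little.

Dose enters every regression on one common scale: raw doses are standardized
to population SD 0.5 once and used in both likelihood and priors. Immune
response means entering the efficacy drift are divided by `M_μ / 2` (half the
elicited maximum possible mean immune response, default `M_μ = 30`). Using a
single scale everywhere avoids silent prior/likelihood mismatches.

### Variants

* `dose_adjusted` adds `γ_2 (d_j − d_{j−1})` to the drift, for settings where
  efficacy is not fully mediated by immune response.
* `alternative1` (comparator) drops the immune-response likelihood entirely
  and drives the drift by dose increments — the immune-response-blind design.
* `alternative2` (comparator) replaces the dynamic efficacy model with a
  parametric cumulative-logit model
  `logit Pr(Y ≤ l) = γ_{0,l,k,M} + γ_1 μ̃_Z + γ_2 μ̃_Z²` at both cut-points
  `l ∈ {0, 1}` with shared slopes, per-(k, M) ordered intercepts and the
  subgroup order constraint `γ_{0,l,k,0} > γ_{0,l,k,1}`. A literal reading
  with a single cut-point cannot produce three categories; two cut-points
  with a shared slope is the committed resolution. Intercepts get `N(0, 5²)`
  priors (vague on the logit scale), slopes half-free Cauchy(0, 2.5) after
  the same `μ̃_Z` standardization.

## Priors (defaults, and why)

| parameter | prior | rationale |
|---|---|---|
| `α_k` | Gamma(mean `α̂_k`=20, SD 3×mean) = Gamma(1/9, 1/180) | elicited maximum immune response, 3× inflation for vagueness |
| `δ` | Gamma(mean log r̂, SD 3×mean), r̂=1.5 | elicited marker-positive/negative ratio |
| `σ_Z²` | Inv-Gamma(0.1, 0.1) | data-dominated |
| `ν` | N(0, 2.3²) truncated > 0 | on the SD-0.5 dose scale a 2-SD dose move then rarely shifts `ν d` by more than 4.6 = logit span from 1% to 99% saturation |
| `β_{0,k}` | N(−4, 1) | no-dose toxicity centred at 0.018, 97.5% limit 0.12 |
| `β_1` | Cauchy(0, 2.5) | weakly informative logistic-regression default on the standardized dose |
| `γ` | Cauchy(0, 2.5), positive half | same logic after standardizing `μ_Z` by `M_μ/2` |
| `λ` | Uniform(0, 8) | spans response-rate ceilings up to 0.99 above any CR/PR rate ≥ 3% |
| `ζ` anchors | `ζ_{(0,k),0} = −2.2`, `τ² = 1` | prior CR/PR ≈ 0.10 at the lowest dose, 2 SD covering 0.01–0.45 |
| `σ_{E,0}² = σ_{E,1}²` | 0.3 | innovation scale, calibrated by simulation |

Gamma distributions use the shape/rate convention; `(1/9, 1/180)` must give
mean 20 and SD 60. `PriorSpec.diffuse()` reproduces the widened sensitivity
setting (5× inflation, IG(0.01, 0.01), `ν`-scale 4.6, Cauchy scale 5,
`λ ~ U(0, 16)`, `β_0 ~ N(−4, 2)`).

## Posterior computation

Metropolis-within-Gibbs, implemented as a numba kernel over per-cell
sufficient statistics so a likelihood evaluation costs `O(JK)` regardless of
the number of patients. Blocks:

* `σ_Z²`: exact conjugate inverse-gamma update;
* `α_k, δ, ν, γ`: scalar random-walk proposals on the log scale (positivity
  built in, Jacobian included);
* `β_{0,k}, β_1, γ_2`, each `ζ_{(j,k),M}` scalar, `λ` and the alternative-2
  parameters: Gaussian random walks with rejection at constraint boundaries
  (`ζ_1 > ζ_0`, `0 < λ < 8`, intercept orderings);
* prior independence proposals for the heavy-tailed globals, and one
  full-state proposal per iteration drawn from the generative prior whose MH
  ratio reduces to the likelihood ratio. The last move is what makes the
  sampler robust: the joint prior of (`α, ν, γ`, `ζ`) has a funnel geometry
  (large `α γ` demands large `ζ` increments) that traps single-site random
  walks when data are sparse; the generative proposal jumps across it, and in
  prior-only mode yields exact i.i.d. prior draws (used by the prior
  calibration tests).

Step sizes adapt every 50 iterations toward ~35% acceptance during burn-in
only and are frozen afterwards, preserving detailed balance for the retained
draws. Defaults: 1000 burn-in, 2000 kept, thin 1; the simulator's in-trial
refits use 500/1000 (posteriors at n ≤ 120 are prior-dominated and short
chains are accurate enough — verified by the recovery and operating-
characteristic tests). Chains are initialized at elicited prior means
(`α = α̂`, `δ = log r̂`, `β_0 = −4`, `ζ = ζ_0` with +0.1 subgroup offset);
heavy-tailed prior *medians* are pathological starting points for `α`
(median ≈ 0.5 against elicited mean 20), so means are used instead.
Everything is deterministic given the seed. Tail probabilities
(`Pr(p < φ_T | D)`, `Pr(π > φ_E | D)`) are empirical draw fractions, not
smoothed. Diagnostics (split-chain R-hat, ESS via arviz, acceptance-rate
warnings) are available via `mcmc_diagnostics`.

## Decision rules

* **Utility**: `U = q_2 + w_1 q_1 − w_2 p − w_3·1{p > φ_T}` with defaults
  `w_1 = 0.5` (two SDs equal one CR/PR), `w_2 = 0.3`, `w_3 = 1.2`,
  `φ_T = 0.3`. The over-toxicity penalty is a *fixed* `w_3` drop by default:
  that is the convention the built-in truth tables are algebraically
  consistent with (a proportional `w_3·p` form, also implemented behind
  `penalty_convention="proportional"`, cannot reproduce them — penalty-active
  cells back-solve to negative CR/PR probabilities). Estimated utilities plug
  in posterior means, with the penalty indicator evaluated at the posterior
  mean `p̂`.
* **Stage I** escalates independently in each schedule in round-robin order,
  one cohort per step, starting from the lowest dose, closing a schedule when
  its highest tried dose fails the Beta(0.1, 0.2)-Binomial screen
  `Pr(p < φ_T | D) > C_I` (default `C_I = 0.05`) or the top dose was treated.
  Stage-I patients count toward `N`.
* **Stage II** refits the posterior once per cohort, forms the admissible set
  per subgroup (`Pr(p < φ_T) > C_T` and `Pr(π > φ_E) > C_E`, strict, defaults
  `C_T = C_E = 0.2`), and randomizes each incoming patient within their
  subgroup with probability proportional to `max(U, ε)` over the admissible
  set (`ε = 0.01`): the floor keeps the vector well defined when estimated
  utilities go negative while nearly excluding undesirable combos. Any combo
  on the grid may be admissible, including ones untried in stage I — the
  model shares strength across the grid. A subgroup with an empty admissible
  set is closed permanently (its patients treated off protocol); the trial
  terminates early when both subgroups close. At `N` the admissible combo
  with the largest posterior-mean utility is selected per subgroup, ties
  broken toward the lowest dose then lowest schedule for reproducibility.

## The simulator and its truth scenarios

Truth scenarios specify, per cell, the mean immune response, DLT probability
and efficacy category probabilities, plus a Gumbel copula parameter
(`θ = 1.5`) coupling toxicity and efficacy. `(X, Y)` pairs are drawn from the
*exact* 2×3 joint table obtained by rectangle inclusion–exclusion of the
copula CDF — equivalent in distribution to transforming a continuous pair but
exactly testable (margins reproduce to 1e-12). Toxicity sits in the upper
tail of the `u` margin, so `θ > 1` associates toxicity with better efficacy,
as expected for immune activation. `Z` is normal around the cell mean with
generation SD `σ_Z,true = 2.0` by default — the truth tables do not pin this
value down; 2.0 makes `Z` informative but noisy on the tables' 1–27 scale,
and it is configurable (larger values make the immune-response channel less
informative and the problem harder).

The eight built-in scenario tables print `(μ_Z, p, π, U)` per cell; the
individual `(q_0, q_1, q_2)` are recovered by inverting the utility. Printed
utilities carry one or two decimals, so the inversion accepts (and clamps)
solutions within the propagated rounding slack; two cells are irreconcilable
with any exact `q_2` at their printed values and clamp to a boundary
(re-evaluating within their printed precision). The published per-subgroup
optima are reproduced exactly when near-ties within one printed ulp (0.01)
are treated as ties — one scenario prints a 0.38/0.39 pair as a joint
optimum. The subgroup-dominance premise (marker-positive `q_2` and `π` at
least as high cell by cell) holds in the printed `π` up to printed precision
but is violated by up to 0.05 in the *reconstructed* `q_2` of a few clearly
inadmissible, penalty-active cells; the validator reports these as warnings
rather than failures since they are features of the published numbers, not
inversion artefacts.

Patient accrual draws each patient's subgroup i.i.d. Bernoulli(prevalence
0.5); cohorts (size 3) are formed by arrival and each patient uses their own
subgroup's current randomization vector. This avoids indefinite waiting for
subgroup-pure cohorts and matches the stated prevalence. Replicate seeds are
split from a master seed by counter (`numpy` `SeedSequence`), so operating
characteristics are reproducible and independent of execution order.

## What the tests show — and what they do not

The simulator draws outcomes from the same distributional families the design
assumes (normal immune response, copula-linked binary/ordinal outcomes), so
passing tests demonstrate correct inference and good operating characteristics
*under the stated truth scenarios*, including ones far from the model (the
truth tables are not generated from the plateau/dynamic models). They do not
demonstrate robustness to real-data features such as delayed outcomes,
accrual drift, missing immune-response measurements, or misclassified
biomarkers — all out of scope here.

Desk-scale sizes are used throughout: operating characteristics use 50–200
replicates with 500/1000-iteration chains (selection percentages then carry
Monte-Carlo SEs of ~3–7 points; the replicate count behind the published
tables is not stated, so tolerances are set by our own binomial error).
Publication-scale runs (~1000 replicates) use the identical code path and are
a multi-hour single-CPU job.

## Numerical choices and edge cases

* Truncations are enforced by proposal rejection; the `ζ_1 | ζ_0` truncated
  normal's normalizing constant is exactly ½ (truncation point at the mean)
  and therefore drops out of all ratios.
* Utility near-ties in `true_optimal` use an explicit tolerance (default
  1e-9; one printed ulp for table comparisons).
* `randomization_probabilities` floors utilities at ε before normalizing;
  an empty admissible set raises and is handled by subgroup closure.
* Degenerate inputs (constant dose grids, zero-length chains, invalid
  margins, inconsistent utilities, unordered intercepts) raise explicit
  errors naming the offending quantity.
* All dose–schedule indices are 0-based in code; file formats (scenario CSV,
  patient-records CSV) use 1-based indices with required headers.

## Known limitations

* Single binary biomarker with known subgroup membership; no delayed
  outcomes; no within-patient re-dosing; fixed maximum sample size.
* The stage-II refit cadence (once per cohort) and the per-patient subgroup
  draw are committed interpretations of "the next cohort in subgroup M";
  other cohort-formation rules would change operating characteristics
  slightly.
* The Gumbel copula couples toxicity with *better* efficacy; scenarios
  needing the opposite association would need `θ = 1` (independence) or a
  different copula orientation.
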