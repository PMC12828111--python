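# dosesched

Bayesian biomarker-based phase I/II **dose–schedule optimization** for
immunotherapy trials, with a full trial simulator.

Early-phase immunotherapy trials increasingly need to pick not just a dose but
a *dose–schedule combination*, and the best combination can differ between
biomarker-defined subgroups (e.g. PD-L1–positive vs. –negative patients).
`dosesched` implements an adaptive design that jointly models three endpoints
for each combination `(j, k)` of dose `d_j` and schedule `s_k` and each
subgroup `M ∈ {0, 1}`:

* **immune response** `Z` (change in log immune activity):
  `Z ~ N(μ_Z((j,k),M), σ_Z²)` with the plateau mean
  `μ_Z = α_k · e^{δM} · (1 − e^{−ν d_j})`;
* **toxicity** `X` (DLT indicator, shared across subgroups):
  `logit p_(j,k) = β_{0,k} + β_1 d_j`;
* **ordinal efficacy** `Y ∈ {PD, SD, CR/PR}`:
  `logit q_2 = ζ_{(j,k),M}` and `logit(q_1+q_2) = λ + ζ_{(j,k),M}`, with a
  dynamic (random-walk-with-drift) prior that centres each `ζ` on the next
  lower dose plus `γ` times the immune-response increment, and a truncated
  normal that keeps the marker-positive response probability above the
  marker-negative one.

Each combination is scored by the elicited risk–benefit utility

```
U((j,k),M) = q_2 + w_1 q_1 − w_2 p − w_3 · 1{p > φ_T}
```

The trial runs in two stages: schedule-wise dose escalation under a
Beta-Binomial safety screen (stage I), then cohort-by-cohort Metropolis-within-
Gibbs posterior refits with adaptive randomization proportional to the
posterior-mean utility over the admissible set
`{(j,k): Pr(p < φ_T | D) > C_T and Pr(π > φ_E | D) > C_E}` (stage II),
finishing with a per-subgroup recommendation. The simulator generates
correlated toxicity/efficacy outcomes from a Gumbel copula and ships eight
built-in truth scenarios plus comparator designs (immune-response-blind and
parametric proportional-odds efficacy variants).

## Worked example

```python
import dosesched as ds
from dosesched.config import default_config
from dosesched.scenarios import load_builtin_scenario, true_optimal
from dosesched.simulate import run_trial

cfg = default_config(mcmc=ds.McmcConfig(n_burn=500, n_keep=1000))
s = load_builtin_scenario(1)          # truth: optimum (d2, s2) in both subgroups
print(true_optimal(s))                # {0: {(1, 1)}, 1: {(1, 1)}}  (0-based)

res = run_trial(s, cfg, seed=11)
print(res.total_enrolled, res.early_terminated)   # 120 False
print(res.selected)                   # {0: (1, 1), 1: (0, 1)}
```

The trial enrolled all 120 patients and recommended `(d2, s2)` — the true
optimum — for the marker-negative subgroup, and `(d1, s2)` for the
marker-positive subgroup in this particular replicate (adaptive trials are
noisy at a single-replicate level; aggregate behaviour is what matters).
Replicated operating characteristics:

```python
from dosesched.simulate import operating_characteristics
oc = operating_characteristics(s, cfg, n_reps=50, seed=123)
print(oc.selection_pct[1, 1, 1])      # 64.0  -> % of trials selecting (d2,s2) for M=1
print(oc.mean_treated[1, 1, 1])       # 10.66 -> mean patients treated there
```

i.e. the design selects the true optimal combination for marker-positive
patients in about 64% of replicate trials and concentrates roughly 11 of the
120 patients on it.

The same functionality is available from the shell:

```bash
dosesched validate-scenarios
dosesched simulate-trial --scenario 1 --seed 11 --out-dir out/
dosesched oc --scenario 1 --n-reps 100 --seed 0 --out-dir out/
dosesched fit records.csv --seed 1          # posterior on observed records
```

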