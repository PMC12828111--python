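"""Trial simulation: copula outcome generation, whole-trial execution and
operating characteristics.

Toxicity and efficacy are generated jointly from a Gumbel copula

    C(u, v) = exp(-[(-ln u)^theta + (-ln v)^theta]^(1/theta)),  theta >= 1,

with toxicity in the upper tail of the u margin and the ordinal efficacy
categories cut on the v margin, so that theta > 1 induces positive
association between toxicity and better efficacy while both margins are
reproduced exactly.  The immune response is drawn from the normal model
around the scenario's true cell mean.

A simulated trial follows the two-stage design: schedule-wise stage-I
escalation under the Beta-Binomial safety screen, then cohort-by-cohort
posterior refits with utility-proportional adaptive randomization within each
biomarker subgroup, and a final per-subgroup selection at the maximum sample
size (or early termination when no combo is admissible for either subgroup).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import DesignConfig
from .decisions import (
    admissible_set,
    estimated_utilities,
    randomization_probabilities,
    select_final,
    stage1_step,
)
from .inference import (
    McmcConfig,
    StageOneState,
    TrialData,
    gibbs_sample,
    posterior_summaries,
)
from .models import PatientOutcome
from .scenarios import ScenarioTruth

__all__ = [
    "gumbel_copula_cdf",
    "discrete_joint_outcomes",
    "JointOutcomeTable",
    "generate_patient",
    "TrialResult",
    "run_trial",
    "OperatingCharacteristics",
    "operating_characteristics",
]


def gumbel_copula_cdf(u: float, v: float, theta: float) -> float:
    """Gumbel copula CDF; theta = 1 is the independence copula."""
    if theta < 1.0:
        raise ValueError("Gumbel copula requires theta >= 1")
    if not (0.0 <= u <= 1.0 and 0.0 <= v <= 1.0):
        raise ValueError("u and v must lie in [0, 1]")
    if u == 0.0 or v == 0.0:
        return 0.0
    if u == 1.0:
        return v
    if v == 1.0:
        return u
    a = (-math.log(u)) ** theta + (-math.log(v)) ** theta
    return math.exp(-(a ** (1.0 / theta)))


@dataclass
class JointOutcomeTable:
    """Exact joint distribution of (X, Y) for one cell: 2x3 probabilities."""

    probs: np.ndarray  # (2, 3): rows X=0/1, cols Y=0/1/2
    p: float
    q: tuple[float, float, float]
    theta: float

    def flat(self) -> np.ndarray:
        return self.probs.reshape(-1)


def discrete_joint_outcomes(
    p: float, q: Sequence[float], theta: float
) -> JointOutcomeTable:
    """Exact cell probabilities Pr(X=x, Y=y) by rectangle inclusion-exclusion
    of the copula CDF.

    The no-toxicity region is ``u <= 1-p`` and efficacy categories are cut at
    ``q0`` and ``q0+q1`` on the v margin, so Pr(X=0, Y<=l) = C(1-p, b_l).
    Margins are reproduced exactly for every theta >= 1.
    """
    q0, q1, q2 = (float(x) for x in q)
    if min(q0, q1, q2) < -1e-12 or abs(q0 + q1 + q2 - 1.0) > 1e-9:
        raise ValueError("q must be a probability simplex over 3 categories")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be a probability")
    b = (0.0, q0, q0 + q1, 1.0)
    tab = np.empty((2, 3))
    for l in range(3):
        x0 = gumbel_copula_cdf(1.0 - p, b[l + 1], theta) - gumbel_copula_cdf(
            1.0 - p, b[l], theta
        )
        x0 = max(x0, 0.0)
        tab[0, l] = x0
        tab[1, l] = max(b[l + 1] - b[l] - x0, 0.0)
    return JointOutcomeTable(tab, p, (q0, q1, q2), theta)


def generate_patient(
    s: ScenarioTruth, j: int, k: int, m: int, rng: np.random.Generator
) -> PatientOutcome:
    """Draw one patient's (Z, X, Y) at combo (j, k) in subgroup m."""
    z = rng.normal(s.mu_z_true[j, k, m], s.sigma_z_true)
    tab = discrete_joint_outcomes(
        float(s.p_tox_true[j, k]), s.q_true[j, k, m], s.copula_theta
    )
    idx = rng.choice(6, p=tab.flat() / tab.flat().sum())
    x, y = divmod(int(idx), 3)
    return PatientOutcome(j, k, m, float(z), x, y)


@dataclass
class TrialResult:
    selected: dict[int, tuple[int, int] | None]
    n_by_combo: np.ndarray  # (J, K, 2) patients treated
    total_enrolled: int
    early_terminated: bool
    seed: int
    trace: list[dict] = field(default_factory=list)

    def write_trace(self, path: str | Path) -> None:
        def _coerce(o):
            if hasattr(o, "item"):  # numpy scalars
                return o.item()
            raise TypeError(f"not JSON serializable: {type(o)}")

        with open(path, "w") as fh:
            for rec in self.trace:
                fh.write(json.dumps(rec, default=_coerce) + "\n")


def _mcmc_for(cfg: DesignConfig, seed: int) -> McmcConfig:
    m = cfg.mcmc
    return McmcConfig(m.n_burn, m.n_keep, m.thin, m.adapt_window, seed)


def run_trial(s: ScenarioTruth, cfg: DesignConfig, seed: int) -> TrialResult:
    """Simulate one complete trial under the configured design.

    Fully reproducible given ``seed``: the patient-level randomness and every
    per-cohort MCMC seed derive from it through a counter-based splitting of
    ``numpy.random.SeedSequence``.
    """
    J, K = cfg.grid.n_doses, cfg.grid.n_schedules
    if s.n_doses != J or s.n_schedules != K:
        raise ValueError("scenario grid does not match design grid")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    mcmc_counter = 0

    data = TrialData()
    counts = np.zeros((J, K, 2))
    trace: list[dict] = []

    def enroll(j: int, k: int, n: int) -> list[PatientOutcome]:
        """Enroll n patients at one combo; subgroup draws are i.i.d.
        Bernoulli(prevalence)."""
        out = []
        for _ in range(n):
            m = int(rng.random() < cfg.prevalence)
            o = generate_patient(s, j, k, m, rng)
            data.append(o)
            counts[j, k, m] += 1
            out.append(o)
        return out

    # ---------------- stage I: schedule-wise escalation -----------------
    stage1 = StageOneState.fresh(J, K)
    open_groups = {0: True, 1: True}
    while not stage1.all_closed and len(data) + cfg.cohort_size <= cfg.N:
        dec = stage1_step(stage1, cfg)
        if dec.complete:
            break
        j, k = dec.assignment
        cohort = enroll(j, k, cfg.cohort_size)
        stage1.record(j, k, len(cohort), sum(o.x for o in cohort))
        trace.append(
            {"stage": 1, "cohort_at": [j, k], "n": len(cohort),
             "tox": int(sum(o.x for o in cohort))}
        )

    # ---------------- stage II: adaptive randomization -------------------
    early = False
    sums = None
    while len(data) + 1 <= cfg.N:
        fit_seed = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(1, mcmc_counter))
            .generate_state(1)[0] % (2**31)
        )
        mcmc_counter += 1
        post = gibbs_sample(
            data, cfg.grid, cfg.hyper, cfg.prior, _mcmc_for(cfg, fit_seed), cfg.variant
        )
        sums = posterior_summaries(post, cfg.grid, cfg.phi_T, cfg.phi_E)
        adm = admissible_set(sums, cfg)
        for m in range(2):
            if open_groups[m] and not adm[m]:
                open_groups[m] = False  # no dose acceptable for this subgroup
        if not any(open_groups.values()):
            early = True
            trace.append({"stage": 2, "event": "early_termination", "n": len(data)})
            break
        utils = estimated_utilities(sums, cfg.weights)
        psi = {
            m: randomization_probabilities(
                {c: utils[c[0], c[1], m] for c in adm[m]},
                sorted(adm[m]),
                cfg.randomization_floor,
            )
            for m in range(2)
            if open_groups[m]
        }
        cohort_assignments = []
        n_slots = min(cfg.cohort_size, cfg.N - len(data))
        for _ in range(n_slots):
            m = int(rng.random() < cfg.prevalence)
            if not open_groups[m]:
                continue  # treated off protocol; not enrolled
            combos = sorted(psi[m].keys())
            probs = np.array([psi[m][c] for c in combos])
            j, k = combos[rng.choice(len(combos), p=probs / probs.sum())]
            o = generate_patient(s, j, k, m, rng)
            data.append(o)
            counts[j, k, m] += 1
            cohort_assignments.append([m, j, k])
        trace.append(
            {
                "stage": 2,
                "n": len(data),
                "admissible": {m: sorted(adm[m]) for m in range(2)},
                "psi": {m: {f"{c[0]},{c[1]}": round(v, 4) for c, v in psi[m].items()} for m in psi},
                "assignments": cohort_assignments,
            }
        )

    # ---------------- final selection ------------------------------------
    selected: dict[int, tuple[int, int] | None] = {0: None, 1: None}
    if not early and len(data) > 0 and any(open_groups.values()):
        fit_seed = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(2, 0))
            .generate_state(1)[0] % (2**31)
        )
        post = gibbs_sample(
            data, cfg.grid, cfg.hyper, cfg.prior, _mcmc_for(cfg, fit_seed), cfg.variant
        )
        sums = posterior_summaries(post, cfg.grid, cfg.phi_T, cfg.phi_E)
        for m in range(2):
            if open_groups[m]:
                selected[m] = select_final(sums, cfg, m)
    trace.append(
        {"stage": "final", "selected": {m: selected[m] for m in range(2)},
         "n": len(data), "early": early}
    )
    return TrialResult(
        selected=selected,
        n_by_combo=counts,
        total_enrolled=len(data),
        early_terminated=early,
        seed=seed,
        trace=trace,
    )


@dataclass
class OperatingCharacteristics:
    """Aggregated design performance over replicate simulated trials."""

    selection_pct: np.ndarray  # (J, K, 2)
    mean_treated: np.ndarray  # (J, K, 2)
    pct_none: np.ndarray  # (2,)
    mean_sample_size: float
    pct_early_termination: float
    n_reps: int

    def to_frame(self, schedules: Sequence[str] | None = None) -> pd.DataFrame:
        J, K, _ = self.selection_pct.shape
        rows = []
        for j in range(J):
            for k in range(K):
                for m in range(2):
                    rows.append(
                        {
                            "dose_index": j + 1,
                            "schedule": schedules[k] if schedules else f"s{k + 1}",
                            "subgroup": m,
                            "selection_pct": self.selection_pct[j, k, m],
                            "mean_treated": self.mean_treated[j, k, m],
                        }
                    )
        return pd.DataFrame(rows)


def operating_characteristics(
    s: ScenarioTruth, cfg: DesignConfig, n_reps: int, seed: int
) -> OperatingCharacteristics:
    """Run ``n_reps`` independent replicate trials and aggregate selection
    percentages and mean patient allocation per combo and subgroup.

    Replicate seeds are split from ``seed`` by counter, so the result does not
    depend on execution order.
    """
    if n_reps < 1:
        raise ValueError("need n_reps >= 1")
    J, K = cfg.grid.n_doses, cfg.grid.n_schedules
    sel = np.zeros((J, K, 2))
    treated = np.zeros((J, K, 2))
    none = np.zeros(2)
    sizes = []
    early = 0
    for rep in range(n_reps):
        rep_seed = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(rep,))
            .generate_state(1)[0] % (2**31)
        )
        res = run_trial(s, cfg, rep_seed)
        for m in range(2):
            if res.selected[m] is None:
                none[m] += 1
            else:
                j, k = res.selected[m]
                sel[j, k, m] += 1
        treated += res.n_by_combo
        sizes.append(res.total_enrolled)
        early += int(res.early_terminated)
    return OperatingCharacteristics(
        selection_pct=100.0 * sel / n_reps,
        mean_treated=treated / n_reps,
        pct_none=100.0 * none / n_reps,
        mean_sample_size=float(np.mean(sizes)),
        pct_early_termination=100.0 * early / n_reps,
        n_reps=n_reps,
    )
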