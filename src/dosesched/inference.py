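"""Posterior sampling and summaries.

``gibbs_sample`` runs a Metropolis-within-Gibbs chain (numba kernel) over the
joint posterior of the immune-response, toxicity and efficacy models, and
stores both parameter draws and the derived per-combo outcome probabilities
that the decision engine consumes.  ``beta_binomial_safety_prob`` is the
stage-I conjugate safety posterior.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from . import _kernel
from .models import (
    DoseGrid,
    EfficacyParams,
    ImmuneParams,
    ModelHyper,
    ParameterState,
    PatientOutcome,
    PriorSpec,
    ToxicityParams,
)

__all__ = [
    "McmcConfig",
    "TrialData",
    "PosteriorSample",
    "PosteriorSummaries",
    "StageOneState",
    "gibbs_sample",
    "sample_prior",
    "posterior_summaries",
    "beta_binomial_safety_prob",
    "mcmc_diagnostics",
]

Variant = Literal["proposed", "dose_adjusted", "alternative1", "alternative2"]
_VARIANT_CODE = {"proposed": 0, "dose_adjusted": 1, "alternative1": 2, "alternative2": 3}


@dataclass(frozen=True)
class McmcConfig:
    n_burn: int = 1000
    n_keep: int = 2000
    thin: int = 1
    adapt_window: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_burn < 0 or self.n_keep <= 0 or self.thin < 1:
            raise ValueError("chain lengths must be positive (thin >= 1)")


@dataclass
class TrialData:
    """Accrued patient records in accrual order."""

    records: list[PatientOutcome] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def append(self, o: PatientOutcome) -> None:
        self.records.append(o)

    def extend(self, os: Iterable[PatientOutcome]) -> None:
        self.records.extend(os)

    def suffstats(self, J: int, K: int):
        """Per-cell sufficient statistics: Z count/sum/sum-of-squares and Y
        category counts per (j, k, M); toxicity count/events per (j, k)."""
        nz = np.zeros((J, K, 2))
        sz = np.zeros((J, K, 2))
        sz2 = np.zeros((J, K, 2))
        ycnt = np.zeros((J, K, 2, 3))
        nx = np.zeros((J, K))
        mx = np.zeros((J, K))
        for o in self.records:
            nz[o.j, o.k, o.m] += 1.0
            sz[o.j, o.k, o.m] += o.z
            sz2[o.j, o.k, o.m] += o.z * o.z
            ycnt[o.j, o.k, o.m, o.y] += 1.0
            nx[o.j, o.k] += 1.0
            mx[o.j, o.k] += o.x
        return nz, sz, sz2, ycnt, nx, mx

    # -- flat-file round trip (1-based indices, header required) ----------
    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialData":
        df = pd.read_csv(path)
        required = {"dose_index", "schedule_index", "subgroup", "z", "x", "y"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"patient-records CSV missing columns: {sorted(missing)}")
        recs = [
            PatientOutcome(
                int(r.dose_index) - 1,
                int(r.schedule_index) - 1,
                int(r.subgroup),
                float(r.z),
                int(r.x),
                int(r.y),
            )
            for r in df.itertuples()
        ]
        return cls(recs)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["dose_index", "schedule_index", "subgroup", "z", "x", "y"])
            for o in self.records:
                w.writerow([o.j + 1, o.k + 1, o.m, o.z, o.x, o.y])


@dataclass
class PosteriorSample:
    """Retained draws plus the derived per-combo outcome probabilities."""

    draws: dict[str, np.ndarray]
    p_draws: np.ndarray  # (n_keep, J, K)
    q1_draws: np.ndarray  # (n_keep, J, K, 2)
    q2_draws: np.ndarray  # (n_keep, J, K, 2)
    acceptance: dict[str, float]
    config: McmcConfig
    variant: Variant

    @property
    def n_draws(self) -> int:
        return self.p_draws.shape[0]

    def parameter_state(self, i: int) -> ParameterState:
        d = self.draws
        return ParameterState(
            immune=ImmuneParams(
                alpha=d["alpha"][i],
                delta=float(d["delta"][i]),
                nu=float(d["nu"][i]),
                sigma_z_sq=float(d["sigma_z_sq"][i]),
            ),
            tox=ToxicityParams(beta0=d["beta0"][i], beta1=float(d["beta1"][i])),
            eff=EfficacyParams(
                zeta=d["zeta"][i],
                gamma=float(d["gamma"][i]),
                lam=float(d["lam"][i]),
                gamma2=float(d["gamma2"][i]),
            ),
        )

    def scalar_frame(self) -> pd.DataFrame:
        """Flat table of draws: one column per scalar, one row per iteration."""
        d = self.draws
        cols: dict[str, np.ndarray] = {}
        K = d["alpha"].shape[1]
        for k in range(K):
            cols[f"alpha[{k + 1}]"] = d["alpha"][:, k]
        cols["delta"] = d["delta"]
        cols["nu"] = d["nu"]
        cols["sigma_z_sq"] = d["sigma_z_sq"]
        for k in range(K):
            cols[f"beta0[{k + 1}]"] = d["beta0"][:, k]
        cols["beta1"] = d["beta1"]
        if self.variant != "alternative2":
            cols["gamma"] = d["gamma"]
            cols["lambda"] = d["lam"]
            J = d["zeta"].shape[1]
            for j in range(J):
                for k in range(K):
                    for m in range(2):
                        cols[f"zeta[{j + 1},{k + 1},{m}]"] = d["zeta"][:, j, k, m]
            if self.variant == "dose_adjusted":
                cols["gamma2"] = d["gamma2"]
        else:
            for l in range(2):
                for k in range(K):
                    for m in range(2):
                        cols[f"g0[{l},{k + 1},{m}]"] = d["alt2_g0"][:, l, k, m]
            cols["g1"] = d["alt2_g1"]
            cols["g2"] = d["alt2_g2"]
        return pd.DataFrame(cols)

    def export_csv(self, path: str | Path) -> None:
        self.scalar_frame().to_csv(path, index=False)


@dataclass
class PosteriorSummaries:
    """Posterior means and tail probabilities per combo (and subgroup)."""

    q1_hat: np.ndarray  # (J, K, 2)
    q2_hat: np.ndarray  # (J, K, 2)
    p_hat: np.ndarray  # (J, K)
    prob_safe: np.ndarray  # (J, K): Pr(p < phi_T | data)
    prob_efficacious: np.ndarray  # (J, K, 2): Pr(pi > phi_E | data)


@dataclass
class StageOneState:
    """Stage-I bookkeeping: per-combo toxicity counts and per-schedule
    escalation status."""

    n_treated: np.ndarray  # (J, K) ints
    n_tox: np.ndarray  # (J, K) ints
    highest_tried: np.ndarray  # (K,) 0-based dose index, -1 if unvisited
    open_flags: np.ndarray  # (K,) bool
    cursor: int = 0

    @classmethod
    def fresh(cls, J: int, K: int) -> "StageOneState":
        return cls(
            n_treated=np.zeros((J, K), dtype=int),
            n_tox=np.zeros((J, K), dtype=int),
            highest_tried=np.full(K, -1, dtype=int),
            open_flags=np.ones(K, dtype=bool),
        )

    @property
    def n_doses(self) -> int:
        return self.n_treated.shape[0]

    @property
    def all_closed(self) -> bool:
        return not bool(self.open_flags.any())

    def record(self, j: int, k: int, n: int, m_tox: int) -> None:
        self.n_treated[j, k] += n
        self.n_tox[j, k] += m_tox
        if j > self.highest_tried[k]:
            self.highest_tried[k] = j


def _default_init(grid: DoseGrid, hyper: ModelHyper, prior: PriorSpec):
    J, K = grid.n_doses, grid.n_schedules
    zeta = np.empty((J, K, 2))
    for k in range(K):
        zeta[:, k, 0] = hyper.zeta0[k]
        zeta[:, k, 1] = hyper.zeta0[k] + 0.1
    g0 = np.empty((2, K, 2))
    g0[0, :, 0] = 0.5
    g0[0, :, 1] = 0.0
    g0[1, :, 0] = 2.5
    g0[1, :, 1] = 2.0
    return dict(
        alpha=np.asarray(prior.alpha_hat, dtype=float).copy(),
        delta=float(prior.delta_mean),
        nu=1.0,
        s2=1.0,
        beta0=np.full(K, prior.beta0_mean),
        beta1=0.5,
        gamma=1.0,
        gamma2=0.0,
        lam=min(2.0, 0.5 * prior.lam_upper),
        zeta=zeta,
        g0=g0,
        g1=-0.5,
        g2=0.0,
    )


def _run(
    grid: DoseGrid,
    hyper: ModelHyper,
    prior: PriorSpec,
    cfg: McmcConfig,
    variant: Variant,
    stats,
) -> PosteriorSample:
    nz, sz, sz2, ycnt, nx, mx = stats
    init = _default_init(grid, hyper, prior)
    out = _kernel.run_chain(
        np.asarray(grid.scaled_doses),
        nz, sz, sz2, ycnt, nx, mx,
        prior.alpha_shape, np.asarray(prior.alpha_rate, dtype=float),
        prior.delta_shape, prior.delta_rate,
        prior.ig_shape, prior.ig_rate, prior.nu_scale,
        prior.beta0_mean, prior.beta0_sd, prior.beta1_scale,
        prior.gamma_scale, prior.lam_upper,
        np.asarray(hyper.zeta0, dtype=float), hyper.tau_sq,
        hyper.sigma_e0_sq, hyper.sigma_e1_sq, prior.mu_scale,
        _VARIANT_CODE[variant], cfg.n_burn, cfg.n_keep, cfg.thin,
        int(cfg.seed) % (2**31),
        init["alpha"], init["delta"], init["nu"], init["s2"],
        init["beta0"], init["beta1"], init["gamma"], init["gamma2"],
        init["lam"], init["zeta"], init["g0"], init["g1"], init["g2"],
    )
    (
        alpha_d, delta_d, nu_d, s2_d, beta0_d, beta1_d, gamma_d, gamma2_d,
        lam_d, zeta_d, g0_d, g1_d, g2_d, p_d, q1_d, q2_d, acc, tries,
    ) = out
    K = grid.n_schedules
    J = grid.n_doses
    names = (
        [f"alpha[{k + 1}]" for k in range(K)]
        + ["delta", "nu"]
        + [f"beta0[{k + 1}]" for k in range(K)]
        + ["beta1", "gamma", "gamma2", "lambda"]
        + [
            f"zeta[{j + 1},{k + 1},{m}]"
            for j in range(J)
            for k in range(K)
            for m in range(2)
        ]
        + [
            f"g0[{l},{k + 1},{m}]"
            for l in range(2)
            for k in range(K)
            for m in range(2)
        ]
        + ["g1", "g2"]
    )
    acceptance = {
        n: float(a / t) for n, a, t in zip(names, acc, tries) if t > 0
    }
    draws = {
        "alpha": alpha_d,
        "delta": delta_d,
        "nu": nu_d,
        "sigma_z_sq": s2_d,
        "beta0": beta0_d,
        "beta1": beta1_d,
        "gamma": gamma_d,
        "gamma2": gamma2_d,
        "lam": lam_d,
        "zeta": zeta_d,
        "alt2_g0": g0_d,
        "alt2_g1": g1_d,
        "alt2_g2": g2_d,
    }
    return PosteriorSample(draws, p_d, q1_d, q2_d, acceptance, cfg, variant)


def gibbs_sample(
    data: TrialData,
    grid: DoseGrid,
    hyper: ModelHyper,
    prior: PriorSpec,
    cfg: McmcConfig,
    variant: Variant = "proposed",
) -> PosteriorSample:
    """Sample the joint posterior given the accrued trial data.

    Deterministic given ``cfg.seed``.  The ``alternative1`` variant drops the
    immune-response likelihood term entirely; ``alternative2`` swaps the
    dynamic efficacy model for a parametric proportional-odds model.
    """
    if len(data) == 0:
        raise ValueError("no patient data; use sample_prior for prior-only draws")
    if variant not in _VARIANT_CODE:
        raise ValueError(f"unknown variant {variant!r}")
    stats = data.suffstats(grid.n_doses, grid.n_schedules)
    if variant == "alternative1":
        nz, sz, sz2, ycnt, nx, mx = stats
        stats = (np.zeros_like(nz), np.zeros_like(sz), np.zeros_like(sz2), ycnt, nx, mx)
    return _run(grid, hyper, prior, cfg, variant, stats)


def sample_prior(
    grid: DoseGrid,
    hyper: ModelHyper,
    prior: PriorSpec,
    cfg: McmcConfig,
    variant: Variant = "proposed",
) -> PosteriorSample:
    """Prior-only sampling (empty-likelihood mode), for prior checks."""
    J, K = grid.n_doses, grid.n_schedules
    stats = (
        np.zeros((J, K, 2)),
        np.zeros((J, K, 2)),
        np.zeros((J, K, 2)),
        np.zeros((J, K, 2, 3)),
        np.zeros((J, K)),
        np.zeros((J, K)),
    )
    return _run(grid, hyper, prior, cfg, variant, stats)


def posterior_summaries(
    s: PosteriorSample, grid: DoseGrid, phi_T: float, phi_E: float
) -> PosteriorSummaries:
    """Monte-Carlo means and empirical tail fractions over the stored draws."""
    if s.n_draws == 0:
        raise ValueError("empty posterior sample")
    pi_draws = s.q1_draws + s.q2_draws
    return PosteriorSummaries(
        q1_hat=s.q1_draws.mean(axis=0),
        q2_hat=s.q2_draws.mean(axis=0),
        p_hat=s.p_draws.mean(axis=0),
        prob_safe=(s.p_draws < phi_T).mean(axis=0),
        prob_efficacious=(pi_draws > phi_E).mean(axis=0),
    )


def beta_binomial_safety_prob(
    m_tox: int, n_treated: int, phi_T: float, kappa1: float = 0.1, kappa2: float = 0.2
) -> float:
    """Pr(p < phi_T) under the conjugate Beta(kappa1+m, kappa2+n-m) posterior."""
    if not (0 <= m_tox <= n_treated):
        raise ValueError("need 0 <= m_tox <= n_treated")
    return float(beta_dist.cdf(phi_T, kappa1 + m_tox, kappa2 + n_treated - m_tox))


@dataclass
class DiagnosticsReport:
    ess: dict[str, float]
    rhat: dict[str, float]
    acceptance: dict[str, float]
    warnings: list[str]


def mcmc_diagnostics(s: PosteriorSample) -> DiagnosticsReport:
    """Effective sample size and split-chain R-hat per scalar, plus
    acceptance-rate warnings (outside [0.1, 0.6])."""
    import arviz as az

    if s.n_draws == 0:
        raise ValueError("empty posterior sample")
    frame = s.scalar_frame()
    half = len(frame) // 2
    ess: dict[str, float] = {}
    rhat: dict[str, float] = {}
    warnings: list[str] = []
    for name, col in frame.items():
        x = col.to_numpy()
        if np.var(x) == 0.0:
            warnings.append(f"{name}: zero-variance chain")
            ess[name] = float("nan")
            rhat[name] = float("nan")
            continue
        split = x[: 2 * half].reshape(2, half)
        ess[name] = float(az.ess(split))
        rhat[name] = float(az.rhat(split))
    for name, rate in s.acceptance.items():
        if not (0.1 <= rate <= 0.6):
            warnings.append(f"{name}: acceptance rate {rate:.2f} outside [0.1, 0.6]")
    return DiagnosticsReport(ess, rhat, s.acceptance, warnings)
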