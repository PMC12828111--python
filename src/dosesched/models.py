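"""Outcome models for the dose-schedule design.

Three endpoints are modelled jointly but independently given the parameters:

* immune response ``Z`` — the increase in a log-transformed immune-activity
  measure, normal with a plateau mean ``alpha_k * exp(delta*M) * (1 - exp(-nu*d_j))``
  that is zero at dose zero and saturates as dose increases;
* toxicity ``X`` — binary dose-limiting toxicity with a per-schedule logistic
  dose model ``logit p_(j,k) = beta0_k + beta1*d_j`` shared across subgroups;
* efficacy ``Y`` — ordinal (0=PD, 1=SD, 2=CR/PR) with ``logit q2 = zeta_(j,k),M``
  and a proportional-odds-style shift ``logit(q1+q2) = lambda + zeta_(j,k),M``.

The efficacy logits are tied together across the dose grid by a dynamic
(random-walk-with-drift) prior whose drift is the increment of the mean immune
response scaled by ``gamma``, and across subgroups by a truncated-normal prior
that forces the marker-positive CR/PR probability above the marker-negative one.

All doses entering regressions are the standardized doses (population SD 0.5);
immune-response means entering the efficacy drift are divided by ``m_mu / 2``
(half the elicited maximum mean immune response), mirroring the weakly
informative prior scalings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import cauchy, gamma as gamma_dist, invgamma, norm

__all__ = [
    "DoseGrid",
    "ImmuneParams",
    "ToxicityParams",
    "EfficacyParams",
    "ModelHyper",
    "PriorSpec",
    "ParameterState",
    "PatientOutcome",
    "standardize_doses",
    "mean_immune_response",
    "toxicity_probability",
    "efficacy_category_probs",
    "efficacy_dynamic_prior_mean",
    "log_likelihood_patient",
    "log_prior",
    "alt2_efficacy_probs",
]

Variant = Literal["proposed", "dose_adjusted", "alternative1", "alternative2"]


@dataclass(frozen=True)
class DoseGrid:
    """Ordered dose grid with standardized doses and schedule labels."""

    raw_doses: tuple[float, ...]
    scaled_doses: tuple[float, ...]
    schedules: tuple[str, ...]

    def __post_init__(self) -> None:
        raw = np.asarray(self.raw_doses, dtype=float)
        if raw.size < 2:
            raise ValueError("need at least two doses")
        if not np.all(np.diff(raw) > 0):
            raise ValueError("raw doses must be strictly increasing")
        sd = float(np.std(np.asarray(self.scaled_doses)))
        if abs(sd - 0.5) > 1e-9:
            raise ValueError(f"scaled doses must have SD 0.5, got {sd}")

    @property
    def n_doses(self) -> int:
        return len(self.raw_doses)

    @property
    def n_schedules(self) -> int:
        return len(self.schedules)


def standardize_doses(
    raw_doses: Sequence[float], schedules: Sequence[str] | None = None
) -> DoseGrid:
    """Scale doses to population standard deviation 0.5.

    The standardized doses are used in every regression term (toxicity slope,
    plateau rate ``nu``) so that priors and likelihood share one scale.
    """
    raw = np.asarray(raw_doses, dtype=float)
    if raw.size < 2:
        raise ValueError("need at least two doses")
    sd = float(np.std(raw))
    if sd <= 0:
        raise ValueError("doses are constant; cannot standardize")
    scaled = raw * (0.5 / sd)
    if schedules is None:
        schedules = ("s1", "s2", "s3")
    return DoseGrid(tuple(raw.tolist()), tuple(scaled.tolist()), tuple(schedules))


@dataclass
class ImmuneParams:
    """Plateau-model parameters for the immune response."""

    alpha: np.ndarray  # (K,) max mean immune response per schedule, M=0
    delta: float  # log ratio of marker-positive to marker-negative maximum
    nu: float  # dose rate (on the standardized dose scale)
    sigma_z_sq: float  # residual variance

    def validate(self) -> None:
        if not np.all(np.asarray(self.alpha) > 0):
            raise ValueError("alpha must be positive")
        if self.delta <= 0 or self.nu <= 0 or self.sigma_z_sq <= 0:
            raise ValueError("delta, nu, sigma_z_sq must be positive")


@dataclass
class ToxicityParams:
    beta0: np.ndarray  # (K,) per-schedule intercepts
    beta1: float  # dose slope (standardized dose)

    def validate(self) -> None:
        if not (np.all(np.isfinite(self.beta0)) and math.isfinite(self.beta1)):
            raise ValueError("toxicity parameters must be finite")


@dataclass
class EfficacyParams:
    """Efficacy logits and hierarchy parameters.

    ``zeta[j, k, M]`` is the logit of the CR/PR probability for combo (j, k)
    and subgroup M; ``lam`` shifts it to the logit of Pr(Y > 0).
    """

    zeta: np.ndarray  # (J, K, 2)
    gamma: float  # immune-response drift effect, > 0
    lam: float  # proportional-odds shift, in (0, lam_upper)
    gamma2: float | None = None  # optional direct dose effect (dose-adjusted)

    def validate(self, lam_upper: float = 8.0) -> None:
        if not np.all(self.zeta[:, :, 1] > self.zeta[:, :, 0]):
            raise ValueError("zeta for M=1 must exceed zeta for M=0 everywhere")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not (0.0 < self.lam < lam_upper):
            raise ValueError("lambda outside prior support")


@dataclass
class ModelHyper:
    """Fixed hyperparameters of the efficacy hierarchy."""

    zeta0: np.ndarray  # (K,) prior means of zeta at the lowest dose, M=0
    tau_sq: float = 1.0
    sigma_e0_sq: float = 0.3
    sigma_e1_sq: float = 0.3

    def validate(self) -> None:
        if min(self.tau_sq, self.sigma_e0_sq, self.sigma_e1_sq) <= 0:
            raise ValueError("hyper variances must be positive")


@dataclass
class PriorSpec:
    """Weakly informative prior specification, built from clinician elicitations.

    ``alpha_hat`` (elicited maximum mean immune response per schedule) and
    ``r_hat`` (elicited marker-positive/negative ratio) set Gamma priors whose
    SD is ``sd_inflation`` times the mean; ``m_mu`` (elicited maximum possible
    mean immune response) sets the covariate scaling for ``gamma``.
    """

    alpha_hat: np.ndarray = field(default_factory=lambda: np.full(3, 20.0))
    r_hat: float = 1.5
    m_mu: float = 30.0
    sd_inflation: float = 3.0
    # Directly adjustable scales (defaults reproduce the base elicitation).
    ig_shape: float = 0.1
    ig_rate: float = 0.1
    nu_scale: float = 2.3
    beta0_mean: float = -4.0
    beta0_sd: float = 1.0
    beta1_scale: float = 2.5
    gamma_scale: float = 2.5
    lam_upper: float = 8.0

    # -- derived Gamma parameterizations (shape/rate) -------------------
    @property
    def alpha_shape(self) -> float:
        # mean a/b = alpha_hat, SD sqrt(a)/b = inflation*alpha_hat
        return 1.0 / self.sd_inflation**2

    @property
    def alpha_rate(self) -> np.ndarray:
        return self.alpha_shape / np.asarray(self.alpha_hat, dtype=float)

    @property
    def delta_mean(self) -> float:
        return math.log(self.r_hat)

    @property
    def delta_shape(self) -> float:
        return 1.0 / self.sd_inflation**2

    @property
    def delta_rate(self) -> float:
        return self.delta_shape / self.delta_mean

    @property
    def mu_scale(self) -> float:
        """Divisor applied to mean immune responses in the efficacy drift."""
        return 0.5 * self.m_mu

    def diffuse(self) -> "PriorSpec":
        """The diffuse sensitivity setting: all prior scales widened."""
        return replace(
            self,
            sd_inflation=5.0,
            ig_shape=0.01,
            ig_rate=0.01,
            nu_scale=4.6,
            beta0_sd=2.0,
            beta1_scale=5.0,
            gamma_scale=5.0,
            lam_upper=16.0,
        )


@dataclass
class ParameterState:
    immune: ImmuneParams
    tox: ToxicityParams
    eff: EfficacyParams

    def validate(self, lam_upper: float = 8.0) -> None:
        self.immune.validate()
        self.tox.validate()
        self.eff.validate(lam_upper)


@dataclass(frozen=True)
class PatientOutcome:
    """One accrued patient record: combo, subgroup and the three outcomes."""

    j: int  # dose index, 0-based
    k: int  # schedule index, 0-based
    m: int  # subgroup, 0 or 1
    z: float  # immune response
    x: int  # DLT indicator
    y: int  # efficacy category 0/1/2


# ---------------------------------------------------------------------------
# elementary model evaluations
# ---------------------------------------------------------------------------

def mean_immune_response(
    p: ImmuneParams, grid: DoseGrid, j: int, k: int, m: int
) -> float:
    """Plateau mean: alpha_k * exp(delta*M) * (1 - exp(-nu * d_j))."""
    d = grid.scaled_doses[j]
    return float(p.alpha[k] * math.exp(p.delta * m) * (1.0 - math.exp(-p.nu * d)))


def toxicity_probability(t: ToxicityParams, grid: DoseGrid, j: int, k: int) -> float:
    return float(expit(t.beta0[k] + t.beta1 * grid.scaled_doses[j]))


def efficacy_category_probs(
    e: EfficacyParams, j: int, k: int, m: int
) -> tuple[float, float, float]:
    """(q0, q1, q2) from the logits: q2 = expit(zeta), q1+q2 = expit(lam+zeta)."""
    zeta = e.zeta[j, k, m]
    q2 = float(expit(zeta))
    pi = float(expit(e.lam + zeta))
    return (1.0 - pi, pi - q2, q2)


def efficacy_dynamic_prior_mean(
    variant: Variant,
    zeta_prev: float,
    immune: ImmuneParams,
    grid: DoseGrid,
    gamma: float,
    j: int,
    k: int,
    mu_scale: float = 15.0,
    gamma2: float = 0.0,
) -> float:
    """Drift mean of ``zeta[j,k,0]`` given ``zeta[j-1,k,0]`` (j >= 1, 0-based).

    * ``proposed``: previous logit plus ``gamma`` times the (scaled)
      marker-negative immune-response increment between the two doses;
    * ``dose_adjusted``: the proposed drift plus ``gamma2 * (d_j - d_{j-1})``;
    * ``alternative1``: previous logit plus ``gamma * (d_j - d_{j-1})``
      (immune response ignored).
    """
    if j < 1:
        raise ValueError("the lowest dose is anchored by the tau^2 prior, not a drift")
    d_lo, d_hi = grid.scaled_doses[j - 1], grid.scaled_doses[j]
    if variant == "alternative1":
        return zeta_prev + gamma * (d_hi - d_lo)
    mu_hi = mean_immune_response(immune, grid, j, k, 0)
    mu_lo = mean_immune_response(immune, grid, j - 1, k, 0)
    drift = gamma * (mu_hi - mu_lo) / mu_scale
    if variant == "dose_adjusted":
        drift += gamma2 * (d_hi - d_lo)
    elif variant != "proposed":
        raise ValueError(f"unknown variant {variant!r}")
    return zeta_prev + drift


def log_likelihood_patient(
    theta: ParameterState, grid: DoseGrid, o: PatientOutcome
) -> float:
    """Log of the product of the normal Z, categorical Y and Bernoulli X terms."""
    mu = mean_immune_response(theta.immune, grid, o.j, o.k, o.m)
    s2 = theta.immune.sigma_z_sq
    ll = -0.5 * math.log(2.0 * math.pi * s2) - (o.z - mu) ** 2 / (2.0 * s2)
    q = efficacy_category_probs(theta.eff, o.j, o.k, o.m)
    ll += math.log(q[o.y])
    p = toxicity_probability(theta.tox, grid, o.j, o.k)
    ll += math.log(p) if o.x == 1 else math.log(1.0 - p)
    return ll


def log_prior(
    theta: ParameterState,
    hyper: ModelHyper,
    prior: PriorSpec,
    grid: DoseGrid,
    variant: Variant = "proposed",
) -> float:
    """Joint log prior density of the full parameter state.

    Returns ``-inf`` outside the support (delta, nu, gamma <= 0, lambda outside
    its uniform support, or any zeta[.,.,1] <= zeta[.,.,0]).
    """
    im, tx, ef = theta.immune, theta.tox, theta.eff
    if (
        im.delta <= 0
        or im.nu <= 0
        or im.sigma_z_sq <= 0
        or ef.gamma <= 0
        or not (0.0 < ef.lam < prior.lam_upper)
        or np.any(np.asarray(im.alpha) <= 0)
        or np.any(ef.zeta[:, :, 1] <= ef.zeta[:, :, 0])
    ):
        return -math.inf

    lp = float(
        np.sum(
            gamma_dist.logpdf(im.alpha, prior.alpha_shape, scale=1.0 / prior.alpha_rate)
        )
    )
    lp += float(
        gamma_dist.logpdf(im.delta, prior.delta_shape, scale=1.0 / prior.delta_rate)
    )
    lp += float(invgamma.logpdf(im.sigma_z_sq, prior.ig_shape, scale=prior.ig_rate))
    # positive-truncated normal for nu: density 2*phi(nu/scale)/scale on nu>0
    lp += float(norm.logpdf(im.nu, 0.0, prior.nu_scale)) + math.log(2.0)
    lp += float(np.sum(norm.logpdf(tx.beta0, prior.beta0_mean, prior.beta0_sd)))
    lp += float(cauchy.logpdf(tx.beta1, 0.0, prior.beta1_scale))
    # gamma > 0: half-Cauchy with the stated scale
    lp += float(cauchy.logpdf(ef.gamma, 0.0, prior.gamma_scale)) + math.log(2.0)
    lp += -math.log(prior.lam_upper)  # uniform lambda

    J, K = grid.n_doses, grid.n_schedules
    se0 = math.sqrt(hyper.sigma_e0_sq)
    se1 = math.sqrt(hyper.sigma_e1_sq)
    tau = math.sqrt(hyper.tau_sq)
    gamma2 = ef.gamma2 if ef.gamma2 is not None else 0.0
    for k in range(K):
        lp += float(norm.logpdf(ef.zeta[0, k, 0], hyper.zeta0[k], tau))
        for j in range(1, J):
            mean = efficacy_dynamic_prior_mean(
                variant if variant != "alternative2" else "proposed",
                ef.zeta[j - 1, k, 0],
                im,
                grid,
                ef.gamma,
                j,
                k,
                mu_scale=prior.mu_scale,
                gamma2=gamma2,
            )
            lp += float(norm.logpdf(ef.zeta[j, k, 0], mean, se0))
        for j in range(J):
            # truncated normal above zeta[j,k,0]; truncation point equals the
            # mean, so the normalizer is exactly 1/2
            lp += float(norm.logpdf(ef.zeta[j, k, 1], ef.zeta[j, k, 0], se1))
            lp += math.log(2.0)
    return lp


def alt2_efficacy_probs(
    intercepts: Sequence[float], gamma1: float, gamma2: float, mu_z: float
) -> tuple[float, float, float]:
    """Efficacy category probabilities under the parametric proportional-odds
    comparator: ``logit Pr(Y <= l) = intercepts[l] + gamma1*mu + gamma2*mu^2``
    for cut-points l in {0, 1}.
    """
    c0, c1 = float(intercepts[0]), float(intercepts[1])
    if not c0 < c1:
        raise ValueError("cumulative-logit intercepts must be strictly increasing")
    shift = gamma1 * mu_z + gamma2 * mu_z * mu_z
    p_le0 = float(expit(c0 + shift))
    p_le1 = float(expit(c1 + shift))
    return (p_le0, p_le1 - p_le0, 1.0 - p_le1)
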