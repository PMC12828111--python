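"""Utility-based decision rules: admissibility, adaptive randomization,
stage-I escalation and final selection.

The desirability of a combo (j, k) for subgroup M is the elicited utility

    U = q2 + w1*q1 - w2*p - penalty(p),

where ``q2``/``q1`` are the CR/PR and SD probabilities, ``p`` the DLT
probability, and the penalty activates above the toxicity limit ``phi_T``.
Two penalty conventions are supported: ``fixed`` (subtract ``w3`` whenever
``p > phi_T``; the default, consistent with the built-in truth tables) and
``proportional`` (subtract ``w3*p``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Literal, Mapping

import numpy as np

from .inference import StageOneState, beta_binomial_safety_prob

if TYPE_CHECKING:  # pragma: no cover
    from .config import DesignConfig
    from .inference import PosteriorSummaries

__all__ = [
    "UtilityWeights",
    "AdmissibleSet",
    "utility",
    "estimated_utilities",
    "stage1_step",
    "admissible_set",
    "randomization_probabilities",
    "select_final",
]

PenaltyConvention = Literal["fixed", "proportional"]


@dataclass(frozen=True)
class UtilityWeights:
    """Elicited risk-benefit weights.

    ``w1`` converts an SD into a fraction of a CR/PR, ``w2`` prices toxicity,
    and ``w3`` is the extra penalty once toxicity exceeds ``phi_T``.
    """

    w1: float = 0.5
    w2: float = 0.3
    w3: float = 1.2
    phi_T: float = 0.3
    penalty_convention: PenaltyConvention = "fixed"

    def __post_init__(self) -> None:
        if not (0.0 < self.w1 < 1.0):
            raise ValueError("w1 must lie in (0, 1)")
        if self.w2 <= 0 or self.w3 <= 0:
            raise ValueError("w2 and w3 must be positive")
        if not (0.0 <= self.phi_T <= 1.0):
            raise ValueError("phi_T must be a probability")
        if self.penalty_convention not in ("fixed", "proportional"):
            raise ValueError("unknown penalty convention")


@dataclass
class AdmissibleSet:
    """Per-subgroup sets of (j, k) combos meeting the safety and efficacy
    posterior requirements."""

    by_subgroup: dict[int, set[tuple[int, int]]] = field(
        default_factory=lambda: {0: set(), 1: set()}
    )

    def __getitem__(self, m: int) -> set[tuple[int, int]]:
        return self.by_subgroup[m]

    @property
    def all_empty(self) -> bool:
        return all(len(s) == 0 for s in self.by_subgroup.values())


def utility(q1: float, q2: float, p: float, w: UtilityWeights) -> float:
    """Risk-benefit utility of a combo given its outcome probabilities."""
    for name, v in (("q1", q1), ("q2", q2), ("p", p)):
        if not (-1e-12 <= v <= 1.0 + 1e-12):
            raise ValueError(f"{name}={v} is not a probability")
    if q1 + q2 > 1.0 + 1e-9:
        raise ValueError("q1 + q2 exceeds 1")
    u = q2 + w.w1 * q1 - w.w2 * p
    if p > w.phi_T:
        u -= w.w3 if w.penalty_convention == "fixed" else w.w3 * p
    return u


def estimated_utilities(
    sums: "PosteriorSummaries", w: UtilityWeights
) -> np.ndarray:
    """Plug-in utilities from posterior-mean probabilities, shape (J, K, 2).

    The over-toxicity indicator is evaluated at the posterior mean ``p_hat``
    (not as the posterior mean of the indicator).
    """
    J, K = sums.p_hat.shape
    out = np.empty((J, K, 2))
    for j in range(J):
        for k in range(K):
            for m in range(2):
                out[j, k, m] = utility(
                    float(sums.q1_hat[j, k, m]),
                    float(sums.q2_hat[j, k, m]),
                    float(sums.p_hat[j, k]),
                    w,
                )
    return out


# ---------------------------------------------------------------------------
# stage I: schedule-wise escalation under the Beta-Binomial screen
# ---------------------------------------------------------------------------

@dataclass
class Stage1Decision:
    """Result of one stage-I step: either an assignment or stage completion."""

    complete: bool
    assignment: tuple[int, int] | None = None  # (j, k), 0-based


def stage1_step(state: StageOneState, cfg: "DesignConfig") -> Stage1Decision:
    """Advance the round-robin stage-I escalation by one cohort assignment.

    On the first visit to a schedule the lowest dose is assigned.  Afterwards
    a schedule is closed once its highest tried dose fails the Beta-Binomial
    screen ``Pr(p < phi_T | data) > C_I`` or the top dose has been tried;
    otherwise the next cohort escalates one dose level.
    """
    if state.all_closed:
        raise RuntimeError("stage I already complete")
    K = len(state.highest_tried)
    start = state.cursor
    for off in range(K):
        k = (start + off) % K
        if not state.open_flags[k]:
            continue
        h = state.highest_tried[k]
        if h < 0:  # schedule not yet visited: treat at the lowest dose
            state.cursor = (k + 1) % K
            return Stage1Decision(False, (0, int(k)))
        n, m = state.n_treated[h, k], state.n_tox[h, k]
        safe = beta_binomial_safety_prob(
            int(m), int(n), cfg.phi_T, cfg.kappa1, cfg.kappa2
        )
        if safe <= cfg.C_I or h == state.n_doses - 1:
            state.open_flags[k] = False
            continue
        state.cursor = (k + 1) % K
        return Stage1Decision(False, (int(h) + 1, int(k)))
    return Stage1Decision(True, None)


# ---------------------------------------------------------------------------
# stage II: admissibility, adaptive randomization, final selection
# ---------------------------------------------------------------------------

def admissible_set(sums: "PosteriorSummaries", cfg: "DesignConfig") -> AdmissibleSet:
    """Combos with posterior safety ``> C_T`` and efficacy ``> C_E`` (strict),
    per subgroup.  Any combo on the grid may qualify: the model borrows
    strength across the grid, so combos untried in stage I are not excluded.
    """
    J, K = sums.p_hat.shape
    out = AdmissibleSet()
    for m in range(2):
        for j in range(J):
            for k in range(K):
                if (
                    sums.prob_safe[j, k] > cfg.C_T
                    and sums.prob_efficacious[j, k, m] > cfg.C_E
                ):
                    out[m].add((j, k))
    return out


def randomization_probabilities(
    utils: Mapping[tuple[int, int], float],
    adm: Iterable[tuple[int, int]],
    floor: float = 0.01,
) -> dict[tuple[int, int], float]:
    """Randomization probabilities proportional to estimated utility over the
    admissible set, with utilities floored at ``floor`` so that negative or
    zero utilities keep a well-defined (but near-zero) chance."""
    adm = list(adm)
    if not adm:
        raise ValueError("admissible set is empty")
    if floor <= 0:
        raise ValueError("floor must be positive")
    vals = np.array([max(float(utils[c]), floor) for c in adm])
    vals /= vals.sum()
    return {c: float(v) for c, v in zip(adm, vals)}


def select_final(
    sums: "PosteriorSummaries", cfg: "DesignConfig", m: int
) -> tuple[int, int] | None:
    """Final recommendation for subgroup ``m``: the admissible combo with the
    largest posterior-mean utility; ``None`` when no combo is admissible.
    Ties are broken toward the lowest dose index, then lowest schedule."""
    adm = admissible_set(sums, cfg)[m]
    if not adm:
        return None
    utils = estimated_utilities(sums, cfg.weights)
    best = max(utils[j, k, m] for (j, k) in adm)
    ties = sorted(c for c in adm if utils[c[0], c[1], m] >= best - 1e-12)
    return ties[0]
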