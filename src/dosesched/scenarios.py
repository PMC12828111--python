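"""Built-in simulation truth scenarios.

Eight published truth tables give, for every (dose, schedule, subgroup) cell,
the mean immune response, the DLT probability, the SD/CR/PR probability
``pi = q1 + q2`` and the true utility.  The individual efficacy category
probabilities are not printed; they are recovered by inverting the utility

    U = q2 + w1*(pi - q2) - w2*p - w3*I(p > phi_T)

for ``q2`` (the fixed-penalty convention; the printed utilities are only
algebraically consistent with this form).  Utilities are printed at mixed
precision (one or two decimals), so the inversion tolerates a discrepancy of
half an ulp of the printed value; the recovered ``q2`` is clamped into
``[0, pi]``.

The copula dependence parameter used for generation is 1.5 throughout.  The
immune-response generation SD is not printed; the default here is 2.0
(informative but noisy on the ~1-27 scale of the tables) and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .decisions import UtilityWeights, utility

__all__ = [
    "ScenarioTruth",
    "ScenarioCell",
    "ValidationReport",
    "load_builtin_scenario",
    "load_scenario_csv",
    "derive_q2_from_utility",
    "validate_scenario",
    "true_optimal",
    "BUILTIN_DOSES",
    "BUILTIN_SCHEDULES",
    "TABLE_OPTIMA",
    "PRINT_TIE_TOL",
]

BUILTIN_DOSES = (0.1, 0.5, 0.9)
BUILTIN_SCHEDULES = ("s1", "s2", "s3")

#: Tie tolerance that reproduces the published per-subgroup optima: utilities
#: are printed at two decimals, so two truly tied combos can differ by up to
#: one printed ulp (0.01) after rounding.
PRINT_TIE_TOL = 0.0105

# Each cell is (mu_z, p_tox, pi, printed utility as a string).  Rows are
# doses d1..d3; columns are (M=0: s1, s2, s3), then (M=1: s1, s2, s3).
_TABLE: dict[int, list[list[tuple[float, float, float, str]]]] = {
    1: [
        [(3.6, 0.10, 0.45, "0.25"), (7.2, 0.16, 0.45, "0.23"), (8.0, 0.43, 0.45, "-1.05"),
         (4.4, 0.10, 0.52, "0.3"), (8.9, 0.16, 0.52, "0.28"), (9.7, 0.43, 0.52, "-1.0")],
        [(8.9, 0.14, 0.58, "0.33"), (17.9, 0.18, 0.7, "0.42"), (19.7, 0.55, 0.73, "-0.87"),
         (10.9, 0.14, 0.65, "0.39"), (21.9, 0.18, 0.76, "0.48"), (24.0, 0.55, 0.78, "-0.82")],
        [(9.8, 0.48, 0.6, "-0.96"), (19.7, 0.55, 0.74, "-0.86"), (21.6, 0.65, 0.76, "-0.86"),
         (12.0, 0.48, 0.67, "-0.9"), (24.0, 0.55, 0.79, "-0.8"), (26.4, 0.65, 0.81, "-0.8")],
    ],
    2: [
        [(1.5, 0.05, 0.33, "0.2"), (2.2, 0.08, 0.33, "0.19"), (4.0, 0.1, 0.33, "0.19"),
         (2.2, 0.05, 0.38, "0.23"), (3.2, 0.08, 0.38, "0.22"), (5.9, 0.1, 0.38, "0.22")],
        [(5.1, 0.12, 0.42, "0.24"), (7.6, 0.15, 0.46, "0.27"), (13.9, 0.17, 0.57, "0.35"),
         (7.5, 0.12, 0.47, "0.28"), (11.3, 0.15, 0.52, "0.3"), (20.7, 0.17, 0.68, "0.39")],
        [(6.7, 0.4, 0.46, "-1.0"), (10.0, 0.47, 0.52, "-1.0"), (18.4, 0.52, 0.68, "-0.86"),
         (10.0, 0.4, 0.51, "-0.97"), (14.9, 0.47, 0.57, "-0.94"), (27.4, 0.52, 0.72, "-0.82")],
    ],
    3: [
        [(0.9, 0.05, 0.07, "0.03"), (1.3, 0.1, 0.11, "0.04"), (2.6, 0.42, 0.11, "-1.3"),
         (1.3, 0.05, 0.08, "0.04"), (1.9, 0.1, 0.13, "0.05"), (3.9, 0.42, 0.13, "-1.2")],
        [(3.6, 0.12, 0.15, "0.06"), (5.4, 0.16, 0.3, "0.14"), (10.9, 0.55, 0.6, "-0.94"),
         (5.4, 0.12, 0.17, "0.07"), (8.1, 0.16, 0.34, "0.2"), (16.2, 0.55, 0.62, "-0.9")],
        [(5.6, 0.16, 0.23, "0.1"), (8.3, 0.18, 0.5, "0.3"), (16.7, 0.56, 0.89, "-0.6"),
         (8.3, 0.16, 0.27, "0.13"), (12.4, 0.18, 0.55, "0.34"), (24.8, 0.56, 0.91, "-0.55")],
    ],
    4: [
        [(7.9, 0.08, 0.35, "0.24"), (7.9, 0.1, 0.52, "0.39"), (8.0, 0.38, 0.35, "-1.05"),
         (13.2, 0.08, 0.4, "0.28"), (13.2, 0.1, 0.57, "0.43"), (13.2, 0.38, 0.4, "-1.0")],
        [(10.0, 0.25, 0.4, "0.23"), (10.0, 0.46, 0.57, "-0.87"), (10.0, 0.55, 0.4, "-1.06"),
         (16.5, 0.25, 0.45, "0.28"), (16.5, 0.46, 0.62, "-0.83"), (16.5, 0.55, 0.45, "-1.01")],
        [(10.0, 0.56, 0.4, "-1.1"), (10.0, 0.58, 0.57, "-0.9"), (10.0, 0.65, 0.4, "-1.1"),
         (16.5, 0.56, 0.45, "-1.0"), (16.5, 0.58, 0.62, "-0.9"), (16.5, 0.65, 0.45, "-1.0")],
    ],
    5: [
        [(8.3, 0.1, 0.29, "0.19"), (8.3, 0.14, 0.4, "0.27"), (8.3, 0.38, 0.31, "-1.1"),
         (10.1, 0.1, 0.33, "0.22"), (10.1, 0.14, 0.45, "0.31"), (10.1, 0.38, 0.35, "-1.05")],
        [(14.6, 0.15, 0.43, "0.3"), (14.7, 0.16, 0.56, "0.4"), (14.7, 0.45, 0.46, "-0.97"),
         (18.0, 0.15, 0.72, "0.57"), (18.0, 0.16, 0.61, "0.45"), (18.0, 0.45, 0.51, "-0.93")],
        [(15.0, 0.46, 0.44, "-0.99"), (15.0, 0.52, 0.57, "-0.9"), (15.0, 0.64, 0.47, "-1.03"),
         (18.3, 0.46, 0.49, "-0.95"), (18.3, 0.52, 0.62, "-0.85"), (18.3, 0.64, 0.52, "-0.98")],
    ],
    6: [
        [(3.5, 0.05, 0.19, "0.13"), (3.5, 0.08, 0.12, "0.06"), (3.5, 0.1, 0.13, "0.06"),
         (4.3, 0.05, 0.23, "0.16"), (4.3, 0.08, 0.14, "0.08"), (4.3, 0.1, 0.15, "0.08")],
        [(13.2, 0.08, 0.39, "0.28"), (13.2, 0.1, 0.26, "0.17"), (13.2, 0.13, 0.28, "0.17"),
         (16.1, 0.08, 0.44, "0.32"), (16.1, 0.1, 0.3, "0.2"), (16.1, 0.13, 0.33, "0.21")],
        [(18.5, 0.1, 0.53, "0.39"), (18.5, 0.12, 0.38, "0.25"), (18.5, 0.14, 0.4, "0.27"),
         (22.6, 0.1, 0.54, "0.4"), (22.6, 0.12, 0.43, "0.29"), (22.6, 0.14, 0.72, "0.56")],
    ],
    7: [
        [(4.3, 0.1, 0.18, "0.12"), (4.3, 0.12, 0.27, "0.19"), (5.2, 0.35, 0.2, "-1.14"),
         (5.0, 0.1, 0.21, "0.15"), (5.0, 0.12, 0.55, "0.45"), (6.0, 0.35, 0.23, "-1.11")],
        [(12.3, 0.13, 0.25, "0.17"), (12.3, 0.15, 0.35, "0.26"), (14.7, 0.45, 0.28, "-1.1"),
         (14.2, 0.13, 0.29, "0.2"), (14.2, 0.15, 0.4, "0.3"), (17.1, 0.45, 0.33, "-1.1")],
        [(14.3, 0.35, 0.27, "-1.1"), (14.3, 0.4, 0.38, "-1.0"), (17.2, 0.64, 0.31, "-1.1"),
         (16.6, 0.35, 0.31, "-1.0"), (16.6, 0.4, 0.37, "-1.0"), (19.9, 0.64, 0.35, "-1.1")],
    ],
    8: [
        [(5.9, 0.08, 0.33, "0.26"), (5.9, 0.28, 0.31, "0.18"), (5.9, 0.45, 0.29, "-1.1"),
         (6.9, 0.08, 0.38, "0.3"), (6.9, 0.28, 0.35, "0.22"), (6.9, 0.45, 0.33, "-1.0")],
        [(13.8, 0.1, 0.42, "0.34"), (13.8, 0.35, 0.4, "-0.96"), (13.8, 0.53, 0.38, "-1.04"),
         (16.0, 0.1, 0.47, "0.38"), (16.0, 0.35, 0.45, "-0.92"), (16.0, 0.53, 0.42, "-0.99")],
        [(14.8, 0.12, 0.44, "0.34"), (14.8, 0.42, 0.41, "-0.97"), (14.8, 0.64, 0.39, "-1.1"),
         (17.2, 0.12, 0.49, "0.39"), (17.2, 0.42, 0.46, "-0.92"), (17.2, 0.64, 0.44, "-1.0")],
    ],
}

#: Published per-subgroup optimal combos (0-based (dose, schedule) indices).
TABLE_OPTIMA: dict[int, dict[int, set[tuple[int, int]]]] = {
    1: {0: {(1, 1)}, 1: {(1, 1)}},
    2: {0: {(1, 2)}, 1: {(1, 2)}},
    3: {0: {(2, 1)}, 1: {(2, 1)}},
    4: {0: {(0, 1)}, 1: {(0, 1)}},
    5: {0: {(1, 1)}, 1: {(1, 0)}},
    6: {0: {(2, 0)}, 1: {(2, 2)}},
    7: {0: {(1, 1)}, 1: {(0, 1)}},
    8: {0: {(1, 0), (2, 0)}, 1: {(1, 0), (2, 0)}},
}


@dataclass(frozen=True)
class ScenarioCell:
    j: int
    k: int
    m: int
    mu_z: float
    p: float
    pi: float
    u_true: float


@dataclass
class ScenarioTruth:
    """Ground-truth outcome distributions for one simulation scenario."""

    doses: tuple[float, ...]
    schedules: tuple[str, ...]
    mu_z_true: np.ndarray  # (J, K, 2)
    p_tox_true: np.ndarray  # (J, K)
    q_true: np.ndarray  # (J, K, 2, 3) category probabilities (q0, q1, q2)
    copula_theta: float = 1.5
    sigma_z_true: float = 2.0
    u_printed: np.ndarray | None = None  # (J, K, 2) printed utilities
    u_decimals: np.ndarray | None = None  # (J, K, 2) printed decimal places
    scenario_id: int | None = None

    @property
    def n_doses(self) -> int:
        return self.mu_z_true.shape[0]

    @property
    def n_schedules(self) -> int:
        return self.mu_z_true.shape[1]

    def pi(self, j: int, k: int, m: int) -> float:
        return float(self.q_true[j, k, m, 1] + self.q_true[j, k, m, 2])

    def cell(self, j: int, k: int, m: int, weights: UtilityWeights) -> ScenarioCell:
        q = self.q_true[j, k, m]
        return ScenarioCell(
            j, k, m,
            float(self.mu_z_true[j, k, m]),
            float(self.p_tox_true[j, k]),
            float(q[1] + q[2]),
            utility(float(q[1]), float(q[2]), float(self.p_tox_true[j, k]), weights),
        )


def derive_q2_from_utility(
    u_true: float,
    pi: float,
    p: float,
    weights: UtilityWeights,
    clamp_tol: float = 1e-6,
) -> float:
    """Invert the utility for the CR/PR probability ``q2``.

    Solves ``U = q2 + w1*(pi - q2) - w2*p - penalty(p)`` and clamps the result
    into ``[0, pi]`` when it lies within ``clamp_tol`` of that interval;
    otherwise raises a consistency error naming the offending inputs.
    """
    if not (0.0 <= pi <= 1.0 and 0.0 <= p <= 1.0):
        raise ValueError("pi and p must be probabilities")
    penalty = 0.0
    if p > weights.phi_T:
        penalty = weights.w3 if weights.penalty_convention == "fixed" else weights.w3 * p
    q2 = (u_true + weights.w2 * p + penalty - weights.w1 * pi) / (1.0 - weights.w1)
    if q2 < -clamp_tol or q2 > pi + clamp_tol:
        raise ValueError(
            f"utility {u_true} with pi={pi}, p={p} under the "
            f"{weights.penalty_convention} penalty convention solves to "
            f"q2={q2:.4f} outside [0, {pi}]"
        )
    return float(min(max(q2, 0.0), pi))


def _decimals(s: str) -> int:
    return len(s.split(".")[1]) if "." in s else 0


def load_builtin_scenario(
    scenario_id: int,
    weights: UtilityWeights | None = None,
    sigma_z_true: float = 2.0,
    copula_theta: float = 1.5,
) -> ScenarioTruth:
    """Build a full ``ScenarioTruth`` from one of the eight published tables.

    Efficacy category probabilities are completed by inverting the printed
    utilities under ``weights`` (fixed-penalty convention by default).  The
    inversion clamp tolerance is 0.06, reflecting utilities printed at one
    decimal in a few cells.
    """
    if scenario_id not in _TABLE:
        raise ValueError(f"unknown built-in scenario id {scenario_id}; use 1..8")
    w = weights if weights is not None else UtilityWeights()
    rows = _TABLE[scenario_id]
    J, K = 3, 3
    mu = np.empty((J, K, 2))
    p = np.empty((J, K))
    q = np.empty((J, K, 2, 3))
    u_printed = np.empty((J, K, 2))
    u_dec = np.empty((J, K, 2), dtype=int)
    for j in range(J):
        for m in range(2):
            for k in range(K):
                mu_z, pt, pi, u_str = rows[j][m * K + k]
                mu[j, k, m] = mu_z
                p[j, k] = pt
                u = float(u_str)
                u_printed[j, k, m] = u
                u_dec[j, k, m] = _decimals(u_str)
                try:
                    q2 = derive_q2_from_utility(u, pi, pt, w, clamp_tol=0.06)
                except ValueError as err:
                    raise ValueError(
                        f"scenario {scenario_id} cell (d{j + 1},s{k + 1},M={m}): {err}"
                    ) from err
                q[j, k, m] = (1.0 - pi, pi - q2, q2)
    return ScenarioTruth(
        doses=BUILTIN_DOSES,
        schedules=BUILTIN_SCHEDULES,
        mu_z_true=mu,
        p_tox_true=p,
        q_true=q,
        copula_theta=copula_theta,
        sigma_z_true=sigma_z_true,
        u_printed=u_printed,
        u_decimals=u_dec,
        scenario_id=scenario_id,
    )


def load_scenario_csv(
    path: str | Path,
    doses: tuple[float, ...],
    schedules: tuple[str, ...] | None = None,
    copula_theta: float = 1.5,
    sigma_z_true: float = 2.0,
) -> ScenarioTruth:
    """Read a user truth scenario from CSV.

    One row per (dose_index, schedule_index, subgroup) with 1-based indices
    and columns mu_z, p_tox, q0, q1, q2 (probabilities as decimals).
    """
    df = pd.read_csv(path)
    required = {"dose_index", "schedule_index", "subgroup", "mu_z", "p_tox", "q0", "q1", "q2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"scenario CSV missing columns: {sorted(missing)}")
    J = int(df["dose_index"].max())
    K = int(df["schedule_index"].max())
    if len(doses) != J:
        raise ValueError(f"doses has {len(doses)} entries but CSV uses {J} dose indices")
    if schedules is None:
        schedules = tuple(f"s{k + 1}" for k in range(K))
    mu = np.full((J, K, 2), np.nan)
    p = np.full((J, K), np.nan)
    q = np.full((J, K, 2, 3), np.nan)
    for r in df.itertuples():
        j, k, m = int(r.dose_index) - 1, int(r.schedule_index) - 1, int(r.subgroup)
        mu[j, k, m] = r.mu_z
        p[j, k] = r.p_tox
        q[j, k, m] = (r.q0, r.q1, r.q2)
    if np.isnan(mu).any() or np.isnan(q).any():
        raise ValueError("scenario CSV does not cover every (dose, schedule, subgroup) cell")
    return ScenarioTruth(
        doses=tuple(float(d) for d in doses),
        schedules=schedules,
        mu_z_true=mu,
        p_tox_true=p,
        q_true=q,
        copula_theta=copula_theta,
        sigma_z_true=sigma_z_true,
    )


@dataclass
class ValidationReport:
    issues: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    passed: bool = True

    def add(self, msg: str) -> None:
        self.issues.append(msg)
        self.passed = False

    def warn(self, msg: str) -> None:
        self.warnings.append(msg)


def validate_scenario(
    s: ScenarioTruth, weights: UtilityWeights | None = None
) -> ValidationReport:
    """Check internal consistency of a truth scenario, cell by cell.

    Verifies probability validity, ``q2`` within ``[0, pi]``, marker-positive
    dominance of ``q2`` and ``pi``, and monotonicity of the mean immune
    response in dose.  When printed utilities are attached, also re-derives
    ``q2`` from them under ``weights`` and flags cells whose printed utility
    is inconsistent beyond its printed precision.
    """
    w = weights if weights is not None else UtilityWeights()
    rep = ValidationReport()
    J, K = s.n_doses, s.n_schedules
    for j in range(J):
        for k in range(K):
            if not (0.0 <= s.p_tox_true[j, k] <= 1.0):
                rep.add(f"(d{j + 1},s{k + 1}): p_tox outside [0,1]")
            for m in range(2):
                q = s.q_true[j, k, m]
                if np.any(q < -1e-9) or np.any(q > 1.0 + 1e-9):
                    rep.add(f"(d{j + 1},s{k + 1},M={m}): category probability outside [0,1]")
                if abs(q.sum() - 1.0) > 1e-9:
                    rep.add(f"(d{j + 1},s{k + 1},M={m}): q0+q1+q2 != 1")
                pi = q[1] + q[2]
                if q[2] < -1e-9 or q[2] > pi + 1e-9:
                    rep.add(f"(d{j + 1},s{k + 1},M={m}): q2 outside [0, pi]")
                if s.u_printed is not None:
                    u = float(s.u_printed[j, k, m])
                    dec = int(s.u_decimals[j, k, m]) if s.u_decimals is not None else 2
                    # allowed slack on q2 from the printed rounding of U
                    slack = (0.5 * 10.0 ** (-dec) + 1e-9) / (1.0 - w.w1)
                    try:
                        derive_q2_from_utility(u, float(pi), float(s.p_tox_true[j, k]), w, clamp_tol=slack)
                    except ValueError:
                        rep.add(
                            f"(d{j + 1},s{k + 1},M={m}): printed utility {u} inconsistent "
                            f"under the {w.penalty_convention} penalty convention"
                        )
            # Subgroup dominance.  For table-derived scenarios q2 is
            # reconstructed from rounded prints, so dominance can only be a
            # warning there; pi is compared at its printed precision.
            from_table = s.u_printed is not None
            pi_tol = 0.0105 if from_table else 1e-9
            q2_gap = s.q_true[j, k, 0, 2] - s.q_true[j, k, 1, 2]
            if q2_gap > 1e-9:
                msg = f"(d{j + 1},s{k + 1}): q2 for M=1 below M=0 by {q2_gap:.3f}"
                if from_table:
                    rep.warn(msg)
                else:
                    rep.add(msg)
            if s.pi(j, k, 1) < s.pi(j, k, 0) - pi_tol:
                rep.add(f"(d{j + 1},s{k + 1}): pi for M=1 below M=0")
    for k in range(K):
        for m in range(2):
            col = s.mu_z_true[:, k, m]
            if np.any(np.diff(col) < -1e-9):
                rep.add(f"(s{k + 1},M={m}): mu_z not nondecreasing in dose")
    return rep


def true_optimal(
    s: ScenarioTruth,
    weights: UtilityWeights | None = None,
    phi_T: float = 0.3,
    phi_E: float = 0.3,
    tie_tol: float = 1e-9,
) -> dict[int, set[tuple[int, int]]]:
    """True subgroup-specific optimal combos: highest true utility among
    combos with ``p < phi_T`` and ``pi > phi_E`` (strict); the returned set
    contains every combo within ``tie_tol`` of the maximum (empty if none is
    admissible)."""
    w = weights if weights is not None else UtilityWeights()
    out: dict[int, set[tuple[int, int]]] = {0: set(), 1: set()}
    for m in range(2):
        cells = []
        for j in range(s.n_doses):
            for k in range(s.n_schedules):
                p = float(s.p_tox_true[j, k])
                pi = s.pi(j, k, m)
                if p < phi_T and pi > phi_E:
                    q = s.q_true[j, k, m]
                    cells.append(((j, k), utility(float(q[1]), float(q[2]), p, w)))
        if not cells:
            continue
        best = max(u for _, u in cells)
        out[m] = {c for c, u in cells if u >= best - tie_tol}
    return out
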