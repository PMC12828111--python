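"""Design configuration: one object bundling everything a trial needs.

Defaults reproduce the base study conditions: doses (0.1, 0.5, 0.9), three
schedules, N = 120 in cohorts of 3, marker-positive prevalence 0.5, toxicity
limit phi_T = 0.3, efficacy limit phi_E = 0.3, cutoffs C_I = 0.05,
C_T = C_E = 0.2, utility weights (w1, w2, w3) = (0.5, 0.3, 1.2), efficacy
hierarchy anchors zeta0 = -2.2 with tau^2 = 1 and sigma_E0^2 = sigma_E1^2 = 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

from .decisions import UtilityWeights
from .inference import McmcConfig
from .models import DoseGrid, ModelHyper, PriorSpec, standardize_doses

__all__ = ["DesignConfig", "load_config", "default_config"]

Variant = Literal["proposed", "dose_adjusted", "alternative1", "alternative2"]


@dataclass
class DesignConfig:
    grid: DoseGrid
    N: int = 120
    cohort_size: int = 3
    prevalence: float = 0.5
    phi_T: float = 0.3
    phi_E: float = 0.3
    C_I: float = 0.05
    C_T: float = 0.2
    C_E: float = 0.2
    kappa1: float = 0.1
    kappa2: float = 0.2
    weights: UtilityWeights = field(default_factory=UtilityWeights)
    hyper: ModelHyper = None  # type: ignore[assignment]
    prior: PriorSpec = field(default_factory=PriorSpec)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    variant: Variant = "proposed"
    randomization_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.hyper is None:
            self.hyper = ModelHyper(zeta0=np.full(self.grid.n_schedules, -2.2))
        for name in ("C_I", "C_T", "C_E"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.cohort_size < 1 or self.N < self.cohort_size:
            raise ValueError("need cohort_size >= 1 and N >= cohort_size")
        if self.randomization_floor <= 0:
            raise ValueError("randomization floor must be positive")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must be a probability")


def default_config(**overrides) -> DesignConfig:
    """The base design configuration (3x3 grid); fields overridable."""
    grid = overrides.pop("grid", None)
    if grid is None:
        grid = standardize_doses((0.1, 0.5, 0.9), ("s1", "s2", "s3"))
    return DesignConfig(grid=grid, **overrides)


def load_config(path: str | Path) -> DesignConfig:
    """Read a DesignConfig from a YAML file mirroring its fields.

    Nested sections ``weights``, ``hyper``, ``prior`` and ``mcmc`` accept the
    corresponding dataclass fields; ``doses`` and ``schedules`` define the grid.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    doses = raw.pop("doses", (0.1, 0.5, 0.9))
    schedules = raw.pop("schedules", None)
    n_schedules = int(raw.pop("n_schedules", 3))
    if schedules is None:
        schedules = tuple(f"s{k + 1}" for k in range(n_schedules))
    grid = standardize_doses(tuple(doses), tuple(schedules))
    kwargs: dict = {"grid": grid}
    if "weights" in raw:
        kwargs["weights"] = UtilityWeights(**raw.pop("weights"))
    if "hyper" in raw:
        h = raw.pop("hyper")
        if "zeta0" in h:
            h["zeta0"] = np.asarray(h["zeta0"], dtype=float)
        kwargs["hyper"] = ModelHyper(**h)
    if "prior" in raw:
        p = raw.pop("prior")
        if "alpha_hat" in p:
            p["alpha_hat"] = np.asarray(p["alpha_hat"], dtype=float)
        kwargs["prior"] = PriorSpec(**p)
    if "mcmc" in raw:
        kwargs["mcmc"] = McmcConfig(**raw.pop("mcmc"))
    kwargs.update(raw)
    return DesignConfig(**kwargs)
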