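import math

import numpy as np
import pytest

import dosesched as ds
from dosesched.inference import TrialData
from dosesched.models import (
    EfficacyParams,
    ImmuneParams,
    PatientOutcome,
    ToxicityParams,
    efficacy_category_probs,
    mean_immune_response,
    toxicity_probability,
)
from dosesched.scenarios import ScenarioTruth


@pytest.fixture(scope="session")
def grid():
    return ds.standardize_doses((0.1, 0.5, 0.9), ("s1", "s2", "s3"))


@pytest.fixture(scope="session")
def hyper():
    return ds.ModelHyper(zeta0=np.full(3, -2.2))


@pytest.fixture(scope="session")
def prior():
    return ds.PriorSpec()


@pytest.fixture(scope="session")
def weights():
    return ds.UtilityWeights()


@pytest.fixture
def quick_mcmc():
    def make(seed=0, n_burn=500, n_keep=1000):
        return ds.McmcConfig(n_burn=n_burn, n_keep=n_keep, seed=seed)

    return make


def draw_state_from_hierarchy(rng, grid, alpha, delta, nu, s2, beta0, beta1, gam, lam,
                              mu_scale=15.0, zeta0=-2.2):
    """Draw zeta from the dynamic hierarchy given global truths, returning a
    full parameter state (used to simulate model-consistent data)."""
    J, K = grid.n_doses, grid.n_schedules
    zeta = np.empty((J, K, 2))
    for k in range(K):
        zeta[0, k, 0] = rng.normal(zeta0, 1.0)
        for j in range(1, J):
            dmu = alpha[k] * (
                math.exp(-nu * grid.scaled_doses[j - 1])
                - math.exp(-nu * grid.scaled_doses[j])
            )
            zeta[j, k, 0] = rng.normal(
                zeta[j - 1, k, 0] + gam * dmu / mu_scale, math.sqrt(0.3)
            )
        for j in range(J):
            v = zeta[j, k, 0] - 1.0
            while v <= zeta[j, k, 0]:
                v = rng.normal(zeta[j, k, 0], math.sqrt(0.3))
            zeta[j, k, 1] = v
    return ds.ParameterState(
        immune=ImmuneParams(np.asarray(alpha, dtype=float), delta, nu, s2),
        tox=ToxicityParams(np.asarray(beta0, dtype=float), beta1),
        eff=EfficacyParams(zeta, gam, lam),
    )


def simulate_model_data(rng, grid, theta, n_per_cell):
    """Balanced data simulated exactly from the outcome models."""
    data = TrialData()
    s_z = math.sqrt(theta.immune.sigma_z_sq)
    for j in range(grid.n_doses):
        for k in range(grid.n_schedules):
            for _ in range(n_per_cell):
                m = int(rng.random() < 0.5)
                z = rng.normal(mean_immune_response(theta.immune, grid, j, k, m), s_z)
                x = int(rng.random() < toxicity_probability(theta.tox, grid, j, k))
                y = int(rng.choice(3, p=efficacy_category_probs(theta.eff, j, k, m)))
                data.append(PatientOutcome(j, k, m, float(z), x, y))
    return data


@pytest.fixture(scope="session")
def model_data_factory(grid):
    def make(seed, n_per_cell=66, nu=2.0, delta=0.4, gam=1.0, lam=2.0):
        rng = np.random.default_rng(seed)
        theta = draw_state_from_hierarchy(
            rng, grid,
            alpha=np.array([10.0, 15.0, 20.0]), delta=delta, nu=nu, s2=4.0,
            beta0=np.array([-3.0, -2.5, -2.0]), beta1=1.0, gam=gam, lam=lam,
        )
        return simulate_model_data(rng, grid, theta, n_per_cell), theta

    return make


@pytest.fixture(scope="session")
def toxic_scenario():
    """A synthetic scenario where every combo is overly toxic (p >= 0.55)."""
    J = K = 3
    mu = np.tile(np.array([5.0, 10.0, 12.0])[:, None, None], (1, K, 2))
    mu[:, :, 1] *= 1.2
    p = np.full((J, K), 0.6)
    q = np.zeros((J, K, 2, 3))
    q[..., 0] = 0.5
    q[..., 1] = 0.3
    q[..., 2] = 0.2
    return ScenarioTruth(
        doses=(0.1, 0.5, 0.9),
        schedules=("s1", "s2", "s3"),
        mu_z_true=mu,
        p_tox_true=p,
        q_true=q,
    )
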