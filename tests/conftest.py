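import numpy as np
import pytest

from flexjm.data import ModelParams, SubjectRecord
from flexjm.simulate import demo_scenario, simulate_dataset
from flexjm.timegrid import TimePartition, design_matrix


@pytest.fixture
def part3():
    """Three intervals on [0, 1] with knots 0.25, 0.5."""
    return TimePartition(np.array([0.0, 0.25, 0.5, 1.0]))


@pytest.fixture
def part5():
    return TimePartition(np.linspace(0.0, 1.0, 6))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_params(M, rng=None, **overrides):
    """Random-but-tame parameter values for an M-interval model."""
    rng = rng or np.random.default_rng(0)
    defaults = dict(
        alpha=np.empty(0),
        beta=rng.normal(0.0, 0.5, M + 1),
        alpha_tilde=np.array([0.9, -0.3]),
        gamma=np.array([0.5, 0.3]),
        sigma_eps=0.4,
        sigma0=0.9,
        sigma1=0.8,
        sigma2=0.6,
        rho=0.2,
    )
    defaults.update(overrides)
    return ModelParams(**defaults)


def make_subject(part, params, rng, n_obs=3, s_star=None, delta=1, sid=0):
    """Simulate one subject's record directly from the model pieces."""
    from flexjm.likelihood import build_sigma

    M = part.M
    s_star = s_star if s_star is not None else min(2, M)
    Sigma = build_sigma(params, M).Sigma
    b = np.linalg.cholesky(Sigma) @ rng.standard_normal(M + 1)
    times = np.sort(rng.uniform(0.0, part.boundaries[s_star], size=n_obs))
    B = design_matrix(times, part).values
    y = B @ (params.beta + b) + rng.normal(0.0, params.sigma_eps, n_obs)
    x_surv = np.column_stack([np.ones(M), part.boundaries[:-1]])
    return SubjectRecord(
        id=sid, times=times, y=y, x_long=np.empty((n_obs, 0)),
        s_star=s_star, delta=delta, x_surv=x_surv,
    )


@pytest.fixture(scope="session")
def demo_data():
    """One small simulated dataset shared by read-only tests."""
    cfg = demo_scenario(N=80, seed=7)
    ds, truth = simulate_dataset(cfg)
    return cfg, ds, truth
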