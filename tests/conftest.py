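import numpy as np
import pytest
from scipy import optimize, stats

from gllvmpy import (
    AbundanceData,
    ModelSpec,
    ParameterSet,
    generate_parameters,
    simulate_responses,
)


@pytest.fixture(scope="session")
def tiny_poisson():
    """n=4, m=3, d=1 poisson dataset with known truth."""
    spec = ModelSpec(family="poisson", n_lv=1)
    params = generate_parameters(3, 1, 1, spec, seed=1)
    rng = np.random.default_rng(2)
    X = rng.standard_normal((4, 1))
    data, latent = simulate_responses(params, X, spec, 4, seed=3)
    return dict(spec=spec, params=params, data=data, latent=latent)


@pytest.fixture(scope="session")
def small_gaussian():
    """n=40, m=4, d=1 gaussian dataset (the exactness fixture)."""
    spec = ModelSpec(family="gaussian", n_lv=1)
    Gamma = np.array([[1.1], [0.8], [-0.6], [0.9]])
    Gamma[0, 0] = abs(Gamma[0, 0])
    params = ParameterSet(
        beta0=np.array([0.2, -0.3, 0.5, 0.0]),
        Gamma=Gamma,
        phi=np.array([0.4, 0.3, 0.5, 0.35]),
    )
    data, latent = simulate_responses(params, None, spec, 40, seed=7)
    return dict(spec=spec, params=params, data=data, latent=latent)


@pytest.fixture(scope="session")
def bimodal_gaussian():
    """Two-factor truth fitted with d=1: a constructed bimodal instance.

    Species 0 anchors only the weak factor (the identifiability constraint
    ties the fitted factor's sign to species 0), while the dominant factor
    loads on species 1-3; `zero` starts bootstrap through species 0 and land
    in the inferior mode.
    """
    spec2 = ModelSpec(family="gaussian", n_lv=2)
    Gamma = np.array(
        [
            [0.9, 0.0],
            [0.1, 1.6],
            [0.1, 1.6],
            [0.1, 1.6],
            [0.9, 0.1],
            [0.9, 0.1],
        ]
    )
    params = ParameterSet(beta0=np.zeros(6), Gamma=Gamma, phi=0.2 * np.ones(6))
    data, _ = simulate_responses(params, None, spec2, 120, seed=33)
    return dict(spec=ModelSpec(family="gaussian", n_lv=1), data=data)


@pytest.fixture(scope="session")
def unimodal_gaussian():
    """Strong single-factor gaussian data: every strategy should agree."""
    spec = ModelSpec(family="gaussian", n_lv=1)
    Gamma = np.array([[1.2], [0.9], [1.1], [0.8], [1.0], [0.7]])
    params = ParameterSet(beta0=np.zeros(6), Gamma=Gamma, phi=0.3 * np.ones(6))
    data, _ = simulate_responses(params, None, spec, 80, seed=21)
    return dict(spec=spec, data=data)


def gaussian_marginal_loglik(beta0, Gamma, phi, Y, X=None, B=None):
    """Closed-form marginal log-likelihood of the gaussian factor model:
    y_i ~ N(beta0 + B x_i, Gamma Gamma' + diag(phi))."""
    mean = np.tile(beta0, (Y.shape[0], 1))
    if X is not None and B is not None:
        mean = mean + X @ B.T
    cov = Gamma @ Gamma.T + np.diag(phi)
    return float(
        np.sum(stats.multivariate_normal.logpdf(Y - mean, mean=None, cov=cov))
    )


def fit_gaussian_factor_oracle(Y, d=1, X=None, k=0, seed=0):
    """Independent maximizer of the closed-form gaussian factor likelihood.

    Deliberately separate from the package's engines: a plain unconstrained
    parameterization (free loading matrix, log variances) optimized by BFGS
    on the analytic marginal likelihood.
    """
    n, m = Y.shape

    def unpack(x):
        pos = 0
        beta0 = x[pos : pos + m]
        pos += m
        B = None
        if k > 0:
            B = x[pos : pos + m * k].reshape(m, k)
            pos += m * k
        Gamma = x[pos : pos + m * d].reshape(m, d)
        pos += m * d
        phi = np.exp(x[pos : pos + m])
        return beta0, B, Gamma, phi

    def nll(x):
        beta0, B, Gamma, phi = unpack(x)
        try:
            return -gaussian_marginal_loglik(beta0, Gamma, phi, Y, X, B)
        except np.linalg.LinAlgError:
            return 1e12

    rng = np.random.default_rng(seed)
    best = None
    for trial in range(3):
        x0 = np.concatenate(
            [
                Y.mean(axis=0),
                np.zeros(m * k),
                0.5 * rng.standard_normal(m * d),
                np.log(np.maximum(Y.var(axis=0), 1e-3)),
            ]
        )
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                options=dict(maxiter=5000, ftol=1e-13, gtol=1e-9))
        if best is None or res.fun < best.fun:
            best = res
    beta0, B, Gamma, phi = unpack(best.x)
    return dict(loglik=-best.fun, beta0=beta0, B=B, Gamma=Gamma, phi=phi)
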