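import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gllvmpy import (
    AbundanceData,
    LatentState,
    ModelSpec,
    ParameterSet,
    constrain_loadings,
    generate_parameters,
    linear_predictor,
    marginal_loglik_bruteforce,
    simulate_responses,
)
from gllvmpy.model_core import GAMMA_DIAG_FLOOR, ParameterMagnitudes, conditional_logpdf
from tests.conftest import gaussian_marginal_loglik


class TestLinearPredictor:
    def test_all_zero(self):
        spec = ModelSpec(family="poisson", n_lv=1)
        params = ParameterSet(beta0=np.zeros(2), Gamma=np.array([[1.0], [0.0]]))
        data = AbundanceData(Y=np.zeros((3, 2)), family="poisson")
        latent = LatentState(U=np.zeros((3, 1)))
        eta = linear_predictor(params, data, latent, spec)
        np.testing.assert_array_equal(eta, np.zeros((3, 2)))

    def test_hand_arithmetic_1x1(self):
        spec = ModelSpec(family="poisson", n_lv=1)
        params = ParameterSet(beta0=[0.5], Gamma=[[2.0]])
        data = AbundanceData(Y=np.zeros((1, 1)), family="poisson")
        latent = LatentState(U=[[1.0]])
        assert linear_predictor(params, data, latent, spec)[0, 0] == pytest.approx(2.5)

    def test_hand_arithmetic_with_covariate(self):
        spec = ModelSpec(family="poisson", n_lv=1)
        params = ParameterSet(
            beta0=[0.0, 1.0], B=[[1.0], [-1.0]], Gamma=[[1.0], [0.5]]
        )
        data = AbundanceData(Y=np.zeros((1, 2)), X=[[1.0]], family="poisson")
        latent = LatentState(U=[[2.0]])
        eta = linear_predictor(params, data, latent, spec)
        np.testing.assert_allclose(eta, [[3.0, 1.0]])

    def test_dimension_mismatch_names_axis(self):
        spec = ModelSpec(family="poisson", n_lv=1)
        params = ParameterSet(beta0=np.zeros(2), Gamma=[[1.0], [0.2]])
        data = AbundanceData(Y=np.zeros((3, 2)), family="poisson")
        latent = LatentState(U=np.zeros((4, 1)))
        with pytest.raises(ValueError, match="site axis"):
            linear_predictor(params, data, latent, spec)

    def test_affine_in_parameter_blocks(self, tiny_poisson):
        spec, params, data = (
            tiny_poisson["spec"], tiny_poisson["params"], tiny_poisson["data"],
        )
        latent = tiny_poisson["latent"]
        eta0 = linear_predictor(params, data, latent, spec)
        for t in [0.5, 2.0]:
            p2 = params.copy()
            p2.beta0 = params.beta0 * t
            eta_t = linear_predictor(p2, data, latent, spec)
            np.testing.assert_allclose(
                eta_t - eta0, (t - 1) * np.tile(params.beta0, (data.n, 1)), atol=1e-12
            )


class TestConditionalLogpdf:
    def test_poisson_zero(self):
        assert conditional_logpdf("poisson", "log", 0.0, 0.0) == pytest.approx(-1.0)

    def test_bernoulli_probit(self):
        assert conditional_logpdf("bernoulli", "probit", 1.0, 0.0) == pytest.approx(
            np.log(0.5)
        )

    def test_nb_against_independent_pmf(self):
        # oracle: textbook size/prob parameterization via scipy.stats.nbinom
        phi, eta, y = 0.5, 0.0, 3.0
        r = 1.0 / phi
        mu = np.exp(eta)
        oracle = stats.nbinom.logpmf(y, r, r / (r + mu))
        got = conditional_logpdf("negative_binomial", "log", y, eta, phi)
        assert got == pytest.approx(float(oracle), rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            conditional_logpdf("poisson", "log", -1.0, 0.0)
        with pytest.raises(ValueError):
            conditional_logpdf("poisson", "log", 1.0, np.inf)
        with pytest.raises(ValueError):
            conditional_logpdf("negative_binomial", "log", 1.0, 0.0, -0.5)


class TestBruteforceLikelihood:
    def test_gaussian_closed_form(self, small_gaussian):
        spec, params, data = (
            small_gaussian["spec"], small_gaussian["params"], small_gaussian["data"],
        )
        sub = AbundanceData(Y=data.Y[:6], family="gaussian")
        exact = gaussian_marginal_loglik(params.beta0, params.Gamma, params.phi, sub.Y)
        got = marginal_loglik_bruteforce(params, sub, spec, 80)
        assert got == pytest.approx(exact, abs=1e-6)

    def test_single_node_is_integrand_at_zero(self, tiny_poisson):
        spec, params, data = (
            tiny_poisson["spec"], tiny_poisson["params"], tiny_poisson["data"],
        )
        from gllvmpy.laplace import joint_logdensity

        latent0 = LatentState(U=np.zeros((data.n, 1)))
        total, _ = joint_logdensity(params, data, latent0, spec)
        got = marginal_loglik_bruteforce(params, data, spec, 1)
        # single Gauss-Hermite node: integrand at zero plus the normal constant
        assert got == pytest.approx(total + 0.5 * data.n * np.log(2 * np.pi), abs=1e-9)

    def test_quadrature_stabilizes(self, tiny_poisson):
        spec, params = tiny_poisson["spec"], tiny_poisson["params"]
        data, _ = simulate_responses(params, tiny_poisson["data"].X[:1], spec, 1, seed=5)
        v40 = marginal_loglik_bruteforce(params, data, spec, 40)
        v60 = marginal_loglik_bruteforce(params, data, spec, 60)
        assert abs(v40 - v60) < 1e-8

    def test_dimension_guard(self):
        spec = ModelSpec(family="poisson", n_lv=4)
        params = generate_parameters(6, 0, 4, spec, seed=0)
        data, _ = simulate_responses(params, None, spec, 2, seed=1)
        with pytest.raises(ValueError, match="infeasible"):
            marginal_loglik_bruteforce(params, data, spec, 5)


class TestSimulate:
    def test_determinism(self, tiny_poisson):
        spec, params = tiny_poisson["spec"], tiny_poisson["params"]
        X = tiny_poisson["data"].X
        d1, l1 = simulate_responses(params, X, spec, 4, seed=42)
        d2, l2 = simulate_responses(params, X, spec, 4, seed=42)
        np.testing.assert_array_equal(d1.Y, d2.Y)
        np.testing.assert_array_equal(l1.U, l2.U)

    def test_zero_loadings_independence(self):
        spec = ModelSpec(family="poisson", n_lv=1)
        Gamma = np.full((4, 1), GAMMA_DIAG_FLOOR)
        params = ParameterSet(beta0=np.full(4, 1.0), Gamma=Gamma)
        data, _ = simulate_responses(params, None, spec, 5000, seed=11)
        C = np.corrcoef(data.Y.T)
        off = C[np.triu_indices(4, k=1)]
        assert np.max(np.abs(off)) < 0.05

    def test_poisson_mean_clt(self):
        spec = ModelSpec(family="poisson", n_lv=1)
        params = ParameterSet(
            beta0=np.full(100, np.log(4.0)), Gamma=np.vstack([[GAMMA_DIAG_FLOOR], np.zeros((99, 1))])
        )
        data, _ = simulate_responses(params, None, spec, 100, seed=13)
        se = np.sqrt(4.0 / data.Y.size)
        assert abs(np.mean(data.Y) - 4.0) < 3 * se

    def test_row_effect_variance(self):
        spec = ModelSpec(family="poisson", n_lv=1, row_effect=True)
        params = generate_parameters(3, 0, 1, spec, seed=2)
        _, latent = simulate_responses(params, None, spec, 4000, seed=3)
        assert np.var(latent.alpha) == pytest.approx(params.sigma2, rel=0.15)


class TestGenerateParameters:
    def test_invariants_and_determinism(self):
        spec = ModelSpec(family="negative_binomial", n_lv=2, row_effect=True)
        p1 = generate_parameters(6, 2, 2, spec, seed=9)
        p2 = generate_parameters(6, 2, 2, spec, seed=9)
        p1.validate()
        np.testing.assert_array_equal(p1.Gamma, p2.Gamma)
        np.testing.assert_array_equal(p1.phi, p2.phi)

    def test_zero_magnitude_floor(self):
        spec = ModelSpec(family="poisson", n_lv=2)
        mags = ParameterMagnitudes(loading_scale=0.0)
        p = generate_parameters(5, 0, 2, spec, magnitudes=mags, seed=0)
        assert np.all(np.diag(p.Gamma[:2, :2]) >= GAMMA_DIAG_FLOOR)
        p.validate()

    def test_d_must_be_below_m(self):
        spec = ModelSpec(family="poisson", n_lv=3)
        with pytest.raises(ValueError, match="d must be"):
            generate_parameters(3, 0, 3, spec, seed=0)


class TestConstrainLoadings:
    def test_identity_case(self):
        G = np.array([[1.0, 0.0], [0.5, 2.0], [0.3, -0.4]])
        out, _ = constrain_loadings(G)
        np.testing.assert_allclose(out, G, atol=1e-12)

    def test_sign_flip(self):
        G = np.array([[-1.0, 0.0], [0.5, 2.0], [0.3, -0.4]])
        U = np.random.default_rng(0).standard_normal((5, 2))
        out, U2 = constrain_loadings(G, U)
        assert out[0, 0] > 0
        np.testing.assert_allclose(U @ G.T, U2 @ out.T, atol=1e-10)

    def test_product_preservation_random(self):
        rng = np.random.default_rng(4)
        G = rng.standard_normal((6, 2))
        U = rng.standard_normal((10, 2))
        G2, U2 = constrain_loadings(G, U)
        assert np.max(np.abs(U @ G.T - U2 @ G2.T)) < 1e-10
        ParameterSet(beta0=np.zeros(6), Gamma=G2).validate()

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        G, _ = constrain_loadings(rng.standard_normal((5, 2)))
        G2, _ = constrain_loadings(G)
        np.testing.assert_allclose(G, G2, atol=1e-10)

    def test_rank_deficient_rejected(self):
        G = np.ones((4, 2))
        with pytest.raises(ValueError, match="rank"):
            constrain_loadings(G)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.integers(2, 4), st.integers(1, 3))
    def test_product_preservation_property(self, seed, m_extra, d):
        m = d + m_extra
        rng = np.random.default_rng(seed)
        G = rng.standard_normal((m, d))
        U = rng.standard_normal((7, d))
        if np.linalg.matrix_rank(G) < d or np.min(
            np.abs(np.linalg.svd(G[:d], compute_uv=False))
        ) < 1e-3:
            return
        G2, U2 = constrain_loadings(G, U)
        assert np.max(np.abs(U @ G.T - U2 @ G2.T)) < 1e-8


def test_pmf_total_mass_grid():
    # conditional_logpdf sums to ~1 over the count support on an (eta, phi) grid
    from gllvmpy import get_family

    fam = get_family("negative_binomial")
    for eta in [-0.5, 0.5, 1.5]:
        for phi in [0.2, 1.0, 3.0]:
            ymax = int(60 * np.exp(eta) * (1 + phi) + 400)
            y = np.arange(ymax + 1.0)
            total = np.sum(np.exp(fam.logpdf(y, eta, phi)))
            assert 1 - 1e-8 <= total <= 1 + 1e-8


def test_abundance_validation():
    with pytest.raises(ValueError, match="non-negative"):
        AbundanceData(Y=np.array([[1.0, -2.0]]), family="poisson")
    with pytest.raises(ValueError, match="0 or 1"):
        AbundanceData(Y=np.array([[2.0, 0.0]]), family="bernoulli")
    with pytest.raises(ValueError, match="site axis"):
        AbundanceData(Y=np.zeros((3, 2)), X=np.zeros((4, 1)), family="poisson")
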