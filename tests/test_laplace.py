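import numpy as np
import pytest

from gllvmpy import (
    AbundanceData,
    FitControl,
    LatentState,
    ModelSpec,
    ParameterSet,
    fit_model,
    generate_parameters,
    la_loglik,
    marginal_loglik_bruteforce,
    simulate_responses,
)
from gllvmpy._numdiff import central_gradient, hessian_from_fun
from gllvmpy.laplace import G_matrix, inner_maximize, joint_logdensity, _newton_all
from gllvmpy.starting_values import make_start
from gllvmpy.variational import fit_va
from tests.conftest import fit_gaussian_factor_oracle


class TestJointLogdensity:
    def test_decomposition_at_zero(self, tiny_poisson):
        spec, params, data = (
            tiny_poisson["spec"], tiny_poisson["params"], tiny_poisson["data"],
        )
        from gllvmpy.model_core import conditional_logpdf, linear_predictor

        latent0 = LatentState(U=np.zeros((data.n, 1)))
        total, per_site = joint_logdensity(params, data, latent0, spec)
        eta = linear_predictor(params, data, latent0, spec)
        want = (
            conditional_logpdf(spec.family, spec.link, data.Y, eta).sum()
            - 0.5 * data.n * np.log(2 * np.pi)
        )
        assert total == pytest.approx(float(want), rel=1e-12)
        assert per_site.shape == (data.n,)

    def test_gradient_in_latents(self, tiny_poisson):
        spec, params, data = (
            tiny_poisson["spec"], tiny_poisson["params"], tiny_poisson["data"],
        )
        rng = np.random.default_rng(0)
        for _ in range(20):
            u = rng.standard_normal((data.n, 1))

            def f(uflat):
                lat = LatentState(U=uflat.reshape(data.n, 1))
                return joint_logdensity(params, data, lat, spec)[0]

            fam = spec.family_obj()
            from gllvmpy.laplace import _model_arrays

            _, Gstar, c, fixed, phi = _model_arrays(params, data, spec)
            eta = fixed + u @ Gstar.T
            analytic = (fam.d1(data.Y, eta, phi) @ Gstar - u / c).ravel()
            fd = central_gradient(f, u.ravel(), 1e-6)
            np.testing.assert_allclose(analytic, fd, rtol=1e-5, atol=1e-6)


class TestInnerMaximize:
    def test_gaussian_closed_form_mode(self, small_gaussian):
        spec, params, data = (
            small_gaussian["spec"], small_gaussian["params"], small_gaussian["data"],
        )
        i = 3
        u_hat = inner_maximize(params, data, spec, i)
        Sigma_inv = np.diag(1.0 / params.phi)
        G = params.Gamma
        M = G.T @ Sigma_inv @ G + np.eye(1)
        closed = np.linalg.solve(M, G.T @ Sigma_inv @ (data.Y[i] - params.beta0))
        np.testing.assert_allclose(u_hat, closed, atol=1e-8)

    def test_symmetric_stationarity(self):
        spec = ModelSpec(family="poisson", n_lv=1)
        params = ParameterSet(beta0=np.zeros(2), Gamma=np.array([[1.0], [-1.0]]))
        # y at the family mean for u=0: exp(0)=1
        data = AbundanceData(Y=np.ones((1, 2)), family="poisson")
        u_hat = inner_maximize(params, data, spec, 0)
        assert abs(u_hat[0]) < 1e-8

    def test_independence_of_start(self, tiny_poisson):
        spec, params, data = (
            tiny_poisson["spec"], tiny_poisson["params"], tiny_poisson["data"],
        )
        rng = np.random.default_rng(1)
        sols = [
            inner_maximize(params, data, spec, 2, u_init=3 * rng.standard_normal(1))
            for _ in range(10)
        ]
        sols = np.array(sols)
        assert np.max(np.abs(sols - sols[0])) < 1e-6


class TestGMatrix:
    def test_poisson_canonical_curvature(self, tiny_poisson):
        spec, params, data = (
            tiny_poisson["spec"], tiny_poisson["params"], tiny_poisson["data"],
        )
        u_hat = inner_maximize(params, data, spec, 0)
        G = G_matrix(params, data, spec, 0, u_hat)
        from gllvmpy.laplace import _model_arrays

        _, Gstar, c, fixed, phi = _model_arrays(params, data, spec)
        eta = fixed[0] + Gstar @ u_hat
        want = np.sum(np.exp(eta) * Gstar[:, 0] ** 2) + 1.0
        assert G[0, 0] == pytest.approx(float(want), rel=1e-12)

    def test_prior_curvature_only(self):
        spec = ModelSpec(family="poisson", n_lv=2)
        Gamma = np.zeros((3, 2))
        Gamma[0, 0] = Gamma[1, 1] = 1e-4
        params = ParameterSet(beta0=np.zeros(3), Gamma=Gamma)
        data = AbundanceData(Y=np.zeros((1, 3)), family="poisson")
        G = G_matrix(params, data, spec, 0, np.zeros(2))
        np.testing.assert_allclose(G, np.eye(2), atol=1e-6)

    def test_matches_fd_hessian_of_joint(self, tiny_poisson):
        spec, params, data = (
            tiny_poisson["spec"], tiny_poisson["params"], tiny_poisson["data"],
        )
        i = 1
        u_hat = inner_maximize(params, data, spec, i)
        G = G_matrix(params, data, spec, i, u_hat)

        def f(u):
            U = np.zeros((data.n, 1))
            U[i] = u
            lat = LatentState(U=U)
            return joint_logdensity(params, data, lat, spec)[1][i]

        H = hessian_from_fun(f, u_hat, step=1e-4)
        np.testing.assert_allclose(G, -H, rtol=1e-5, atol=1e-5)


class TestLaLoglik:
    def test_gaussian_exact(self, small_gaussian):
        spec, params, data = (
            small_gaussian["spec"], small_gaussian["params"], small_gaussian["data"],
        )
        from tests.conftest import gaussian_marginal_loglik

        exact = gaussian_marginal_loglik(params.beta0, params.Gamma, params.phi, data.Y)
        assert la_loglik(params, data, spec) == pytest.approx(exact, abs=1e-6)

    def test_poisson_gap_small_and_shrinking_in_m(self):
        spec = ModelSpec(family="poisson", n_lv=1)
        rng = np.random.default_rng(8)
        gaps = {}
        for m in (3, 12):
            reps = 4  # replicate the m=3 species layout to m=12
            beta0 = np.tile(np.array([0.2, -0.1, 0.4]), m // 3)
            Gamma = np.tile(np.array([[0.8], [0.5], [-0.6]]), (m // 3, 1))
            Gamma[0, 0] = abs(Gamma[0, 0])
            params = ParameterSet(beta0=beta0, Gamma=Gamma)
            data, _ = simulate_responses(params, None, spec, 2, seed=9)
            gap = abs(
                la_loglik(params, data, spec)
                - marginal_loglik_bruteforce(params, data, spec, 60)
            ) / data.n
            gaps[m] = gap
        assert gaps[3] < 0.05
        assert gaps[12] < gaps[3]

    def test_species_permutation_invariance(self):
        spec = ModelSpec(family="poisson", n_lv=1)
        params = ParameterSet(
            beta0=np.array([0.1, -0.2, 0.5, 0.0]),
            Gamma=np.array([[0.7], [0.4], [0.9], [0.2]]),  # all positive: any
            # permutation keeps the constraint valid
        )
        data, _ = simulate_responses(params, None, spec, 3, seed=10)
        perm = np.array([2, 0, 3, 1])
        params_p = ParameterSet(beta0=params.beta0[perm], Gamma=params.Gamma[perm])
        data_p = AbundanceData(Y=data.Y[:, perm], family="poisson")
        assert la_loglik(params, data, spec) == pytest.approx(
            la_loglik(params_p, data_p, spec), rel=1e-10
        )

    def test_mode_close_to_posterior_mean(self, tiny_poisson):
        # on log-concave poisson instances the Laplace mode should track the
        # quadrature posterior mean closely
        spec, params, data = (
            tiny_poisson["spec"], tiny_poisson["params"], tiny_poisson["data"],
        )
        _, U, _, _ = la_loglik(params, data, spec, return_state=True)
        x, w = np.polynomial.hermite.hermgauss(60)
        fam = spec.family_obj()
        from gllvmpy.laplace import _model_arrays

        _, Gstar, c, fixed, phi = _model_arrays(params, data, spec)
        for i in range(data.n):
            u = np.sqrt(2.0) * x
            ll = fam.logpdf(data.Y[i][None, :], fixed[i][None, :] + u[:, None] @ Gstar.T[:1, :].reshape(1, -1), phi).sum(axis=1)
            wgt = w * np.exp(ll - ll.max())
            post_mean = np.sum(wgt * u) / np.sum(wgt)
            assert abs(U[i, 0] - post_mean) < 0.1


class TestFitLa:
    def test_gaussian_objective_matches_va_and_oracle(self, small_gaussian):
        spec, data = small_gaussian["spec"], small_gaussian["data"]
        sv = make_start(data, spec, "res", seed=0)[0]
        ctl = FitControl(ftol=1e-12)
        fl = fit_model(data, spec, method="la", start="res", seed=0, control=ctl)
        fv = fit_va(data, spec, sv, ctl)
        assert fl.objective == pytest.approx(fv.objective, abs=1e-4)
        oracle = fit_gaussian_factor_oracle(data.Y, d=1, seed=0)
        assert fl.objective == pytest.approx(oracle["loglik"], abs=1e-4)

    def test_ascent_contract(self, small_gaussian):
        spec, data = small_gaussian["spec"], small_gaussian["data"]
        fit = fit_model(data, spec, method="la", start="res", seed=0)
        assert fit.objective >= fit.start_objective - 1e-9

    def test_inner_modes_interior(self, small_gaussian):
        spec, data = small_gaussian["spec"], small_gaussian["data"]
        fit = fit_model(data, spec, method="la", start="res", seed=0)
        # every inner solution is an interior maximizer: gradient ~ 0
        ll, U, G, _ = la_loglik(
            fit.params, data, spec,
            warm_starts=fit.latents_hat.ustar(), return_state=True,
        )
        assert ll == pytest.approx(fit.objective, abs=1e-8)

    def test_fd_gradient_consistency(self, tiny_poisson):
        # directional-derivative (Richardson) check of the FD outer gradient
        spec, data = tiny_poisson["spec"], tiny_poisson["data"]
        from gllvmpy.laplace import _LAObjective
        from gllvmpy.packing import ParamPacker

        packer = ParamPacker.for_spec(data.n, data.m, data.k, spec)
        obj = _LAObjective(data, spec, packer, FitControl())
        x = packer.pack(tiny_poisson["params"])
        g = obj.grad(x)
        rng = np.random.default_rng(2)
        v = rng.standard_normal(x.size)
        v /= np.linalg.norm(v)
        for h in (1e-4, 1e-5):
            dd = (obj.value(x + h * v) - obj.value(x - h * v)) / (2 * h)
            assert dd == pytest.approx(float(g @ v), rel=1e-4, abs=1e-6)

    def test_nb_parameter_recovery(self):
        spec = ModelSpec(family="negative_binomial", n_lv=1)
        truth = generate_parameters(15, 0, 1, spec, seed=11)
        biases = []
        for rep in range(8):
            data, _ = simulate_responses(truth, None, spec, 200, seed=400 + rep)
            fit = fit_model(data, spec, method="la", start="res", seed=rep)
            biases.append(np.abs(fit.params.beta0 - truth.beta0))
        assert np.median(np.concatenate(biases)) < 0.1
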