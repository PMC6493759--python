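"""Data-driven starting values.

Four strategies are provided:

``res``
    Fit an independent GLM per species, compute randomized-quantile
    (Dunn-Smyth) residuals from the fitted distribution functions, and run a
    factor analysis on the residual matrix to initialize latent variables and
    loadings.  Row effects start at zero.
``res3``
    Multi-start variant of ``res``: the latent starting values are jittered
    with independent normal noise (default sd 0.2) to produce several sets;
    the fixed parameters, loadings and dispersions are shared across sets.
``zero``
    All parameters at zero apart from the constraint floors on the loading
    diagonal and unit dispersions.
``random``
    Latent variables drawn from a standard normal; fixed effects and
    loadings from per-species GLMs on the covariates and the drawn latents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import optimize, stats

from .model_core import (
    GAMMA_DIAG_FLOOR,
    PHI_FLOOR,
    SIGMA2_FLOOR,
    AbundanceData,
    LatentState,
    ModelSpec,
    ParameterSet,
    constrain_loadings,
)
from .variational import VariationalState

__all__ = [
    "StartingValues",
    "GLMStart",
    "fit_marginal_glms",
    "dunn_smyth_residuals",
    "residual_factor_analysis",
    "make_start",
]

_START_SIGMA2 = 0.25
_VA_COV_SCALE = 0.1


@dataclass
class StartingValues:
    params0: ParameterSet
    latents0: LatentState
    varstate0: Optional[VariationalState] = None
    label: str = "res"
    set_index: int = 0


@dataclass
class GLMStart:
    """Per-species marginal GLM fits and the induced distribution functions."""

    beta0: np.ndarray
    B: Optional[np.ndarray]
    phi: Optional[np.ndarray]
    cdf: np.ndarray  # F_ij(y_ij)
    cdf_left: np.ndarray  # F_ij(y_ij-)
    fallback: np.ndarray  # species flagged as intercept-only fallbacks


def _design(data: AbundanceData, extra: Optional[np.ndarray] = None) -> np.ndarray:
    cols = [np.ones((data.n, 1))]
    if data.X is not None:
        cols.append(data.X)
    if extra is not None:
        cols.append(extra)
    return np.hstack(cols)


def _nb_profile_phi(y, mu):
    """ML dispersion for fixed means, by 1-d search on the log scale."""
    from .families import get_family

    fam = get_family("negative_binomial")

    def nll(logphi):
        return -float(np.sum(fam.logpdf(y, np.log(np.maximum(mu, 1e-10)), np.exp(logphi))))

    res = optimize.minimize_scalar(nll, bounds=(-12.0, 6.0), method="bounded")
    return float(np.exp(res.x))


def _fit_one_glm(y, exog, spec: ModelSpec):
    """Fit one species' GLM; returns (coefs, phi, ok_flag)."""
    import statsmodels.api as sm

    fam_name, link = spec.family, spec.link
    ncoef = exog.shape[1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if fam_name == "poisson":
                fit = sm.GLM(y, exog, family=sm.families.Poisson()).fit()
                return np.asarray(fit.params), None, True
            if fam_name == "gaussian":
                fit = sm.OLS(y, exog).fit()
                phi = float(np.mean(fit.resid**2))
                return np.asarray(fit.params), max(phi, PHI_FLOOR), True
            if fam_name == "bernoulli":
                if y.min() == y.max():
                    raise ValueError("degenerate binary column")
                linkobj = (
                    sm.families.links.Probit() if link == "probit" else sm.families.links.Logit()
                )
                fit = sm.GLM(y, exog, family=sm.families.Binomial(link=linkobj)).fit()
                if np.max(np.abs(fit.params)) > 30:
                    raise ValueError("separation")
                return np.asarray(fit.params), None, True
            # negative binomial: joint ML over coefficients and dispersion
            from statsmodels.discrete.discrete_model import NegativeBinomial

            nbfit = NegativeBinomial(y, exog, loglike_method="nb2").fit(
                disp=0, maxiter=200
            )
            coefs = np.asarray(nbfit.params[:ncoef])
            alpha = float(nbfit.params[-1])
            if not np.all(np.isfinite(coefs)) or not np.isfinite(alpha) or alpha <= 0:
                raise ValueError("NB ML failed")
            return coefs, max(alpha, PHI_FLOOR), True
    except Exception:
        pass
    # Fallbacks keep the pipeline alive for degenerate columns.
    if fam_name == "negative_binomial":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(y, exog, family=sm.families.Poisson()).fit()
            coefs = np.asarray(fit.params)
            phi = _nb_profile_phi(y, fit.fittedvalues)
            return coefs, max(phi, PHI_FLOOR), True
        except Exception:
            pass
    n = y.shape[0]
    coefs = np.zeros(ncoef)
    if fam_name == "bernoulli":
        p = np.clip(np.mean(y), 0.5 / n, 1.0 - 0.5 / n)
        coefs[0] = stats.norm.ppf(p) if link == "probit" else np.log(p / (1 - p))
        return coefs, None, False
    if fam_name == "gaussian":
        coefs[0] = float(np.mean(y))
        return coefs, max(float(np.var(y)), PHI_FLOOR), False
    mean = max(float(np.mean(y)), 0.5 / n)
    coefs[0] = np.log(mean)
    phi = 1.0 if fam_name == "negative_binomial" else None
    return coefs, phi, False


def fit_marginal_glms(
    data: AbundanceData,
    spec: ModelSpec,
    extra_covariates: Optional[np.ndarray] = None,
) -> GLMStart:
    """Independent per-species GLM fits plus fitted distribution functions."""
    fam = spec.family_obj()
    exog = _design(data, extra_covariates)
    m = data.m
    ncoef = exog.shape[1]
    coefs = np.zeros((m, ncoef))
    phi = np.ones(m) if fam.has_dispersion else None
    fallback = np.zeros(m, dtype=bool)
    for j in range(m):
        cj, pj, ok = _fit_one_glm(data.Y[:, j], exog, spec)
        coefs[j] = cj
        if fam.has_dispersion:
            phi[j] = pj
        fallback[j] = not ok
    eta = exog @ coefs.T
    phi_row = phi[None, :] if fam.has_dispersion else None
    cdf = fam.cdf(data.Y, eta, phi_row)
    cdf_left = fam.cdf_left(data.Y, eta, phi_row)
    k = data.k
    B = coefs[:, 1 : 1 + k] if k > 0 else None
    return GLMStart(
        beta0=coefs[:, 0].copy(),
        B=B,
        phi=phi,
        cdf=np.asarray(cdf, dtype=float),
        cdf_left=np.asarray(cdf_left, dtype=float),
        fallback=fallback,
    )


def dunn_smyth_residuals(Y, cdf, cdf_left, seed: int) -> np.ndarray:
    """Randomized quantile residuals
    r_ij = Phi^-1( z_ij F(y_ij) + (1 - z_ij) F(y_ij-) ), z ~ U(0, 1)."""
    rng = np.random.default_rng(seed)
    z = rng.uniform(size=np.shape(Y))
    arg = z * np.asarray(cdf) + (1.0 - z) * np.asarray(cdf_left)
    arg = np.clip(arg, 1e-10, 1.0 - 1e-10)
    return stats.norm.ppf(arg)


def residual_factor_analysis(R: np.ndarray, d: int):
    """Factor-analyze a residual matrix; returns constrained (U0, Gamma0).

    Maximum-likelihood factor analysis with regression-method scores; falls
    back to a truncated SVD when the residual matrix is (numerically) of rank
    <= d or when the ML fit degenerates.
    """
    R = np.asarray(R, dtype=float)
    n, m = R.shape
    if not (0 < d < min(n, m)):
        raise ValueError("factor dimension must satisfy 0 < d < min(n, m)")
    if not np.all(np.isfinite(R)):
        raise ValueError("residual matrix contains non-finite entries")
    mu = R.mean(axis=0)
    Rc = R - mu
    sv = np.linalg.svd(Rc, compute_uv=False)
    noise_frac = np.sum(sv[d:] ** 2) / max(np.sum(sv**2), 1e-300)
    U0 = Gamma0 = None
    if noise_frac > 1e-12:
        try:
            from sklearn.decomposition import FactorAnalysis

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fa = FactorAnalysis(n_components=d, svd_method="lapack", max_iter=1000)
                scores = fa.fit_transform(R)
            loadings = fa.components_.T
            if (
                np.all(np.isfinite(scores))
                and np.all(np.isfinite(loadings))
                and np.linalg.matrix_rank(loadings) == d
            ):
                U0, Gamma0 = scores, loadings
        except Exception:
            U0 = Gamma0 = None
    if U0 is None:
        W, s, Vt = np.linalg.svd(Rc, full_matrices=False)
        U0 = np.sqrt(n) * W[:, :d]
        Gamma0 = (Vt[:d].T * s[:d]) / np.sqrt(n)
    Gamma0, U0 = constrain_loadings(Gamma0, U0)
    return U0, Gamma0


def _zero_params(data: AbundanceData, spec: ModelSpec) -> ParameterSet:
    fam = spec.family_obj()
    m, k, d = data.m, data.k, spec.n_lv
    Gamma = np.zeros((m, d))
    Gamma[np.arange(d), np.arange(d)] = GAMMA_DIAG_FLOOR
    return ParameterSet(
        beta0=np.zeros(m),
        B=np.zeros((m, k)) if k > 0 else None,
        Gamma=Gamma,
        phi=np.ones(m) if fam.has_dispersion else None,
        sigma2=SIGMA2_FLOOR if spec.row_effect else None,
    )


def _assemble(data, spec, params, U, label, set_index):
    alpha = np.zeros(data.n) if spec.row_effect else None
    latents = LatentState(U=U, alpha=alpha)
    varstate = VariationalState.from_means(latents.ustar(), scale=_VA_COV_SCALE)
    return StartingValues(
        params0=params.validate(),
        latents0=latents,
        varstate0=varstate,
        label=label,
        set_index=set_index,
    )


def make_start(
    data: AbundanceData,
    spec: ModelSpec,
    method: str = "res",
    n_sets: int = 3,
    jitter_sd: float = 0.2,
    seed: int = 0,
) -> List[StartingValues]:
    """Construct one or more sets of starting values."""
    if method not in ("res", "res3", "zero", "random"):
        raise ValueError(f"unknown starting-value method {method!r}")
    d = spec.n_lv
    rng = np.random.default_rng(seed)

    if method == "zero":
        params = _zero_params(data, spec)
        return [_assemble(data, spec, params, np.zeros((data.n, d)), "zero", 0)]

    if method == "random":
        U = rng.standard_normal((data.n, d))
        # one pass: per-species GLM on [1, X, U]; the trailing d coefficients
        # are raw loadings, rotated (with U) onto the constrained form
        exog = _design(data, U)
        fam = spec.family_obj()
        m, k = data.m, data.k
        coefs = np.zeros((m, exog.shape[1]))
        phi = np.ones(m) if fam.has_dispersion else None
        for j in range(m):
            cj, pj, ok = _fit_one_glm(data.Y[:, j], exog, spec)
            coefs[j] = cj
            if fam.has_dispersion:
                phi[j] = pj
        Gamma_raw = coefs[:, 1 + k :]
        if np.linalg.matrix_rank(Gamma_raw) < d:
            Gamma_raw = Gamma_raw + 1e-3 * np.eye(m, d)
        Gamma0, U0 = constrain_loadings(Gamma_raw, U)
        params = ParameterSet(
            beta0=coefs[:, 0],
            B=coefs[:, 1 : 1 + k] if k > 0 else None,
            Gamma=Gamma0,
            phi=phi,
            sigma2=_START_SIGMA2 if spec.row_effect else None,
        )
        return [_assemble(data, spec, params, U0, "random", 0)]

    # res / res3
    glms = fit_marginal_glms(data, spec)
    ds_seed = int(rng.integers(0, 2**31 - 1))
    R = dunn_smyth_residuals(data.Y, glms.cdf, glms.cdf_left, seed=ds_seed)
    U0, Gamma0 = residual_factor_analysis(R, d)
    beta0 = glms.beta0
    if spec.link == "log":
        # the marginal GLM intercept absorbs the latent variance
        # (E[y] = exp(beta0 + gamma' gamma / 2)); remove it so the latent
        # term is not double counted at the start
        SU = np.atleast_2d(np.cov(U0.T))
        beta0 = beta0 - 0.5 * np.einsum("jp,pq,jq->j", Gamma0, SU, Gamma0)
    params = ParameterSet(
        beta0=beta0,
        B=glms.B,
        Gamma=Gamma0,
        phi=glms.phi,
        sigma2=_START_SIGMA2 if spec.row_effect else None,
    )
    if method == "res":
        return [_assemble(data, spec, params, U0, "res", 0)]
    sets = []
    for s in range(max(1, n_sets)):
        Uj = U0 + rng.normal(0.0, jitter_sd, size=U0.shape)
        sets.append(_assemble(data, spec, params.copy(), Uj, "res3", s))
    return sets
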