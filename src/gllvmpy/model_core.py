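"""Model definition: data containers, linear predictor, identifiability
constraints, a brute-force quadrature likelihood (test oracle), and the
simulator.

The model regresses each of m response variables (species) at each of n sites
on k observed covariates plus d shared latent site scores:

    g(mu_ij) = eta_ij = alpha_i + beta0_j + x_i' beta_j + u_i' gamma_j

with u_i ~ N_d(0, I) and, optionally, a random row intercept
alpha_i ~ N(0, sigma2).  The augmented latent vector is
u*_i = (alpha_i, u_i')' with loadings gamma*_j = (1, gamma_j')' and prior
covariance C = bdiag(sigma2, I_d).  For identifiability the loading matrix
Gamma is constrained to have a zero upper triangle and a positive diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .families import Family, get_family

__all__ = [
    "AbundanceData",
    "ModelSpec",
    "ParameterSet",
    "LatentState",
    "ParameterMagnitudes",
    "linear_predictor",
    "conditional_logpdf",
    "marginal_loglik_bruteforce",
    "simulate_responses",
    "generate_parameters",
    "constrain_loadings",
    "GAMMA_DIAG_FLOOR",
    "PHI_FLOOR",
    "SIGMA2_FLOOR",
]

# Floors keeping the log-parameterizations finite.
GAMMA_DIAG_FLOOR = 1e-4
PHI_FLOOR = 1e-6
SIGMA2_FLOOR = 1e-6


@dataclass
class ModelSpec:
    """Configuration of the latent-variable model."""

    family: str = "poisson"
    link: Optional[str] = None
    n_lv: int = 2
    row_effect: bool = False

    def __post_init__(self):
        fam = get_family(self.family, self.link)
        self.family = fam.name
        self.link = fam.link
        if self.n_lv < 1:
            raise ValueError("n_lv must be >= 1")

    def family_obj(self) -> Family:
        return get_family(self.family, self.link)

    @property
    def d(self) -> int:
        return self.n_lv

    def latent_dim(self) -> int:
        """Dimension of the augmented latent vector u*_i."""
        return self.n_lv + (1 if self.row_effect else 0)


@dataclass
class AbundanceData:
    """Site x species response matrix with optional site covariates."""

    Y: np.ndarray
    X: Optional[np.ndarray] = None
    family: str = "poisson"
    link: Optional[str] = None
    site_ids: Optional[list] = None
    species_names: Optional[list] = None

    def __post_init__(self):
        fam = get_family(self.family, self.link)
        self.family = fam.name
        self.link = fam.link
        self.Y = fam.validate_y(np.asarray(self.Y, dtype=float))
        if self.Y.ndim != 2:
            raise ValueError("Y must be a 2-d (sites x species) matrix")
        if self.X is not None:
            self.X = np.asarray(self.X, dtype=float)
            if self.X.ndim != 2:
                raise ValueError("X must be a 2-d (sites x covariates) matrix")
            if self.X.shape[0] != self.Y.shape[0]:
                raise ValueError(
                    f"covariate rows ({self.X.shape[0]}) do not match "
                    f"response rows ({self.Y.shape[0]}) along the site axis"
                )
            if not np.all(np.isfinite(self.X)):
                raise ValueError("X contains non-finite entries")

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def m(self) -> int:
        return self.Y.shape[1]

    @property
    def k(self) -> int:
        return 0 if self.X is None else self.X.shape[1]


@dataclass
class ParameterSet:
    """All model parameters: intercepts, covariate coefficients, loadings,
    dispersions and the row-effect variance."""

    beta0: np.ndarray
    B: Optional[np.ndarray] = None
    Gamma: np.ndarray = None
    phi: Optional[np.ndarray] = None
    sigma2: Optional[float] = None

    def __post_init__(self):
        self.beta0 = np.atleast_1d(np.asarray(self.beta0, dtype=float))
        if self.Gamma is None:
            raise ValueError("Gamma is required")
        self.Gamma = np.atleast_2d(np.asarray(self.Gamma, dtype=float))
        if self.B is not None:
            self.B = np.asarray(self.B, dtype=float)
            if self.B.size == 0:
                self.B = None
            else:
                self.B = np.atleast_2d(self.B)
        if self.phi is not None:
            self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))

    @property
    def m(self) -> int:
        return self.beta0.shape[0]

    @property
    def d(self) -> int:
        return self.Gamma.shape[1]

    @property
    def k(self) -> int:
        return 0 if self.B is None else self.B.shape[1]

    def validate(self):
        m, d = self.Gamma.shape
        if m != self.m:
            raise ValueError("Gamma row count does not match beta0 length")
        iu = np.triu_indices(min(m, d), k=1, m=d)
        upper = self.Gamma[: min(m, d)][iu]
        if upper.size and np.max(np.abs(upper)) > 0:
            raise ValueError("Gamma upper triangle must be zero")
        diag = np.diag(self.Gamma[:d, :d])
        if np.any(diag <= 0):
            raise ValueError("Gamma diagonal entries must be positive")
        if self.phi is not None and np.any(self.phi <= 0):
            raise ValueError("phi must be positive")
        if self.sigma2 is not None and self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        return self

    def gamma_star(self, row_effect: bool) -> np.ndarray:
        """Augmented loadings gamma*_j = (1, gamma_j')' as an (m, p) array."""
        if row_effect:
            return np.hstack([np.ones((self.m, 1)), self.Gamma])
        return self.Gamma

    def c_diag(self, row_effect: bool) -> np.ndarray:
        """Diagonal of the prior covariance C = bdiag(sigma2, I_d)."""
        if row_effect:
            if self.sigma2 is None:
                raise ValueError("row_effect model requires sigma2")
            return np.concatenate([[float(self.sigma2)], np.ones(self.d)])
        return np.ones(self.d)

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            beta0=self.beta0.copy(),
            B=None if self.B is None else self.B.copy(),
            Gamma=self.Gamma.copy(),
            phi=None if self.phi is None else self.phi.copy(),
            sigma2=self.sigma2,
        )


@dataclass
class LatentState:
    """Latent-variable values: site scores U and optional row effects."""

    U: np.ndarray
    alpha: Optional[np.ndarray] = None

    def __post_init__(self):
        self.U = np.atleast_2d(np.asarray(self.U, dtype=float))
        if self.alpha is not None:
            self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
            if self.alpha.shape[0] != self.U.shape[0]:
                raise ValueError("alpha length does not match U rows (site axis)")
        if not np.all(np.isfinite(self.U)):
            raise ValueError("latent values must be finite")

    @property
    def n(self) -> int:
        return self.U.shape[0]

    @property
    def d(self) -> int:
        return self.U.shape[1]

    def ustar(self) -> np.ndarray:
        """Augmented latent matrix, (n, d+1) when row effects are present."""
        if self.alpha is not None:
            return np.hstack([self.alpha[:, None], self.U])
        return self.U

    @staticmethod
    def from_ustar(Ustar: np.ndarray, row_effect: bool) -> "LatentState":
        Ustar = np.atleast_2d(Ustar)
        if row_effect:
            return LatentState(U=Ustar[:, 1:], alpha=Ustar[:, 0])
        return LatentState(U=Ustar)


def linear_predictor(
    params: ParameterSet,
    data: AbundanceData,
    latent: LatentState,
    spec: ModelSpec,
) -> np.ndarray:
    """eta_ij = alpha_i + beta0_j + x_i' beta_j + u_i' gamma_j, an (n, m) array."""
    params.validate()
    n, m = data.n, data.m
    if params.m != m:
        raise ValueError(
            f"parameter species dimension ({params.m}) does not match data ({m}) "
            "along the species axis"
        )
    if latent.n != n:
        raise ValueError(
            f"latent site dimension ({latent.n}) does not match data ({n}) "
            "along the site axis"
        )
    if latent.d != params.d:
        raise ValueError(
            f"latent dimension ({latent.d}) does not match loadings ({params.d})"
        )
    eta = np.tile(params.beta0, (n, 1))
    if data.X is not None and params.B is not None:
        if params.B.shape[1] != data.k:
            raise ValueError(
                f"coefficient columns ({params.B.shape[1]}) do not match "
                f"covariates ({data.k}) along the covariate axis"
            )
        eta = eta + data.X @ params.B.T
    eta = eta + latent.U @ params.Gamma.T
    if spec.row_effect:
        if latent.alpha is None:
            raise ValueError("row_effect model requires latent.alpha")
        eta = eta + latent.alpha[:, None]
    return eta


def conditional_logpdf(family, link, y, eta, phi=None):
    """log f(y | eta) for the given family, elementwise."""
    fam = get_family(family, link) if isinstance(family, str) else family
    y = np.asarray(y, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta contains non-finite entries")
    if fam.has_dispersion:
        if phi is None:
            raise ValueError(f"{fam.name} requires a dispersion parameter")
        phi = np.asarray(phi, dtype=float)
        if np.any(phi <= 0):
            raise ValueError("phi must be positive")
    fam.validate_y(y)
    return fam.logpdf(y, eta, phi)


def _phi_row(params: ParameterSet, fam: Family):
    if not fam.has_dispersion:
        return None
    if params.phi is None:
        raise ValueError(f"{fam.name} requires dispersion parameters phi")
    return params.phi[None, :]


def marginal_loglik_bruteforce(
    params: ParameterSet,
    data: AbundanceData,
    spec: ModelSpec,
    quad_points: int = 40,
) -> float:
    """Marginal log-likelihood by tensor-product Gauss-Hermite quadrature.

    This is the slow, direct evaluation of the latent-variable integral,
    feasible only for small latent dimension; it serves as the independent
    oracle against which the Laplace and variational objectives are checked.
    """
    if quad_points < 1:
        raise ValueError("quad_points must be >= 1")
    p = spec.latent_dim()
    if p > 3:
        raise ValueError(f"tensor quadrature infeasible for latent dimension {p}")
    params.validate()
    fam = spec.family_obj()
    phi = _phi_row(params, fam)
    x, w = np.polynomial.hermite.hermgauss(quad_points)
    grids = np.meshgrid(*([x] * p), indexing="ij")
    nodes = np.stack([g.ravel() for g in grids], axis=1)  # (Knodes, p)
    logw = np.sum(
        np.stack(np.meshgrid(*([np.log(w)] * p), indexing="ij"), axis=0).reshape(p, -1),
        axis=0,
    )
    # u* = sqrt(2) * C^{1/2} x; the Jacobian cancels the normal constant so
    # that integral f(y|u) N(u; 0, C) du = pi^{-p/2} sum_k w_k f(y | u_k).
    c_sqrt = np.sqrt(params.c_diag(spec.row_effect))
    ustar = np.sqrt(2.0) * nodes * c_sqrt[None, :]
    Gstar = params.gamma_star(spec.row_effect)  # (m, p)
    fixed = np.tile(params.beta0, (data.n, 1))
    if data.X is not None and params.B is not None:
        fixed = fixed + data.X @ params.B.T
    total = 0.0
    for i in range(data.n):
        eta = fixed[i][None, :] + ustar @ Gstar.T  # (Knodes, m)
        ll = fam.logpdf(data.Y[i][None, :], eta, phi)
        total += logsumexp(logw + ll.sum(axis=1)) - 0.5 * p * np.log(np.pi)
    return float(total)


def simulate_responses(
    params: ParameterSet,
    X: Optional[np.ndarray],
    spec: ModelSpec,
    n: int,
    seed: int,
):
    """Draw latent variables and responses from the model.

    Returns ``(data, latent)`` where ``latent`` holds the generating latent
    values.  A fixed seed yields bitwise-identical output.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    d = params.d
    U = rng.standard_normal((n, d))
    alpha = None
    if spec.row_effect:
        if params.sigma2 is None:
            raise ValueError("row_effect model requires sigma2")
        alpha = rng.normal(0.0, np.sqrt(params.sigma2), size=n)
    latent = LatentState(U=U, alpha=alpha)
    fam = spec.family_obj()
    data_stub = AbundanceData(
        Y=np.zeros((n, params.m)), X=X, family="gaussian", link="identity"
    )
    eta = linear_predictor(params, data_stub, latent, spec)
    phi = _phi_row(params, fam)
    Y = fam.sample(rng, eta, phi)
    data = AbundanceData(Y=np.asarray(Y, dtype=float), X=X, family=fam.name, link=fam.link)
    return data, latent


@dataclass
class ParameterMagnitudes:
    """Scales for the synthetic parameter generator."""

    beta0_loc: float = 0.0
    beta0_scale: float = 0.5
    beta_scale: float = 0.5
    loading_scale: float = 0.7
    log_phi_loc: float = 0.0
    log_phi_scale: float = 0.3
    sigma2: float = 0.25


def generate_parameters(
    m: int,
    k: int,
    d: int,
    spec: ModelSpec,
    magnitudes: Optional[ParameterMagnitudes] = None,
    seed: int = 0,
) -> ParameterSet:
    """Draw a constraint-valid parameter set from configurable distributions."""
    if d >= m:
        raise ValueError("latent dimension d must be < m")
    mag = magnitudes or ParameterMagnitudes()
    rng = np.random.default_rng(seed)
    beta0 = rng.normal(mag.beta0_loc, mag.beta0_scale, size=m)
    B = rng.normal(0.0, mag.beta_scale, size=(m, k)) if k > 0 else None
    Gamma_raw = rng.normal(0.0, mag.loading_scale, size=(m, d))
    try:
        Gamma, _ = constrain_loadings(Gamma_raw)
    except ValueError:
        # degenerate draw (e.g. zero loading magnitude): keep the raw lower
        # triangle and floor the diagonal
        Gamma = np.tril(Gamma_raw)[:, :d]
        Gamma[np.arange(d), np.arange(d)] = np.maximum(
            np.abs(Gamma[np.arange(d), np.arange(d)]), GAMMA_DIAG_FLOOR
        )
    fam = spec.family_obj()
    phi = None
    if fam.has_dispersion:
        phi = np.exp(rng.normal(mag.log_phi_loc, mag.log_phi_scale, size=m))
        phi = np.maximum(phi, PHI_FLOOR)
    sigma2 = max(mag.sigma2, SIGMA2_FLOOR) if spec.row_effect else None
    return ParameterSet(beta0=beta0, B=B, Gamma=Gamma, phi=phi, sigma2=sigma2).validate()


def constrain_loadings(Gamma_raw: np.ndarray, U_raw: Optional[np.ndarray] = None):
    """Rotate loadings to zero upper triangle and positive diagonal.

    Applies the orthogonal transform that makes the top d x d block of the
    loading matrix lower triangular with positive diagonal, and applies the
    inverse rotation to the latent scores so the product U Gamma' is unchanged.
    """
    Gamma_raw = np.atleast_2d(np.asarray(Gamma_raw, dtype=float))
    m, d = Gamma_raw.shape
    if m < d:
        raise ValueError("loading matrix needs at least d rows")
    if np.linalg.matrix_rank(Gamma_raw) < d:
        raise ValueError("loading matrix is rank deficient; cannot identify rotation")
    top = Gamma_raw[:d, :]
    # top' = Q R  =>  top @ Q = R' (lower triangular)
    Q, R = np.linalg.qr(top.T)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Q = Q * signs[None, :]
    Gamma = Gamma_raw @ Q
    # kill round-off in the structural zeros
    iu = np.triu_indices(d, k=1, m=d)
    Gamma[: d][iu] = 0.0
    diag = np.diag(Gamma[:d, :d]).copy()
    if np.any(diag < GAMMA_DIAG_FLOOR):
        diag = np.maximum(diag, GAMMA_DIAG_FLOOR)
        Gamma[np.arange(d), np.arange(d)] = diag
    U = None if U_raw is None else np.atleast_2d(np.asarray(U_raw, dtype=float)) @ Q
    return Gamma, U
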