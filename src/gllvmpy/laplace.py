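"""Laplace approximation of the marginal log-likelihood.

For each site the joint log-density of responses and latent vector,

    h_i(u) = sum_j log f(y_ij | eta_ij) - u' C^-1 u / 2
             - logdet(C) / 2 - (d + r) log(2 pi) / 2,

is maximized over u by damped Newton iterations (all implemented families are
log-concave in eta, so the curvature matrix

    G_i = sum_j [-d2 log f / d eta2] gamma*_j gamma*_j' + C^-1

is symmetric positive definite everywhere and the inner problem has a unique
maximizer).  The approximate marginal log-likelihood is then

    l~(Psi) = sum_i [ h_i(u^_i) - logdet(G_i)/2 + (d + r) log(2 pi)/2 ],

maximized over Psi with outer gradients obtained by central finite
differences with warm-started inner solves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .fitbase import FitControl, FitResult
from .model_core import AbundanceData, LatentState, ModelSpec, ParameterSet
from .packing import ParamPacker

__all__ = [
    "LAFit",
    "joint_logdensity",
    "inner_maximize",
    "G_matrix",
    "la_loglik",
    "fit_la",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class LAFit(FitResult):
    latents_hat: LatentState = None
    inner_iterations: Optional[np.ndarray] = None
    curvatures: Optional[np.ndarray] = None  # (n, p, p) G matrices at optimum


def _model_arrays(params: ParameterSet, data: AbundanceData, spec: ModelSpec):
    fam = spec.family_obj()
    Gstar = params.gamma_star(spec.row_effect)
    c = params.c_diag(spec.row_effect)
    fixed = np.tile(params.beta0, (data.n, 1))
    if data.X is not None and params.B is not None:
        fixed = fixed + data.X @ params.B.T
    phi = params.phi[None, :] if fam.has_dispersion else None
    return fam, Gstar, c, fixed, phi


def _h_sites(Y, fixed, Gstar, c, fam, phi, U):
    """Per-site joint log-density h_i(u_i) for U an (n, p) matrix."""
    eta = fixed + U @ Gstar.T
    ll = fam.logpdf(Y, eta, phi).sum(axis=1)
    p = U.shape[1]
    return (
        ll
        - 0.5 * np.einsum("ip,p,ip->i", U, 1.0 / c, U)
        - 0.5 * np.sum(np.log(c))
        - 0.5 * p * _LOG2PI
    )


def joint_logdensity(
    params: ParameterSet,
    data: AbundanceData,
    latent: LatentState,
    spec: ModelSpec,
):
    """Joint log-density of responses and latent variables.

    Returns ``(total, per_site)`` where ``per_site`` is the length-n vector of
    site contributions.
    """
    params.validate()
    fam, Gstar, c, fixed, phi = _model_arrays(params, data, spec)
    U = latent.ustar()
    h = _h_sites(data.Y, fixed, Gstar, c, fam, phi, U)
    return float(h.sum()), h


def _newton_all(params, data, spec, U0, tol=1e-9, max_iter=100):
    """Damped Newton maximization of h_i(u) for all sites simultaneously.

    Returns (U_hat, G, h, n_iter, converged_mask).
    """
    fam, Gstar, c, fixed, phi = _model_arrays(params, data, spec)
    Y = data.Y
    n = data.n
    p = Gstar.shape[1]
    U = np.array(U0, dtype=float, copy=True).reshape(n, p)
    h = _h_sites(Y, fixed, Gstar, c, fam, phi, U)
    iters = np.zeros(n, dtype=int)
    cinv = 1.0 / c
    for it in range(max_iter):
        eta = fixed + U @ Gstar.T
        d1 = fam.d1(Y, eta, phi)
        grad = d1 @ Gstar - U * cinv[None, :]
        gnorm = np.max(np.abs(grad), axis=1)
        active = gnorm > tol
        if not np.any(active):
            break
        W = -fam.d2(Y, eta, phi)
        G = np.einsum("ij,jp,jq->ipq", W, Gstar, Gstar) + np.diag(cinv)[None, :, :]
        try:
            step = np.linalg.solve(G, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.linalg.solve(
                G + 1e-8 * np.eye(p)[None, :, :], grad[:, :, None]
            )[:, :, 0]
        alpha = np.where(active, 1.0, 0.0)
        for _ in range(40):
            U_cand = U + alpha[:, None] * step
            h_cand = _h_sites(Y, fixed, Gstar, c, fam, phi, U_cand)
            worse = (active & (h_cand < h - 1e-12)) | ~np.isfinite(h_cand)
            if not np.any(worse):
                break
            alpha[worse] *= 0.5
        else:
            alpha[worse] = 0.0
        U = U + alpha[:, None] * step
        h = _h_sites(Y, fixed, Gstar, c, fam, phi, U)
        iters[active] += 1
    eta = fixed + U @ Gstar.T
    d1 = fam.d1(Y, eta, phi)
    grad = d1 @ Gstar - U * cinv[None, :]
    W = -fam.d2(Y, eta, phi)
    G = np.einsum("ij,jp,jq->ipq", W, Gstar, Gstar) + np.diag(cinv)[None, :, :]
    # a site counts as converged when its gradient is small on the scale of
    # its joint log-density (floating-point limits the achievable tolerance
    # for large |h|)
    converged = np.max(np.abs(grad), axis=1) <= np.maximum(tol, 1e-7 * (1.0 + np.abs(h)))
    return U, G, h, iters, converged


def inner_maximize(
    params: ParameterSet,
    data: AbundanceData,
    spec: ModelSpec,
    site: int,
    u_init: Optional[np.ndarray] = None,
    tol: float = 1e-9,
) -> np.ndarray:
    """Maximize the site-i joint log-density over the latent vector."""
    params.validate()
    p = spec.latent_dim()
    sub = AbundanceData(
        Y=data.Y[[site]],
        X=None if data.X is None else data.X[[site]],
        family=data.family,
        link=data.link,
    )
    U0 = np.zeros((1, p)) if u_init is None else np.asarray(u_init, float).reshape(1, p)
    U, _, _, _, conv = _newton_all(params, sub, spec, U0, tol=tol)
    if not conv[0]:
        raise RuntimeError(f"inner Newton failed to converge for site {site}")
    return U[0]


def G_matrix(
    params: ParameterSet,
    data: AbundanceData,
    spec: ModelSpec,
    site: int,
    u_hat: np.ndarray,
) -> np.ndarray:
    """Curvature matrix G_i = sum_j [-d2 logf] gamma* gamma*' + C^-1 at u_hat."""
    fam, Gstar, c, fixed, phi = _model_arrays(params, data, spec)
    u = np.asarray(u_hat, dtype=float).reshape(1, -1)
    eta = fixed[[site]] + u @ Gstar.T
    W = -fam.d2(data.Y[[site]], eta, phi)
    G = np.einsum("ij,jp,jq->pq", W, Gstar, Gstar) + np.diag(1.0 / c)
    try:
        np.linalg.cholesky(G)
    except np.linalg.LinAlgError:
        raise RuntimeError(f"curvature matrix not positive definite at site {site}")
    return G


def la_loglik(
    params: ParameterSet,
    data: AbundanceData,
    spec: ModelSpec,
    warm_starts: Optional[np.ndarray] = None,
    inner_tol: float = 1e-9,
    return_state: bool = False,
):
    """Laplace-approximate marginal log-likelihood l~(Psi)."""
    params.validate()
    p = spec.latent_dim()
    U0 = np.zeros((data.n, p)) if warm_starts is None else warm_starts
    U, G, h, iters, conv = _newton_all(params, data, spec, U0, tol=inner_tol)
    if not np.all(conv):
        bad = int(np.sum(~conv))
        raise RuntimeError(f"inner Newton failed for {bad} site(s)")
    sign, logdet = np.linalg.slogdet(G)
    if np.any(sign <= 0):
        raise RuntimeError("non-positive-definite curvature at inner optimum")
    ll = float(np.sum(h - 0.5 * logdet + 0.5 * p * _LOG2PI))
    if return_state:
        return ll, U, G, iters
    return ll


class _LAObjective:
    """Negative Laplace log-likelihood over the free parameter vector with
    warm-started inner solves and finite-difference gradients."""

    def __init__(self, data, spec, packer: ParamPacker, control: FitControl):
        self.data, self.spec, self.packer = data, spec, packer
        self.control = control
        self.warm = np.zeros((data.n, spec.latent_dim()))
        self.state = None

    def _eval(self, x, warm):
        params = self.packer.unpack(x)
        with np.errstate(over="ignore", invalid="ignore"):
            try:
                ll, U, G, iters = la_loglik(
                    params, self.data, self.spec,
                    warm_starts=warm, inner_tol=self.control.inner_tol,
                    return_state=True,
                )
            except (RuntimeError, np.linalg.LinAlgError):
                return -np.inf, None, None, None
        if not np.isfinite(ll):
            return -np.inf, None, None, None
        return ll, U, G, iters

    def value(self, x):
        ll, U, G, iters = self._eval(x, self.warm)
        if U is None:
            return np.inf  # infeasible point: force the optimizer to backtrack
        self.warm = U
        self.state = (U, G, iters)
        return -ll

    def grad(self, x):
        base_warm = self.warm.copy()
        g = np.zeros_like(x)
        step = self.control.fd_step
        f0 = None
        for i in range(x.size):
            h = step * max(1.0, abs(x[i]))
            xp = x.copy()
            xp[i] += h
            fp, _, _, _ = self._eval(xp, base_warm)
            xm = x.copy()
            xm[i] -= h
            fm, _, _, _ = self._eval(xm, base_warm)
            if np.isfinite(fp) and np.isfinite(fm):
                g[i] = -(fp - fm) / (2.0 * h)
            else:
                # one-sided fallback at the edge of the feasible region
                if f0 is None:
                    f0, _, _, _ = self._eval(x, base_warm)
                if np.isfinite(fp):
                    g[i] = -(fp - f0) / h
                elif np.isfinite(fm):
                    g[i] = -(f0 - fm) / h
                else:
                    g[i] = 0.0
        return g


def fit_la(
    data: AbundanceData,
    spec: ModelSpec,
    start,
    control: Optional[FitControl] = None,
) -> LAFit:
    """Maximize the Laplace-approximate log-likelihood over the model
    parameters, with nested warm-started inner solves."""
    control = control or FitControl()
    packer = ParamPacker.for_spec(data.n, data.m, data.k, spec)
    obj = _LAObjective(data, spec, packer, control)

    params0 = start.params0.validate()
    obj.warm = start.latents0.ustar().copy()
    x0 = packer.pack(params0)
    f0 = obj.value(x0)
    if not np.isfinite(f0):
        raise ValueError("non-finite Laplace objective at the starting values")

    res = optimize.minimize(
        obj.value,
        x0,
        jac=obj.grad,
        method="L-BFGS-B",
        bounds=packer.bounds(),
        options=dict(maxiter=control.max_iter, ftol=control.ftol, gtol=control.gtol,
                     maxcor=20),
    )
    # refresh the inner state at the solution
    fstar = obj.value(res.x)
    U, G, iters = obj.state
    params = packer.unpack(res.x)
    grad_norm = float(np.max(np.abs(res.jac)))
    return LAFit(
        params=params,
        latents_hat=LatentState.from_ustar(U, spec.row_effect),
        objective=float(-fstar),
        converged=bool(res.success) and grad_norm < control.gtol * max(1.0, abs(fstar)),
        n_iter=int(res.nit),
        grad_norm=grad_norm,
        start_objective=float(-f0),
        spec=spec,
        data=data,
        message=str(res.message),
        inner_iterations=iters,
        curvatures=G,
    )
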