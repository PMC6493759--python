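"""Flat-vector parameterizations used by the optimizers.

Model parameters are estimated on an unconstrained scale: dispersions, the
row-effect variance and the diagonal of the loading matrix are log
transformed, and only the free (lower-triangular) loading entries enter the
vector, so every point of the search space satisfies the identifiability
constraints by construction.  The variational parameters are packed the same
way: per-site means plus the free entries of lower-triangular Cholesky
factors with log-diagonal.
"""

from __future__ import annotations

import numpy as np

from .model_core import ModelSpec, ParameterSet


class ParamPacker:
    """Bijection between ParameterSet and an unconstrained free vector."""

    def __init__(self, m: int, k: int, d: int, has_dispersion: bool, row_effect: bool):
        self.m, self.k, self.d = m, k, d
        self.has_dispersion = has_dispersion
        self.row_effect = row_effect
        rows, cols, isdiag = [], [], []
        for j in range(m):
            for l in range(min(j + 1, d)):
                rows.append(j)
                cols.append(l)
                isdiag.append(j == l)
        self.g_rows = np.array(rows, dtype=int)
        self.g_cols = np.array(cols, dtype=int)
        self.g_isdiag = np.array(isdiag, dtype=bool)
        n_gamma = len(rows)
        sizes = [m, m * k, n_gamma, m if has_dispersion else 0, 1 if row_effect else 0]
        starts = np.concatenate([[0], np.cumsum(sizes)])
        self.sl_beta0 = slice(starts[0], starts[1])
        self.sl_B = slice(starts[1], starts[2])
        self.sl_gamma = slice(starts[2], starts[3])
        self.sl_logphi = slice(starts[3], starts[4])
        self.sl_logsigma2 = slice(starts[4], starts[5])
        self.n_free = int(starts[5])

    @classmethod
    def for_spec(cls, n: int, m: int, k: int, spec: ModelSpec) -> "ParamPacker":
        return cls(m, k, spec.n_lv, spec.family_obj().has_dispersion, spec.row_effect)

    def pack(self, params: ParameterSet) -> np.ndarray:
        x = np.zeros(self.n_free)
        x[self.sl_beta0] = params.beta0
        if self.k > 0:
            x[self.sl_B] = params.B.ravel()
        g = params.Gamma[self.g_rows, self.g_cols].copy()
        g[self.g_isdiag] = np.log(g[self.g_isdiag])
        x[self.sl_gamma] = g
        if self.has_dispersion:
            x[self.sl_logphi] = np.log(params.phi)
        if self.row_effect:
            x[self.sl_logsigma2] = np.log(params.sigma2)
        return x

    def unpack(self, x: np.ndarray) -> ParameterSet:
        beta0 = x[self.sl_beta0].copy()
        B = x[self.sl_B].reshape(self.m, self.k).copy() if self.k > 0 else None
        Gamma = np.zeros((self.m, self.d))
        g = x[self.sl_gamma].copy()
        g[self.g_isdiag] = np.exp(g[self.g_isdiag])
        Gamma[self.g_rows, self.g_cols] = g
        phi = np.exp(x[self.sl_logphi]).copy() if self.has_dispersion else None
        sigma2 = float(np.exp(x[self.sl_logsigma2][0])) if self.row_effect else None
        return ParameterSet(beta0=beta0, B=B, Gamma=Gamma, phi=phi, sigma2=sigma2)

    def pack_grad(
        self,
        params: ParameterSet,
        g_beta0: np.ndarray,
        g_B,
        g_Gamma: np.ndarray,
        g_logphi,
        g_logsigma2,
    ) -> np.ndarray:
        """Chain full-matrix gradients onto the free vector.

        ``g_Gamma`` is the gradient with respect to the full loading matrix;
        the diagonal chain rule for the log parameterization is applied here.
        ``g_logphi``/``g_logsigma2`` are already on the log scale.
        """
        g = np.zeros(self.n_free)
        g[self.sl_beta0] = g_beta0
        if self.k > 0:
            g[self.sl_B] = np.asarray(g_B).ravel()
        gg = g_Gamma[self.g_rows, self.g_cols].copy()
        gg[self.g_isdiag] *= params.Gamma[self.g_rows, self.g_cols][self.g_isdiag]
        g[self.sl_gamma] = gg
        if self.has_dispersion:
            g[self.sl_logphi] = g_logphi
        if self.row_effect:
            g[self.sl_logsigma2] = g_logsigma2
        return g

    def bounds(self, log_bound: float = 16.0) -> list:
        """Box bounds for L-BFGS-B: log-parameterized coordinates are kept in
        [-log_bound, log_bound] so exp() cannot overflow during line search."""
        out = [(None, None)] * self.n_free
        idx = np.arange(self.n_free)
        for i in idx[self.sl_gamma][self.g_isdiag]:
            out[i] = (-log_bound, log_bound)
        for sl in (self.sl_logphi, self.sl_logsigma2):
            for i in idx[sl]:
                out[i] = (-log_bound, log_bound)
        return out

    def names(self) -> list:
        out = [f"beta0[{j}]" for j in range(self.m)]
        for j in range(self.m):
            for l in range(self.k):
                out.append(f"B[{j},{l}]")
        for j, l, isd in zip(self.g_rows, self.g_cols, self.g_isdiag):
            out.append(f"log_Gamma[{j},{l}]" if isd else f"Gamma[{j},{l}]")
        if self.has_dispersion:
            out += [f"log_phi[{j}]" for j in range(self.m)]
        if self.row_effect:
            out.append("log_sigma2")
        return out

    def block_indices(self, block: str) -> np.ndarray:
        """Indices of a named block in the free vector.

        Blocks: ``beta0``, ``B``, ``Gamma`` (free entries), ``log_phi``,
        ``log_sigma2``.
        """
        sl = {
            "beta0": self.sl_beta0,
            "B": self.sl_B,
            "Gamma": self.sl_gamma,
            "log_phi": self.sl_logphi,
            "log_sigma2": self.sl_logsigma2,
        }[block]
        return np.arange(self.n_free)[sl]


class VAPacker:
    """Packing of per-site variational means and Cholesky factors.

    With a row effect the covariance is block diagonal,
    A_i = bdiag(A_alpha_i, A_u_i), so the free entries of L_i are the scalar
    sqrt(A_alpha_i) plus the lower triangle of the d x d u-block; diagonal
    entries are log parameterized.
    """

    def __init__(self, n: int, d: int, row_effect: bool):
        self.n, self.d = n, d
        self.row_effect = row_effect
        self.p = d + (1 if row_effect else 0)
        r = 1 if row_effect else 0
        rows, cols, isdiag = [], [], []
        if row_effect:
            rows.append(0)
            cols.append(0)
            isdiag.append(True)
        for a in range(d):
            for b in range(a + 1):
                rows.append(a + r)
                cols.append(b + r)
                isdiag.append(a == b)
        self.l_rows = np.array(rows, dtype=int)
        self.l_cols = np.array(cols, dtype=int)
        self.l_isdiag = np.array(isdiag, dtype=bool)
        self.n_l = len(rows)
        self.n_free = n * self.p + n * self.n_l
        self.sl_a = slice(0, n * self.p)
        self.sl_L = slice(n * self.p, self.n_free)

    def pack(self, a: np.ndarray, L: np.ndarray) -> np.ndarray:
        x = np.zeros(self.n_free)
        x[self.sl_a] = a.ravel()
        lv = L[:, self.l_rows, self.l_cols].copy()
        lv[:, self.l_isdiag] = np.log(lv[:, self.l_isdiag])
        x[self.sl_L] = lv.ravel()
        return x

    def unpack(self, x: np.ndarray):
        a = x[self.sl_a].reshape(self.n, self.p).copy()
        lv = x[self.sl_L].reshape(self.n, self.n_l).copy()
        lv[:, self.l_isdiag] = np.exp(lv[:, self.l_isdiag])
        L = np.zeros((self.n, self.p, self.p))
        L[:, self.l_rows, self.l_cols] = lv
        return a, L

    def bounds(self, log_bound: float = 16.0) -> list:
        out = [(None, None)] * self.n_free
        isdiag_tiled = np.tile(self.l_isdiag, self.n)
        offset = self.n * self.p
        for j, isd in enumerate(isdiag_tiled):
            if isd:
                out[offset + j] = (-log_bound, log_bound)
        return out

    def pack_grad(self, L: np.ndarray, g_a: np.ndarray, g_L: np.ndarray) -> np.ndarray:
        g = np.zeros(self.n_free)
        g[self.sl_a] = g_a.ravel()
        gl = g_L[:, self.l_rows, self.l_cols].copy()
        gl[:, self.l_isdiag] *= L[:, self.l_rows, self.l_cols][:, self.l_isdiag]
        g[self.sl_L] = gl.ravel()
        return g
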