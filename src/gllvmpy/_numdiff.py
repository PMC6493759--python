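"""Finite-difference helpers used for Laplace outer gradients and for the
Hessians backing Wald standard errors."""

from __future__ import annotations

import numpy as np


def central_gradient(fun, x, step=1e-5):
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    for i in range(x.size):
        h = step * max(1.0, abs(x[i]))
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (fun(xp) - fun(xm)) / (2.0 * h)
    return g


def hessian_from_grad(gradfun, x, step=1e-5):
    """Jacobian of a gradient function by central differences, symmetrized."""
    x = np.asarray(x, dtype=float)
    n = x.size
    H = np.zeros((n, n))
    for i in range(n):
        h = step * max(1.0, abs(x[i]))
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        H[i] = (gradfun(xp) - gradfun(xm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def hessian_from_fun(fun, x, step=1e-4):
    """Dense Hessian by second-order central differences of the function."""
    x = np.asarray(x, dtype=float)
    n = x.size
    H = np.zeros((n, n))
    f0 = fun(x)
    hs = step * np.maximum(1.0, np.abs(x))

    def at(**shifts):
        xx = x.copy()
        for idx, mult in shifts.items():
            xx[int(idx)] += mult
        return fun(xx)

    for i in range(n):
        hi = hs[i]
        fp = at(**{str(i): hi})
        fm = at(**{str(i): -hi})
        H[i, i] = (fp - 2.0 * f0 + fm) / hi**2
    for i in range(n):
        for j in range(i + 1, n):
            hi, hj = hs[i], hs[j]
            xx = x.copy()
            xx[i] += hi
            xx[j] += hj
            fpp = fun(xx)
            xx = x.copy()
            xx[i] += hi
            xx[j] -= hj
            fpm = fun(xx)
            xx = x.copy()
            xx[i] -= hi
            xx[j] += hj
            fmp = fun(xx)
            xx = x.copy()
            xx[i] -= hi
            xx[j] -= hj
            fmm = fun(xx)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * hi * hj)
    return H
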