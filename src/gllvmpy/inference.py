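"""Wald inference: Hessian-based standard errors, confidence intervals, and
latent-variable prediction errors.

For a Laplace fit the covariance of the estimates is the inverse negative
Hessian of the approximate log-likelihood over the model parameters.  For a
variational fit the Hessian is taken over the joint vector of model and
variational parameters and the model-parameter block of its inverse is used,
which accounts for the estimation of the variational parameters.  All
standard errors are reported on the estimation scale (log dispersions, log
row-effect variance, log loading diagonal); delta-method standard errors on
the natural scale are provided alongside for the log-parameterized blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from ._numdiff import hessian_from_fun, hessian_from_grad
from .fitbase import FitControl
from .laplace import LAFit, _LAObjective
from .packing import ParamPacker, VAPacker
from .variational import VAFit, _VAObjective

__all__ = ["InferenceReport", "standard_errors", "wald_ci"]

_PINV_RTOL = 1e-10


@dataclass
class InferenceReport:
    names: list
    estimates: np.ndarray  # estimation-scale free vector
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    level: float
    lv_prediction_sd: np.ndarray  # (n, d + r)
    flags: np.ndarray  # parameters whose SE came from a pseudo-inverse fallback
    packer: ParamPacker = None

    def block(self, name: str):
        """(estimates, se, lower, upper) for a named parameter block."""
        idx = self.packer.block_indices(name)
        return (
            self.estimates[idx],
            self.se[idx],
            self.ci_lower[idx],
            self.ci_upper[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.names,
                "estimate": self.estimates,
                "se": self.se,
                "lower": self.ci_lower,
                "upper": self.ci_upper,
                "pinv_flag": self.flags,
            }
        )


def wald_ci(estimates, se, level: float = 0.95):
    """estimate +/- z_{1-alpha/2} * se, elementwise."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    estimates = np.asarray(estimates, dtype=float)
    se = np.asarray(se, dtype=float)
    return estimates - z * se, estimates + z * se


def _safe_inverse(negH: np.ndarray):
    """Inverse of the negative Hessian with pseudo-inverse fallback."""
    flags = np.zeros(negH.shape[0], dtype=bool)
    try:
        L = np.linalg.cholesky(negH)
        identity = np.eye(negH.shape[0])
        cov = np.linalg.solve(L.T, np.linalg.solve(L, identity))
        return cov, flags
    except np.linalg.LinAlgError:
        pass
    w, V = np.linalg.eigh(negH)
    keep = w > _PINV_RTOL * np.max(np.abs(w))
    winv = np.where(keep, 1.0 / np.where(keep, w, 1.0), 0.0)
    cov = (V * winv[None, :]) @ V.T
    # flag parameters dominated by truncated directions
    bad = V[:, ~keep]
    if bad.size:
        flags = np.max(np.abs(bad), axis=1) > 0.5
    return cov, flags


def standard_errors(
    fit,
    level: float = 0.95,
    control: Optional[FitControl] = None,
    hessian_step: float = 1e-4,
) -> InferenceReport:
    """Hessian-based standard errors and Wald intervals for a fitted model."""
    control = control or FitControl()
    data, spec = fit.data, fit.spec
    ppack = ParamPacker.for_spec(data.n, data.m, data.k, spec)
    xpsi = ppack.pack(fit.params)

    if isinstance(fit, VAFit):
        vpack = VAPacker(data.n, spec.n_lv, spec.row_effect)
        obj = _VAObjective(data, spec, ppack, vpack)
        x = np.concatenate([xpsi, vpack.pack(fit.varstate.a, fit.varstate.L)])

        def grad(xx):
            return obj.value_and_grad(xx)[1]

        negH = hessian_from_grad(grad, x, step=1e-5)
        cov_full, flags_full = _safe_inverse(negH)
        P = ppack.n_free
        cov = cov_full[:P, :P]
        flags = flags_full[:P]
        lv_sd = np.sqrt(np.diagonal(fit.varstate.cov(), axis1=1, axis2=2))
    elif isinstance(fit, LAFit):
        obj = _LAObjective(data, spec, ppack, control)
        obj.warm = fit.latents_hat.ustar().copy()

        def fun(xx):
            return obj.value(xx)

        negH = hessian_from_fun(fun, xpsi, step=hessian_step)
        cov, flags = _safe_inverse(negH)
        Ginv = np.linalg.inv(fit.curvatures)
        lv_sd = np.sqrt(np.diagonal(Ginv, axis1=1, axis2=2))
    else:
        raise TypeError(f"unsupported fit type {type(fit).__name__}")

    var = np.diagonal(cov).copy()
    bad = ~(var > 0)
    flags = flags | bad
    var[bad] = np.nan
    se = np.sqrt(var)
    lower, upper = wald_ci(xpsi, se, level)
    return InferenceReport(
        names=ppack.names(),
        estimates=xpsi,
        se=se,
        ci_lower=lower,
        ci_upper=upper,
        level=level,
        lv_prediction_sd=lv_sd,
        flags=flags,
        packer=ppack,
    )
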