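"""Response families and link functions.

Each family exposes the conditional log-density ``logpdf(y, eta, phi)`` on the
linear-predictor scale together with its first two derivatives in ``eta`` and,
where a dispersion parameter exists, the derivative in ``phi``.  These are the
only primitives the two estimation engines need: the Laplace engine consumes
``d1``/``d2`` for the inner Newton solves and the curvature matrix, while the
variational engine consumes ``expected_logpdf`` — the expectation of the
log-density under a normal distribution on ``eta`` — and its partial
derivatives with respect to the normal's mean and variance.

The negative binomial is parameterized by its mean ``mu`` and dispersion
``phi`` with quadratic mean-variance relationship ``Var(y) = mu + phi*mu**2``.
The gaussian/identity family exists for testing only: both approximations are
exact there, which turns several integration identities into exact oracles.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats
from scipy.special import expit, gammaln

__all__ = ["get_family", "Family", "FAMILY_NAMES"]

FAMILY_NAMES = ("poisson", "negative_binomial", "bernoulli", "gaussian")

# Fixed-order Gauss-Hermite rule used for the non-closed-form variational
# expectations; 32 points keeps the quadrature error far below optimizer
# tolerances for the variances that arise in practice.
_GH_ORDER = 32
_GH_X, _GH_W = np.polynomial.hermite.hermgauss(_GH_ORDER)
_GH_W = _GH_W / np.sqrt(np.pi)

_SQRT_2PI = np.sqrt(2.0 * np.pi)


def _norm_logcdf(z):
    return special.log_ndtr(z)


def _mills(z):
    """phi(z) / Phi(z), computed stably via log functions."""
    logpdf = -0.5 * z * z - np.log(_SQRT_2PI)
    return np.exp(logpdf - special.log_ndtr(z))


class Family:
    """Base class; subclasses implement the scalar/vectorized primitives."""

    name: str = ""
    link: str = ""
    has_dispersion: bool = False
    discrete: bool = True

    # -- mean / inverse link ------------------------------------------------
    def mean(self, eta):
        raise NotImplementedError

    # -- conditional log density and eta-derivatives ------------------------
    def logpdf(self, y, eta, phi=None):
        raise NotImplementedError

    def d1(self, y, eta, phi=None):
        """First derivative of logpdf with respect to eta."""
        raise NotImplementedError

    def d2(self, y, eta, phi=None):
        """Second derivative of logpdf with respect to eta (non-positive
        for all implemented families: log-concave likelihoods)."""
        raise NotImplementedError

    def dphi(self, y, eta, phi):
        """Derivative of logpdf with respect to the dispersion phi."""
        raise NotImplementedError

    # -- distribution functions (for randomized quantile residuals) ---------
    def cdf(self, y, eta, phi=None):
        raise NotImplementedError

    def cdf_left(self, y, eta, phi=None):
        """Left limit F(y-) of the distribution function at y."""
        raise NotImplementedError

    # -- sampling -----------------------------------------------------------
    def sample(self, rng, eta, phi=None):
        raise NotImplementedError

    def validate_y(self, Y):
        Y = np.asarray(Y, dtype=float)
        if not np.all(np.isfinite(Y)):
            raise ValueError(f"{self.name}: response matrix contains non-finite entries")
        if self.discrete:
            if np.any(Y < 0) or np.any(Y != np.round(Y)):
                raise ValueError(
                    f"{self.name}: responses must be non-negative integers"
                )
        return Y

    # -- variational expectation E[log f(y | eta)], eta ~ N(eta_t, s2) ------
    def expected_logpdf(self, y, eta_t, s2, phi=None, grad=False):
        """Gaussian expectation of the log-density.

        Returns ``val`` or, when ``grad`` is true, ``(val, e1, e2, gphi)``
        where ``e1 = d val/d eta_t``, ``e2 = d val/d s2`` and ``gphi`` is the
        derivative in phi (``None`` without a dispersion parameter).  The
        default implementation uses Gauss-Hermite quadrature; ``e2`` uses the
        identity d/ds2 E[g] = E[g'']/2, which avoids dividing by sqrt(s2).
        """
        sd = np.sqrt(np.maximum(s2, 0.0))
        val = 0.0
        e1 = 0.0
        e2 = 0.0
        gphi = 0.0 if self.has_dispersion else None
        for xk, wk in zip(_GH_X, _GH_W):
            eta = eta_t + np.sqrt(2.0) * sd * xk
            val = val + wk * self.logpdf(y, eta, phi)
            if grad:
                e1 = e1 + wk * self.d1(y, eta, phi)
                e2 = e2 + 0.5 * wk * self.d2(y, eta, phi)
                if self.has_dispersion:
                    gphi = gphi + wk * self.dphi(y, eta, phi)
        if grad:
            return val, e1, e2, gphi
        return val


class Poisson(Family):
    name = "poisson"
    link = "log"

    def mean(self, eta):
        return np.exp(eta)

    def logpdf(self, y, eta, phi=None):
        return y * eta - np.exp(eta) - gammaln(y + 1.0)

    def d1(self, y, eta, phi=None):
        return y - np.exp(eta)

    def d2(self, y, eta, phi=None):
        return -np.exp(eta)

    def cdf(self, y, eta, phi=None):
        return stats.poisson.cdf(y, np.exp(eta))

    def cdf_left(self, y, eta, phi=None):
        return stats.poisson.cdf(y - 1.0, np.exp(eta))

    def sample(self, rng, eta, phi=None):
        return rng.poisson(np.exp(eta))

    def expected_logpdf(self, y, eta_t, s2, phi=None, grad=False):
        # E[y*eta - exp(eta) - log y!] has the closed form below.
        M = np.exp(eta_t + 0.5 * s2)
        val = y * eta_t - M - gammaln(y + 1.0)
        if grad:
            return val, y - M, -0.5 * M, None
        return val


class NegativeBinomial(Family):
    name = "negative_binomial"
    link = "log"
    has_dispersion = True

    def mean(self, eta):
        return np.exp(eta)

    def logpdf(self, y, eta, phi):
        mu = np.exp(eta)
        r = 1.0 / phi
        return (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1.0)
            + y * (np.log(phi) + eta)
            - (y + r) * np.log1p(phi * mu)
        )

    def d1(self, y, eta, phi):
        mu = np.exp(eta)
        return (y - mu) / (1.0 + phi * mu)

    def d2(self, y, eta, phi):
        mu = np.exp(eta)
        return -mu * (1.0 + phi * y) / (1.0 + phi * mu) ** 2

    def dphi(self, y, eta, phi):
        mu = np.exp(eta)
        r = 1.0 / phi
        t = np.log1p(phi * mu)
        return (
            (special.digamma(r) - special.digamma(y + r)) * r**2
            + y * r
            + t * r**2
            - (y + r) * mu / (1.0 + phi * mu)
        )

    def cdf(self, y, eta, phi):
        mu = np.exp(eta)
        r = 1.0 / phi
        return stats.nbinom.cdf(y, r, r / (r + mu))

    def cdf_left(self, y, eta, phi):
        mu = np.exp(eta)
        r = 1.0 / phi
        return stats.nbinom.cdf(y - 1.0, r, r / (r + mu))

    def sample(self, rng, eta, phi):
        mu = np.exp(eta)
        r = 1.0 / (phi * np.ones_like(mu))
        return rng.negative_binomial(r, r / (r + mu))


class Bernoulli(Family):
    name = "bernoulli"

    def __init__(self, link="probit"):
        if link not in ("probit", "logit"):
            raise ValueError(f"bernoulli supports probit or logit link, got {link!r}")
        self.link = link

    def mean(self, eta):
        if self.link == "probit":
            return special.ndtr(eta)
        return expit(eta)

    def validate_y(self, Y):
        Y = super().validate_y(Y)
        if np.any((Y != 0) & (Y != 1)):
            raise ValueError("bernoulli: responses must be 0 or 1")
        return Y

    def logpdf(self, y, eta, phi=None):
        if self.link == "probit":
            w = 2.0 * y - 1.0
            return _norm_logcdf(w * eta)
        return y * eta - np.logaddexp(0.0, eta)

    def d1(self, y, eta, phi=None):
        if self.link == "probit":
            w = 2.0 * y - 1.0
            return w * _mills(w * eta)
        return y - expit(eta)

    def d2(self, y, eta, phi=None):
        if self.link == "probit":
            w = 2.0 * y - 1.0
            z = w * eta
            lam = _mills(z)
            return -lam * (z + lam)
        p = expit(eta)
        return -p * (1.0 - p)

    def cdf(self, y, eta, phi=None):
        p = self.mean(eta)
        return np.where(y < 1, 1.0 - p, 1.0)

    def cdf_left(self, y, eta, phi=None):
        p = self.mean(eta)
        return np.where(y < 1, 0.0, 1.0 - p)

    def sample(self, rng, eta, phi=None):
        return rng.binomial(1, self.mean(eta))


class Gaussian(Family):
    """Identity-link normal responses with per-species variance phi.

    Internal test fixture: the marginal likelihood is available in closed
    form, and both the Laplace and the variational approximations are exact.
    """

    name = "gaussian"
    link = "identity"
    has_dispersion = True
    discrete = False

    def mean(self, eta):
        return eta

    def validate_y(self, Y):
        Y = np.asarray(Y, dtype=float)
        if not np.all(np.isfinite(Y)):
            raise ValueError("gaussian: response matrix contains non-finite entries")
        return Y

    def logpdf(self, y, eta, phi):
        return -0.5 * np.log(2.0 * np.pi * phi) - (y - eta) ** 2 / (2.0 * phi)

    def d1(self, y, eta, phi):
        return (y - eta) / phi

    def d2(self, y, eta, phi):
        return -np.ones_like(np.broadcast_to(eta, np.broadcast_shapes(np.shape(y), np.shape(eta)))) / phi

    def dphi(self, y, eta, phi):
        return -0.5 / phi + (y - eta) ** 2 / (2.0 * phi**2)

    def cdf(self, y, eta, phi):
        return stats.norm.cdf(y, loc=eta, scale=np.sqrt(phi))

    cdf_left = cdf

    def sample(self, rng, eta, phi):
        return rng.normal(eta, np.sqrt(phi * np.ones_like(eta)))

    def expected_logpdf(self, y, eta_t, s2, phi, grad=False):
        val = -0.5 * np.log(2.0 * np.pi * phi) - ((y - eta_t) ** 2 + s2) / (2.0 * phi)
        if grad:
            e1 = (y - eta_t) / phi
            e2 = -0.5 / phi * np.ones_like(val)
            gphi = -0.5 / phi + ((y - eta_t) ** 2 + s2) / (2.0 * phi**2)
            return val, e1, e2, gphi
        return val


_LINKS = {
    "poisson": ("log",),
    "negative_binomial": ("log",),
    "bernoulli": ("probit", "logit"),
    "gaussian": ("identity",),
}


def get_family(name: str, link: str | None = None) -> Family:
    """Construct a family object, validating the family/link combination."""
    aliases = {"nb": "negative_binomial", "negbin": "negative_binomial",
               "binomial": "bernoulli", "normal": "gaussian"}
    name = aliases.get(name, name)
    if name not in _LINKS:
        raise ValueError(f"unknown family {name!r}; choose from {FAMILY_NAMES}")
    if link is None:
        link = _LINKS[name][0]
    if link not in _LINKS[name]:
        raise ValueError(f"family {name!r} does not support link {link!r}")
    if name == "poisson":
        return Poisson()
    if name == "negative_binomial":
        return NegativeBinomial()
    if name == "bernoulli":
        return Bernoulli(link)
    return Gaussian()
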