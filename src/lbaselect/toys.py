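"""Conjugate toy targets with analytic marginal likelihoods.

These tiny models plug into the same sampler / marginal-likelihood API as
the LBA targets and serve as ground truth for validating the sampler,
bridge sampling, and thermodynamic integration: their posteriors, power
posteriors, and marginal likelihoods are available in closed form.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import betaln, gammaln, ndtr, ndtri

__all__ = ["NormalNormalToy", "BetaBinomialToy"]

_LOG_SQRT2PI = 0.5 * math.log(2.0 * math.pi)


class NormalNormalToy:
    """y_i ~ N(mu, sigma^2) with known sigma and mu ~ N(mu0, tau0^2)."""

    param_names = ("mu",)
    k = 1

    def __init__(self, y, sigma=1.0, mu0=0.0, tau0=1.0):
        self.y = np.asarray(y, dtype=float)
        self.sigma = float(sigma)
        self.mu0 = float(mu0)
        self.tau0 = float(tau0)
        self.n = self.y.size

    def log_prior(self, thetas):
        mu = np.atleast_2d(thetas)[:, 0]
        z = (mu - self.mu0) / self.tau0
        return -0.5 * z * z - math.log(self.tau0) - _LOG_SQRT2PI

    def log_lik(self, thetas):
        mu = np.atleast_2d(thetas)[:, 0]
        resid = self.y[None, :] - mu[:, None]
        return (
            -0.5 * (resid / self.sigma) ** 2
            - math.log(self.sigma)
            - _LOG_SQRT2PI
        ).sum(axis=1)

    def per_trial_log_lik(self, thetas):
        mu = np.atleast_2d(thetas)[:, 0]
        resid = self.y[None, :] - mu[:, None]
        return -0.5 * (resid / self.sigma) ** 2 - math.log(self.sigma) - _LOG_SQRT2PI

    def sample_prior(self, rng, size):
        return rng.normal(self.mu0, self.tau0, size=(size, 1))

    def log_unnormalized_posterior(self, thetas):
        return self.log_prior(thetas) + self.log_lik(thetas)

    def posterior(self, temperature: float = 1.0):
        """Mean and SD of mu under the power posterior at ``temperature``."""
        prec = 1.0 / self.tau0**2 + temperature * self.n / self.sigma**2
        mean = (
            self.mu0 / self.tau0**2 + temperature * self.y.sum() / self.sigma**2
        ) / prec
        return mean, 1.0 / math.sqrt(prec)

    def expected_log_lik(self, temperature: float) -> float:
        """E_t[log p(y | mu)] under the power posterior — the TI integrand."""
        mean, sd = self.posterior(temperature)
        resid2 = ((self.y - mean) ** 2).sum() + self.n * sd**2
        return (
            -0.5 * resid2 / self.sigma**2
            - self.n * (math.log(self.sigma) + _LOG_SQRT2PI)
        )

    def log_ml(self) -> float:
        """Analytic log marginal likelihood (y jointly normal)."""
        n, s2, t2 = self.n, self.sigma**2, self.tau0**2
        ybar = self.y.mean()
        ss = ((self.y - ybar) ** 2).sum()
        # decompose: within-mean residuals + marginal of ybar ~ N(mu0, s2/n + t2)
        v = s2 / n + t2
        return (
            -0.5 * (n - 1) * math.log(2 * math.pi * s2)
            - 0.5 * math.log(n)  # Jacobian bookkeeping for the ybar factorization
            - 0.5 * ss / s2
            - 0.5 * math.log(2 * math.pi * v)
            - 0.5 * (ybar - self.mu0) ** 2 / v
        )


class BetaBinomialToy:
    """y successes in n Bernoulli trials, rate theta ~ Beta(a, b).

    The parameter is sampled on the probit scale eta = Phi^{-1}(theta) to
    give the DE-MCMC chains an unbounded support; the prior density carries
    the Jacobian so the implied prior on theta is exactly Beta(a, b).
    """

    param_names = ("eta",)
    k = 1

    def __init__(self, y: int, n: int, a: float = 1.0, b: float = 1.0):
        if not 0 <= y <= n:
            raise ValueError("need 0 <= y <= n")
        self.y, self.n, self.a, self.b = int(y), int(n), float(a), float(b)

    def _theta(self, etas):
        return np.clip(ndtr(etas), 1e-12, 1 - 1e-12)

    def log_prior(self, thetas):
        eta = np.atleast_2d(thetas)[:, 0]
        th = self._theta(eta)
        log_jac = -0.5 * eta * eta - _LOG_SQRT2PI  # d theta / d eta = phi(eta)
        return (
            (self.a - 1) * np.log(th)
            + (self.b - 1) * np.log1p(-th)
            - betaln(self.a, self.b)
            + log_jac
        )

    def log_lik(self, thetas):
        eta = np.atleast_2d(thetas)[:, 0]
        th = self._theta(eta)
        return (
            gammaln(self.n + 1)
            - gammaln(self.y + 1)
            - gammaln(self.n - self.y + 1)
            + self.y * np.log(th)
            + (self.n - self.y) * np.log1p(-th)
        )

    def sample_prior(self, rng, size):
        th = rng.beta(self.a, self.b, size=(size, 1))
        return ndtri(np.clip(th, 1e-12, 1 - 1e-12))

    def log_unnormalized_posterior(self, thetas):
        return self.log_prior(thetas) + self.log_lik(thetas)

    def log_ml(self) -> float:
        """Analytic log marginal likelihood: C(n, y) B(y+a, n-y+b) / B(a, b)."""
        return (
            gammaln(self.n + 1)
            - gammaln(self.y + 1)
            - gammaln(self.n - self.y + 1)
            + betaln(self.y + self.a, self.n - self.y + self.b)
            - betaln(self.a, self.b)
        )
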