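"""Canonical exponential families.

A k-parameter canonical exponential family has density (or mass function)

    f_eta(y) = exp{ eta' T(y) - psi(eta) } h(y),

with natural parameter ``eta`` in the open convex set H, sufficient
statistic ``T(y)`` and strictly convex cumulant (log-normalizer) ``psi``.
The first two derivatives of ``psi`` give the mean and covariance of the
sufficient statistic,

    grad psi(eta) = E_eta[T(Y)],     hess psi(eta) = var_eta[T(Y)],

and ``hess psi`` is symmetric positive definite everywhere on H.

The natural-parameter vector splits into a block of dimension ``k1`` that
is allowed to depend on covariates and a block of dimension ``k2 = k - k1``
that is covariate-free (e.g. the variance parameter of a homoscedastic
Gaussian).  Three families are provided:

* :class:`Multinomial` -- one draw from q categories, last category is the
  reference, ``k = k1 = q - 1``, ``eta_i = log(p_i / p_q)``;
* :class:`Poisson` -- q independent Poisson counts with log link,
  ``k = k1 = q``;
* :class:`Gaussian` -- q-variate normal with spherical covariance; either
  the variance is known (``k2 = 0``) or it enters as one covariate-free
  natural parameter (``k2 = 1``).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.special import logsumexp


class DomainError(ValueError):
    """Natural parameter outside the family's domain H."""


class ExponentialFamily:
    """Abstract canonical exponential family.

    Subclasses set ``name``, ``k1``, ``k2`` and implement the single-eta
    and vectorized cumulant/moment methods plus samplers.  All vectorized
    methods take an ``(n, k)`` array of natural parameters.
    """

    name: str = "abstract"
    k1: int = 0
    k2: int = 0

    @property
    def k(self) -> int:
        return self.k1 + self.k2

    # -- domain -----------------------------------------------------------
    def in_domain(self, eta: np.ndarray) -> bool:
        """Whether ``eta`` lies in the natural parameter space H."""
        eta = np.asarray(eta, dtype=float)
        return eta.shape == (self.k,) and bool(self.domain_ok(eta[None, :]))

    def domain_ok(self, etas: np.ndarray) -> bool:
        """Vectorized domain check for an (n, k) array; True iff all rows in H."""
        return bool(np.all(np.isfinite(etas)))

    def require_domain(self, etas: np.ndarray) -> None:
        if not self.domain_ok(np.atleast_2d(etas)):
            raise DomainError(self._domain_message(np.atleast_2d(etas)))

    def _domain_message(self, etas: np.ndarray) -> str:
        return f"{self.name}: natural parameter outside H (non-finite entry)"

    # -- cumulant and moments ---------------------------------------------
    def psi(self, eta: np.ndarray) -> float:
        eta = self._check_eta(eta)
        return float(self.psi_vec(eta[None, :])[0])

    def grad_psi(self, eta: np.ndarray) -> np.ndarray:
        eta = self._check_eta(eta)
        return self.mean_vec(eta[None, :])[0]

    def hess_psi(self, eta: np.ndarray) -> np.ndarray:
        eta = self._check_eta(eta)
        return self.cov_vec(eta[None, :])[0]

    def psi_vec(self, etas: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def mean_vec(self, etas: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def cov_vec(self, etas: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # -- data -------------------------------------------------------------
    def suff_stats(self, Y) -> np.ndarray:
        """Map observed responses to the (n, k) sufficient-statistic matrix."""
        raise NotImplementedError

    def sample(self, eta: np.ndarray, n: int, seed=None) -> np.ndarray:
        """n i.i.d. responses at a single natural parameter."""
        if n < 1:
            raise ValueError("sample size n must be >= 1")
        eta = self._check_eta(eta)
        rng = np.random.default_rng(seed)
        return self.sample_conditional(np.broadcast_to(eta, (n, self.k)), rng)

    def sample_conditional(self, etas: np.ndarray, rng: np.random.Generator):
        """One response per row of ``etas`` (per-observation natural parameters)."""
        raise NotImplementedError

    def init_natural(self, t_bar: np.ndarray) -> np.ndarray:
        """An interior eta whose mean is close to the observed T average."""
        raise NotImplementedError

    def contrast_labels(self) -> list:
        """Display labels for the k1 covariate-dependent coordinates."""
        return [f"eta{i + 1}" for i in range(self.k1)]

    def validate_responses(self, Y) -> None:
        """Raise on structurally invalid responses (called before fitting)."""

    # -- helpers ----------------------------------------------------------
    def _check_eta(self, eta) -> np.ndarray:
        eta = np.asarray(eta, dtype=float).ravel()
        if eta.shape != (self.k,):
            raise ValueError(
                f"{self.name}: eta must have length k={self.k}, got {eta.shape}"
            )
        self.require_domain(eta[None, :])
        return eta

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{type(self).__name__}(k1={self.k1}, k2={self.k2})"


class Multinomial(ExponentialFamily):
    """Single multinomial draw over q categories, last category as reference.

    T(y) is the indicator vector of the first q-1 categories and
    psi(eta) = log(1 + sum_i exp(eta_i)), which normalizes the mass
    function; H = R^{q-1}.
    """

    def __init__(self, q: int):
        if q < 2:
            raise ValueError("multinomial requires q >= 2 categories")
        self.q = int(q)
        self.k1 = self.q - 1
        self.k2 = 0
        self.name = f"multinomial(q={q})"

    def psi_vec(self, etas):
        padded = np.concatenate([etas, np.zeros((etas.shape[0], 1))], axis=1)
        return logsumexp(padded, axis=1)

    def full_probs(self, etas: np.ndarray) -> np.ndarray:
        """(n, q) category probabilities, reference category last."""
        etas = np.atleast_2d(np.asarray(etas, dtype=float))
        padded = np.concatenate([etas, np.zeros((etas.shape[0], 1))], axis=1)
        padded -= padded.max(axis=1, keepdims=True)
        e = np.exp(padded)
        return e / e.sum(axis=1, keepdims=True)

    def mean_vec(self, etas):
        return self.full_probs(etas)[:, : self.k1]

    def cov_vec(self, etas):
        p = self.mean_vec(etas)
        n, k = p.shape
        cov = -p[:, :, None] * p[:, None, :]
        cov[:, np.arange(k), np.arange(k)] += p
        return cov

    def suff_stats(self, Y):
        Y = np.asarray(Y)
        if Y.ndim == 2 and Y.shape[1] == self.q:
            # indicator rows (y1,...,yq); keep first q-1 columns
            return Y[:, : self.k1].astype(float)
        labels = Y.ravel().astype(int)
        if np.any((labels < 1) | (labels > self.q)):
            bad = labels[(labels < 1) | (labels > self.q)][0]
            raise ValueError(
                f"multinomial labels must lie in 1..{self.q}; found {bad}"
            )
        T = np.zeros((labels.size, self.k1))
        for i in range(self.k1):
            T[labels == i + 1, i] = 1.0
        return T

    def validate_responses(self, Y):
        T = self.suff_stats(Y)
        counts = np.concatenate([T.sum(axis=0), [len(T) - T.sum()]])
        if np.any(counts == 0):
            empty = int(np.argmin(counts)) + 1
            raise ValueError(
                f"category {empty} has no observations; "
                "drop it or merge categories before fitting"
            )

    def sample_conditional(self, etas, rng):
        p = self.full_probs(etas)
        u = rng.random((p.shape[0], 1))
        labels = (u > np.cumsum(p, axis=1)).sum(axis=1) + 1
        return labels

    def init_natural(self, t_bar):
        p = np.append(np.clip(t_bar, 1e-8, None), max(1.0 - t_bar.sum(), 1e-8))
        return np.log(p[: self.k1] / p[self.k1])

    def contrast_labels(self):
        return [f"log(p{i + 1}/p{self.q})" for i in range(self.k1)]


class Poisson(ExponentialFamily):
    """q independent Poisson counts with canonical log link; psi = sum exp(eta_i)."""

    def __init__(self, q: int = 1):
        if q < 1:
            raise ValueError("Poisson requires q >= 1")
        self.q = int(q)
        self.k1 = self.q
        self.k2 = 0
        self.name = f"poisson(q={q})"

    def psi_vec(self, etas):
        return np.exp(etas).sum(axis=1)

    def mean_vec(self, etas):
        return np.exp(etas)

    def cov_vec(self, etas):
        mu = np.exp(etas)
        n, k = mu.shape
        cov = np.zeros((n, k, k))
        cov[:, np.arange(k), np.arange(k)] = mu
        return cov

    def suff_stats(self, Y):
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[1] != self.q:
            Y = Y.reshape(-1, self.q)
        if np.any(Y < 0) or np.any(Y != np.round(Y)):
            raise ValueError("Poisson responses must be nonnegative integers")
        return Y

    def sample_conditional(self, etas, rng):
        return rng.poisson(np.exp(etas))

    def init_natural(self, t_bar):
        return np.log(np.clip(t_bar, 1e-3, None))

    def contrast_labels(self):
        return [f"log(mu{i + 1})" for i in range(self.q)]


class Gaussian(ExponentialFamily):
    """q-variate normal with spherical covariance sigma^2 I.

    With known variance (``sigma2`` given) the family has T(y) = y,
    eta = mu / sigma^2 and psi(eta) = sigma^2 ||eta||^2 / 2, so k2 = 0.

    With unknown variance the covariate-free block holds the single
    natural parameter eta2 = -1/(2 sigma^2) < 0, T(y) = (y, ||y||^2) and

        psi(eta1, eta2) = -||eta1||^2 / (4 eta2) + (q/2) log(pi / (-eta2)),

    the log-normalizer of the Lebesgue-base-measure Gaussian.
    """

    def __init__(self, q: int, sigma2: float | None = None):
        if q < 1:
            raise ValueError("Gaussian requires q >= 1")
        if sigma2 is not None and sigma2 <= 0:
            raise ValueError("known variance must be positive")
        self.q = int(q)
        self.sigma2 = None if sigma2 is None else float(sigma2)
        self.k1 = self.q
        self.k2 = 0 if sigma2 is not None else 1
        self.name = f"gaussian(q={q}, " + (
            f"sigma2={sigma2})" if sigma2 is not None else "free variance)"
        )

    def domain_ok(self, etas):
        if not np.all(np.isfinite(etas)):
            return False
        if self.k2 == 1 and np.any(etas[:, -1] >= 0):
            return False
        return True

    def _domain_message(self, etas):
        if self.k2 == 1 and np.any(etas[:, -1] >= 0):
            return "gaussian: variance natural parameter eta2 must be negative"
        return super()._domain_message(etas)

    def psi_vec(self, etas):
        if self.k2 == 0:
            return 0.5 * self.sigma2 * np.sum(etas**2, axis=1)
        eta1, eta2 = etas[:, : self.q], etas[:, -1]
        return -np.sum(eta1**2, axis=1) / (4.0 * eta2) + 0.5 * self.q * np.log(
            -np.pi / eta2
        )

    def mean_vec(self, etas):
        if self.k2 == 0:
            return self.sigma2 * etas
        eta1, eta2 = etas[:, : self.q], etas[:, -1:]
        d_eta1 = -eta1 / (2.0 * eta2)
        d_eta2 = np.sum(eta1**2, axis=1, keepdims=True) / (
            4.0 * eta2**2
        ) - 0.5 * self.q / eta2
        return np.concatenate([d_eta1, d_eta2], axis=1)

    def cov_vec(self, etas):
        n = etas.shape[0]
        if self.k2 == 0:
            cov = np.zeros((n, self.q, self.q))
            cov[:, np.arange(self.q), np.arange(self.q)] = self.sigma2
            return cov
        q = self.q
        eta1, eta2 = etas[:, :q], etas[:, -1]
        cov = np.zeros((n, q + 1, q + 1))
        cov[:, np.arange(q), np.arange(q)] = (-1.0 / (2.0 * eta2))[:, None]
        cross = eta1 / (2.0 * eta2**2)[:, None]
        cov[:, :q, q] = cross
        cov[:, q, :q] = cross
        cov[:, q, q] = -np.sum(eta1**2, axis=1) / (2.0 * eta2**3) + 0.5 * q / eta2**2
        return cov

    def suff_stats(self, Y):
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if self.k2 == 0:
            return Y
        return np.concatenate([Y, np.sum(Y**2, axis=1, keepdims=True)], axis=1)

    def sample_conditional(self, etas, rng):
        if self.k2 == 0:
            mu = self.sigma2 * etas
            return mu + math.sqrt(self.sigma2) * rng.standard_normal(mu.shape)
        eta1, eta2 = etas[:, : self.q], etas[:, -1:]
        sigma2 = -1.0 / (2.0 * eta2)
        mu = eta1 * sigma2
        return mu + np.sqrt(sigma2) * rng.standard_normal(mu.shape)

    def init_natural(self, t_bar):
        if self.k2 == 0:
            return t_bar / self.sigma2
        mu = t_bar[: self.q]
        # E||Y||^2 = ||mu||^2 + q sigma^2
        sigma2 = max((t_bar[-1] - mu @ mu) / self.q, 1e-6)
        return np.append(mu / sigma2, -1.0 / (2.0 * sigma2))

    def log_h(self, Y) -> np.ndarray:
        """log base measure h(y); completes psi to the Gaussian log-density."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if self.k2 == 0:
            return -0.5 * self.q * np.log(2 * np.pi * self.sigma2) - np.sum(
                Y**2, axis=1
            ) / (2.0 * self.sigma2)
        return np.zeros(Y.shape[0])

    def contrast_labels(self):
        return [f"mu{i + 1}" for i in range(self.q)]


_FAMILY_BUILDERS = {
    "multinomial": Multinomial,
    "poisson": Poisson,
    "gaussian": Gaussian,
}


def family_by_name(name: str, q: int, **kwargs) -> ExponentialFamily:
    """Build a family from its CLI/config name ('multinomial', 'poisson', 'gaussian')."""
    try:
        builder = _FAMILY_BUILDERS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown family {name!r}; choose from {sorted(_FAMILY_BUILDERS)}"
        ) from None
    return builder(q, **kwargs)
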