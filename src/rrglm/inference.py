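"""Asymptotic inference for (partial reduced-rank) multivariate GLM MLEs.

For the unrestricted MLE, sqrt(n)(xi_hat - xi0) is asymptotically normal
with covariance

    W = ( E[ F(X)' hess_psi(F(X) xi0) F(X) ] )^{-1},

estimated by plugging in xi_hat and averaging over the observed x_i.

The rank restriction beta1 = C B defines a smooth non-convex parameter
manifold.  The restricted MLE remains asymptotically normal, with
covariance obtained by projecting W onto the tangent space of the
manifold.  With G the Jacobian of the factorization chart
theta = (eta_bar1, vec C, vec B, vec beta2, eta_bar2) -> xi,

    G = blockdiag( I,  [ B' (x) I_k1 | I_r (x) C ],  I,  I ),

the restricted asymptotic covariance is

    avar = Pi(W^{-1}) W = G (G' W^{-1} G)^+ G',

where Pi(S) = G (G' S G)^+ G' S is the oblique projection onto span(G)
that is self-adjoint under the inner product induced by S, and ^+ is the
Moore-Penrose pseudoinverse (G is rank-deficient by exactly the d^2
redundancy of the factorization, so an ordinary inverse does not exist;
the projection depends on G only through its column span, which makes the
pseudoinverse choice immaterial).  W - avar is positive semidefinite: the
restriction never costs efficiency.

Standard errors of individual coordinates are sqrt(avar_ii / n), feeding
Wald z-tests and confidence intervals; a case-resampling bootstrap and an
AIC scan over candidate ranks complete the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats

from .design import (
    ModelSpec,
    ParamVector,
    count_parameters,
    design_tensor,
    eta_matrix,
)
from .estimate import FitResult, fit_full, fit_reduced


@dataclass
class AsymCov:
    """Asymptotic covariance of sqrt(n)(xi_hat - xi0), with its parts.

    ``W`` is the unrestricted covariance, ``G`` the factorization-chart
    Jacobian (``None`` for an unrestricted fit, where avar = W), ``avar``
    the covariance actually attained, and ``n`` the sample size used for
    per-coordinate standard errors.
    """

    W: np.ndarray
    avar: np.ndarray
    n: int
    G: Optional[np.ndarray] = None

    @property
    def se(self) -> np.ndarray:
        """Per-coordinate standard errors sqrt(avar_ii / n)."""
        return np.sqrt(np.clip(np.diag(self.avar), 0.0, None) / self.n)


# ---------------------------------------------------------------------------
# plug-in W
# ---------------------------------------------------------------------------

def estimate_W(X, params: ParamVector, spec: ModelSpec) -> np.ndarray:
    """Plug-in unrestricted asymptotic covariance.

    Inverse of the empirical mean of F(x_i)' hess_psi(eta_i) F(x_i)
    evaluated at the fitted parameters.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    D = design_tensor(X, spec)
    etas = eta_matrix(params, X, spec)
    spec.family.require_domain(etas)
    H = spec.family.cov_vec(etas)
    info = np.einsum("nkm,nkl,nlj->mj", D, H, D, optimize=True) / X.shape[0]
    info = 0.5 * (info + info.T)
    eigval, eigvec = np.linalg.eigh(info)
    if eigval[0] <= 1e-12 * max(eigval[-1], 1.0):
        null = eigvec[:, 0]
        j = int(np.argmax(np.abs(null)))
        raise ValueError(
            "singular information matrix; null direction dominated by "
            f"coordinate {j} of xi (eigenvalue {eigval[0]:.3e})"
        )
    return eigvec @ np.diag(1.0 / eigval) @ eigvec.T


# ---------------------------------------------------------------------------
# factorization gradient and projection
# ---------------------------------------------------------------------------

def build_G(C0: np.ndarray, B0: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Jacobian of theta -> xi for the factorization beta1 = C B.

    Rows are xi coordinates (k1 + k1 p + k2), columns theta coordinates
    (k1 + k1 d + d r + k1 (p - r) + k2).  The vec(beta1) block is
    [ B0' (x) I_k1 | I_r (x) C0 ], the differential of vec(C B).
    """
    C0 = np.atleast_2d(np.asarray(C0, dtype=float))
    B0 = np.atleast_2d(np.asarray(B0, dtype=float))
    k1, k2, p, r = spec.k1, spec.k2, spec.p, spec.r
    d = C0.shape[1]
    if C0.shape[0] != k1 or B0.shape != (d, r):
        raise ValueError(
            f"factor shapes {C0.shape} x {B0.shape} do not match "
            f"k1={k1}, r={r}"
        )
    if np.linalg.matrix_rank(C0 @ B0) < d:
        raise ValueError(f"C0 B0 has rank < d={d}")
    n_xi = k1 + k1 * p + k2
    n_theta = k1 + k1 * d + d * r + k1 * (p - r) + k2
    G = np.zeros((n_xi, n_theta))
    G[:k1, :k1] = np.eye(k1)
    rows = slice(k1, k1 + k1 * r)
    G[rows, k1:k1 + k1 * d] = np.kron(B0.T, np.eye(k1))
    G[rows, k1 + k1 * d:k1 + k1 * d + d * r] = np.kron(np.eye(r), C0)
    rows2 = slice(k1 + k1 * r, k1 + k1 * p)
    cols2 = slice(k1 + k1 * d + d * r, k1 + k1 * d + d * r + k1 * (p - r))
    G[rows2, cols2] = np.eye(k1 * (p - r))
    if k2:
        G[k1 + k1 * p:, n_theta - k2:] = np.eye(k2)
    return G


def projection(G: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """Oblique projection Pi = G (G' Sigma G)^+ G' Sigma onto span(G).

    Idempotent, with column span equal to span(G), and self-adjoint for
    the inner product <x, y> = y' Sigma x.  ``Sigma`` must be symmetric
    positive definite.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    if Sigma.shape[0] != Sigma.shape[1] or not np.allclose(
        Sigma, Sigma.T, atol=1e-10
    ):
        raise ValueError("Sigma must be symmetric")
    if np.linalg.eigvalsh(Sigma)[0] <= 0:
        raise ValueError("Sigma must be positive definite")
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if not np.any(G):
        raise ValueError("G must be nonzero")
    core = G.T @ Sigma @ G
    return G @ np.linalg.pinv(core, hermitian=True) @ G.T @ Sigma


def avar_reduced(W: np.ndarray, G: np.ndarray, n: int = 1) -> AsymCov:
    """Restricted asymptotic covariance avar = G (G' W^{-1} G)^+ G'."""
    W = np.asarray(W, dtype=float)
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if G.shape[0] != W.shape[0]:
        raise ValueError(
            f"G has {G.shape[0]} rows but W is {W.shape[0]} x {W.shape[1]}"
        )
    Winv = np.linalg.inv(W)
    Winv = 0.5 * (Winv + Winv.T)
    core = G.T @ Winv @ G
    avar = G @ np.linalg.pinv(core, hermitian=True) @ G.T
    avar = 0.5 * (avar + avar.T)
    return AsymCov(W=W, avar=avar, n=n, G=G)


def asymptotic_covariance(fit: FitResult, X) -> AsymCov:
    """Plug-in AsymCov for a fitted model (restricted or not)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    W = estimate_W(X, fit.params, fit.spec)
    if not fit.restricted:
        return AsymCov(W=W, avar=W, n=X.shape[0])
    params = fit.params
    if params.C is None or params.B is None:
        from .estimate import factorize_corner

        C, B, _ = factorize_corner(params.beta1, fit.spec.d)
    else:
        C, B = params.C, params.B
    G = build_G(C, B, fit.spec)
    cov = avar_reduced(W, G, n=X.shape[0])
    return cov


# ---------------------------------------------------------------------------
# Wald table
# ---------------------------------------------------------------------------

def coordinate_labels(spec: ModelSpec) -> pd.DataFrame:
    """Block / predictor / contrast labels for every xi coordinate."""
    k1, k2, p, r = spec.k1, spec.k2, spec.p, spec.r
    contrasts = spec.family.contrast_labels()
    names = spec.ordered_names()
    rows = []
    for a in range(k1):
        rows.append(("eta_bar1", "Intercept", contrasts[a]))
    for j in range(p):
        block = "beta1" if j < r else "beta2"
        for a in range(k1):
            rows.append((block, names[j], contrasts[a]))
    for b in range(k2):
        rows.append(("eta_bar2", "Intercept", f"eta2_{b + 1}"))
    return pd.DataFrame(rows, columns=["block", "predictor", "contrast"])


def wald_table(fit: FitResult, cov: AsymCov, level: float = 0.95) -> pd.DataFrame:
    """Entrywise Wald inference for every coordinate of xi.

    Columns: estimate, se, z, pvalue, ci_low, ci_high and a 5%-level
    significance star.  Coordinates with zero asymptotic variance get a
    degenerate interval at the estimate.
    """
    if not fit.converged:
        raise ValueError(
            "refusing to build a Wald table from a non-converged fit: "
            + (fit.message or "no convergence")
        )
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    xi = fit.params.pack()
    se = cov.se
    tab = coordinate_labels(fit.spec)
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, xi / se, np.inf * np.sign(xi))
        z = np.where((se == 0) & (xi == 0), 0.0, z)
    pval = np.where(np.isinf(z), 0.0, 2.0 * stats.norm.sf(np.abs(z)))
    pval = np.where((se == 0) & (xi == 0), 1.0, pval)
    tab["estimate"] = xi
    tab["se"] = se
    tab["z"] = z
    tab["pvalue"] = pval
    tab["ci_low"] = xi - zcrit * se
    tab["ci_high"] = xi + zcrit * se
    tab["sig"] = np.where(tab["pvalue"] < 0.05, "*", "")
    return tab


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_cov(X, Y, spec: ModelSpec, n_boot: int, seed,
                  max_fail_rate: float = 0.05) -> np.ndarray:
    """Case-resampling bootstrap covariance of the restricted MLE.

    Resamples (x_i, y_i) pairs jointly, refits the rank-restricted model
    on each replicate (warm-started at the base fit) and returns the
    sample covariance of the replicate estimates on the sqrt(n) scale,
    i.e. an estimate of avar.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be a positive number of replicates")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y)
    n = X.shape[0]
    base = fit_reduced(X, Y, spec)
    if not base.converged:
        raise RuntimeError("base restricted fit did not converge: "
                           + base.message)
    rng = np.random.default_rng(seed)
    draws = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            rep = fit_reduced(X[idx], Y[idx], spec, init=base.params)
        except (ValueError, RuntimeError):
            failures += 1
            continue
        if not rep.converged:
            failures += 1
            continue
        draws.append(rep.params.pack())
    if failures > max_fail_rate * n_boot:
        raise RuntimeError(
            f"{failures} of {n_boot} bootstrap replicates failed to "
            "converge (more than the tolerated 5%)"
        )
    draws = np.asarray(draws)
    return n * np.cov(draws, rowvar=False)


# ---------------------------------------------------------------------------
# AIC rank selection
# ---------------------------------------------------------------------------

def aic_rank_path(X, Y, spec: ModelSpec, ranks: Sequence[int]) -> pd.DataFrame:
    """Fit the restricted model at each candidate rank and compare by AIC.

    The effective parameter count subtracts the d^2 factor-redundancy from
    the raw count, since (C, B) -> (C M, M^{-1} B) leaves the model
    unchanged.  AIC = -2 loglik_total + 2 * n_eff; the minimizer is
    flagged.  Non-converged ranks are kept in the table and flagged.
    """
    ranks = sorted(int(dd) for dd in ranks)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    dmax = min(spec.k1, len(spec.constrained) or spec.p)
    rows = []
    for dd in ranks:
        if not 0 < dd <= dmax:
            raise ValueError(f"rank {dd} outside 1..{dmax}")
        spec_d = spec.with_rank(dd)
        fit = fit_reduced(X, Y, spec_d)
        n_raw = count_parameters(spec_d, restricted=True)
        n_eff = n_raw - dd * dd
        ll_total = n * fit.loglik
        rows.append(
            {
                "rank": dd,
                "loglik": ll_total,
                "n_params": n_eff,
                "aic": -2.0 * ll_total + 2.0 * n_eff,
                "converged": fit.converged,
            }
        )
    tab = pd.DataFrame(rows)
    best = tab.loc[tab["converged"], "aic"]
    tab["selected"] = False
    if len(best):
        tab.loc[best.idxmin(), "selected"] = True
    return tab
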