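"""Maximum likelihood estimation for (partial reduced-rank) multivariate GLMs.

Two estimators are provided.

``fit_full`` maximizes the average conditional log-likelihood

    L_n(xi) = (1/n) sum_i [ eta_{x_i}' T(y_i) - psi(eta_{x_i}) ]

over the unrestricted parameter xi by Fisher scoring with step-halving:
the expected information F(x)' hess_psi(eta) F(x) is positive definite
wherever the design has full column rank, so every accepted step increases
the likelihood.

``fit_reduced`` maximizes the same criterion subject to rank(beta1) <= d
by alternating over the factorization beta1 = C B:

  (i)  with B fixed, (eta_bar1, C, beta2, eta_bar2) solves a multivariate
       GLM in the reduced predictors nu = B x1 joined with x2;
  (ii) with C fixed, (eta_bar1, B, beta2, eta_bar2) solves a GLM that is
       still linear in its parameters, with per-observation design
       [ I | x1' (x) C | x2' (x) I ].

Each half-step is a full Fisher-scoring solve, so the outer log-likelihood
trace is nondecreasing.  After every outer iteration the factors are
renormalized to the corner form C = [I_d; A] (rows permuted so the leading
d rows of beta1 are independent), which pins down the chart without moving
the identified product C B.

``gaussian_rrr_closed_form`` implements the classical multivariate linear
reduced-rank solution (truncated SVD of the OLS fit); it exists purely as
an independent oracle for testing the iterative estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg

from .design import (
    ModelSpec,
    ParamVector,
    design_tensor,
    eta_matrix,
)
from .expfam import DomainError, ExponentialFamily

#: relative log-likelihood tolerance for the outer alternation
OUTER_TOL = 1e-9
#: sup-norm tolerance on the mean score for full fits (comfortably inside
#: the 1e-6 contract; scoring is quadratically convergent so the extra
#: iteration is cheap)
SCORE_TOL = 1e-9
MAX_OUTER = 500
MAX_SCORING = 200


@dataclass
class FitResult:
    """A fitted (possibly rank-restricted) multivariate GLM."""

    params: ParamVector
    loglik_trace: list
    converged: bool
    n_iter: int
    restricted: bool
    spec: ModelSpec
    message: str = ""

    @property
    def loglik(self) -> float:
        """Average log-likelihood (1/n convention) at the estimate."""
        return float(self.loglik_trace[-1])


# ---------------------------------------------------------------------------
# criterion
# ---------------------------------------------------------------------------

def loglik(params: ParamVector, X, Y, spec: ModelSpec) -> float:
    """Average conditional log-likelihood (up to the base-measure term)."""
    Tn = spec.family.suff_stats(Y)
    etas = eta_matrix(params, X, spec)
    spec.family.require_domain(etas)
    return float(
        np.mean(np.sum(etas * Tn, axis=1) - spec.family.psi_vec(etas))
    )


def _avg_loglik(family, etas, Tn) -> float:
    return float(np.mean(np.sum(etas * Tn, axis=1) - family.psi_vec(etas)))


# ---------------------------------------------------------------------------
# inner Fisher-scoring solver
# ---------------------------------------------------------------------------

def _fisher_scoring(
    D: np.ndarray,
    Tn: np.ndarray,
    family: ExponentialFamily,
    theta0: np.ndarray,
    score_tol: float = SCORE_TOL,
    max_iter: int = MAX_SCORING,
):
    """Maximize the average log-likelihood of a linear natural-parameter model.

    ``D`` is the (n, k, m) stack of per-observation design operators, so
    eta_i = D[i] @ theta.  Returns (theta, avg-loglik trace, converged).
    """
    n = D.shape[0]
    theta = np.asarray(theta0, dtype=float).copy()
    etas = np.einsum("nkm,m->nk", D, theta)
    if not family.domain_ok(etas):
        raise DomainError(
            f"{family.name}: initial parameters give natural parameters outside H"
        )
    ll = _avg_loglik(family, etas, Tn)
    trace = [ll]
    converged = False
    for _ in range(max_iter):
        mu = family.mean_vec(etas)
        H = family.cov_vec(etas)
        score = np.einsum("nkm,nk->m", D, Tn - mu) / n
        info = np.einsum("nkm,nkl,nlj->mj", D, H, D, optimize=True) / n
        try:
            step = scipy.linalg.solve(info, score, assume_a="pos")
        except (scipy.linalg.LinAlgError, ValueError):
            # the design was validated full rank, so a singular expected
            # information means the iterates reached the boundary of the
            # mean space (saturation / separation): report, do not raise
            break
        # a vanishing score alone does not prove an interior optimum: under
        # data separation the score decays while the Newton step stays
        # large; require both to be small
        if np.max(np.abs(score)) <= score_tol and np.max(
            np.abs(step)
        ) <= 1e-5 * (1.0 + np.max(np.abs(theta))):
            converged = True
            break
        # step-halving keeps the trace monotone and eta inside H
        alpha = 1.0
        for _half in range(40):
            cand = theta + alpha * step
            etas_new = np.einsum("nkm,m->nk", D, cand)
            if family.domain_ok(etas_new):
                ll_new = _avg_loglik(family, etas_new, Tn)
                if ll_new >= ll - 1e-13:
                    break
            alpha *= 0.5
        else:
            converged = np.max(np.abs(score)) <= 10 * score_tol
            break
        theta, etas, ll = cand, etas_new, ll_new
        trace.append(ll)
    return theta, trace, converged


# ---------------------------------------------------------------------------
# data validation
# ---------------------------------------------------------------------------

def _validate(X: np.ndarray, Y, spec: ModelSpec, restricted: bool) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != spec.p:
        raise ValueError(f"X must have p={spec.p} columns, got {X.shape[1]}")
    Tn = spec.family.suff_stats(Y)
    if Tn.shape[0] != X.shape[0]:
        raise ValueError(
            f"X has {X.shape[0]} rows but the response has {Tn.shape[0]}"
        )
    spec.family.validate_responses(Y)
    if restricted:
        names = spec.ordered_names()
        for pos, j in enumerate(spec.constrained):
            if np.ptp(X[:, j]) == 0:
                raise ValueError(
                    f"constrained predictor {names[pos]!r} is constant; "
                    "remove it or leave it unconstrained"
                )
    Xt = np.column_stack([np.ones(X.shape[0]), X])
    if np.linalg.matrix_rank(Xt) < spec.p + 1:
        raise ValueError("rank-deficient design: predictors plus intercept "
                         "do not have full column rank")
    return X


def _init_theta(Tn: np.ndarray, spec: ModelSpec) -> np.ndarray:
    eta0 = spec.family.init_natural(Tn.mean(axis=0))
    params = ParamVector(
        eta_bar1=eta0[: spec.k1],
        beta1=np.zeros((spec.k1, spec.r)),
        beta2=np.zeros((spec.k1, spec.p - spec.r)),
        eta_bar2=eta0[spec.k1:],
    )
    return params.pack()


# ---------------------------------------------------------------------------
# full-rank MLE
# ---------------------------------------------------------------------------

def fit_full(X, Y, spec: ModelSpec, score_tol: float = SCORE_TOL,
             max_iter: int = MAX_SCORING) -> FitResult:
    """Unrestricted MLE by Fisher scoring with step-halving."""
    X = _validate(X, Y, spec, restricted=False)
    Tn = spec.family.suff_stats(Y)
    if X.shape[0] <= spec.n_params:
        raise ValueError(
            f"n={X.shape[0]} observations cannot identify "
            f"{spec.n_params} parameters"
        )
    D = design_tensor(X, spec)
    theta, trace, converged = _fisher_scoring(
        D, Tn, spec.family, _init_theta(Tn, spec), score_tol, max_iter
    )
    params = ParamVector.unpack(theta, spec)
    message = "" if converged else _divergence_message(theta)
    return FitResult(params, trace, converged, len(trace) - 1, False, spec,
                     message)


def _divergence_message(theta: np.ndarray) -> str:
    if np.max(np.abs(theta)) > 10.0:
        return ("did not converge; parameter norm is diverging with "
                "increasing likelihood -- data separation is likely")
    return "did not converge within the iteration limit"


# ---------------------------------------------------------------------------
# corner factorization
# ---------------------------------------------------------------------------

def factorize_corner(beta1: np.ndarray, d: int, tol: float = 1e-9):
    """Factor a rank-d matrix as beta1 = C B with C in corner form.

    Returns ``(C, B, perm)`` where ``perm`` is a row permutation such that
    ``C[perm][:d] = I_d`` (the leading d rows of the permuted beta1 are
    linearly independent) and ``C @ B`` reconstructs beta1 exactly.  The
    permutation is the identity whenever the first d rows already qualify.
    """
    beta1 = np.atleast_2d(np.asarray(beta1, dtype=float))
    k1, r = beta1.shape
    if not 0 < d <= min(k1, r):
        raise ValueError(f"rank d={d} must lie in 1..min({k1}, {r})")
    sv = np.linalg.svd(beta1, compute_uv=False)
    if sv[d - 1] <= tol * max(1.0, sv[0]):
        raise ValueError(
            f"beta1 has numerical rank < {d} (singular values {sv})"
        )
    lead = np.linalg.svd(beta1[:d], compute_uv=False)
    if d <= r and lead.size == d and lead[-1] > tol * max(1.0, sv[0]):
        perm = np.arange(k1)
    else:
        # pivot rows: QR with column pivoting on beta1'
        _, _, piv = scipy.linalg.qr(beta1.T, pivoting=True)
        rest = [i for i in range(k1) if i not in set(piv[:d])]
        perm = np.array(list(piv[:d]) + rest)
    Bp = beta1[perm[:d], :]
    A = beta1[perm[d:], :] @ Bp.T @ np.linalg.inv(Bp @ Bp.T)
    C_perm = np.vstack([np.eye(d), A])
    C = np.empty((k1, d))
    C[perm] = C_perm
    return C, Bp, perm


# ---------------------------------------------------------------------------
# rank-restricted MLE by alternating maximization
# ---------------------------------------------------------------------------

def _design_fixed_C(Xo: np.ndarray, C: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Per-observation design for step (ii): theta = (eta1, vecB, vec beta2, eta2)."""
    n = Xo.shape[0]
    k1, k2, p, r, d = spec.k1, spec.k2, spec.p, spec.r, spec.d
    m = k1 + d * r + k1 * (p - r) + k2
    D = np.zeros((n, k1 + k2, m))
    for a in range(k1):
        D[:, a, a] = 1.0
    X1, X2 = Xo[:, :r], Xo[:, r:]
    for j in range(r):
        for l in range(d):
            D[:, :k1, k1 + j * d + l] = X1[:, j:j + 1] * C[None, :, l]
    off = k1 + d * r
    for j in range(p - r):
        for a in range(k1):
            D[:, a, off + j * k1 + a] = X2[:, j]
    if k2:
        D[:, k1:, off + (p - r) * k1:] = np.eye(k2)
    return D


def _polish_corner(D, Tn, spec: ModelSpec, eta1, C, B, beta2, eta2, perm,
                   score_tol: float = SCORE_TOL, max_iter: int = 50):
    """Gauss-Newton refinement on the injective corner chart.

    The alternation converges only linearly near the optimum; a few
    Newton steps on the chart (eta_bar1, free rows of C, B, beta2,
    eta_bar2) -- whose gradient has full column rank -- converge
    quadratically to the restricted MLE.  Step-halving preserves the
    monotone log-likelihood trace.
    """
    from .inference import build_G  # local import; inference builds on estimate

    family = spec.family
    k1, k2, p, r, d = spec.k1, spec.k2, spec.p, spec.r, spec.d
    n = D.shape[0]
    free_a = [a for a in range(k1) if a not in set(perm[:d].tolist())]
    nfree = len(free_a)

    def current():
        return ParamVector(eta1, C @ B, beta2, eta2, C=C, B=B)

    xi = current().pack()
    etas = np.einsum("nkm,m->nk", D, xi)
    ll = _avg_loglik(family, etas, Tn)
    trace = []
    converged = False
    for _ in range(max_iter):
        mu = family.mean_vec(etas)
        H = family.cov_vec(etas)
        score = np.einsum("nkm,nk->m", D, Tn - mu) / n
        info = np.einsum("nkm,nkl,nlj->mj", D, H, D, optimize=True) / n
        G = build_G(C, B, spec)
        keep = np.ones(G.shape[1], dtype=bool)
        frozen = set(perm[:d].tolist())
        for l in range(d):
            for a in range(k1):
                if a in frozen:
                    keep[k1 + l * k1 + a] = False
        Gh = G[:, keep]
        g = Gh.T @ score
        M = Gh.T @ info @ Gh
        ev = np.linalg.eigvalsh(M)
        if ev[0] <= 1e-13 * max(ev[-1], 1.0):
            break  # chart information numerically singular; keep current
        try:
            delta = scipy.linalg.solve(M, g, assume_a="pos")
        except (scipy.linalg.LinAlgError, ValueError):
            break
        if np.max(np.abs(g)) <= score_tol and np.max(np.abs(delta)) <= 1e-5 * (
            1.0 + np.max(np.abs(xi))
        ):
            converged = True
            break
        # unpack the chart step
        o = 0
        d_eta1 = delta[o:o + k1]; o += k1
        dC = np.zeros((k1, d))
        for l in range(d):
            for i, a in enumerate(free_a):
                dC[a, l] = delta[o + l * nfree + i]
        o += nfree * d
        dB = delta[o:o + d * r].reshape(d, r, order="F"); o += d * r
        d_beta2 = delta[o:o + k1 * (p - r)].reshape(k1, p - r, order="F")
        o += k1 * (p - r)
        d_eta2 = delta[o:]
        alpha = 1.0
        for _half in range(40):
            cand = (eta1 + alpha * d_eta1, C + alpha * dC, B + alpha * dB,
                    beta2 + alpha * d_beta2, eta2 + alpha * d_eta2)
            xi_new = ParamVector(cand[0], cand[1] @ cand[2], cand[3],
                                 cand[4]).pack()
            etas_new = np.einsum("nkm,m->nk", D, xi_new)
            if family.domain_ok(etas_new):
                ll_new = _avg_loglik(family, etas_new, Tn)
                if ll_new >= ll - 1e-13:
                    break
            alpha *= 0.5
        else:
            break
        eta1, C, B, beta2, eta2 = cand
        xi, etas, ll = xi_new, etas_new, ll_new
        trace.append(ll)
    return eta1, C, B, beta2, eta2, trace, converged


def fit_reduced(X, Y, spec: ModelSpec, init: Optional[ParamVector] = None,
                outer_tol: float = OUTER_TOL, max_outer: int = MAX_OUTER,
                inner_tol: float = 1e-9) -> FitResult:
    """Rank-restricted MLE via alternating Fisher-scoring maximizations."""
    if spec.d is None:
        raise ValueError("spec must carry a rank d for a restricted fit")
    X = _validate(X, Y, spec, restricted=True)
    Tn = spec.family.suff_stats(Y)
    family = spec.family
    k1, k2, p, r, d = spec.k1, spec.k2, spec.p, spec.r, spec.d
    Xo = spec.reorder(X)

    # initialization: unrestricted MLE, then SVD-truncate its beta1 block
    if init is None:
        full = fit_full(X, Y, spec)
        b1 = full.params.beta1
        U, s, Vt = np.linalg.svd(b1, full_matrices=False)
        C = U[:, :d] * s[:d]
        B = Vt[:d, :]
        eta1, beta2, eta2 = (full.params.eta_bar1, full.params.beta2,
                             full.params.eta_bar2)
    else:
        if init.C is not None and init.B is not None:
            C, B = init.C.copy(), init.B.copy()
        else:
            C, B, _ = factorize_corner(init.beta1, d)
        eta1, beta2, eta2 = init.eta_bar1, init.beta2, init.eta_bar2
    try:
        C, B, _ = factorize_corner(C @ B, d)
    except ValueError:
        pass  # degenerate start; corner form restored once iterates move

    spec_step1 = ModelSpec(family, d + (p - r))
    cur = ParamVector(eta1, C @ B, beta2, eta2, C=C, B=B)
    ll = loglik(cur, X, Y, spec)
    trace = [ll]
    converged = False
    for it in range(max_outer):
        # (i) fix B: GLM in nu = B x1 and x2, coefficients [C | beta2]
        Xnu = np.column_stack([Xo[:, :r] @ B.T, Xo[:, r:]])
        D1 = design_tensor(Xnu, spec_step1)
        theta0 = np.concatenate(
            [eta1, C.ravel(order="F"), beta2.ravel(order="F"), eta2]
        )
        theta1, _, _ = _fisher_scoring(D1, Tn, family, theta0, inner_tol)
        pv1 = ParamVector.unpack(theta1, spec_step1)
        eta1, eta2 = pv1.eta_bar1, pv1.eta_bar2
        C = pv1.beta[:, :d]
        beta2 = pv1.beta[:, d:]

        # (ii) fix C: GLM with design [I | x1' (x) C | x2' (x) I]
        D2 = _design_fixed_C(Xo, C, spec)
        theta0 = np.concatenate(
            [eta1, B.ravel(order="F"), beta2.ravel(order="F"), eta2]
        )
        theta2, _, _ = _fisher_scoring(D2, Tn, family, theta0, inner_tol)
        eta1 = theta2[:k1]
        B = theta2[k1:k1 + d * r].reshape(d, r, order="F")
        beta2 = theta2[k1 + d * r:k1 + d * r + k1 * (p - r)].reshape(
            k1, p - r, order="F"
        )
        eta2 = theta2[k1 + d * r + k1 * (p - r):]

        # renormalize to the corner chart; the product C B is unchanged
        try:
            C, B, _ = factorize_corner(C @ B, d)
        except ValueError:
            pass
        cur = ParamVector(eta1, C @ B, beta2, eta2, C=C, B=B)
        ll_new = loglik(cur, X, Y, spec)
        trace.append(ll_new)
        if abs(ll_new - ll) <= outer_tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    # terminal Gauss-Newton polish on the corner chart
    try:
        C, B, perm = factorize_corner(C @ B, d)
    except ValueError:
        perm = None
    if perm is not None:
        D_full = design_tensor(X, spec)
        eta1, C, B, beta2, eta2, extra, polished = _polish_corner(
            D_full, Tn, spec, eta1, C, B, beta2, eta2, perm,
            score_tol=inner_tol,
        )
        trace.extend(extra)
        # a completed polish certifies the optimum; an aborted one (e.g.
        # ill-conditioned chart) falls back on the alternation criterion
        converged = polished or converged
        cur = ParamVector(eta1, C @ B, beta2, eta2, C=C, B=B)
    message = "" if converged else _divergence_message(cur.pack())
    return FitResult(cur, trace, converged, len(trace) - 1, True, spec, message)


# ---------------------------------------------------------------------------
# classical Gaussian reduced-rank regression (testing oracle)
# ---------------------------------------------------------------------------

def gaussian_rrr_closed_form(X, Y, rank: int) -> np.ndarray:
    """Rank-truncated OLS coefficient matrix for the linear model Y = B X + e.

    B_ols minimizes sum_i ||y_i - B x_i||^2; the rank-``rank`` solution
    projects the fitted values onto their leading singular subspace:
    B_rrr = U_r U_r' B_ols with U_r the top left singular vectors of the
    fitted-value matrix.  No intercept; center the data first if needed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, p = X.shape
    q = Y.shape[1]
    if not 0 < rank <= min(p, q):
        raise ValueError(f"rank must lie in 1..min({p}, {q})")
    gram = X.T @ X
    if np.linalg.matrix_rank(gram) < p:
        raise ValueError("singular Gram matrix X'X")
    B_ols = np.linalg.solve(gram, X.T @ Y).T  # q x p
    Yhat = X @ B_ols.T
    U, _, _ = np.linalg.svd(Yhat.T @ Yhat)
    Ur = U[:, :rank]
    return Ur @ Ur.T @ B_ols
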