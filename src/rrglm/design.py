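"""Model specification and the linear natural-parameter design.

The multivariate GLM models the natural parameter of ``Y | X = x`` as

    eta_x = ( eta_bar1 + beta1 x1 + beta2 x2 ,  eta_bar2 ),

where ``x1`` holds the r rank-constrained predictors, ``x2`` the remaining
p - r unconstrained ones, ``beta1`` is k1 x r with rank(beta1) <= d, and
``eta_bar2`` is the covariate-free natural-parameter block.  Stacking the
free parameters as

    xi = ( eta_bar1, vec(beta1), vec(beta2), eta_bar2 ),

with column-stacking ``vec``, the map x -> eta_x is linear in xi with
design operator

    F(x) = [ (1, x1', x2') (x) I_k1      0    ]
           [            0               I_k2  ],

so that ``eta_x = F(x) xi``.  Constrained predictors may be any subset of
columns; they are reordered internally so the constrained block comes
first.  The intercept always sits in ``eta_bar1`` and is never part of the
rank constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .expfam import ExponentialFamily


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of a (partial reduced-rank) multivariate GLM.

    Parameters
    ----------
    family : ExponentialFamily
        Conditional response family; supplies k1 and k2.
    p : int
        Total number of predictors (excluding the intercept).
    constrained : tuple of int, optional
        Column indices (0-based, in the caller's column order) of the
        rank-constrained predictors.  ``None`` constrains all p columns.
    d : int, optional
        Rank bound for beta1.  ``None`` means the unrestricted model.
    names : tuple of str, optional
        Predictor names, for reporting.
    """

    family: ExponentialFamily
    p: int
    constrained: Optional[tuple] = None
    d: Optional[int] = None
    names: Optional[tuple] = None

    def __post_init__(self):
        if self.p < 1:
            raise ValueError("need at least one predictor")
        cons = tuple(range(self.p)) if self.constrained is None else tuple(
            int(j) for j in self.constrained
        )
        if len(set(cons)) != len(cons):
            raise ValueError("constrained indices must be distinct")
        if cons and (min(cons) < 0 or max(cons) >= self.p):
            raise ValueError("constrained indices out of range")
        if not cons and self.d is not None:
            raise ValueError("a rank restriction needs a nonempty constrained block")
        object.__setattr__(self, "constrained", cons)
        if self.names is not None:
            names = tuple(str(s) for s in self.names)
            if len(names) != self.p:
                raise ValueError("names must have length p")
            object.__setattr__(self, "names", names)
        if self.d is not None:
            d = int(self.d)
            if not 0 < d <= min(self.k1, self.r):
                raise ValueError(
                    f"rank d={d} must satisfy 0 < d <= min(k1={self.k1}, r={self.r})"
                )
            object.__setattr__(self, "d", d)

    # -- dimension bookkeeping -------------------------------------------
    @property
    def k1(self) -> int:
        return self.family.k1

    @property
    def k2(self) -> int:
        return self.family.k2

    @property
    def r(self) -> int:
        return len(self.constrained)

    @property
    def unconstrained(self) -> tuple:
        cons = set(self.constrained)
        return tuple(j for j in range(self.p) if j not in cons)

    @property
    def column_order(self) -> tuple:
        """Original column indices in internal (x1, x2) order."""
        return self.constrained + self.unconstrained

    @property
    def n_params(self) -> int:
        """Length of xi."""
        return self.k1 + self.k1 * self.p + self.k2

    def reorder(self, X: np.ndarray) -> np.ndarray:
        """Reorder predictor columns to (constrained, unconstrained)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.p:
            raise ValueError(f"X must have p={self.p} columns, got {X.shape[1]}")
        return X[:, list(self.column_order)]

    def ordered_names(self) -> list:
        base = self.names or tuple(f"x{j + 1}" for j in range(self.p))
        return [base[j] for j in self.column_order]

    def with_rank(self, d: Optional[int]) -> "ModelSpec":
        return ModelSpec(self.family, self.p, self.constrained, d, self.names)


@dataclass
class ParamVector:
    """Parameters of the linear natural-parameter model.

    ``beta1`` columns follow the order of ``spec.constrained``; ``beta2``
    columns follow ``spec.unconstrained``.  ``C`` (k1 x d) and ``B``
    (d x r) optionally carry a factorization beta1 = C B.
    """

    eta_bar1: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    eta_bar2: np.ndarray
    C: Optional[np.ndarray] = None
    B: Optional[np.ndarray] = None

    def __post_init__(self):
        self.eta_bar1 = np.asarray(self.eta_bar1, dtype=float).ravel()
        self.beta1 = np.atleast_2d(np.asarray(self.beta1, dtype=float))
        self.beta2 = np.asarray(self.beta2, dtype=float).reshape(
            self.beta1.shape[0], -1
        )
        self.eta_bar2 = np.asarray(self.eta_bar2, dtype=float).ravel()
        if self.C is not None:
            self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        if self.B is not None:
            self.B = np.atleast_2d(np.asarray(self.B, dtype=float))

    @property
    def beta(self) -> np.ndarray:
        """Full k1 x p coefficient matrix in internal (x1, x2) column order."""
        return np.concatenate([self.beta1, self.beta2], axis=1)

    def pack(self) -> np.ndarray:
        """xi = (eta_bar1, vec(beta1), vec(beta2), eta_bar2), column-stacked vec."""
        return np.concatenate(
            [
                self.eta_bar1,
                self.beta1.ravel(order="F"),
                self.beta2.ravel(order="F"),
                self.eta_bar2,
            ]
        )

    @classmethod
    def unpack(cls, xi: np.ndarray, spec: ModelSpec) -> "ParamVector":
        xi = np.asarray(xi, dtype=float).ravel()
        k1, k2, p, r = spec.k1, spec.k2, spec.p, spec.r
        if xi.size != spec.n_params:
            raise ValueError(
                f"xi has length {xi.size}, expected {spec.n_params}"
            )
        a = k1
        b = a + k1 * r
        c = b + k1 * (p - r)
        return cls(
            eta_bar1=xi[:a],
            beta1=xi[a:b].reshape(k1, r, order="F"),
            beta2=xi[b:c].reshape(k1, p - r, order="F"),
            eta_bar2=xi[c:],
        )

    def copy(self) -> "ParamVector":
        return ParamVector(
            self.eta_bar1.copy(),
            self.beta1.copy(),
            self.beta2.copy(),
            self.eta_bar2.copy(),
            None if self.C is None else self.C.copy(),
            None if self.B is None else self.B.copy(),
        )


def build_F(x: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Design operator F(x): k x (k1 + k1*p + k2) with F(x) xi = eta_x.

    ``x`` is in the caller's original column order; it is reordered to the
    internal (constrained, unconstrained) convention.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size != spec.p:
        raise ValueError(f"x must have length p={spec.p}, got {x.size}")
    return design_tensor(x[None, :], spec)[0]


def design_tensor(X: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Stacked design operators: (n, k, n_params) array with D[i] = F(x_i)."""
    Xo = spec.reorder(X)
    n = Xo.shape[0]
    k1, k2, p = spec.k1, spec.k2, spec.p
    D = np.zeros((n, k1 + k2, spec.n_params))
    Xt = np.column_stack([np.ones(n), Xo])
    for j in range(p + 1):
        for a in range(k1):
            D[:, a, j * k1 + a] = Xt[:, j]
    if k2:
        D[:, k1:, k1 * (p + 1):] = np.eye(k2)
    return D


def eta_of_x(params: ParamVector, x: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Natural parameter eta_x = (eta_bar1 + beta1 x1 + beta2 x2, eta_bar2)."""
    x = np.asarray(x, dtype=float).ravel()
    xo = spec.reorder(x[None, :])[0]
    eta1 = (
        params.eta_bar1
        + params.beta1 @ xo[: spec.r]
        + params.beta2 @ xo[spec.r:]
    )
    return np.concatenate([eta1, params.eta_bar2])


def eta_matrix(params: ParamVector, X: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """(n, k) natural parameters for all rows of X."""
    Xo = spec.reorder(X)
    eta1 = (
        params.eta_bar1[None, :]
        + Xo[:, : spec.r] @ params.beta1.T
        + Xo[:, spec.r:] @ params.beta2.T
    )
    if spec.k2 == 0:
        return eta1
    n = Xo.shape[0]
    return np.concatenate(
        [eta1, np.broadcast_to(params.eta_bar2, (n, spec.k2))], axis=1
    )


def count_parameters(spec: ModelSpec, restricted: bool = False) -> int:
    """Number of raw parameters.

    Unrestricted: entries of (eta_bar1, beta, eta_bar2) = k1 + k1*p + k2.
    Restricted:   entries of (eta_bar1, C, B, beta2, eta_bar2)
                  = k1 + k1*d + d*r + k1*(p-r) + k2
    (raw factor entries; the d^2 reparametrization redundancy of (C, B) is
    not subtracted here -- AIC accounts for it separately).
    """
    k1, k2, p = spec.k1, spec.k2, spec.p
    if not restricted:
        return k1 + k1 * p + k2
    if spec.d is None:
        raise ValueError("restricted count needs a rank d in the spec")
    d, r = spec.d, spec.r
    return k1 + k1 * d + d * r + k1 * (p - r) + k2
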