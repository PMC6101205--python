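"""Model / Results interface for partial reduced-rank multivariate GLMs.

`ReducedRankGLM` is built from data plus a family, an optional set of
rank-constrained predictor columns and a rank; `fit()` returns a
`ReducedRankGLMResults` carrying the estimate, its asymptotic covariance,
per-coordinate standard errors and Wald inference, mirroring the
model/results split of classical regression packages.

Example
-------
>>> from rrglm import ReducedRankGLM, Multinomial
>>> from rrglm.simulate import workforce_like_scenario, simulate_dataset
>>> X, y = simulate_dataset(workforce_like_scenario(n=4105, seed=7))
>>> model = ReducedRankGLM(y, X, family=Multinomial(4),
...                        constrained=list(range(12)), rank=1)
>>> res = model.fit()
>>> res.params_table.head()          # doctest: +SKIP
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import ModelSpec, ParamVector, count_parameters
from .estimate import FitResult, fit_full, fit_reduced, loglik
from .expfam import ExponentialFamily
from .inference import (
    AsymCov,
    aic_rank_path,
    asymptotic_covariance,
    bootstrap_cov,
    wald_table,
)


class ReducedRankGLM:
    """Multivariate GLM with an optional rank restriction on a coefficient block.

    Parameters
    ----------
    endog : array-like
        Responses in family-native coding (multinomial: integer labels
        1..q or an n x q indicator matrix; Poisson / Gaussian: n x q
        matrices).
    exog : DataFrame or array-like
        n x p predictor matrix, without an intercept column (an intercept
        is always included and never rank-constrained).
    family : ExponentialFamily
    constrained : sequence of column names or indices, optional
        Predictors whose joint coefficient block beta1 is rank-bounded.
        Defaults to all columns.
    rank : int, optional
        Rank bound d for beta1; ``None`` fits the unrestricted model.
    """

    def __init__(self, endog, exog, family: ExponentialFamily,
                 constrained: Optional[Sequence] = None,
                 rank: Optional[int] = None):
        if isinstance(exog, pd.DataFrame):
            names = tuple(str(c) for c in exog.columns)
            X = exog.to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(exog, dtype=float))
            names = tuple(f"x{j + 1}" for j in range(X.shape[1]))
        cons = None
        if constrained is not None:
            cons = tuple(
                names.index(c) if isinstance(c, str) else int(c)
                for c in constrained
            )
        self.endog = endog
        self.exog = X
        self.spec = ModelSpec(family=family, p=X.shape[1],
                              constrained=cons, d=rank, names=names)

    @classmethod
    def from_dataframes(cls, y: pd.DataFrame | pd.Series, X: pd.DataFrame,
                        family: ExponentialFamily,
                        constrained: Optional[Sequence] = None,
                        rank: Optional[int] = None) -> "ReducedRankGLM":
        y_arr = y.to_numpy() if hasattr(y, "to_numpy") else np.asarray(y)
        return cls(y_arr, X, family, constrained=constrained, rank=rank)

    @property
    def family(self) -> ExponentialFamily:
        return self.spec.family

    def fit(self, init: Optional[ParamVector] = None,
            **kwargs) -> "ReducedRankGLMResults":
        """Maximum likelihood fit; restricted iff a rank was given."""
        if self.spec.d is None:
            raw = fit_full(self.exog, self.endog, self.spec, **kwargs)
        else:
            raw = fit_reduced(self.exog, self.endog, self.spec, init=init,
                              **kwargs)
        return ReducedRankGLMResults(self, raw)

    def loglik(self, params: ParamVector) -> float:
        return loglik(params, self.exog, self.endog, self.spec)

    def rank_path(self, ranks: Sequence[int]) -> pd.DataFrame:
        """AIC over candidate ranks (see :func:`rrglm.inference.aic_rank_path`)."""
        base = self.spec.with_rank(min(self.spec.k1, self.spec.r))
        return aic_rank_path(self.exog, self.endog, base, ranks)


class ReducedRankGLMResults:
    """Estimates, uncertainty and diagnostics of a fitted model."""

    def __init__(self, model: ReducedRankGLM, raw: FitResult):
        self.model = model
        self.raw = raw
        self._cov: Optional[AsymCov] = None

    # -- basic accessors --------------------------------------------------
    @property
    def spec(self) -> ModelSpec:
        return self.raw.spec

    @property
    def param_vector(self) -> ParamVector:
        return self.raw.params

    @property
    def params(self) -> np.ndarray:
        """Packed xi = (eta_bar1, vec beta1, vec beta2, eta_bar2)."""
        return self.raw.params.pack()

    @property
    def nobs(self) -> int:
        return self.model.exog.shape[0]

    @property
    def converged(self) -> bool:
        return self.raw.converged

    @property
    def loglik_trace(self) -> list:
        return self.raw.loglik_trace

    @property
    def llf(self) -> float:
        """Total log-likelihood n * L_n (base measure omitted)."""
        return self.nobs * self.raw.loglik

    @property
    def df_model(self) -> int:
        """Effective number of free parameters (factor redundancy removed)."""
        if not self.raw.restricted:
            return count_parameters(self.spec)
        return count_parameters(self.spec, restricted=True) - self.spec.d**2

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.df_model

    # -- covariance and inference ----------------------------------------
    @property
    def cov(self) -> AsymCov:
        """Plug-in asymptotic covariance of sqrt(n)(xi_hat - xi0)."""
        if self._cov is None:
            self._cov = asymptotic_covariance(self.raw, self.model.exog)
        return self._cov

    @property
    def bse(self) -> np.ndarray:
        return self.cov.se

    @property
    def params_table(self) -> pd.DataFrame:
        return self.wald_table()

    def wald_table(self, level: float = 0.95) -> pd.DataFrame:
        return wald_table(self.raw, self.cov, level=level)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        tab = self.wald_table(level=1.0 - alpha)
        return tab[["ci_low", "ci_high"]].to_numpy()

    def bootstrap_cov(self, n_boot: int = 200, seed=None) -> np.ndarray:
        return bootstrap_cov(self.model.exog, self.model.endog, self.spec,
                             n_boot=n_boot, seed=seed)

    # -- presentation ------------------------------------------------------
    def summary(self, level: float = 0.95) -> str:
        """Plain-text summary table, coefficients with SEs in parentheses."""
        from .io import format_report

        head = [
            f"Partial reduced-rank multivariate GLM ({self.spec.family.name})",
            f"n = {self.nobs}    restricted = {self.raw.restricted}"
            + (f" (rank d = {self.spec.d})" if self.raw.restricted else ""),
            f"log-likelihood = {self.llf:.3f}    AIC = {self.aic:.3f}    "
            f"free parameters = {self.df_model}",
            f"converged = {self.raw.converged} after {self.raw.n_iter} "
            "iterations",
            "",
        ]
        return "\n".join(head) + format_report(self.wald_table(level))

    def plot_loglik_trace(self, ax=None):  # pragma: no cover - optional viz
        """Diagnostic plot of the (nondecreasing) log-likelihood trace."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.raw.loglik_trace, marker=".")
        ax.set_xlabel("iteration")
        ax.set_ylabel("average log-likelihood")
        return ax

    def __repr__(self) -> str:  # pragma: no cover
        kind = "restricted" if self.raw.restricted else "full-rank"
        return (f"<ReducedRankGLMResults {kind}, n={self.nobs}, "
                f"llf={self.llf:.3f}, converged={self.converged}>")
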