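"""Shared fixtures.

The workforce-like Monte-Carlo battery (1000 restricted fits at n = 2000)
and the AIC rank-selection battery (100 datasets at n = 4000) are
session-scoped because several sampling-distribution checks share them:
the empirical covariance of the estimator, confidence-interval coverage,
type-I error of the Wald test, and rank recovery.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rrglm import (
    ModelSpec,
    Multinomial,
    ParamVector,
    fit_reduced,
)
from rrglm.inference import aic_rank_path, asymptotic_covariance, avar_reduced, build_G, estimate_W
from rrglm.simulate import Scenario, simulate_dataset, workforce_like_scenario

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_reduced_instance(rng, k1=None, r=None, d=None, p_extra=None):
    """A random small multinomial spec with rank-d true parameters."""
    k1 = k1 or int(rng.integers(2, 5))
    r = r or int(rng.integers(2, 6))
    d = d or int(rng.integers(1, min(k1, r) + 1))
    p_extra = int(rng.integers(0, 3)) if p_extra is None else p_extra
    p = r + p_extra
    spec = ModelSpec(Multinomial(k1 + 1), p, constrained=tuple(range(r)), d=d)
    C = rng.standard_normal((k1, d))
    B = rng.standard_normal((d, r))
    params = ParamVector(
        eta_bar1=0.3 * rng.standard_normal(k1),
        beta1=C @ B,
        beta2=0.5 * rng.standard_normal((k1, p - r)),
        eta_bar2=np.zeros(0),
        C=C,
        B=B,
    )
    return spec, params


@pytest.fixture(scope="session")
def workforce_scenario():
    return workforce_like_scenario(n=2000, seed=0)


@pytest.fixture(scope="session")
def workforce_truth_avar(workforce_scenario):
    """Analytic asymptotic covariance at the true parameters.

    W is evaluated at the truth with the predictor expectation replaced by
    a 200k-draw average over the predictor law.
    """
    scen = workforce_scenario
    big = Scenario(scen.spec, scen.true_params, scen.predictor_laws,
                   n=200_000, seed=987)
    Xbig, _ = simulate_dataset(big)
    W = estimate_W(Xbig.to_numpy(), scen.true_params, scen.spec)
    G = build_G(scen.true_params.C, scen.true_params.B, scen.spec)
    return avar_reduced(W, G, n=scen.n)


@pytest.fixture(scope="session")
def workforce_battery(workforce_scenario):
    """1000 restricted fits of workforce-like replicates at n = 2000.

    Returns (scenario, xi_hats, ses, n_failed) with one row per converged
    replicate: the packed estimate and its plug-in standard errors.
    """
    scen = workforce_scenario
    xis, ses = [], []
    n_failed = 0
    for rep in range(1000):
        X, y = simulate_dataset(scen, seed=10_000 + rep)
        Xn = X.to_numpy()
        fit = fit_reduced(Xn, y, scen.spec)
        if not fit.converged:
            n_failed += 1
            continue
        cov = asymptotic_covariance(fit, Xn)
        xis.append(fit.params.pack())
        ses.append(cov.se)
    return scen, np.asarray(xis), np.asarray(ses), n_failed


@pytest.fixture(scope="session")
def aic_battery():
    """AIC-selected ranks over 100 strong-signal rank-1 replicates at n = 4000."""
    scen = workforce_like_scenario(n=4000, seed=55)
    selected = []
    for rep in range(100):
        X, y = simulate_dataset(scen, seed=40_000 + rep)
        tab = aic_rank_path(X.to_numpy(), y, scen.spec, ranks=[1, 2, 3])
        sel = tab.loc[tab["selected"], "rank"]
        selected.append(int(sel.iloc[0]) if len(sel) else -1)
    return np.asarray(selected)
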