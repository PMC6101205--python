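"""Synthetic data generation for partial reduced-rank multivariate GLMs.

A :class:`Scenario` couples a model specification, true parameters with a
rank-d coefficient block stored in corner-factor form, and a sampling law
for each predictor column.  ``simulate_dataset`` draws predictors i.i.d.
from those laws and responses from the family at eta_x.

``workforce_like_scenario`` builds a look-alike of a workforce
questionnaire study: a 4-category marital-status response (married /
partnered as the reference and most frequent category), twelve binary
lifestyle and psychological indicators whose coefficient matrix has rank
one, and two unconstrained continuous covariates (centered age in years
and a log-education score).  Coefficient magnitudes are of the order
0.0-1.1 on the log-odds scale.  The binary predictors are simulated
independently -- a deliberate simplification; real questionnaire items
are correlated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import ModelSpec, ParamVector, eta_matrix
from .expfam import DomainError, Multinomial


@dataclass(frozen=True)
class PredictorLaw:
    """Marginal law of one predictor column.

    kind 'bernoulli' uses ``prob``; kind 'normal' uses ``mean`` and ``sd``.
    """

    kind: str
    prob: float = 0.5
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self):
        if self.kind not in ("bernoulli", "normal"):
            raise ValueError(f"unknown predictor law {self.kind!r}")
        if self.kind == "bernoulli" and not 0 < self.prob < 1:
            raise ValueError("bernoulli success probability must be in (0,1)")
        if self.kind == "normal" and self.sd <= 0:
            raise ValueError("normal sd must be positive")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "bernoulli":
            return (rng.random(n) < self.prob).astype(float)
        return self.mean + self.sd * rng.standard_normal(n)


@dataclass
class Scenario:
    spec: ModelSpec
    true_params: ParamVector
    predictor_laws: Sequence[PredictorLaw]
    n: int
    seed: int = 0

    def __post_init__(self):
        if len(self.predictor_laws) != self.spec.p:
            raise ValueError(
                f"need one predictor law per column ({self.spec.p}), "
                f"got {len(self.predictor_laws)}"
            )
        if self.spec.d is not None:
            b1 = self.true_params.beta1
            if np.linalg.matrix_rank(b1) != self.spec.d:
                raise ValueError(
                    f"true beta1 must have rank exactly d={self.spec.d}"
                )


def simulate_dataset(scenario: Scenario, seed=None):
    """Draw (X, Y) from a scenario; X is a named DataFrame, Y a label/response array.

    ``seed`` overrides the scenario's stored seed, so replicate batteries
    can reuse one scenario object.
    """
    spec = scenario.spec
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n = scenario.n
    X = np.column_stack(
        [law.draw(n, rng) for law in scenario.predictor_laws]
    )
    etas = eta_matrix(scenario.true_params, X, spec)
    if not spec.family.domain_ok(etas):
        raise DomainError(
            "scenario parameters push eta_x outside the family domain; "
            "check true_params against the predictor laws"
        )
    Y = spec.family.sample_conditional(etas, rng)
    names = spec.names or tuple(f"x{j + 1}" for j in range(spec.p))
    return pd.DataFrame(X, columns=list(names)), Y


# ---------------------------------------------------------------------------
# the workforce look-alike study design
# ---------------------------------------------------------------------------

BINARY_NAMES = (
    "binge", "smokenow", "sun", "nerves", "nervous", "hurt",
    "tense", "miserable", "fedup", "worry", "worrier", "mood",
)
CONTINUOUS_NAMES = ("age30", "logedu1")

# moderate questionnaire prevalences for the twelve binary items
_BINARY_PREVALENCE = (
    0.25, 0.30, 0.35, 0.25, 0.20, 0.40, 0.30, 0.25, 0.30, 0.40, 0.25, 0.45,
)

# rank-1 structure: per-contrast scaling (corner form, leading entry 1)
# and per-predictor loadings on the first log-odds contrast, spanning the
# 0.0-1.1 log-odds range ("worry" exactly null); strengths are set so the
# identified product C B is recoverable to ~10% at study-scale samples
_C0 = np.array([[1.0], [1.38], [1.96]])
_B0 = np.array(
    [[1.05, 0.85, 0.60, -0.50, 0.75, 0.55,
      0.70, 0.40, 0.45, 0.0, -0.65, 0.35]]
)
# unconstrained block: centered age (per year) and log-education effects
_BETA2 = np.array(
    [
        [-0.19, 0.34],
        [0.012, -0.37],
        [0.086, -0.09],
    ]
)
# intercepts keep the reference (married/partnered) category most
# frequent (~65% marginally) while leaving every category populated at
# study-scale n (the rarest, widower-like category sits near 5%)
_ETA_BAR1 = np.array([-3.92, -3.64, -6.48])


def workforce_like_scenario(n: int, seed: int = 0) -> Scenario:
    """Multinomial q=4 scenario emulating the workforce study design.

    Twelve binary rank-constrained predictors (rank-1 coefficient block),
    two continuous unconstrained ones, 45 unrestricted / 24 restricted
    parameters.
    """
    if n < 100:
        raise ValueError("need n >= 100 for a meaningful study replicate")
    family = Multinomial(4)
    names = BINARY_NAMES + CONTINUOUS_NAMES
    spec = ModelSpec(
        family=family,
        p=14,
        constrained=tuple(range(12)),
        d=1,
        names=names,
    )
    params = ParamVector(
        eta_bar1=_ETA_BAR1.copy(),
        beta1=_C0 @ _B0,
        beta2=_BETA2.copy(),
        eta_bar2=np.zeros(0),
        C=_C0.copy(),
        B=_B0.copy(),
    )
    laws = [PredictorLaw("bernoulli", prob=pr) for pr in _BINARY_PREVALENCE]
    laws.append(PredictorLaw("normal", mean=0.0, sd=10.0))   # age30
    laws.append(PredictorLaw("normal", mean=1.4, sd=0.5))    # logedu1
    return Scenario(spec=spec, true_params=params,
                    predictor_laws=tuple(laws), n=n, seed=seed)


def scenario_from_config(cfg: dict) -> Scenario:
    """Build a Scenario from a parsed YAML/JSON config dictionary."""
    from .expfam import family_by_name

    if cfg.get("scenario") == "workforce":
        return workforce_like_scenario(int(cfg["n"]), int(cfg.get("seed", 0)))
    family = family_by_name(cfg["family"], int(cfg["q"]))
    laws = []
    for law in cfg["predictors"]:
        laws.append(PredictorLaw(**law))
    spec = ModelSpec(
        family=family,
        p=len(laws),
        constrained=tuple(cfg["constrained"]) if cfg.get("constrained") else None,
        d=cfg.get("rank"),
        names=tuple(cfg["names"]) if cfg.get("names") else None,
    )
    pr = cfg["params"]
    params = ParamVector(
        eta_bar1=np.asarray(pr["eta_bar1"], dtype=float),
        beta1=np.asarray(pr["beta1"], dtype=float),
        beta2=np.asarray(pr.get("beta2", np.zeros((spec.k1, 0))), dtype=float),
        eta_bar2=np.asarray(pr.get("eta_bar2", []), dtype=float),
    )
    return Scenario(spec=spec, true_params=params, predictor_laws=tuple(laws),
                    n=int(cfg["n"]), seed=int(cfg.get("seed", 0)))
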