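"""CSV / JSON / YAML readers and writers, and report formatting.

Data live in headered CSV files: predictors as an n x p numeric table,
responses either as a single column of integer category labels 1..q
(multinomial) or as an n x q numeric table (Poisson counts, Gaussian
reals).  Fits are serialized to JSON; scenarios and run configs to YAML.
Reports mirror the usual presentation of multinomial fits: one row per
predictor, one column per log-odds contrast, standard errors in
parentheses and a star at the 5% level.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ModelSpec, ParamVector
from .estimate import FitResult
from .expfam import ExponentialFamily, Gaussian, Multinomial, family_by_name


def read_dataset(path_x, path_y, family: ExponentialFamily):
    """Read predictors and responses from CSV, validating coding.

    Returns ``(X, Y)`` with ``X`` a numeric DataFrame (column names kept)
    and ``Y`` family-native (label vector for multinomial, numeric matrix
    otherwise).
    """
    X = pd.read_csv(path_x, float_precision="round_trip")
    bad = [c for c in X.columns if not np.issubdtype(X[c].dtype, np.number)]
    if bad:
        raise ValueError(f"non-numeric predictor columns: {bad}")
    Ydf = pd.read_csv(path_y, float_precision="round_trip")
    if len(Ydf) != len(X):
        raise ValueError(
            f"row-count mismatch: {len(X)} predictor rows vs "
            f"{len(Ydf)} response rows"
        )
    if isinstance(family, Multinomial):
        if Ydf.shape[1] == family.q:
            Y = Ydf.to_numpy(dtype=float)
        else:
            if Ydf.shape[1] != 1:
                raise ValueError(
                    "multinomial responses must be one label column or "
                    f"{family.q} indicator columns"
                )
            col = Ydf.iloc[:, 0]
            vals = col.to_numpy()
            if not np.all(vals == np.round(vals.astype(float))):
                bad_row = int(np.argmax(vals != np.round(vals.astype(float))))
                raise ValueError(
                    f"non-integer category label in row {bad_row}"
                )
            labels = vals.astype(int)
            unknown = (labels < 1) | (labels > family.q)
            if unknown.any():
                raise ValueError(
                    f"unknown category label {labels[unknown][0]} in row "
                    f"{int(np.argmax(unknown))}; expected 1..{family.q}"
                )
            seen = set(labels.tolist())
            missing = sorted(set(range(1, family.q + 1)) - seen)
            if missing:
                warnings.warn(
                    f"categories {missing} absent from the response; "
                    "their indicators are all zero",
                    stacklevel=2,
                )
            Y = labels
    else:
        Y = Ydf.to_numpy(dtype=float)
    return X, Y


def write_dataset(X: pd.DataFrame, Y, path_x, path_y,
                  family: ExponentialFamily) -> None:
    X.to_csv(path_x, index=False)
    Y = np.asarray(Y)
    if Y.ndim == 1:
        pd.DataFrame({"y": Y}).to_csv(path_y, index=False)
    else:
        cols = [f"y{i + 1}" for i in range(Y.shape[1])]
        pd.DataFrame(Y, columns=cols).to_csv(path_y, index=False)


# ---------------------------------------------------------------------------
# fit serialization
# ---------------------------------------------------------------------------

def fit_to_dict(fit: FitResult) -> dict:
    spec = fit.spec
    fam = spec.family
    d = {
        "family": {"name": type(fam).__name__.lower(), "q": getattr(fam, "q", None)},
        "p": spec.p,
        "constrained": list(spec.constrained),
        "rank": spec.d,
        "names": list(spec.names) if spec.names else None,
        "restricted": fit.restricted,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "message": fit.message,
        "loglik_trace": [float(v) for v in fit.loglik_trace],
        "params": {
            "eta_bar1": fit.params.eta_bar1.tolist(),
            "beta1": fit.params.beta1.tolist(),
            "beta2": fit.params.beta2.tolist(),
            "eta_bar2": fit.params.eta_bar2.tolist(),
            "C": None if fit.params.C is None else fit.params.C.tolist(),
            "B": None if fit.params.B is None else fit.params.B.tolist(),
        },
    }
    if isinstance(fam, Gaussian):
        d["family"]["sigma2"] = fam.sigma2
    return d


def fit_from_dict(d: dict) -> FitResult:
    famd = d["family"]
    kwargs = {}
    if famd["name"] == "gaussian" and famd.get("sigma2") is not None:
        kwargs["sigma2"] = famd["sigma2"]
    family = family_by_name(famd["name"], famd["q"], **kwargs)
    spec = ModelSpec(
        family=family,
        p=d["p"],
        constrained=tuple(d["constrained"]),
        d=d["rank"],
        names=tuple(d["names"]) if d.get("names") else None,
    )
    pr = d["params"]
    params = ParamVector(
        eta_bar1=np.asarray(pr["eta_bar1"]),
        beta1=np.asarray(pr["beta1"]),
        beta2=np.asarray(pr["beta2"]),
        eta_bar2=np.asarray(pr["eta_bar2"]),
        C=None if pr["C"] is None else np.asarray(pr["C"]),
        B=None if pr["B"] is None else np.asarray(pr["B"]),
    )
    return FitResult(params, list(d["loglik_trace"]), d["converged"],
                     d["n_iter"], d["restricted"], spec,
                     d.get("message", ""))


def save_fit(fit: FitResult, path) -> None:
    Path(path).write_text(json.dumps(fit_to_dict(fit), indent=2) + "\n")


def load_fit(path) -> FitResult:
    return fit_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def pivot_report(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a Wald table to predictor rows x contrast columns.

    Each cell reads ``estimate[*] (se)`` with the star marking 5%
    significance, e.g. ``0.569* (0.125)``.
    """
    tab = table.copy()
    tab["cell"] = [
        f"{est:.3f}{sig} ({se:.3f})"
        for est, sig, se in zip(tab["estimate"], tab["sig"], tab["se"])
    ]
    order = tab["predictor"].drop_duplicates().tolist()
    wide = tab.pivot_table(
        index="predictor", columns="contrast", values="cell",
        aggfunc="first", sort=False,
    )
    contrasts = tab["contrast"].drop_duplicates().tolist()
    return wide.reindex(index=order, columns=contrasts)


def format_report(table: pd.DataFrame) -> str:
    wide = pivot_report(table)
    return wide.to_string() + "\n\n* significant at the 5% level\n"


def write_report(fit: FitResult, table: pd.DataFrame, path) -> Path:
    """Write a fitted-model report as CSV plus a text rendering.

    ``path`` is the CSV destination; a sibling ``.txt`` file holds the
    human-readable layout.  Refuses non-converged fits.
    """
    if not fit.converged:
        raise ValueError("refusing to report a non-converged fit: "
                         + (fit.message or "no convergence"))
    path = Path(path)
    wide = pivot_report(table)
    wide.to_csv(path)
    txt = path.with_suffix(".txt")
    txt.write_text(format_report(table))
    return path
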