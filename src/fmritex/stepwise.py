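"""Forward stepwise binary logistic regression for E vs NE discrimination.

Class coding is E = 1, NE = 0 (the positive class is true functional
activity, so sensitivity is defined on E). Selection is classic forward
stepwise with bidirectional pruning: at each round the candidate whose
entry-test p-value is smallest and below ``p_enter`` (default 0.05) joins
the model, unless the enlarged model's AIC would exceed the current one
(the overfitting guard); any included term whose p-value rises above
``p_remove`` (default 0.15) is then dropped, largest first. Entry/removal
tests are Wald tests on the term by default; a likelihood-ratio variant is
available. Features enter on their raw scale.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from fmritex.errors import SchemaError, SeparationWarning, SingularDesignError
from fmritex.volumes import E, NE


def encode_labels(labels) -> np.ndarray:
    """Map E/NE labels to 1/0."""
    arr = np.asarray(labels)
    bad = set(np.unique(arr)) - {E, NE}
    if bad:
        raise ValueError(f"labels must be E or NE, got extras {sorted(bad)}")
    return (arr == E).astype(float)


@dataclasses.dataclass
class FittedLogit:
    """A maximum-likelihood logistic fit with its Wald table."""

    features: list[str]
    params: pd.Series          # intercept ('const') + one per feature
    bse: pd.Series
    wald_z: pd.Series
    wald_p: pd.Series
    llf: float
    aic: float
    separation: bool = False


def _design(table: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise SchemaError(f"feature table missing columns {missing}")
    X = table[list(features)].astype(float)
    return sm.add_constant(X, has_constant="add")


def fit_logistic(table: pd.DataFrame, features) -> FittedLogit:
    """Fit logit(P(E)) = b0 + b'x by maximum likelihood.

    The problem is convex, so the fit is deterministic given the data.
    Quasi-perfect separation is flagged (SeparationWarning) and the
    coefficients of the interrupted fit are still reported; a rank-deficient
    design (e.g. a constant feature) raises SingularDesignError.
    """
    features = list(features)
    y = encode_labels(table["label"])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit")
    X = _design(table, features)
    for col in features:
        if X[col].nunique() < 2:
            raise SingularDesignError(f"feature {col!r} is constant")
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")

    model = sm.Logit(y, X)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = model.fit(disp=0, maxiter=100)
        except (PerfectSeparationError, PerfectSeparationWarning,
                np.linalg.LinAlgError):
            # a singular Hessian on a tiny or quasi-separated sample is
            # handled like separation: refit by BFGS and flag
            separation = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(disp=0, method="bfgs", maxiter=200)
    if separation:
        warnings.warn("perfect separation detected; coefficients are not "
                      "finite MLEs", SeparationWarning)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = res.params / res.bse
        p = 2.0 * stats.norm.sf(np.abs(z))
    return FittedLogit(features=features,
                       params=res.params, bse=res.bse,
                       wald_z=pd.Series(z, index=res.params.index),
                       wald_p=pd.Series(p, index=res.params.index),
                       llf=float(res.llf), aic=float(res.aic),
                       separation=separation)


def _entry_p(table: pd.DataFrame, current: list[str], candidate: str,
             base: FittedLogit, test: str) -> tuple[float, FittedLogit]:
    fit = fit_logistic(table, current + [candidate])
    # Wald p-values collapse toward 1 under (quasi-)separation (the
    # Hauck-Donner effect); fall back to the likelihood-ratio test there.
    if test == "wald" and not fit.separation:
        return float(fit.wald_p[candidate]), fit
    # likelihood-ratio test on the added term (1 df)
    lr = 2.0 * (fit.llf - base.llf)
    return float(stats.chi2.sf(max(lr, 0.0), 1)), fit


@dataclasses.dataclass
class StepwiseModel:
    """Result of stepwise selection: terms, coefficients and the step log."""

    selected_features: list[str]
    coefficients: dict[str, float]   # 'const' + selected features, log-odds
    wald_stats: dict[str, dict]      # per term: z, p
    aic_trace: list[float]           # AIC after each accepted step
    step_log: list[dict]             # entries/removals with p-values
    final_fit: FittedLogit | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "selected_features": self.selected_features,
            "coefficients": self.coefficients,
            "wald_stats": self.wald_stats,
            "aic_trace": self.aic_trace,
            "step_log": self.step_log,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "StepwiseModel":
        d = json.loads(text)
        return cls(selected_features=d["selected_features"],
                   coefficients=d["coefficients"],
                   wald_stats=d["wald_stats"], aic_trace=d["aic_trace"],
                   step_log=d["step_log"])


def stepwise_select(table: pd.DataFrame, p_enter: float = 0.05,
                    p_remove: float = 0.15, candidates=None,
                    test: str = "wald") -> StepwiseModel:
    """Forward stepwise selection with removal pruning and an AIC guard.

    Stops when no candidate's entry p-value is below ``p_enter`` or when the
    best addition would raise the AIC. Equal candidate p-values break ties
    by feature name, so the step log is fully deterministic.
    """
    if table.empty:
        raise ValueError("empty feature table")
    if p_enter > p_remove:
        raise ValueError("p_enter must be <= p_remove (else selection cycles)")
    if test not in ("wald", "lr"):
        raise ValueError("test must be 'wald' or 'lr'")
    if candidates is None:
        reserved = {"subject_id", "roi_id", "label",
                    "n_levels", "distance", "voxel_count"}  # provenance
        candidates = [c for c in table.columns if c not in reserved
                      and pd.api.types.is_numeric_dtype(table[c])]
    candidates = list(candidates)

    selected: list[str] = []
    current = fit_logistic(table, [])
    aic_trace = [current.aic]
    step_log: list[dict] = []

    while True:
        pool = sorted(c for c in candidates if c not in selected)
        best: tuple[float, str, FittedLogit] | None = None
        for cand in pool:
            try:
                p, fit = _entry_p(table, selected, cand, current, test)
            except SingularDesignError:
                continue
            if p < p_enter and (best is None or p < best[0]):
                best = (p, cand, fit)
        if best is None:
            break
        p_best, cand, fit = best
        if fit.aic > current.aic:
            step_log.append({"action": "reject_aic", "feature": cand,
                             "p": p_best, "aic": fit.aic})
            break
        selected.append(cand)
        current = fit
        aic_trace.append(current.aic)
        step_log.append({"action": "enter", "feature": cand, "p": p_best,
                         "aic": current.aic})

        # removal phase: drop the worst offender until all terms survive
        # (skipped under separation, where Wald p-values are meaningless)
        while len(selected) > 1 and not current.separation:
            worst = max(selected, key=lambda f: (current.wald_p[f], f))
            p_worst = float(current.wald_p[worst])
            if p_worst <= p_remove:
                break
            selected.remove(worst)
            current = fit_logistic(table, selected)
            aic_trace.append(current.aic)
            step_log.append({"action": "remove", "feature": worst,
                             "p": p_worst, "aic": current.aic})

    wald = {term: {"z": float(current.wald_z[term]),
                   "p": float(current.wald_p[term])}
            for term in current.params.index}
    return StepwiseModel(selected_features=list(selected),
                         coefficients={k: float(v)
                                       for k, v in current.params.items()},
                         wald_stats=wald, aic_trace=aic_trace,
                         step_log=step_log, final_fit=current)


def predict(model: StepwiseModel, rows: pd.DataFrame) -> np.ndarray:
    """Probability of E per row via the inverse logit of the linear predictor."""
    missing = [f for f in model.selected_features if f not in rows.columns]
    if missing:
        raise SchemaError(f"prediction input missing features {missing}")
    eta = np.full(len(rows), model.coefficients.get("const", 0.0))
    for feat in model.selected_features:
        eta = eta + model.coefficients[feat] * rows[feat].to_numpy(dtype=float)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-eta))


def odds_ratios(model: StepwiseModel, alpha: float = 0.05) -> pd.DataFrame:
    """exp(coefficient) per selected term with a Wald significance flag."""
    rows = []
    for feat in model.selected_features:
        p = model.wald_stats[feat]["p"]
        rows.append({"feature": feat,
                     "odds_ratio": float(np.exp(model.coefficients[feat])),
                     "wald_p": p, "significant": bool(p < alpha)})
    return pd.DataFrame(rows, columns=["feature", "odds_ratio", "wald_p",
                                       "significant"])


def model_table(model: StepwiseModel) -> pd.DataFrame:
    """Regression-table export: estimate, |z| and p per term."""
    rows = []
    for term in ["const"] + model.selected_features:
        rows.append({"term": "(Intercept)" if term == "const" else term,
                     "estimate": model.coefficients[term],
                     "abs_z": abs(model.wald_stats[term]["z"]),
                     "p_value": model.wald_stats[term]["p"]})
    return pd.DataFrame(rows)
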