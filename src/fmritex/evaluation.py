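"""Patient-grouped repeated-holdout evaluation with ROC analysis.

Training and test ROIs always come from disjoint subject sets, so the model
is never scored on a patient it has seen — the grouped analogue of the
study design (12 of 15 subjects train, 3 test, repeated 100 times with
replacement across repeats). Per repeat the pipeline refits the stepwise
model on the training ROIs only, then reports accuracy at threshold 0.5,
trapezoidal AUC, and the Youden-optimal sensitivity/specificity on the
held-out ROIs; aggregates are arithmetic means over repeats.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from fmritex.errors import DegenerateStatisticWarning, UndefinedAUCError
from fmritex.stepwise import encode_labels, predict, stepwise_select


@dataclasses.dataclass(frozen=True)
class SplitPlan:
    repeat_index: int
    train_subjects: frozenset[str]
    test_subjects: frozenset[str]
    seed: int

    def __post_init__(self) -> None:
        if self.train_subjects & self.test_subjects:
            raise ValueError("train and test subject sets overlap")


def make_splits(subjects, n_train: int, n_repeats: int,
                seed: int) -> list[SplitPlan]:
    """Uniform random subject-level partitions, reproducible from the seed.

    Partitions are drawn independently per repeat (the same split may recur
    across repeats).
    """
    uniq = sorted(set(map(str, subjects)))
    if not 1 <= n_train < len(uniq):
        raise ValueError(
            f"n_train must be in [1, {len(uniq) - 1}], got {n_train}")
    rng = np.random.default_rng(seed)
    plans = []
    for r in range(n_repeats):
        train = rng.choice(uniq, size=n_train, replace=False)
        train_set = frozenset(train.tolist())
        plans.append(SplitPlan(repeat_index=r, train_subjects=train_set,
                               test_subjects=frozenset(uniq) - train_set,
                               seed=seed))
    return plans


def roc_points(labels, scores) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC sweep (FPR, TPR, thresholds) and trapezoidal AUC.

    The trapezoidal AUC equals the Mann-Whitney U statistic normalized by
    n_pos * n_neg (ties counted 1/2).
    """
    y = encode_labels(labels) if not np.issubdtype(
        np.asarray(labels).dtype, np.number) else np.asarray(labels, float)
    if len(np.unique(y)) < 2:
        raise UndefinedAUCError("ROC needs both classes in the label list")
    fpr, tpr, thr = _sk_roc_curve(y, np.asarray(scores, float),
                                  drop_intermediate=False)
    return fpr, tpr, thr, float(_trapezoid_auc(fpr, tpr))


def youden_optimal(fpr: np.ndarray, tpr: np.ndarray,
                   thresholds: np.ndarray) -> tuple[float, float, float]:
    """(sensitivity, specificity, threshold) maximizing J = TPR - FPR."""
    k = int(np.argmax(tpr - fpr))
    return float(tpr[k]), float(1.0 - fpr[k]), float(thresholds[k])


@dataclasses.dataclass
class EvalResult:
    per_repeat: pd.DataFrame  # accuracy, auc, sensitivity, specificity, threshold
    aggregate: dict[str, float]
    n_repeats: int
    seed: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"aggregate": self.aggregate, "n_repeats": self.n_repeats,
                   "seed": self.seed,
                   "per_repeat": self.per_repeat.to_dict(orient="records")}
        text = json.dumps(payload, indent=2, allow_nan=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_cv(table: pd.DataFrame, plans, p_enter: float = 0.05,
           p_remove: float = 0.15, threshold: float = 0.5) -> EvalResult:
    """Stepwise fit on training subjects, metrics on held-out subjects.

    A repeat whose test set contains a single class has no defined ROC; its
    AUC/sensitivity/specificity are recorded as NaN, excluded from the
    aggregate means with a warning.
    """
    subj = table["subject_id"].astype(str)
    rows = []
    for plan in plans:
        missing = (set(subj) - plan.train_subjects) - plan.test_subjects
        if missing:
            raise ValueError(f"subjects {sorted(missing)} missing from plan "
                             f"{plan.repeat_index}")
        train = table[subj.isin(plan.train_subjects)]
        test = table[subj.isin(plan.test_subjects)]
        model = stepwise_select(train, p_enter=p_enter, p_remove=p_remove)
        scores = predict(model, test)
        y = encode_labels(test["label"])
        accuracy = float(np.mean((scores >= threshold) == y))
        try:
            fpr, tpr, thr, auc_val = roc_points(y, scores)
            sens, spec, opt_thr = youden_optimal(fpr, tpr, thr)
        except UndefinedAUCError:
            warnings.warn(
                f"repeat {plan.repeat_index}: single-class test set, AUC "
                "undefined for this repeat", DegenerateStatisticWarning)
            auc_val = sens = spec = opt_thr = np.nan
        rows.append({"repeat_index": plan.repeat_index, "accuracy": accuracy,
                     "auc": auc_val, "optimal_sensitivity": sens,
                     "optimal_specificity": spec, "threshold": opt_thr,
                     "n_selected": len(model.selected_features)})
    per_repeat = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        aggregate = {
            "accuracy": float(per_repeat["accuracy"].mean()),
            "auc": float(np.nanmean(per_repeat["auc"])),
            "optimal_sensitivity": float(
                np.nanmean(per_repeat["optimal_sensitivity"])),
            "optimal_specificity": float(
                np.nanmean(per_repeat["optimal_specificity"])),
        }
    return EvalResult(per_repeat=per_repeat, aggregate=aggregate,
                      n_repeats=len(per_repeat),
                      seed=plans[0].seed if len(plans) else -1)
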