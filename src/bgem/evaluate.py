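"""Labelling, cross-validated model evaluation, and serial test combination.

A measurement is labelled *elevated* when its reference glucose is
>= 7.8 mmol/L (boundary inclusive).  Seven classifier families are scored
with stratified 10-fold cross-validation on six imbalance-aware metrics
(accuracy, sensitivity, specificity, precision, G-mean, F score, all in
percent), reported per fold and as mean +/- SD across folds.  Repeated
measurements of one subject can be combined serially: the OR rule
(positive if any test positive) raises sensitivity, the AND rule (positive
only if all positive) raises specificity.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

__all__ = [
    "ELEVATED_THRESHOLD_MMOL_L", "GlucoseLabel", "label_glucose",
    "Metrics", "compute_metrics", "MODEL_FAMILIES", "make_model",
    "MetricsTable", "stratified_cv",
    "SerialRule", "serial_combine_empirical", "serial_theoretical",
]

ELEVATED_THRESHOLD_MMOL_L = 7.8
METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision",
                "gmean", "fscore")
MODEL_FAMILIES = ("nb", "knn", "lr", "rf", "svm", "xgb", "lgbm")


@dataclasses.dataclass(frozen=True)
class GlucoseLabel:
    glucose: float
    label: str  # "elevated" | "normal"

    @property
    def positive(self) -> bool:
        return self.label == "elevated"


def label_glucose(glucose: float) -> GlucoseLabel:
    """Elevated iff glucose >= 7.8 mmol/L."""
    if not glucose > 0:
        raise ValueError(f"glucose must be positive, got {glucose}")
    label = "elevated" if glucose >= ELEVATED_THRESHOLD_MMOL_L else "normal"
    return GlucoseLabel(glucose=float(glucose), label=label)


@dataclasses.dataclass
class Metrics:
    """Six classification metrics in percent; undefined ratios reported as
    0 with the offending metric listed in ``undefined``."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    gmean: float
    fscore: float
    undefined: tuple = ()

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> Metrics:
    total = tp + fp + tn + fn
    if total <= 0:
        raise ValueError("empty confusion matrix")
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    acc = (tp + tn) / total
    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    prec = ratio(tp, tp + fp, "precision")
    gmean = float(np.sqrt(sens * spec))
    fscore = ratio(2 * prec * sens, prec + sens, "fscore") if (prec + sens) > 0 else 0.0
    if (prec + sens) == 0:
        undefined.append("fscore")
    return Metrics(accuracy=100 * acc, sensitivity=100 * sens,
                   specificity=100 * spec, precision=100 * prec,
                   gmean=100 * gmean, fscore=100 * fscore,
                   undefined=tuple(undefined))


def make_model(family: str, seed: int = 0, params: Mapping | None = None):
    """Instantiate one classifier family with documented defaults.

    Scale-sensitive models are wrapped in a standardizing Pipeline.
    """
    params = dict(params or {})
    if family == "nb":
        return Pipeline([("scale", StandardScaler()), ("clf", GaussianNB(**params))])
    if family == "knn":
        params.setdefault("n_neighbors", 5)
        return Pipeline([("scale", StandardScaler()),
                         ("clf", KNeighborsClassifier(**params))])
    if family == "lr":
        params.setdefault("max_iter", 2000)
        return Pipeline([("scale", StandardScaler()),
                         ("clf", LogisticRegression(random_state=seed, **params))])
    if family == "rf":
        params.setdefault("n_estimators", 500)
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "svm":
        params.setdefault("C", 1.0)
        params.setdefault("gamma", "scale")
        return Pipeline([("scale", StandardScaler()),
                         ("clf", SVC(kernel="rbf", random_state=seed, **params))])
    if family == "xgb":
        params.setdefault("n_estimators", 200)
        params.setdefault("max_depth", 3)
        return XGBClassifier(random_state=seed, n_jobs=1, tree_method="hist",
                             eval_metric="logloss", **params)
    if family == "lgbm":
        params.setdefault("n_estimators", 200)
        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1, **params)
    raise ValueError(f"unknown model family {family!r}")


@dataclasses.dataclass
class MetricsTable:
    """Per-fold metrics and their mean/SD aggregation, per model family."""

    per_fold: pd.DataFrame   # columns: model, fold, <metrics>
    summary: pd.DataFrame    # index: model; columns: <metric>_mean, <metric>_sd

    def mean(self, model: str, metric: str) -> float:
        return float(self.summary.loc[model, f"{metric}_mean"])

    def sd(self, model: str, metric: str) -> float:
        return float(self.summary.loc[model, f"{metric}_sd"])


def stratified_cv(X, y, models: Sequence[str] | str = "all", k: int = 10,
                  seed: int = 0, groups: np.ndarray | None = None,
                  model_params: Mapping[str, Mapping] | None = None) -> MetricsTable:
    """Stratified k-fold evaluation of the requested model families.

    Folds preserve class proportions; when ``groups`` is given (repeated
    measurements of one subject) a group-aware stratified split keeps a
    subject's measurements in the same fold.  Metrics are computed per
    fold, then aggregated as mean and SD across folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    fams = MODEL_FAMILIES if models == "all" else tuple(models)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs >= {k} members, got {counts}")
    if groups is None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(splitter.split(X, y))
    else:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(splitter.split(X, y, groups))
    rows = []
    for fam in fams:
        for fold, (tr, te) in enumerate(splits):
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                raise RuntimeError(f"single-class fold {fold}; increase n")
            model = make_model(fam, seed=seed,
                               params=(model_params or {}).get(fam))
            model.fit(X[tr], y[tr])
            pred = np.asarray(model.predict(X[te])).astype(int)
            tp = int(np.sum((pred == 1) & (y[te] == 1)))
            fp = int(np.sum((pred == 1) & (y[te] == 0)))
            tn = int(np.sum((pred == 0) & (y[te] == 0)))
            fn = int(np.sum((pred == 0) & (y[te] == 1)))
            m = compute_metrics(tp, fp, tn, fn)
            rows.append({"model": fam, "fold": fold, **m.as_dict()})
    per_fold = pd.DataFrame(rows)
    agg = per_fold.groupby("model")[list(METRIC_NAMES)].agg(["mean", "std"])
    agg.columns = [f"{metric}_{'sd' if stat == 'std' else stat}"
                   for metric, stat in agg.columns]
    return MetricsTable(per_fold=per_fold, summary=agg)


@dataclasses.dataclass(frozen=True)
class SerialRule:
    rule: str  # "AND" | "OR"
    k: int = 2

    def __post_init__(self) -> None:
        if self.rule not in ("AND", "OR"):
            raise ValueError("rule must be 'AND' or 'OR'")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def serial_combine_empirical(predictions: np.ndarray, rule: SerialRule) -> np.ndarray:
    """Combine k binary predictions per subject; predictions shape (n, k)."""
    p = np.asarray(predictions, dtype=bool)
    if p.ndim != 2 or p.shape[1] != rule.k:
        raise ValueError(f"expected shape (n, {rule.k}), got {p.shape}")
    return p.any(axis=1) if rule.rule == "OR" else p.all(axis=1)


def serial_theoretical(se: float, sp: float, rule: str, k: int) -> tuple[float, float]:
    """Sensitivity/specificity of k independent repeats under OR or AND.

    OR: se' = 1-(1-se)^k, sp' = sp^k.  AND: se' = se^k, sp' = 1-(1-sp)^k.
    Assumes conditional independence of the repeats given disease status.
    """
    if not (0 < se < 1 and 0 < sp < 1):
        raise ValueError("se and sp must lie in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if rule == "OR":
        return 1 - (1 - se) ** k, sp**k
    if rule == "AND":
        return se**k, 1 - (1 - sp) ** k
    raise ValueError("rule must be 'AND' or 'OR'")
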