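"""Ensemble feature selection: six rankers, majority vote, correlation pruning.

Six heterogeneous selectors (ANOVA F, mutual information, dispersion ratio,
recursive feature elimination around an L2 linear classifier, L1-penalized
logistic regression, and gradient-boosted-tree gain importance) each pick
their top 30 features.  Features chosen by more than one selector survive
the majority vote, ranked by vote count with ties broken by mean
within-method rank and then catalogue order; greedy correlation pruning
then drops any survivor whose |Pearson r| with an already-kept feature
exceeds the threshold (default 0.9).

``EnsembleFeatureSelector`` packages this as a scikit-learn selector
(fit / transform / get_support) so it composes with Pipelines.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import RFE, SelectorMixin, f_classif, mutual_info_classif
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

__all__ = ["SelectionResult", "EnsembleFeatureSelector", "rank_features",
           "majority_vote", "drop_correlated", "ensemble_select", "METHODS"]

METHODS = ("anova", "mutual_info", "dispersion_ratio", "rfe", "lasso", "gbt")
TOP_K = 30


@dataclasses.dataclass
class SelectionResult:
    """Full audit trail of one ensemble-selection run."""

    per_method_top30: dict[str, list[str]]
    vote_counts: dict[str, int]
    voted_set: list[str]          # vote >= threshold, in final rank order
    pruned_set: list[str]         # after correlation pruning
    correlation_threshold: float
    forced: list[str] = dataclasses.field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SelectionResult":
        return cls(**json.loads(text))


def _prepare(X, feature_names: Sequence[str] | None, impute: str):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        names = list(feature_names) if feature_names is not None else \
            [f"x{i}" for i in range(mat.shape[1])]
    if np.isnan(mat).any():
        if impute == "median":
            med = np.nanmedian(mat, axis=0)
            med = np.where(np.isnan(med), 0.0, med)
            idx = np.where(np.isnan(mat))
            mat = mat.copy()
            mat[idx] = np.take(med, idx[1])
            keep_rows = np.ones(mat.shape[0], dtype=bool)
        elif impute == "drop":
            keep_rows = ~np.isnan(mat).any(axis=1)
            mat = mat[keep_rows]
        else:
            raise ValueError(f"unknown impute policy {impute!r}")
    else:
        keep_rows = np.ones(mat.shape[0], dtype=bool)
    return mat, names, keep_rows


def _order_with_constants_last(scores: np.ndarray, constant: np.ndarray,
                               n: int) -> np.ndarray:
    """Descending-score order; constant columns rank last by convention."""
    s = np.where(constant, -np.inf, np.where(np.isnan(scores), -np.inf, scores))
    # stable sort so equal scores keep catalogue order
    return np.argsort(-s, kind="stable")[:n]


def rank_features(X, y, method: str, feature_names: Sequence[str] | None = None,
                  top_k: int = TOP_K, random_state: int = 0,
                  impute: str = "median") -> list[str]:
    """Ordered top-k feature identifiers for one selection method."""
    mat, names, keep = _prepare(X, feature_names, impute)
    yv = np.asarray(y)[keep]
    if len(np.unique(yv)) < 2:
        raise ValueError("need both classes present for supervised ranking")
    constant = mat.std(axis=0) == 0
    scaler = StandardScaler()
    with np.errstate(invalid="ignore", divide="ignore"):
        z = scaler.fit_transform(mat)
    z[:, constant] = 0.0

    if method == "anova":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores, _ = f_classif(mat, yv)
        order = _order_with_constants_last(scores, constant, top_k)
    elif method == "mutual_info":
        scores = mutual_info_classif(mat, yv, random_state=random_state)
        order = _order_with_constants_last(scores, constant, top_k)
    elif method == "dispersion_ratio":
        shifted = mat - mat.min(axis=0) + 1.0
        am = shifted.mean(axis=0)
        gm = np.exp(np.log(shifted).mean(axis=0))
        scores = am / gm
        order = _order_with_constants_last(scores, constant, top_k)
    elif method == "rfe":
        est = LogisticRegression(max_iter=2000, random_state=random_state)
        rfe = RFE(est, n_features_to_select=top_k, step=5)
        rfe.fit(z, yv)
        coef = np.zeros(mat.shape[1])
        coef[rfe.support_] = np.abs(rfe.estimator_.coef_.ravel())
        scores = np.where(rfe.support_, 1e6 + coef, -rfe.ranking_.astype(float))
        order = _order_with_constants_last(scores, constant, top_k)
    elif method == "lasso":
        coef = None
        for c in (0.1, 1.0, 10.0, 100.0, 1000.0):
            est = LogisticRegression(l1_ratio=1.0, C=c, solver="liblinear",
                                     max_iter=5000, random_state=random_state)
            est.fit(z, yv)
            coef = np.abs(est.coef_.ravel())
            if np.count_nonzero(coef) >= top_k:
                break
        scores = np.where(coef > 0, coef, -np.inf)
        order = _order_with_constants_last(scores, constant, top_k)
    elif method == "gbt":
        est = XGBClassifier(n_estimators=200, max_depth=3, learning_rate=0.1,
                            tree_method="hist", random_state=random_state,
                            n_jobs=1, importance_type="gain",
                            eval_metric="logloss")
        est.fit(mat, yv)
        scores = est.feature_importances_
        order = _order_with_constants_last(scores, constant, top_k)
    else:
        raise ValueError(f"unknown selection method {method!r}")
    return [names[i] for i in order]


def majority_vote(per_method_top: dict[str, list[str]],
                  catalog_order: Sequence[str] | None = None,
                  threshold: int = 2) -> tuple[list[str], dict[str, int]]:
    """Features chosen by >= threshold methods, ranked.

    Rank: descending vote count; ties by mean within-method rank (1-based,
    over the lists that contain the feature); remaining ties by catalogue
    order.
    """
    counts: dict[str, int] = {}
    ranks: dict[str, list[int]] = {}
    for lst in per_method_top.values():
        for r, fid in enumerate(lst, start=1):
            counts[fid] = counts.get(fid, 0) + 1
            ranks.setdefault(fid, []).append(r)
    order_index = {fid: i for i, fid in enumerate(catalog_order)} \
        if catalog_order is not None else {}
    voted = [fid for fid, c in counts.items() if c >= threshold]
    voted.sort(key=lambda fid: (-counts[fid],
                                float(np.mean(ranks[fid])),
                                order_index.get(fid, 0), fid))
    return voted, counts


def drop_correlated(X, voted_ids: Sequence[str], threshold: float = 0.9,
                    feature_names: Sequence[str] | None = None,
                    impute: str = "median") -> list[str]:
    """Greedy pruning: walk the ranked list, drop anything with
    |Pearson r| > threshold against an already-kept feature."""
    mat, names, _ = _prepare(X, feature_names, impute)
    idx = {n: i for i, n in enumerate(names)}
    kept: list[str] = []
    for fid in voted_ids:
        col = mat[:, idx[fid]]
        ok = True
        for kfid in kept:
            kcol = mat[:, idx[kfid]]
            if col.std() == 0 or kcol.std() == 0:
                continue
            r = np.corrcoef(col, kcol)[0, 1]
            if abs(r) > threshold:
                ok = False
                break
        if ok:
            kept.append(fid)
    return kept


class EnsembleFeatureSelector(SelectorMixin, BaseEstimator):
    """Majority-vote ensemble feature selector with correlation pruning.

    Parameters
    ----------
    methods : tuple of str
        Ranking methods to ensemble (default: all six).
    top_k : int
        Features each method nominates (default 30).
    vote_threshold : int
        Minimum number of nominating methods ("more than 1 model" -> 2).
    corr_threshold : float
        |Pearson r| above which a lower-ranked survivor is dropped.
    force_include : tuple of str
        Feature names appended to the final set regardless of votes
        (mirrors post-hoc inclusion of a covariate of interest).
    impute : {"median", "drop"}
        Handling of NaN rows (e.g. missing MSE blocks) before ranking.
    random_state : int
        Seed for the stochastic rankers.

    Attributes
    ----------
    result_ : SelectionResult
    feature_names_in_ : list of str
    support_ : boolean mask over input features
    """

    def __init__(self, methods: tuple = METHODS, top_k: int = TOP_K,
                 vote_threshold: int = 2, corr_threshold: float = 0.9,
                 force_include: tuple = (), impute: str = "median",
                 random_state: int = 0):
        self.methods = methods
        self.top_k = top_k
        self.vote_threshold = vote_threshold
        self.corr_threshold = corr_threshold
        self.force_include = force_include
        self.impute = impute
        self.random_state = random_state

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        mat, names, _ = _prepare(X, feature_names, self.impute)
        self.feature_names_in_ = names
        self.n_features_in_ = len(names)
        per_method = {m: rank_features(X, y, m, feature_names=names,
                                       top_k=self.top_k,
                                       random_state=self.random_state,
                                       impute=self.impute)
                      for m in self.methods}
        voted, counts = majority_vote(per_method, catalog_order=names,
                                      threshold=self.vote_threshold)
        pruned = drop_correlated(X, voted, threshold=self.corr_threshold,
                                 feature_names=names, impute=self.impute)
        forced = [f for f in self.force_include if f not in pruned]
        self.result_ = SelectionResult(
            per_method_top30=per_method,
            vote_counts={fid: counts.get(fid, 0) for fid in names
                         if counts.get(fid, 0) > 0},
            voted_set=voted, pruned_set=pruned + forced,
            correlation_threshold=self.corr_threshold, forced=forced)
        self.support_ = np.array([n in self.result_.pruned_set for n in names])
        return self

    def _get_support_mask(self) -> np.ndarray:
        return self.support_

    def selected_names(self) -> list[str]:
        return list(self.result_.pruned_set)


def ensemble_select(X, y, seed: int = 0, feature_names: Sequence[str] | None = None,
                    **kwargs) -> SelectionResult:
    """Functional wrapper: run the full ensemble and return the audit trail."""
    sel = EnsembleFeatureSelector(random_state=seed, **kwargs)
    sel.fit(X, y, feature_names=feature_names)
    return sel.result_
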