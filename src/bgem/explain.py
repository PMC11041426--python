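"""Shapley-value attribution of model scores to input features.

The attribution of feature j is its average marginal contribution to the
model score across feature coalitions, with the value of a coalition S
defined interventionally: v(S) = E_b[f(x_S, b_{\\S})] over a background
matrix b.  For the small final feature sets used here (<= 12 features)
coalitions are enumerated exactly, so the efficiency axiom
base_value + sum(phi) = f(x) holds to machine precision; larger sets fall
back to seeded permutation sampling.
"""

from __future__ import annotations

import dataclasses
from math import factorial

import numpy as np

__all__ = ["Attribution", "ComplexityError", "shapley_attributions",
           "global_importance"]

EXACT_MAX_FEATURES = 12
HARD_MAX_FEATURES = 20


class ComplexityError(ValueError):
    """Exact enumeration requested for too many features; use sampling."""


@dataclasses.dataclass
class Attribution:
    """base_value + phi.sum() = prediction (efficiency axiom)."""

    base_value: float
    phi: np.ndarray
    prediction: float
    feature_names: tuple = ()


def _score_fn(model):
    """Real-valued score: decision margin if available, else P(class 1)."""
    if callable(model) and not hasattr(model, "predict"):
        return model
    if hasattr(model, "decision_function"):
        return lambda X: np.asarray(model.decision_function(X), dtype=float)
    if hasattr(model, "predict_proba"):
        return lambda X: np.asarray(model.predict_proba(X))[:, 1].astype(float)
    return lambda X: np.asarray(model.predict(X), dtype=float)


def _coalition_values(score, background: np.ndarray, x: np.ndarray) -> np.ndarray:
    """v(S) for every coalition bitmask S (exact, vectorized over background)."""
    n_bg, p = background.shape
    values = np.empty(1 << p)
    for mask in range(1 << p):
        mat = background.copy()
        for j in range(p):
            if mask >> j & 1:
                mat[:, j] = x[j]
        values[mask] = float(np.mean(score(mat)))
    return values


def shapley_attributions(model, background: np.ndarray, x: np.ndarray,
                         mode: str = "auto", n_permutations: int = 200,
                         random_state: int = 0,
                         feature_names=()) -> Attribution:
    """Shapley attribution of one sample's model score.

    mode="exact" enumerates all coalitions (<= 20 features, intended for
    <= 12); mode="sampling" averages marginal contributions over seeded
    random feature orderings; "auto" picks exact up to 12 features.
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    x = np.asarray(x, dtype=float).ravel()
    p = x.size
    if background.shape[1] != p:
        raise ValueError("background and x disagree on feature count")
    if background.shape[0] == 0:
        raise ValueError("background must be non-empty")
    score = _score_fn(model)
    if mode == "auto":
        mode = "exact" if p <= EXACT_MAX_FEATURES else "sampling"
    if mode == "exact" and p > HARD_MAX_FEATURES:
        raise ComplexityError(
            f"{p} features is too many for exact enumeration; use sampling mode")

    base = float(np.mean(score(background)))
    pred = float(np.mean(score(x[None, :])))

    if mode == "exact":
        values = _coalition_values(score, background, x)
        # precompute coalition weights |S|!(p-|S|-1)!/p!
        w = np.array([factorial(s) * factorial(p - s - 1) / factorial(p)
                      for s in range(p)])
        sizes = np.array([bin(m).count("1") for m in range(1 << p)])
        phi = np.zeros(p)
        for j in range(p):
            bit = 1 << j
            without = np.flatnonzero((np.arange(1 << p) & bit) == 0)
            phi[j] = float(np.sum(w[sizes[without]]
                                  * (values[without | bit] - values[without])))
    elif mode == "sampling":
        rng = np.random.default_rng(random_state)
        phi = np.zeros(p)
        for _ in range(n_permutations):
            order = rng.permutation(p)
            mat = background.copy()
            prev = float(np.mean(score(mat)))
            for j in order:
                mat[:, j] = x[j]
                cur = float(np.mean(score(mat)))
                phi[j] += cur - prev
                prev = cur
        phi /= n_permutations
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return Attribution(base_value=base, phi=phi, prediction=pred,
                       feature_names=tuple(feature_names))


def global_importance(model, X: np.ndarray, background: np.ndarray | None = None,
                      feature_names=(), **kwargs) -> list[tuple[str, float]]:
    """Mean |phi| per feature over the rows of X, ranked descending."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    background = X if background is None else background
    names = tuple(feature_names) or tuple(f"x{i}" for i in range(X.shape[1]))
    acc = np.zeros(X.shape[1])
    for row in X:
        att = shapley_attributions(model, background, row, **kwargs)
        acc += np.abs(att.phi)
    acc /= X.shape[0]
    ranked = sorted(zip(names, acc), key=lambda t: -t[1])
    return [(n, float(v)) for n, v in ranked]
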