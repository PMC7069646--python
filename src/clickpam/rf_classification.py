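"""Random-Forest species classification with out-of-bag evaluation.

Each forest is fitted with bootstrap resampling per tree and a random
subset of m_try = floor(sqrt(M)) of the M = 8 parameters per split;
class labels are assigned by majority vote.  Because every tree leaves
roughly (1 - 1/n)^n ~ 37% of the training rows out of its bootstrap,
those out-of-bag (OOB) rows provide an internal estimate of the correct
classification rate without a held-out set.

A single forest yields one OOB rate, so quantiles are obtained by
refitting the forest ``n_repeats`` times with independent seeds and
reporting the median and 5th/95th quantiles of the per-repeat rates.
Variable importance is Breiman-style permutation importance (mean
decrease in OOB accuracy per tree), averaged over a configurable subset
of the repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import (
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)

from .feature_extraction import PARAMS

__all__ = [
    "RFConfig",
    "RFResult",
    "fit_evaluate",
    "expected_chance_rate",
    "oob_fraction",
    "importance_ranking",
]


@dataclass(frozen=True)
class RFConfig:
    """Forest hyperparameters and the repeated-evaluation protocol."""

    n_tree: int = 3000
    m_try: int | None = None       # None -> floor(sqrt(n_parameters))
    n_repeats: int = 100
    seed: int = 0
    n_importance_repeats: int = 10  # repeats used for permutation importance
    compute_importance: bool = True
    per_tree_quantiles: bool = False  # alternative: quantiles of per-tree OOB error

    def __post_init__(self) -> None:
        if self.n_tree < 1:
            raise ValueError("n_tree must be >= 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class RFResult:
    """Summary of the repeated-forest OOB evaluation (rates in percent)."""

    classes: list[str]
    overall: dict[str, float]                   # median/q5/q95
    per_class: dict[str, dict[str, float]]      # class -> median/q5/q95
    chance_rate: dict[str, float]               # class -> prior (%)
    importance: pd.Series | None                # mean decrease in accuracy
    importance_ties: list[tuple[str, str]] = field(default_factory=list)
    confusion: pd.DataFrame | None = None       # mean OOB confusion counts
    overall_rates: np.ndarray | None = None     # per-repeat overall rates (%)
    per_tree_error: dict[str, float] | None = None


def oob_fraction(n: int) -> float:
    """Expected fraction of rows left out of a size-n bootstrap: (1-1/n)^n.

    Approaches 1/e ~ 36.8% for large n ("approximately 37%").
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return float((1.0 - 1.0 / n) ** n)


def expected_chance_rate(labels) -> dict[str, float]:
    """Per-class expected correct-classification rate by chance, in percent.

    Equals the class priors: a classifier that assigns labels with the
    empirical class frequencies is correct on a class at its prior rate.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    classes, counts = np.unique(labels, return_counts=True)
    return {str(c): 100.0 * k / labels.size for c, k in zip(classes, counts)}


def _quantile_summary(rates: np.ndarray) -> dict[str, float]:
    return {
        "median": float(np.median(rates)),
        "q5": float(np.quantile(rates, 0.05)),
        "q95": float(np.quantile(rates, 0.95)),
    }


def _oob_predictions(rf: RandomForestClassifier, y: np.ndarray) -> np.ndarray:
    """Majority-vote OOB class labels; rows never OOB get the prior winner."""
    proba = rf.oob_decision_function_
    votes = np.nan_to_num(proba, nan=0.0)
    never_oob = ~np.isfinite(proba).all(axis=1) | (votes.sum(axis=1) == 0)
    pred_idx = votes.argmax(axis=1)
    if never_oob.any():  # vanishingly rare with thousands of trees
        classes, counts = np.unique(y, return_counts=True)
        majority = int(np.flatnonzero(rf.classes_ == classes[counts.argmax()])[0])
        pred_idx[never_oob] = majority
    return rf.classes_[pred_idx]


def _permutation_importance_oob(
    rf: RandomForestClassifier, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Breiman mean decrease in accuracy: per tree, OOB accuracy minus
    OOB accuracy after permuting one predictor, averaged over trees."""
    n = X.shape[0]
    n_bootstrap = _get_n_samples_bootstrap(n, rf.max_samples, None)
    y_enc = np.searchsorted(rf.classes_, y)  # trees predict encoded classes
    drops = np.zeros(X.shape[1])
    n_trees = 0
    for tree in rf.estimators_:
        oob_idx = _generate_unsampled_indices(tree.random_state, n, n_bootstrap, None)
        if oob_idx.size == 0:
            continue
        X_oob = X[oob_idx]
        y_oob = y_enc[oob_idx]
        base = np.mean(tree.predict(X_oob) == y_oob)
        for j in range(X.shape[1]):
            X_perm = X_oob.copy()
            X_perm[:, j] = X_perm[rng.permutation(oob_idx.size), j]
            drops[j] += base - np.mean(tree.predict(X_perm) == y_oob)
        n_trees += 1
    return drops / max(n_trees, 1)


def _per_tree_error_quantiles(
    rf: RandomForestClassifier, X: np.ndarray, y: np.ndarray
) -> dict[str, float]:
    """Quantiles of single-tree OOB error rates (diagnostic alternative)."""
    n = X.shape[0]
    n_bootstrap = _get_n_samples_bootstrap(n, rf.max_samples, None)
    y_enc = np.searchsorted(rf.classes_, y)
    errors = []
    for tree in rf.estimators_:
        oob_idx = _generate_unsampled_indices(tree.random_state, n, n_bootstrap, None)
        if oob_idx.size:
            errors.append(float(np.mean(tree.predict(X[oob_idx]) != y_enc[oob_idx])))
    arr = 100.0 * np.asarray(errors)
    return _quantile_summary(arr)


def fit_evaluate(features: pd.DataFrame, cfg: RFConfig | None = None) -> RFResult:
    """Repeated-forest OOB evaluation of species separability.

    For each of ``cfg.n_repeats`` seeds, fit a forest of ``cfg.n_tree``
    trees and record the overall and per-class OOB correct rates; report
    their median and 5th/95th quantiles.  Classes are the values of the
    ``species`` column; predictors are the eight click parameters.
    """
    if cfg is None:
        cfg = RFConfig()
    missing = [p for p in PARAMS if p not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks parameter columns: {missing}")
    X = features[PARAMS].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("feature table contains missing or non-finite values")
    y = features["species"].to_numpy(dtype=object)
    classes = sorted(map(str, np.unique(y)))
    if len(classes) < 2:
        raise ValueError("need at least two species to classify")
    m_try = cfg.m_try if cfg.m_try is not None else int(np.floor(np.sqrt(len(PARAMS))))

    master = np.random.default_rng(cfg.seed)
    fit_seeds = master.integers(0, 2**31 - 1, size=cfg.n_repeats)
    overall = np.empty(cfg.n_repeats)
    per_class = {c: np.empty(cfg.n_repeats) for c in classes}
    importance_acc = np.zeros(len(PARAMS))
    importance_n = 0
    confusion_acc = np.zeros((len(classes), len(classes)))
    per_tree_error = None

    for r, fs in enumerate(fit_seeds):
        rf = RandomForestClassifier(
            n_estimators=cfg.n_tree,
            max_features=m_try,
            bootstrap=True,
            oob_score=True,
            random_state=int(fs),
            n_jobs=1,
        ).fit(X, y)
        pred = _oob_predictions(rf, y)
        overall[r] = 100.0 * np.mean(pred == y)
        for ci, c in enumerate(classes):
            mask = y == c
            per_class[c][r] = 100.0 * np.mean(pred[mask] == c)
            for cj, c2 in enumerate(classes):
                confusion_acc[ci, cj] += np.sum(pred[mask] == c2)
        if cfg.compute_importance and importance_n < cfg.n_importance_repeats:
            rng = np.random.default_rng(int(fs) + 1)
            importance_acc += _permutation_importance_oob(rf, X, y, rng)
            importance_n += 1
        if cfg.per_tree_quantiles and r == 0:
            per_tree_error = _per_tree_error_quantiles(rf, X, y)

    importance = None
    ties: list[tuple[str, str]] = []
    if cfg.compute_importance and importance_n:
        importance = pd.Series(importance_acc / importance_n, index=PARAMS)
    confusion = pd.DataFrame(
        confusion_acc / cfg.n_repeats, index=classes, columns=classes
    )
    result = RFResult(
        classes=classes,
        overall=_quantile_summary(overall),
        per_class={c: _quantile_summary(v) for c, v in per_class.items()},
        chance_rate=expected_chance_rate(y),
        importance=importance,
        confusion=confusion,
        overall_rates=overall,
        per_tree_error=per_tree_error,
    )
    if importance is not None:
        result.importance_ties = _find_ties(importance)
    return result


TIE_TOLERANCE = 0.01  # absolute difference in mean accuracy decrease


def _find_ties(importance: pd.Series, tol: float = TIE_TOLERANCE) -> list[tuple[str, str]]:
    ranked = importance.sort_values(ascending=False)
    ties = []
    for (n1, v1), (n2, v2) in zip(ranked.items(), list(ranked.items())[1:]):
        if abs(v1 - v2) < tol:
            ties.append(tuple(sorted((n1, n2))))
    return ties


def importance_ranking(result: RFResult) -> list[str]:
    """Parameters ordered by descending mean decrease in accuracy.

    Parameters whose importances differ by less than the tie tolerance
    appear in ``result.importance_ties``; within a tie the alphabetical
    order of the names decides the rank.
    """
    if result.importance is None:
        raise ValueError("result carries no importance estimates")
    df = result.importance.rename_axis("name").reset_index(name="mda")
    df = df.sort_values(["mda", "name"], ascending=[False, True], kind="mergesort")
    return df["name"].tolist()
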