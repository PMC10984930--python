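"""Neighborhood rough-set classification and evaluation harnesses.

A test sample forms its adaptive δ-neighborhood over the training table and
takes the plurality class of the members.  Vote ties are broken
deterministically: first by smaller mean member distance among the tied
classes, then by lexicographically smallest class label.  Evaluation
harnesses cover stratified k-fold cross-validation (k = 10 by default),
seeded holdout splits, and radius sweeps over a grid of r values with
identical folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .data_model import HybridRecord, HybridTable
from .distance import DistanceParams, fit_distance_params
from .errors import ConfigurationError, ContractViolation
from .neighborhood import DEFAULT_RADIUS, Neighborhood, build_neighborhood


@dataclass(frozen=True)
class Prediction:
    """A predicted label plus the neighborhood and votes behind it."""

    label: str
    neighborhood: Neighborhood
    votes: Mapping[str, int]
    tie_broken: bool


@dataclass(frozen=True)
class CVReport:
    """k-fold cross-validation outcome for one (table, r, seed) setting."""

    k: int
    fold_accuracies: tuple[float, ...]
    mean_accuracy: float
    seed: int
    r: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "r": self.r,
                "seed": self.seed,
                "fold_accuracies": list(self.fold_accuracies),
                "mean_accuracy": self.mean_accuracy,
            },
            indent=2,
            sort_keys=True,
        )


def predict(
    query: HybridRecord,
    train: HybridTable,
    params: DistanceParams,
    r: float = DEFAULT_RADIUS,
) -> Prediction:
    """Classify ``query`` by majority vote inside its adaptive neighborhood."""
    if len(train) == 0:
        raise ContractViolation("training table is empty")
    if not train.has_labels:
        raise ContractViolation("training table is unlabeled")
    nbhd = build_neighborhood(query, train, params, r)
    labels = train.labels
    votes: dict[str, int] = {}
    for idx in nbhd.members:
        votes[labels[idx]] = votes.get(labels[idx], 0) + 1
    top = max(votes.values())
    tied = sorted(c for c, v in votes.items() if v == top)
    if len(tied) == 1:
        return Prediction(label=tied[0], neighborhood=nbhd, votes=votes, tie_broken=False)
    # tie-break 1: smaller mean member distance; tie-break 2: lexical label
    def mean_dist(c: str) -> float:
        ds = [nbhd.distances[i] for i in nbhd.members if labels[i] == c]
        return float(np.mean(ds))

    winner = min(tied, key=lambda c: (mean_dist(c), c))
    return Prediction(label=winner, neighborhood=nbhd, votes=votes, tie_broken=True)


def _fold_indices(
    labels: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified folds when every class can fill them, plain folds otherwise."""
    n = len(labels)
    if k > n:
        raise ConfigurationError(f"k = {k} exceeds the record count {n}")
    if k < 2:
        raise ConfigurationError("k must be at least 2")
    _, counts = np.unique(labels.astype(str), return_counts=True)
    if counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return list(splitter.split(np.zeros(n), labels.astype(str)))
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros(n)))


def _score_split(
    table: HybridTable,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    r: float,
    weights: Optional[Mapping[str, float]],
    normalize_lev: bool,
) -> float:
    train = table.subset(train_idx)
    params = fit_distance_params(train, weights=weights, normalize_lev=normalize_lev)
    labels = table.labels
    hits = 0
    for i in test_idx:
        pred = predict(table.record(int(i)), train, params, r)
        hits += int(pred.label == labels[int(i)])
    return hits / len(test_idx)


def evaluate_kfold(
    table: HybridTable,
    k: int = 10,
    r: float = DEFAULT_RADIUS,
    seed: int = 0,
    weights: Optional[Mapping[str, float]] = None,
    normalize_lev: bool = True,
) -> CVReport:
    """Stratified k-fold cross-validation with per-fold refit of σ.

    Distance parameters are refitted on each training split so the test
    fold never leaks into the normalizers.
    """
    if not table.has_labels:
        raise ContractViolation("cross-validation needs a labeled table")
    labels = table.labels
    folds = _fold_indices(labels, k, seed)
    accs = tuple(
        _score_split(table, tr, te, r, weights, normalize_lev) for tr, te in folds
    )
    return CVReport(
        k=k,
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        seed=seed,
        r=r,
    )


def evaluate_holdout(
    table: HybridTable,
    n_train: int,
    n_test: int,
    r: float = DEFAULT_RADIUS,
    seed: int = 0,
    weights: Optional[Mapping[str, float]] = None,
    normalize_lev: bool = True,
) -> float:
    """Seeded-shuffle holdout: first ``n_train`` rows train, next ``n_test`` test."""
    if n_train <= 0 or n_test <= 0:
        raise ConfigurationError("n_train and n_test must be positive")
    if n_train + n_test > len(table):
        raise ConfigurationError(
            f"n_train + n_test = {n_train + n_test} exceeds table size {len(table)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(table))
    train_idx = order[:n_train]
    test_idx = order[n_train : n_train + n_test]
    return _score_split(table, train_idx, test_idx, r, weights, normalize_lev)


def radius_sweep(
    table: HybridTable,
    radii: Sequence[float],
    k: int = 10,
    seed: int = 0,
    weights: Optional[Mapping[str, float]] = None,
    normalize_lev: bool = True,
) -> dict[float, float]:
    """Mean k-fold CV accuracy for each radius, on identical folds."""
    if len(radii) == 0:
        raise ConfigurationError("radii list is empty")
    if len(set(radii)) != len(radii):
        raise ConfigurationError("duplicate radii in sweep")
    if any(r < 0 for r in radii):
        raise ConfigurationError("radii must be nonnegative")
    return {
        float(r): evaluate_kfold(
            table, k=k, r=r, seed=seed, weights=weights, normalize_lev=normalize_lev
        ).mean_accuracy
        for r in radii
    }
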