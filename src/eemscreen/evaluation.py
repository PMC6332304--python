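"""Balanced-accuracy scoring, split protocol, grid search and meta-analyses.

Balanced accuracy, BAC = (sensitivity + specificity) / 2, is the study's
single figure of merit because the datasets are class-imbalanced.  Models
are tuned by exhaustive grid search on a shared stratified 1:1 train/test
split, and three meta-statistics summarize the grids:

* best-fingerprint tables — per (target, method), the maximum BAC across
  fingerprint schemes, i.e. the method "chooses" its representation;
* ranking profiles — the probability that a method occupies each rank
  position when methods are ordered by decreasing BAC, with tied methods
  sharing the spanned positions in equal fractional credit (the matrix is
  doubly stochastic);
* stability curves — P(BAC >= T) under a uniformly random hyperparameter
  choice from the grid, an exact finite-grid tail distribution measuring
  how forgiving a method is to mis-tuning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baselines import HyperGrid, fit_baseline
from .errors import DegenerateDatasetError, UndefinedMetricError
from .labeling import ACTIVE, LabeledDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise UndefinedMetricError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray,
                     positive=ACTIVE) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def balanced_accuracy(c: ConfusionCounts) -> float:
    """BAC = 1/2 (TP/(TP+FN) + TN/(TN+FP)); undefined if a class is absent."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise UndefinedMetricError(
            "balanced accuracy is undefined when a class has no members"
        )
    return 0.5 * (c.tp / (c.tp + c.fn) + c.tn / (c.tn + c.fp))


def score_predictions(y_true, y_pred, positive=ACTIVE) -> float:
    return balanced_accuracy(confusion_counts(y_true, y_pred, positive))


def split_dataset(dataset: LabeledDataset, proportion: float = 0.5,
                  seed: int = 0) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified random train/test split (default 1:1).

    Class proportions are preserved to within one compound; deterministic
    given the seed.
    """
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in np.unique(dataset.y):
        members = np.flatnonzero(dataset.y == label)
        if len(members) < 2:
            raise DegenerateDatasetError(
                f"class {label!r} has {len(members)} member(s); cannot stratify"
            )
        perm = rng.permutation(members)
        n_train = int(round(proportion * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)  # both parts non-empty
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    parts = []
    for idx in (sorted(train_idx), sorted(test_idx)):
        idx = np.array(idx, dtype=int)
        parts.append(
            LabeledDataset(
                X=dataset.X[idx],
                y=dataset.y[idx],
                provenance=dataset.provenance[idx],
                ids=dataset.ids[idx],
                scheme=dataset.scheme,
                target=dataset.target,
            )
        )
    return parts[0], parts[1]


@dataclass
class EvalRecord:
    target: str
    scheme: str
    method: str
    params: dict
    split_seed: int
    bac: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.bac <= 1.0:
            raise UndefinedMetricError(f"bac out of range: {self.bac}")


@dataclass
class GridResult:
    """Per-point BAC over a full hyperparameter grid on one shared split."""

    method: str
    points: list
    bacs: list
    errors: list
    best_index: int
    split_seed: int
    best_model: object = None

    @property
    def best_params(self) -> dict:
        return self.points[self.best_index]

    @property
    def best_bac(self) -> float:
        return self.bacs[self.best_index]

    @property
    def valid_bacs(self) -> list:
        return [b for b in self.bacs if b is not None]


def pick_winner(bacs: list) -> int:
    """Index of the maximum BAC; ties go to the first point in grid order."""
    valid = [(i, b) for i, b in enumerate(bacs) if b is not None]
    if not valid:
        raise DegenerateDatasetError("no valid grid point")
    best = max(b for _, b in valid)
    return next(i for i, b in valid if b == best)


def grid_search(method: str, dataset: LabeledDataset, grid: HyperGrid,
                split_seed: int = 0, proportion: float = 0.5) -> GridResult:
    """Fit-and-score every grid point on one shared stratified split.

    Failed fits are recorded and excluded; the winner is the first point
    reaching the maximum test BAC in deterministic grid order.
    """
    train, test = split_dataset(dataset, proportion=proportion, seed=split_seed)
    points = grid.points()
    bacs: list = []
    errors: list = []
    models: list = []
    for params in points:
        try:
            model = fit_baseline(method, params, train.X, train.y, seed=split_seed)
            bac = score_predictions(test.y, model.predict(test.X))
            bacs.append(bac)
            errors.append(None)
            models.append(model)
        except Exception as exc:  # recorded per point, point excluded
            logger.warning("grid point %s failed: %s", params, exc)
            bacs.append(None)
            errors.append(str(exc))
            models.append(None)
    best = pick_winner(bacs)
    return GridResult(
        method=method, points=points, bacs=bacs, errors=errors,
        best_index=best, split_seed=split_seed, best_model=models[best],
    )


def best_fingerprint(records: list) -> pd.DataFrame:
    """Per (target, method): the maximum BAC over fingerprint schemes.

    Ties are reported as the lexicographically first scheme with a flag.
    """
    if not records:
        return pd.DataFrame(
            columns=["target", "method", "best_scheme", "bac", "tie"]
        )
    rows = []
    frame = pd.DataFrame(
        [
            {"target": r.target, "method": r.method, "scheme": r.scheme, "bac": r.bac}
            for r in records
        ]
    )
    for (target, method), group in frame.groupby(["target", "method"], sort=True):
        best = group["bac"].max()
        winners = sorted(group.loc[group["bac"] == best, "scheme"])
        rows.append(
            {
                "target": target,
                "method": method,
                "best_scheme": winners[0],
                "bac": best,
                "tie": len(winners) > 1,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RankingProfile:
    """P(method at rank position), methods x positions, doubly stochastic."""

    methods: tuple
    matrix: np.ndarray
    n_experiments: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            index=pd.Index(self.methods, name="method"),
            columns=[f"position_{p + 1}" for p in range(self.matrix.shape[1])],
        )


def ranking_profile(experiments: list, methods: tuple = ("EEM", "SVM", "ET", "RF")
                    ) -> RankingProfile:
    """Empirical rank-position probabilities over experiments.

    Each experiment is a mapping method -> best BAC.  Methods are ordered
    by decreasing BAC; tied methods share the positions they span with
    equal fractional credit, so each row and column of the resulting
    matrix sums to 1.  Experiments missing a method are excluded with a
    warning.
    """
    k = len(methods)
    matrix = np.zeros((k, k))
    used = 0
    for exp in experiments:
        if any(m not in exp for m in methods):
            logger.warning("experiment missing a method, excluded: %s", sorted(exp))
            continue
        used += 1
        order = sorted(methods, key=lambda m: (-exp[m], methods.index(m)))
        pos = 0
        while pos < k:
            tied = [m for m in order if exp[m] == exp[order[pos]]]
            g = len(tied)
            for m in tied:
                for p in range(pos, pos + g):
                    matrix[methods.index(m), p] += 1.0 / g
            pos += g
    if used == 0:
        raise DegenerateDatasetError("no complete experiment to rank")
    return RankingProfile(methods=tuple(methods), matrix=matrix / used,
                          n_experiments=used)


@dataclass
class StabilityCurve:
    """Exact tail distribution P(BAC >= T) over a finite hyperparameter grid."""

    thresholds: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.thresholds) <= 0):
            raise UndefinedMetricError("thresholds must be strictly ascending")
        if np.any(np.diff(self.probability) > 1e-12):
            raise UndefinedMetricError("tail probabilities must be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "probability": self.probability}
        )


def stability_curve(bacs, thresholds) -> StabilityCurve:
    """P(BAC >= T) by exact counting over the valid grid points."""
    valid = np.array([b for b in bacs if b is not None], dtype=float)
    if len(valid) == 0:
        raise DegenerateDatasetError("no valid grid point")
    thresholds = np.asarray(thresholds, dtype=float)
    probability = np.array([np.mean(valid >= t) for t in thresholds])
    return StabilityCurve(thresholds=thresholds, probability=probability)
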