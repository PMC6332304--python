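"""Comparator classifiers and the benchmark hyperparameter grids.

The three baselines — SVM with an RBF kernel, Random Forest and Extremely
Randomized Trees — delegate to scikit-learn; all three weight samples of
the smaller class (inverse class frequency) so that they, like the EEM,
optimize toward balanced accuracy.  The grids are the benchmark's tuning
ranges: EEM varies the projection count h and ridge strength C, SVM the
kernel width gamma and margin penalty C, and the forests the number of
trees; tree feature subsets use the standard sqrt(d) default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.svm import SVC

from .eem import EEMClassifier
from .errors import ConfigurationError, DegenerateDatasetError

METHODS = ("EEM", "SVM", "ET", "RF")

_GRID_AXES = {
    "EEM": {"C": [1e3, 1e4, 1e5, 1e6, 1e7], "h": [1000, 1500, 2000, 2500, 3000]},
    "SVM": {"C": [0.1, 1.0, 10.0, 100.0, 1000.0], "gamma": [0.1, 0.01, 0.001, 0.0001]},
    "ET": {"n_trees": [10, 50, 100, 200, 500]},
    "RF": {"n_trees": [10, 50, 100, 200, 500]},
}


@dataclass(frozen=True)
class HyperGrid:
    """Named parameter axes; points enumerate the full Cartesian product."""

    method: str
    axes: dict

    def points(self) -> list[dict]:
        """Grid points in deterministic order: axes sorted by name, values
        in their listed order."""
        names = sorted(self.axes)
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.axes[n] for n in names))
        ]

    def __len__(self) -> int:
        out = 1
        for values in self.axes.values():
            out *= len(values)
        return out


def make_grid(method: str) -> HyperGrid:
    if method not in _GRID_AXES:
        raise ConfigurationError(f"unknown method {method!r}; choose from {METHODS}")
    return HyperGrid(method=method, axes={k: list(v) for k, v in _GRID_AXES[method].items()})


def fit_baseline(method: str, params: dict, X: np.ndarray, y: np.ndarray,
                 seed: int = 0):
    """Fit one classifier configuration; returns the fitted estimator.

    The EEM projection count h is capped at the training-set size inside
    the estimator itself.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DegenerateDatasetError("training data contains a single class")
    if method == "EEM":
        clf = EEMClassifier(h=params["h"], C=params["C"], random_state=seed)
    elif method == "SVM":
        clf = SVC(
            kernel="rbf",
            C=params["C"],
            gamma=params["gamma"],
            class_weight="balanced",
            random_state=seed,
        )
    elif method == "RF":
        clf = RandomForestClassifier(
            n_estimators=params["n_trees"],
            bootstrap=True,
            max_features="sqrt",
            class_weight="balanced",
            random_state=seed,
            n_jobs=1,
        )
    elif method == "ET":
        # no bootstrap: each tree sees the full training set
        clf = ExtraTreesClassifier(
            n_estimators=params["n_trees"],
            bootstrap=False,
            max_features="sqrt",
            class_weight="balanced",
            random_state=seed,
            n_jobs=1,
        )
    else:
        raise ConfigurationError(f"unknown method {method!r}; choose from {METHODS}")
    return clf.fit(np.asarray(X, dtype=np.float64) if method == "SVM" else X, y)
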