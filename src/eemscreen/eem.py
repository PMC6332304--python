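"""Extreme Entropy Machine with Tanimoto random projection.

The classifier represents each compound by its Tanimoto similarity to a
random subset of h training compounds (h columns of the Gram matrix, never
the full N x N matrix) and fits, in that projected space, a closed-form
regularized discriminant: the weight vector solves

    (1/2 (S+ + S-) + I/C) beta = m+ - m-

where m+/- and S+/- are the projected class means and (shrinkage-
regularized) class covariances, and the intercept is the crossing point of
the two univariate Gaussian densities N(beta' m, beta' S beta) under equal
class priors.  Equal priors make the decision class-balanced by
construction, which is what makes the method robust to the heavy class
imbalance typical of screening data.  Training costs O(N h^2 + h^3) and
prediction O(h d) per sample.

The Tanimoto coefficient of two binary fingerprints is |A and B| / |A or B|,
with the convention that two all-zero fingerprints have similarity 1
(identical empty substructure sets).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from .errors import DegenerateDatasetError, InputError

_VAR_FLOOR = 1e-12


def _check_binary(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M)
    if M.ndim != 2:
        raise InputError(f"{name} must be a 2-D matrix")
    if M.size and not np.isin(M, (0, 1)).all():
        raise InputError(f"{name} must contain only 0/1 entries")
    return M


def tanimoto_kernel(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto coefficients between rows of two 0/1 matrices.

    Returns an (n, m) matrix with entries in [0, 1].  A pair of all-zero
    rows scores 1.0.  Memory use is O(n m); nothing larger is formed.
    """
    A = _check_binary(A, "A")
    B = _check_binary(B, "B")
    if A.shape[1] != B.shape[1]:
        raise InputError(
            f"bit-dimension mismatch: {A.shape[1]} vs {B.shape[1]}"
        )
    Af = A.astype(np.float64)
    Bf = B.astype(np.float64)
    intersection = Af @ Bf.T
    union = Af.sum(axis=1)[:, None] + Bf.sum(axis=1)[None, :] - intersection
    return np.where(union > 0, intersection / np.maximum(union, 1.0), 1.0)


@dataclass
class ProjectionBasis:
    """A random subset of training fingerprints used as kernel landmarks."""

    indices: np.ndarray
    h_requested: int
    h_eff: int
    fingerprints: np.ndarray
    kernel: str = "tanimoto"

    def __post_init__(self) -> None:
        if self.h_eff != len(self.indices) or self.h_eff != self.fingerprints.shape[0]:
            raise InputError("basis indices and fingerprints must agree with h_eff")
        if len(np.unique(self.indices)) != len(self.indices):
            raise InputError("basis indices must be distinct")


def select_basis(N: int, h_requested: int, seed: int) -> np.ndarray:
    """Choose min(h_requested, N) distinct row indices uniformly at random.

    When the requested number of projections exceeds the training-set size
    it is capped at N, so the basis is then the whole training set.
    """
    if N < 1 or h_requested < 1:
        raise InputError("N and h_requested must be >= 1")
    h_eff = min(h_requested, N)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(N, size=h_eff, replace=False))


def build_basis(X: np.ndarray, h_requested: int, seed: int) -> ProjectionBasis:
    X = _check_binary(X, "X")
    indices = select_basis(X.shape[0], h_requested, seed)
    return ProjectionBasis(
        indices=indices,
        h_requested=h_requested,
        h_eff=len(indices),
        fingerprints=X[indices].copy(),
    )


def project(X: np.ndarray, basis: ProjectionBasis) -> np.ndarray:
    """Tanimoto similarities of every row of X to every basis fingerprint."""
    return tanimoto_kernel(X, basis.fingerprints)


def _shrunk_covariance(Z: np.ndarray, shrinkage: float) -> np.ndarray:
    """(1 - delta) empirical covariance + delta * mean-variance * I."""
    h = Z.shape[1]
    centered = Z - Z.mean(axis=0)
    emp = centered.T @ centered / Z.shape[0]
    mean_var = float(np.trace(emp)) / h
    return (1.0 - shrinkage) * emp + shrinkage * mean_var * np.eye(h)


def _gaussian_threshold(mu_neg: float, mu_pos: float,
                        var_neg: float, var_pos: float) -> float:
    """Equal-prior crossing point of two 1-D Gaussians, if it lies between
    the means; otherwise the midpoint."""
    midpoint = 0.5 * (mu_neg + mu_pos)
    vp = max(var_pos, _VAR_FLOOR)
    vn = max(var_neg, _VAR_FLOOR)
    a = 0.5 * (1.0 / vn - 1.0 / vp)
    b = mu_pos / vp - mu_neg / vn
    c = 0.5 * (mu_neg**2 / vn - mu_pos**2 / vp) + 0.5 * np.log(vn / vp)
    lo, hi = min(mu_neg, mu_pos), max(mu_neg, mu_pos)
    if abs(a) < 1e-15:  # equal variances: linear crossing
        if abs(b) < 1e-15:
            return midpoint
        x = -c / b
        return x if lo <= x <= hi else midpoint
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        return midpoint
    sq = np.sqrt(disc)
    for x in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
        if lo <= x <= hi:
            return float(x)
    return midpoint


def eem_fit(Phi: np.ndarray, y_positive: np.ndarray, C: float,
            shrinkage: float = 0.1) -> tuple[np.ndarray, float]:
    """Closed-form solve in the projected space.

    ``y_positive`` is a boolean mask of positive-class rows of ``Phi``.
    Returns (beta, intercept); the decision rule is Phi @ beta - intercept > 0.
    """
    Phi = np.asarray(Phi, dtype=np.float64)
    y_positive = np.asarray(y_positive, dtype=bool)
    if C <= 0:
        raise InputError("C must be positive")
    pos, neg = Phi[y_positive], Phi[~y_positive]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateDatasetError("both classes must be present to fit")
    m_pos, m_neg = pos.mean(axis=0), neg.mean(axis=0)
    S_pos = _shrunk_covariance(pos, shrinkage)
    S_neg = _shrunk_covariance(neg, shrinkage)
    h = Phi.shape[1]
    A = 0.5 * (S_pos + S_neg) + np.eye(h) / C
    beta = scipy.linalg.solve(A, m_pos - m_neg, assume_a="pos")
    mu_pos, mu_neg = float(beta @ m_pos), float(beta @ m_neg)
    var_pos, var_neg = float(beta @ S_pos @ beta), float(beta @ S_neg @ beta)
    intercept = _gaussian_threshold(mu_neg, mu_pos, var_neg, var_pos)
    return beta, float(intercept)


@dataclass
class EEMModel:
    """A fitted model: projection basis, weights, intercept and class order."""

    basis: ProjectionBasis
    beta: np.ndarray
    intercept: float
    C: float
    class_order: tuple = ("active", "inactive")
    shrinkage: float = 0.1


def eem_predict(model: EEMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores and labels for new fingerprints.

    A score of exactly 0 classifies as the negative class (documented
    tie-break).
    """
    scores = project(X, model.basis) @ model.beta - model.intercept
    positive, negative = model.class_order
    labels = np.where(scores > 0, positive, negative).astype(object)
    return scores, labels


class EEMClassifier:
    """scikit-learn-style wrapper around the closed-form EEM solve.

    Parameters
    ----------
    h : requested number of random projections; capped at the training-set
        size at fit time.
    C : regularization strength (larger = weaker ridge).
    shrinkage : covariance shrinkage toward the scaled identity, needed to
        stabilize the h x h solve when class counts are below h.
    positive_label : the label treated as the positive class.
    random_state : seed of the basis subsample.
    """

    def __init__(self, h: int = 1000, C: float = 1e6, shrinkage: float = 0.1,
                 positive_label="active", random_state: int = 0):
        self.h = h
        self.C = C
        self.shrinkage = shrinkage
        self.positive_label = positive_label
        self.random_state = random_state
        self.model_: EEMModel | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "EEMClassifier":
        X = _check_binary(X, "X")
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise DegenerateDatasetError("training data contains a single class")
        if len(classes) > 2:
            raise InputError("binary classification only")
        if self.positive_label not in classes:
            raise InputError(
                f"positive label {self.positive_label!r} absent from y"
            )
        negative = classes[classes != self.positive_label][0]
        basis = build_basis(X, self.h, self.random_state)
        Phi = project(X, basis)
        beta, intercept = eem_fit(Phi, y == self.positive_label, self.C,
                                  self.shrinkage)
        self.model_ = EEMModel(
            basis=basis, beta=beta, intercept=intercept, C=self.C,
            class_order=(self.positive_label, negative),
            shrinkage=self.shrinkage,
        )
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return eem_predict(self.model_, X)[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return eem_predict(self.model_, X)[1]

    @property
    def h_eff_(self) -> int:
        return self.model_.basis.h_eff


# ---------------------------------------------------------------------------
# serialization: JSON metadata + TSV matrices, exact reload


def save_model(model: EEMModel, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "kernel": model.basis.kernel,
        "h_requested": int(model.basis.h_requested),
        "h_eff": int(model.basis.h_eff),
        "indices": [int(i) for i in model.basis.indices],
        "beta": [float(b) for b in model.beta],
        "intercept": model.intercept,
        "C": model.C,
        "shrinkage": model.shrinkage,
        "class_order": list(model.class_order),
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    np.savetxt(prefix.with_suffix(".basis.tsv"), model.basis.fingerprints,
               fmt="%d", delimiter="\t")


def load_model(prefix: str | Path) -> EEMModel:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    fingerprints = np.loadtxt(prefix.with_suffix(".basis.tsv"),
                              dtype=np.uint8, delimiter="\t", ndmin=2)
    basis = ProjectionBasis(
        indices=np.array(meta["indices"], dtype=np.int64),
        h_requested=meta["h_requested"],
        h_eff=meta["h_eff"],
        fingerprints=fingerprints,
        kernel=meta["kernel"],
    )
    return EEMModel(
        basis=basis,
        beta=np.array(meta["beta"], dtype=np.float64),
        intercept=float(meta["intercept"]),
        C=float(meta["C"]),
        class_order=tuple(meta["class_order"]),
        shrinkage=float(meta["shrinkage"]),
    )
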