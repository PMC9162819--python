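"""Dimensionality reduction: PCA variance retention, then HHO subset search.

The reduction is two-staged.  First PCA keeps the smallest number of
principal components whose cumulative explained-variance ratio reaches a
threshold (0.99 by default — "retain 99% of the information").  Second, a
binary wrapper selector runs Harris hawks optimization over the unit cube
``[0, 1]^k``: a continuous hawk position is thresholded at 0.5 into a
component mask, and the mask's fitness is the penalized cross-validated
error of a fast estimator restricted to the masked columns,

    fitness(mask) = (1 - mean CV accuracy) + alpha * |mask| / k .

Lower is better; the size penalty (default alpha = 0.01) breaks ties toward
smaller subsets.  The selector never returns an empty mask: an all-below-
threshold position falls back to its single largest component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .hho import OptimizationResult, OptimizerConfig, SearchSpace, hho_optimize

__all__ = [
    "PcaModel",
    "FeatureMask",
    "FitnessSpec",
    "fit_pca",
    "transform_pca",
    "inverse_transform_pca",
    "position_to_mask",
    "wrapper_fitness",
    "select_features_hho",
]


@dataclass(frozen=True)
class PcaModel:
    """Retained principal axes: k x d loadings, column means, variance ratios."""

    components: np.ndarray  # (k, d), rows orthonormal
    mean: np.ndarray  # (d,)
    explained_ratio: np.ndarray  # (k,)
    explained_variance: np.ndarray  # (k,) eigenvalues of the retained axes
    variance_threshold: float

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def retained_variance(self) -> float:
        return float(self.explained_ratio.sum())

    def to_json(self) -> str:
        return json.dumps(
            {
                "components": self.components.tolist(),
                "mean": self.mean.tolist(),
                "explained_ratio": self.explained_ratio.tolist(),
                "variance_threshold": self.variance_threshold,
            }
        )


@dataclass(frozen=True)
class FeatureMask:
    """Binary column mask plus the continuous hawk position it came from."""

    bits: np.ndarray  # bool, (d,)
    source_position: np.ndarray  # float in [0,1], (d,)

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)

    def to_json(self) -> str:
        return json.dumps(
            {
                "bits": self.bits.astype(int).tolist(),
                "source_position": self.source_position.tolist(),
            }
        )

    def column_list(self, names: list[str] | None = None) -> str:
        """One-line plain-text listing of the selected columns (audit trail)."""
        if names is None:
            names = [f"c{j}" for j in range(self.bits.size)]
        return " ".join(names[j] for j in self.indices)


_WRAPPER_ESTIMATORS = {
    "knn": lambda seed: KNeighborsClassifier(),
    "dt": lambda seed: DecisionTreeClassifier(random_state=seed),
    "nb": lambda seed: GaussianNB(),
}


@dataclass(frozen=True)
class FitnessSpec:
    """Wrapper-fitness knobs: estimator, folds, size penalty, seed."""

    estimator: str = "knn"
    cv_folds: int = 5
    penalty_alpha: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.estimator not in _WRAPPER_ESTIMATORS:
            raise ValueError(
                f"unknown wrapper estimator {self.estimator!r}; "
                f"supported: {sorted(_WRAPPER_ESTIMATORS)}"
            )
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if not 0.0 <= self.penalty_alpha <= 0.1:
            raise ValueError("penalty_alpha must lie in [0, 0.1]")


def fit_pca(X: np.ndarray, variance_threshold: float = 0.99) -> PcaModel:
    """Center the columns and keep the fewest axes reaching the threshold."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("X must be an n x d matrix with n >= 2, d >= 1")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must lie in (0, 1]")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("X has zero variance in every column; PCA is undefined")
    full = PCA(svd_solver="full").fit(X)
    cumulative = np.cumsum(full.explained_variance_ratio_)
    # tiny fp slack so threshold=1.0 selects exactly rank(X_centered) axes
    k = int(np.argmax(cumulative >= variance_threshold - 1e-12)) + 1
    return PcaModel(
        components=full.components_[:k].copy(),
        mean=full.mean_.copy(),
        explained_ratio=full.explained_variance_ratio_[:k].copy(),
        explained_variance=full.explained_variance_[:k].copy(),
        variance_threshold=variance_threshold,
    )


def transform_pca(model: PcaModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.mean.size:
        raise ValueError(
            f"X must have {model.mean.size} columns, got {X.shape[1] if X.ndim == 2 else X.shape}"
        )
    return (X - model.mean) @ model.components.T


def inverse_transform_pca(model: PcaModel, scores: np.ndarray) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    return scores @ model.components + model.mean


def position_to_mask(position: np.ndarray) -> FeatureMask:
    """Threshold a continuous position at 0.5 (inclusive) into a column mask.

    An empty result falls back to the single largest component, so a mask
    always selects at least one column.
    """
    position = np.clip(np.asarray(position, dtype=float), 0.0, 1.0)
    bits = position >= 0.5
    if not bits.any():
        bits = np.zeros_like(bits)
        bits[int(np.argmax(position))] = True
    return FeatureMask(bits=bits, source_position=position)


def wrapper_fitness(
    mask: FeatureMask | np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    spec: FitnessSpec = FitnessSpec(),
) -> float:
    """Penalized stratified-CV error of the wrapper estimator on masked columns."""
    bits = mask.bits if isinstance(mask, FeatureMask) else np.asarray(mask, dtype=bool)
    if not bits.any():
        raise ValueError("mask selects no columns")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("y contains a single class")
    if X.shape[0] < spec.cv_folds:
        raise ValueError("fewer rows than CV folds")
    Xm = X[:, bits]
    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    accs = []
    for train_idx, test_idx in skf.split(Xm, y):
        est = _WRAPPER_ESTIMATORS[spec.estimator](spec.seed)
        est.fit(Xm[train_idx], y[train_idx])
        accs.append(float(np.mean(est.predict(Xm[test_idx]) == y[test_idx])))
    error = 1.0 - float(np.mean(accs))
    return error + spec.penalty_alpha * bits.sum() / bits.size


def select_features_hho(
    X: np.ndarray,
    y: np.ndarray,
    *,
    pop_size: int = 15,
    max_iter: int = 40,
    seed: int = 0,
    beta: float = 1.5,
    fitness_spec: FitnessSpec | None = None,
) -> tuple[FeatureMask, OptimizationResult]:
    """Search component subsets with HHO over the unit cube.

    ``X`` is usually a PCA score matrix (the reduction order is PCA first,
    subset search on the components); any feature matrix works.  Masks are
    memoized so re-visited subsets cost nothing.
    """
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    if fitness_spec is None:
        fitness_spec = FitnessSpec(seed=seed)
    cache: dict[bytes, float] = {}

    def objective(position: np.ndarray) -> float:
        mask = position_to_mask(position)
        key = mask.bits.tobytes()
        if key not in cache:
            cache[key] = wrapper_fitness(mask, X, y, fitness_spec)
        return cache[key]

    config = OptimizerConfig(
        pop_size=pop_size,
        max_iter=max_iter,
        space=SearchSpace.cube(d, 0.0, 1.0),
        beta=beta,
        seed=seed,
    )
    result = hho_optimize(objective, config)
    return position_to_mask(result.best_position), result
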