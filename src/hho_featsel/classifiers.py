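"""Uniform classifier surface: the deep network plus classical baselines.

Every model — the dense network (``dnn``), decision tree (``dt``),
k-nearest neighbours (``knn``), Gaussian naive Bayes (``nb``), support
vector machine (``svm``) and gradient-boosted trees (``xgboost``) — is
wrapped in a :class:`ClassifierHandle` with the same fit/predict contract:
a float feature matrix and binary labels in, hard labels plus continuous
scores out.  That uniformity is what lets the pipeline run the same
experiment matrix over all of them.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .nn import ACTIVATIONS, OPTIMIZERS, MLPBinaryClassifier

__all__ = [
    "DnnSpec",
    "ClassifierHandle",
    "build_dnn",
    "fit_predict",
    "baseline_registry",
    "get_classifier",
]


@dataclass(frozen=True)
class DnnSpec:
    """Architecture and training schedule for the dense network.

    The reference configuration is five hidden layers with softsign
    activations, a sigmoid output, Adam, 600 epochs, batch size 64.  Hidden
    widths default to a pyramid; exact widths are a free design choice for
    small tabular inputs.
    """

    hidden_layers: tuple[int, ...] = (64, 32, 16, 8, 4)
    hidden_activation: str = "softsign"
    output_activation: str = "sigmoid"
    optimizer: str = "adam"
    epochs: int = 600
    batch_size: int = 64
    learning_rate: float | None = None
    seed: int = 0
    early_stopping: bool = False  # reference schedule trains the full budget

    def __post_init__(self) -> None:
        if len(self.hidden_layers) < 1:
            raise ValueError("need at least one hidden layer")
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        if self.hidden_activation not in ACTIVATIONS:
            raise ValueError(
                f"unknown activation {self.hidden_activation!r}; "
                f"supported: {sorted(ACTIVATIONS)}"
            )
        if self.output_activation != "sigmoid":
            raise ValueError("only a sigmoid output unit is supported (binary task)")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(
                f"unknown optimizer {self.optimizer!r}; supported: {sorted(OPTIMIZERS)}"
            )


@dataclass
class ClassifierHandle:
    """A model id plus the uniform fit/predict contract and run metadata."""

    model_id: str
    model: object
    fitted: bool = False
    metadata: dict = field(default_factory=dict)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ClassifierHandle":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        t0 = time.perf_counter()
        self.model.fit(np.asarray(X, dtype=float), y)
        self.metadata["train_seconds"] = time.perf_counter() - t0
        self.fitted = True
        return self

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (hard labels, continuous scores)."""
        if not self.fitted:
            raise RuntimeError(f"model {self.model_id!r} is not fitted")
        X = np.asarray(X, dtype=float)
        m = self.model
        if isinstance(m, MLPBinaryClassifier):
            scores = m.predict_proba(X)
            return (scores >= 0.5).astype(int), scores
        if hasattr(m, "predict_proba"):
            scores = m.predict_proba(X)[:, 1]
        else:
            scores = m.decision_function(X)
        return np.asarray(m.predict(X)).astype(int), scores


def build_dnn(spec: DnnSpec, input_dim: int) -> ClassifierHandle:
    """Construct (and seed-initialize) the dense network for a given input width."""
    net = MLPBinaryClassifier(
        hidden_layers=spec.hidden_layers,
        activation=spec.hidden_activation,
        optimizer=spec.optimizer,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        learning_rate=spec.learning_rate,
        seed=spec.seed,
    ).initialize(input_dim)
    return ClassifierHandle(
        model_id="dnn",
        model=net,
        metadata={"seed": spec.seed, "epochs": spec.epochs},
    )


def fit_predict(
    handle: ClassifierHandle,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Train the handle and score the held-out rows: (labels, scores)."""
    handle.fit(X_train, y_train)
    return handle.predict(X_test)


def baseline_registry(seed: int = 0) -> dict[str, Callable[[], ClassifierHandle]]:
    """Constructors for the six comparison models, keyed by id.

    Hyperparameters are library defaults unless configured; xgboost and the
    network are pinned to one thread / one seed so runs are reproducible.
    """

    def _make(model_id: str, factory: Callable[[], object]) -> Callable[[], ClassifierHandle]:
        def construct(**overrides) -> ClassifierHandle:
            model = factory()
            if overrides:
                model.set_params(**overrides)
            return ClassifierHandle(model_id=model_id, model=model, metadata={"seed": seed})

        return construct

    def construct_dnn(**overrides) -> ClassifierHandle:
        spec = DnnSpec(seed=seed, **overrides) if overrides else DnnSpec(seed=seed)
        return ClassifierHandle(
            model_id="dnn",
            model=MLPBinaryClassifier(
                hidden_layers=spec.hidden_layers,
                activation=spec.hidden_activation,
                optimizer=spec.optimizer,
                epochs=spec.epochs,
                batch_size=spec.batch_size,
                learning_rate=spec.learning_rate,
                seed=spec.seed,
            ),
            metadata={"seed": seed},
        )

    return {
        "dnn": construct_dnn,
        "dt": _make("dt", lambda: DecisionTreeClassifier(random_state=seed)),
        "knn": _make("knn", lambda: KNeighborsClassifier()),
        "nb": _make("nb", lambda: GaussianNB()),
        "svm": _make("svm", lambda: SVC(random_state=seed)),
        "xgboost": _make(
            "xgboost",
            lambda: XGBClassifier(
                n_estimators=100,
                random_state=seed,
                n_jobs=1,
                verbosity=0,
                eval_metric="logloss",
            ),
        ),
    }


def get_classifier(model_id: str, seed: int = 0, **overrides) -> ClassifierHandle:
    registry = baseline_registry(seed=seed)
    if model_id not in registry:
        raise KeyError(
            f"unknown model id {model_id!r}; available: {sorted(registry)}"
        )
    return registry[model_id](**overrides)
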