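"""Experiment orchestration: the {raw, PCA, PCA+HHO} x classifier matrix.

One experiment draws (or loads) a retinopathy table, makes a single seeded
stratified 80/20 holdout, and then for each reduction variant fits the
reduction *on the training rows only*, transforms both sides, trains every
requested classifier and scores it on the held-out rows.  Fitting
reductions on training data only is deliberate: fitting PCA or running the
wrapper search on all rows would leak test information into the comparison.

Two schedules exist: the default fast mode (network epochs 50, HHO
population 10 with 30 iterations) keeps the full 18-cell matrix cheap on a
single CPU, and ``paper_scale=True`` restores the 600-epoch training
budget.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifiers import DnnSpec, baseline_registry
from .data_io import (
    RetinopathyTable,
    SyntheticSpec,
    generate_synthetic,
    read_arff,
    read_csv,
)
from .dimensionality import (
    FeatureMask,
    FitnessSpec,
    fit_pca,
    select_features_hho,
    transform_pca,
)
from .evaluation import (
    METRIC_NAMES,
    MetricReport,
    compute_metrics,
    confusion,
    split_holdout,
)

__all__ = ["ExperimentSpec", "RunRecord", "run_experiment", "sweep", "report"]

VARIANTS = ("raw", "pca", "pca_hho")
MODEL_IDS = ("dnn", "dt", "knn", "nb", "svm", "xgboost")
SWEEP_AXES = ("activation", "optimizer", "depth", "epochs")


@dataclass
class ExperimentSpec:
    """Everything one run needs: data source, variants, models, seeds, knobs."""

    data: SyntheticSpec | str | Path = field(default_factory=SyntheticSpec)
    variants: tuple[str, ...] = VARIANTS
    models: tuple[str, ...] = MODEL_IDS
    train_fraction: float = 0.8
    split_seed: int = 0
    pca_threshold: float = 0.99
    hho_pop_size: int = 10
    hho_max_iter: int = 30
    hho_seed: int = 0
    fitness: FitnessSpec = field(default_factory=FitnessSpec)
    dnn: DnnSpec | None = None
    paper_scale: bool = False
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        self.variants = tuple(self.variants)
        self.models = tuple(self.models)
        if not self.variants or any(v not in VARIANTS for v in self.variants):
            raise ValueError(f"variants must be a non-empty subset of {VARIANTS}")
        if not self.models or any(m not in MODEL_IDS for m in self.models):
            raise ValueError(f"models must be a non-empty subset of {MODEL_IDS}")
        if self.dnn is None:
            epochs = 600 if self.paper_scale else 50
            self.dnn = DnnSpec(epochs=epochs, seed=self.split_seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentSpec":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        data = raw.pop("data", None)
        if isinstance(data, dict):
            kind = data.pop("kind", "synthetic")
            if kind == "synthetic":
                data = SyntheticSpec(**data)
            elif kind in ("arff", "csv"):
                data = data["path"]
            else:
                raise ValueError(f"unknown data kind {kind!r}")
        elif data is None:
            data = SyntheticSpec()
        fitness = FitnessSpec(**raw.pop("fitness", {}))
        dnn_cfg = raw.pop("dnn", None)
        dnn = None
        if dnn_cfg:
            if "hidden_layers" in dnn_cfg:
                dnn_cfg["hidden_layers"] = tuple(dnn_cfg["hidden_layers"])
            dnn = DnnSpec(**dnn_cfg)
        if "variants" in raw:
            raw["variants"] = tuple(raw["variants"])
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(data=data, fitness=fitness, dnn=dnn, **raw)

    def canonical_dict(self) -> dict:
        d = {
            "data": asdict(self.data) if isinstance(self.data, SyntheticSpec) else str(self.data),
            "variants": list(self.variants),
            "models": list(self.models),
            "train_fraction": self.train_fraction,
            "split_seed": self.split_seed,
            "pca_threshold": self.pca_threshold,
            "hho": {
                "pop_size": self.hho_pop_size,
                "max_iter": self.hho_max_iter,
                "seed": self.hho_seed,
            },
            "fitness": asdict(self.fitness),
            "dnn": asdict(self.dnn),
            "paper_scale": self.paper_scale,
        }
        return d

    def spec_hash(self) -> str:
        payload = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunRecord:
    """One experiment's outputs: a report per (variant, model) cell."""

    spec_hash: str
    reports: dict[tuple[str, str], MetricReport]
    counts: dict[tuple[str, str], dict]
    durations: dict[tuple[str, str], float]
    masks: dict[str, FeatureMask]
    errors: dict[tuple[str, str], str]
    seeds: dict[str, int]
    package_version: str = __version__

    def record_hash(self) -> str:
        payload = json.dumps(
            {
                "spec": self.spec_hash,
                "metrics": {
                    f"{v}/{m}": r.as_dict() for (v, m), r in sorted(self.reports.items())
                },
            },
            sort_keys=True,
            allow_nan=True,
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _load_table(spec: ExperimentSpec) -> RetinopathyTable:
    if isinstance(spec.data, SyntheticSpec):
        return generate_synthetic(spec.data)
    path = Path(spec.data)
    if path.suffix.lower() == ".arff":
        return read_arff(path)
    return read_csv(path)


def run_experiment(spec: ExperimentSpec) -> RunRecord:
    """Execute the matrix; a failing cell is recorded, not fatal to the run."""
    table = _load_table(spec)
    X, y = table.features, table.labels
    train_idx, test_idx = split_holdout(X, y, spec.train_fraction, spec.split_seed)
    X_train, y_train = X[train_idx], y[train_idx]
    X_test, y_test = X[test_idx], y[test_idx]

    reports: dict[tuple[str, str], MetricReport] = {}
    counts: dict[tuple[str, str], dict] = {}
    durations: dict[tuple[str, str], float] = {}
    masks: dict[str, FeatureMask] = {}
    errors: dict[tuple[str, str], str] = {}

    for variant in spec.variants:
        # reductions are fit on the training rows only (leakage guard)
        if variant == "raw":
            tr, te = X_train, X_test
        else:
            pca = fit_pca(X_train, spec.pca_threshold)
            tr, te = transform_pca(pca, X_train), transform_pca(pca, X_test)
            if variant == "pca_hho":
                mask, _ = select_features_hho(
                    tr,
                    y_train,
                    pop_size=spec.hho_pop_size,
                    max_iter=spec.hho_max_iter,
                    seed=spec.hho_seed,
                    fitness_spec=spec.fitness,
                )
                masks[variant] = mask
                tr, te = tr[:, mask.bits], te[:, mask.bits]
        registry = baseline_registry(seed=spec.split_seed)
        for model_id in spec.models:
            cell = (variant, model_id)
            try:
                if model_id == "dnn":
                    d = spec.dnn
                    handle = registry["dnn"](
                        hidden_layers=d.hidden_layers,
                        hidden_activation=d.hidden_activation,
                        optimizer=d.optimizer,
                        epochs=d.epochs,
                        batch_size=d.batch_size,
                        learning_rate=d.learning_rate,
                    )
                else:
                    handle = registry[model_id]()
                t0 = time.perf_counter()
                handle.fit(tr, y_train)
                y_pred, _ = handle.predict(te)
                durations[cell] = time.perf_counter() - t0
                c = confusion(y_test, y_pred)
                reports[cell] = compute_metrics(c)
                counts[cell] = {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn}
            except Exception as exc:  # noqa: BLE001 — cell isolation by design
                errors[cell] = f"{type(exc).__name__}: {exc}"

    record = RunRecord(
        spec_hash=spec.spec_hash(),
        reports=reports,
        counts=counts,
        durations=durations,
        masks=masks,
        errors=errors,
        seeds={"split": spec.split_seed, "hho": spec.hho_seed, "dnn": spec.dnn.seed},
    )
    if spec.output_dir is not None:
        report(record, spec.output_dir)
    return record


def _cell_label(variant: str, model_id: str) -> str:
    base = {"dnn": "DNN", "dt": "DT", "knn": "KNN", "nb": "NB", "svm": "SVM", "xgboost": "XGBoost"}[
        model_id
    ]
    suffix = {"raw": "", "pca": "-PCA", "pca_hho": "-PCA-HHO"}[variant]
    return base + suffix


def record_to_frame(record: RunRecord) -> pd.DataFrame:
    """Metrics-by-method table in percent (one column per matrix cell)."""
    data = {}
    for (variant, model_id), rep in record.reports.items():
        data[_cell_label(variant, model_id)] = rep.as_percent()
    frame = pd.DataFrame(data)
    return frame.reindex(list(METRIC_NAMES))


def report(record: RunRecord, out_dir: str | Path, formats: tuple[str, ...] = ("csv", "md")) -> list[Path]:
    """Write comparison tables (CSV/Markdown), timings, counts and masks."""
    unknown = set(formats) - {"csv", "md"}
    if unknown:
        raise ValueError(f"unknown report format(s): {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = record_to_frame(record)
    written = []
    if "csv" in formats:
        p = out / "metrics.csv"
        frame.to_csv(p, float_format="%.1f")
        written.append(p)
        t = out / "training_times.csv"
        pd.Series(
            {_cell_label(v, m): s for (v, m), s in record.durations.items()},
            name="train_seconds",
        ).to_csv(t)
        written.append(t)
    if "md" in formats:
        p = out / "metrics.md"
        lines = [
            "| metric | " + " | ".join(frame.columns) + " |",
            "|" + "---|" * (len(frame.columns) + 1),
        ]
        for metric, row in frame.iterrows():
            cells = " | ".join("NA" if np.isnan(v) else f"{v:.1f}" for v in row)
            lines.append(f"| {metric} | {cells} |")
        lines.append("")
        lines.append(
            "_recall and sensitivity share the formula TP/(TP+FN) and are "
            "therefore identical by construction._"
        )
        p.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(p)
    meta = out / "run_record.json"
    meta.write_text(
        json.dumps(
            {
                "spec_hash": record.spec_hash,
                "record_hash": record.record_hash(),
                "package_version": record.package_version,
                "seeds": record.seeds,
                "counts": {f"{v}/{m}": c for (v, m), c in record.counts.items()},
                "errors": {f"{v}/{m}": e for (v, m), e in record.errors.items()},
            },
            indent=2,
        ),
        encoding="utf-8",
    )
    written.append(meta)
    for variant, mask in record.masks.items():
        p = out / f"mask_{variant}.txt"
        p.write_text(mask.column_list() + "\n", encoding="utf-8")
        written.append(p)
    return written


def sweep(
    axis: str,
    values: list,
    base_spec: ExperimentSpec,
    n_seeds: int = 3,
) -> pd.DataFrame:
    """Train/test accuracy of the network along one architecture axis.

    ``axis`` is one of activation | optimizer | depth | epochs.  Each value
    is run with ``n_seeds`` seeds on ``base_spec``'s data (raw features); the
    returned table has one row per value with mean train and test accuracy.
    """
    if axis not in SWEEP_AXES:
        raise ValueError(f"unknown sweep axis {axis!r}; supported: {SWEEP_AXES}")
    table = _load_table(base_spec)
    X, y = table.features, table.labels
    train_idx, test_idx = split_holdout(X, y, base_spec.train_fraction, base_spec.split_seed)
    rows = []
    for value in values:
        train_accs, test_accs = [], []
        for s in range(n_seeds):
            d = base_spec.dnn
            if axis == "activation":
                d = replace(d, hidden_activation=value, seed=s)
            elif axis == "optimizer":
                d = replace(d, optimizer=value, seed=s)
            elif axis == "depth":
                widths = tuple(max(2, 64 // 2**l) for l in range(int(value)))
                d = replace(d, hidden_layers=widths, seed=s)
            else:  # epochs
                d = replace(d, epochs=int(value), seed=s)
            registry = baseline_registry(seed=s)
            handle = registry["dnn"](
                hidden_layers=d.hidden_layers,
                hidden_activation=d.hidden_activation,
                optimizer=d.optimizer,
                epochs=d.epochs,
                batch_size=d.batch_size,
                learning_rate=d.learning_rate,
            )
            handle.fit(X[train_idx], y[train_idx])
            pred_train, _ = handle.predict(X[train_idx])
            pred_test, _ = handle.predict(X[test_idx])
            train_accs.append(float(np.mean(pred_train == y[train_idx])))
            test_accs.append(float(np.mean(pred_test == y[test_idx])))
        rows.append(
            {
                axis: value,
                "train_accuracy": float(np.mean(train_accs)),
                "test_accuracy": float(np.mean(test_accs)),
                "train_accuracy_sd": float(np.std(train_accs)),
                "test_accuracy_sd": float(np.std(test_accs)),
            }
        )
    return pd.DataFrame(rows)
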