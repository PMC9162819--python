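"""Readers and a synthetic generator for Debrecen-style retinopathy tables.

The UCI "Diabetic Retinopathy Debrecen" table holds 1151 records of 19
features extracted from Messidor fundus photographs plus a binary outcome:

* two binary flags (image quality, pre-screening result),
* six microaneurysm detection counts at increasing confidence thresholds
  (alpha = 0.5 .. 1.0) — counts shrink as the threshold tightens,
* eight exudate area-like features, normalised and non-negative,
* the macula–optic-disc distance and the optic-disc diameter, both
  normalised to [0, 1],
* an AM/FM-classification flag,
* the class label (1 = signs of diabetic retinopathy).

``generate_synthetic`` emulates that schema with explicit distribution
families and a *planted signal*: chosen columns receive a class-conditional
mean shift of a configurable number of standard deviations, so feature
selectors can be benchmarked against a known ground truth, entirely offline.
"""

from __future__ import annotations

import hashlib
import urllib.request
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff

__all__ = [
    "COLUMN_NAMES",
    "COLUMN_FAMILIES",
    "RetinopathyTable",
    "SyntheticSpec",
    "read_arff",
    "read_csv",
    "write_csv",
    "generate_synthetic",
    "fetch_uci",
]

COLUMN_NAMES: tuple[str, ...] = (
    "quality",
    "pre_screening",
    "ma_05",
    "ma_06",
    "ma_07",
    "ma_08",
    "ma_09",
    "ma_10",
    "exudate_1",
    "exudate_2",
    "exudate_3",
    "exudate_4",
    "exudate_5",
    "exudate_6",
    "exudate_7",
    "exudate_8",
    "macula_od_distance",
    "od_diameter",
    "am_fm",
)
LABEL_NAME = "class"

# distribution family per feature column, by index
COLUMN_FAMILIES: tuple[str, ...] = (
    ("binary",) * 2 + ("count",) * 6 + ("continuous",) * 8 + ("bounded",) * 2 + ("binary",)
)

UCI_URL = (
    "https://archive.ics.uci.edu/static/public/329/"
    "diabetic+retinopathy+debrecen.zip"
)


@dataclass
class RetinopathyTable:
    """In-memory feature table: n x 19 matrix, binary labels, provenance."""

    features: np.ndarray
    labels: np.ndarray
    column_names: tuple[str, ...] = COLUMN_NAMES
    provenance: str = "synthetic"

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.features, columns=list(self.column_names))
        frame[LABEL_NAME] = self.labels
        return frame

    def validate(self) -> None:
        """Enforce the schema invariants; raises ValueError on violation."""
        X, y = self.features, self.labels
        if X.ndim != 2 or X.shape[1] != len(self.column_names):
            raise ValueError(f"feature matrix must be n x {len(self.column_names)}")
        if not np.isfinite(X).all():
            raise ValueError("missing or non-finite feature values")
        if y.shape != (X.shape[0],) or not np.isin(np.unique(y), (0, 1)).all():
            raise ValueError("labels must be a binary vector matching the rows")
        for j, family in enumerate(COLUMN_FAMILIES):
            col = X[:, j]
            name = self.column_names[j]
            if family == "binary" and not np.isin(np.unique(col), (0, 1)).all():
                raise ValueError(f"column {name} must be binary")
            if family == "count" and (np.any(col < 0) or np.any(col != np.round(col))):
                raise ValueError(f"column {name} must hold non-negative integers")
            if family == "continuous" and np.any(col < 0):
                raise ValueError(f"column {name} must be non-negative")
            if family == "bounded" and (np.any(col < 0) or np.any(col > 1)):
                raise ValueError(f"column {name} must lie in [0, 1]")


@dataclass
class SyntheticSpec:
    """Conditions for the synthetic generator.

    Defaults emulate the real table: 1151 rows, positive fraction 0.531
    (the Debrecen outcome balance), signal planted in the four mid-ladder
    microaneurysm counts with a one-standard-deviation class shift.
    """

    n_rows: int = 1151
    class_balance: float = 0.531
    informative_indices: tuple[int, ...] = (3, 4, 5, 6)
    effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1:
            raise ValueError("n_rows must be positive")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        idx = tuple(self.informative_indices)
        if len(idx) == 0 or any(j < 0 or j >= len(COLUMN_NAMES) for j in idx):
            raise ValueError("informative_indices must be a non-empty subset of columns")


# Baseline generator parameters per column family.  Microaneurysm rates are
# non-increasing along the confidence ladder; exudate scales taper similarly.
_BINARY_P = {"quality": 0.996, "pre_screening": 0.92, "am_fm": 0.35}
_MA_RATES = (40.0, 33.0, 26.0, 20.0, 13.0, 7.0)
_EXUDATE_SCALES = (60.0, 25.0, 10.0, 5.0, 2.0, 1.0, 0.5, 0.25)


def generate_synthetic(spec: SyntheticSpec) -> RetinopathyTable:
    """Draw a schema-conforming table with a planted class signal.

    Families: binary flags ~ Bernoulli; microaneurysm counts ~ Poisson with
    rates non-increasing along the confidence ladder; exudate features ~
    exponential; distance/diameter ~ U[0, 1].  An informative column's
    positive-class rows get a mean shift of ``effect_size`` of that column's
    standard deviation (clipped back to the family's support where needed).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_rows
    y = (rng.random(n) < spec.class_balance).astype(int)
    pos = y == 1
    X = np.zeros((n, len(COLUMN_NAMES)))
    informative = set(spec.informative_indices)

    for j, (name, family) in enumerate(zip(COLUMN_NAMES, COLUMN_FAMILIES)):
        if family == "binary":
            p = _BINARY_P[name]
            if j in informative:
                p_pos = float(np.clip(p + spec.effect_size * np.sqrt(p * (1 - p)), 0.01, 0.99))
                prob = np.where(pos, p_pos, p)
            else:
                prob = np.full(n, p)
            X[:, j] = (rng.random(n) < prob).astype(float)
        elif family == "count":
            lam = _MA_RATES[j - 2]
            if j in informative:
                lam_pos = lam + spec.effect_size * np.sqrt(lam)  # Poisson sd = sqrt(rate)
                rate = np.where(pos, lam_pos, lam)
            else:
                rate = np.full(n, lam)
            X[:, j] = rng.poisson(rate).astype(float)
        elif family == "continuous":
            scale = _EXUDATE_SCALES[j - 8]
            if j in informative:
                scale_arr = np.where(pos, scale * (1.0 + spec.effect_size), scale)
            else:
                scale_arr = np.full(n, scale)
            X[:, j] = rng.exponential(scale_arr)
        else:  # bounded
            base = rng.random(n)
            if j in informative:
                shift = spec.effect_size * np.sqrt(1.0 / 12.0)  # U[0,1] sd
                base = np.where(pos, np.clip(base + shift, 0.0, 1.0), base)
            X[:, j] = base

    table = RetinopathyTable(features=X, labels=y, provenance="synthetic")
    table.validate()
    return table


def generate_planted_scores(
    n_rows: int = 1000,
    n_columns: int = 12,
    informative_indices: tuple[int, ...] = (0, 1, 2, 3),
    effect_size: float = 1.0,
    class_balance: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, tuple[int, ...]]:
    """Continuous benchmark matrix with a known informative subset.

    Emulates a PCA score matrix: standard-normal columns, with the
    informative ones given a class-conditional mean shift of
    ``effect_size`` standard deviations.  Used to check that a feature
    selector can recover a planted signal.  Returns (X, y, informative).
    """
    if any(j < 0 or j >= n_columns for j in informative_indices):
        raise ValueError("informative_indices out of range")
    rng = np.random.default_rng(seed)
    y = (rng.random(n_rows) < class_balance).astype(int)
    X = rng.standard_normal((n_rows, n_columns))
    for j in informative_indices:
        X[:, j] += effect_size * y
    return X, y, tuple(informative_indices)


def read_arff(path: str | Path) -> RetinopathyTable:
    """Parse a UCI-dialect ARFF retinopathy table (19 features + class)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        data, meta = scipy_arff.loadarff(str(path))
    except Exception as exc:  # surface the offending file, not a bare parse error
        raise ValueError(f"malformed ARFF file {path}: {exc}") from exc
    names = list(meta.names())
    if len(names) != len(COLUMN_NAMES) + 1:
        raise ValueError(
            f"{path}: expected {len(COLUMN_NAMES) + 1} attributes, found {len(names)}"
        )
    frame = pd.DataFrame(data)
    label_col = frame.columns[-1]
    labels = frame[label_col]
    if labels.dtype == object:  # nominal class comes back as bytes
        labels = labels.map(lambda b: b.decode() if isinstance(b, bytes) else b)
    labels = labels.astype(float).astype(int).to_numpy()
    features = frame.iloc[:, :-1].astype(float).to_numpy()
    table = RetinopathyTable(
        features=features, labels=labels, provenance="uci"
    )
    table.validate()
    return table


def write_csv(table: RetinopathyTable, path: str | Path) -> None:
    """Write header + rows as UTF-8 CSV with '.' decimals (lossless)."""
    if table.n_rows == 0:
        raise ValueError("refusing to write an empty table")
    table.to_frame().to_csv(path, index=False, encoding="utf-8")


def read_csv(path: str | Path) -> RetinopathyTable:
    path = Path(path)
    frame = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    expected = list(COLUMN_NAMES) + [LABEL_NAME]
    if list(frame.columns) != expected:
        raise ValueError(
            f"{path}: header mismatch; expected columns {expected}, "
            f"found {list(frame.columns)}"
        )
    table = RetinopathyTable(
        features=frame[list(COLUMN_NAMES)].to_numpy(dtype=float),
        labels=frame[LABEL_NAME].to_numpy(dtype=int),
        provenance="csv",
    )
    table.validate()
    return table


def fetch_uci(dest_dir: str | Path, url: str = UCI_URL) -> Path:
    """Download the UCI archive, extract the ARFF and write a SHA-256 manifest.

    Network access is required; nothing in the package calls this implicitly.
    """
    dest = Path(dest_dir)
    dest.mkdir(parents=True, exist_ok=True)
    archive = dest / "diabetic_retinopathy_debrecen.zip"
    urllib.request.urlretrieve(url, archive)
    with zipfile.ZipFile(archive) as zf:
        zf.extractall(dest)
    manifest = dest / "SHA256SUMS"
    lines = []
    for f in sorted(dest.iterdir()):
        if f.is_file() and f != manifest:
            digest = hashlib.sha256(f.read_bytes()).hexdigest()
            lines.append(f"{digest}  {f.name}")
    manifest.write_text("\n".join(lines) + "\n", encoding="utf-8")
    arffs = sorted(dest.glob("*.arff"))
    if not arffs:
        raise FileNotFoundError(f"no ARFF file found in the downloaded archive at {dest}")
    return arffs[0]
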