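"""Cell-type classification from the 12-feature table.

Three classifiers mirror the reference analysis: k-nearest neighbors
(k = 3, on z-scored features), multinomial logistic regression (L2,
z-scored features), and gradient-boosted trees (XGBoost, raw features —
trees are invariant to monotone per-feature scaling).  Performance is
reported as held-out accuracy, the multiclass Matthews Correlation
Coefficient, and a 7x7 confusion matrix in the fixed type vocabulary
order; the boosted model additionally reports gain-based feature
importances normalized to sum to 1.

UMAP embedding of the feature table (random_state 42, spread 3,
min_dist 0.1) gives the 2D overview in which well-separated types form
distinct clusters.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, confusion_matrix, matthews_corrcoef
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import LabelEncoder, StandardScaler

from .features import FEATURE_COLUMNS

#: the seven airway epithelial cell types, fixed report order
CELL_TYPES = [
    "basal",
    "ciliated",
    "secretory",
    "hillock",
    "ionocyte",
    "tuft",
    "neuroendocrine",
]

CLASSIFIER_KINDS = ("knn", "multinomial_lr", "gradient_boosted")

#: the three autofluorescence-intensity features (for ablation studies)
AUTOFLUORESCENCE_FEATURES = ["fad", "nadh", "ratio"]


class TypingError(ValueError):
    pass


@dataclass
class TypingReport:
    """Evaluation summary for one classifier on one train/test split."""

    classifier_kind: str
    accuracy: float
    mcc: float
    confusion: np.ndarray  # 7x7 counts, rows = true, cols = predicted
    class_order: list[str] = field(default_factory=lambda: list(CELL_TYPES))
    importances: dict[str, float] | None = None
    train_indices: np.ndarray | None = None
    test_indices: np.ndarray | None = None
    seed: int | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "classifier_kind": self.classifier_kind,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "class_order": self.class_order,
            "confusion": np.asarray(self.confusion).tolist(),
            "importances": self.importances,
            "train_indices": None if self.train_indices is None else np.asarray(self.train_indices).tolist(),
            "test_indices": None if self.test_indices is None else np.asarray(self.test_indices).tolist(),
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# feature matrix plumbing
# ---------------------------------------------------------------------------

def feature_matrix(
    table: pd.DataFrame, feature_names: list[str] | None = None
) -> np.ndarray:
    """Extract the feature matrix, validating the schema.

    Raises ``TypingError`` ("feature schema error") on missing columns or
    rows with no usable values.
    """
    feature_names = feature_names or FEATURE_COLUMNS
    missing = [c for c in feature_names if c not in table.columns]
    if missing:
        raise TypingError(f"feature schema error: missing columns {missing}")
    X = table[feature_names].to_numpy(dtype=float)
    if len(X) and np.isnan(X).all(axis=1).any():
        raise TypingError("feature schema error: row with all features missing")
    return X


def embed_umap(
    table: pd.DataFrame,
    random_state: int = 42,
    spread: float = 3.0,
    min_dist: float = 0.1,
    n_neighbors: int = 15,
    feature_names: list[str] | None = None,
) -> np.ndarray:
    """2D UMAP embedding of the (standardized, median-imputed) features.

    Deterministic for a fixed ``random_state``: identical inputs give a
    bitwise-identical embedding.
    """
    import umap  # deferred: numba compilation makes this import slow

    X = feature_matrix(table, feature_names)
    if len(X) < n_neighbors + 1:
        raise TypingError(
            f"too few cells: {len(X)} rows < n_neighbors + 1 = {n_neighbors + 1}"
        )
    X = SimpleImputer(strategy="median").fit_transform(X)
    X = StandardScaler().fit_transform(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            random_state=random_state,
            spread=spread,
            min_dist=min_dist,
            n_neighbors=n_neighbors,
        )
        return np.asarray(reducer.fit_transform(X), dtype=np.float64)


def split_train_test(
    table: pd.DataFrame,
    test_frac: float = 0.25,
    seed: int = 0,
    stratified: bool = True,
    label_column: str = "cell_type",
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, covering train/test row indices.

    Test size is round-half-up of ``test_frac * N`` (206 cells at 0.25
    gives 52).  Stratification by cell type is attempted first and falls
    back to an unstratified split (with a warning) when some class has
    fewer than 2 members.
    """
    if not 0 < test_frac < 1:
        raise TypingError(f"test_frac must be in (0, 1): {test_frac}")
    n = len(table)
    n_test = int(math.floor(test_frac * n + 0.5))
    n_test = min(max(n_test, 1), n - 1)
    y = table[label_column].to_numpy()

    if stratified:
        counts = pd.Series(y).value_counts()
        if (counts < 2).any() or n_test < len(counts):
            warnings.warn("stratified split infeasible; falling back to unstratified")
        else:
            splitter = StratifiedShuffleSplit(n_splits=1, test_size=n_test, random_state=seed)
            train_idx, test_idx = next(splitter.split(np.zeros(n), y))
            return np.sort(train_idx), np.sort(test_idx)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

@dataclass
class CellTyper:
    """A fitted classifier plus the schema it was trained with."""

    kind: str
    model: object
    label_encoder: LabelEncoder
    feature_names: list[str]
    imputer: SimpleImputer
    seed: int | None = None

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = self.imputer.transform(feature_matrix(table, self.feature_names))
        return self.label_encoder.inverse_transform(self.model.predict(X))

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        X = self.imputer.transform(feature_matrix(table, self.feature_names))
        return self.model.predict_proba(X)


def train_classifier(
    kind: str,
    train_table: pd.DataFrame,
    feature_names: list[str] | None = None,
    label_column: str = "cell_type",
    seed: int = 42,
    **hyperparams,
) -> CellTyper:
    """Fit one of the three classifier kinds on a labeled feature table.

    knn: k = 3 on z-scored features (k overridable via ``n_neighbors``).
    multinomial_lr: L2-regularized logistic regression, max 1000 iterations.
    gradient_boosted: XGBoost, 200 trees, depth 3, learning rate 0.1,
    fixed seed, gain importances; consumes raw (unscaled) features.
    """
    feature_names = feature_names or FEATURE_COLUMNS
    if kind not in CLASSIFIER_KINDS:
        raise TypingError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")
    if len(train_table) == 0:
        raise TypingError("degenerate training data: empty training set")
    y_raw = train_table[label_column].to_numpy()
    if len(np.unique(y_raw)) < 2:
        raise TypingError("degenerate training data: fewer than 2 classes")

    X = feature_matrix(train_table, feature_names)
    imputer = SimpleImputer(strategy="median").fit(X)
    X = imputer.transform(X)
    encoder = LabelEncoder().fit(y_raw)
    y = encoder.transform(y_raw)

    if kind == "knn":
        k = hyperparams.pop("n_neighbors", 3)
        model = Pipeline(
            [("scale", StandardScaler()), ("knn", KNeighborsClassifier(n_neighbors=k, **hyperparams))]
        )
    elif kind == "multinomial_lr":
        model = Pipeline(
            [
                ("scale", StandardScaler()),
                ("lr", LogisticRegression(max_iter=hyperparams.pop("max_iter", 1000), **hyperparams)),
            ]
        )
    else:
        from xgboost import XGBClassifier

        model = XGBClassifier(
            n_estimators=hyperparams.pop("n_estimators", 200),
            max_depth=hyperparams.pop("max_depth", 3),
            learning_rate=hyperparams.pop("learning_rate", 0.1),
            random_state=seed,
            importance_type="gain",
            verbosity=0,
            **hyperparams,
        )
    model.fit(X, y)
    return CellTyper(
        kind=kind,
        model=model,
        label_encoder=encoder,
        feature_names=list(feature_names),
        imputer=imputer,
        seed=seed,
    )


def evaluate_classifier(
    typer_model: CellTyper,
    test_table: pd.DataFrame,
    label_column: str = "cell_type",
    class_order: list[str] | None = None,
) -> TypingReport:
    """Accuracy, multiclass MCC, confusion matrix and (for boosted trees)
    normalized gain importances on a labeled test table."""
    if len(test_table) == 0:
        raise TypingError("empty evaluation: no test rows")
    class_order = class_order or list(CELL_TYPES)
    y_true = test_table[label_column].to_numpy()
    y_pred = typer_model.predict(test_table)
    acc = float(accuracy_score(y_true, y_pred))
    mcc = float(matthews_corrcoef(y_true, y_pred))
    present = [c for c in class_order if c in set(y_true) | set(y_pred)] or class_order
    order = class_order if set(y_true) | set(y_pred) <= set(class_order) else present
    conf = confusion_matrix(y_true, y_pred, labels=order)

    importances = None
    if typer_model.kind == "gradient_boosted":
        raw = np.asarray(typer_model.model.feature_importances_, dtype=float)
        total = raw.sum()
        norm = raw / total if total > 0 else np.full_like(raw, 1.0 / len(raw))
        importances = {name: float(v) for name, v in zip(typer_model.feature_names, norm)}
    return TypingReport(
        classifier_kind=typer_model.kind,
        accuracy=acc,
        mcc=mcc,
        confusion=conf,
        class_order=order,
        importances=importances,
        seed=typer_model.seed,
    )


def predict_types(typer_model: CellTyper, table: pd.DataFrame) -> pd.DataFrame:
    """Predicted type and score per row of an unlabeled feature table.

    The score is the neighbor vote fraction for knn and the winning class
    probability for logistic regression / boosted trees.
    """
    proba = typer_model.predict_proba(table)
    idx = np.argmax(proba, axis=1)
    labels = typer_model.label_encoder.inverse_transform(idx)
    out = pd.DataFrame(
        {
            "cell_id": table["cell_id"].to_numpy() if "cell_id" in table.columns else np.arange(len(table)),
            "predicted_type": labels,
            "score": proba[np.arange(len(table)), idx],
        }
    )
    return out


# ---------------------------------------------------------------------------
# repeated-split evaluation (the headline numbers depend on the split)
# ---------------------------------------------------------------------------

def repeated_split_performance(
    table: pd.DataFrame,
    kinds: tuple[str, ...] = CLASSIFIER_KINDS,
    n_splits: int = 20,
    test_frac: float = 0.25,
    base_seed: int = 0,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Accuracy/MCC for each classifier over repeated stratified splits.

    Returns one row per (split, classifier) with columns ``seed``,
    ``classifier_kind``, ``accuracy``, ``mcc``.
    """
    records = []
    for i in range(n_splits):
        seed = base_seed + i
        train_idx, test_idx = split_train_test(table, test_frac=test_frac, seed=seed)
        train, test = table.iloc[train_idx], table.iloc[test_idx]
        for kind in kinds:
            model = train_classifier(kind, train, feature_names=feature_names, seed=seed)
            report = evaluate_classifier(model, test)
            records.append(
                {"seed": seed, "classifier_kind": kind, "accuracy": report.accuracy, "mcc": report.mcc}
            )
    return pd.DataFrame.from_records(records)
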