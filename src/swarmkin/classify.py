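"""Exploratory classification of operational sex ratio from kinematics.

A random forest (default 30 trees) is trained on per-frame kinematic
features (speed, X, Y, Z, distance from origin) of core swarming
tracks, with the OSR codes {0, 50, 100, 150, 200} as categorical
labels. Class imbalance is handled by SMOTE on the training split
only — the test split is never touched, so there is no leakage.
Evaluation reports a confusion matrix, per-class precision / recall /
F1, one-vs-rest ROC-AUC from forest class probabilities, and
mean-decrease-in-impurity feature importances normalised to sum to 1.

The classifier is an interpretive tool for which features separate
sex-ratio groups, not a production predictor.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support, roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigError, TrackDataError
from .kinematics import FEATURE_COLUMNS

__all__ = [
    "ClassifierConfig",
    "ClassifierReport",
    "split_train_test",
    "smote_oversample",
    "train_forest",
    "feature_importance",
    "evaluate",
    "run_classifier",
]

log = logging.getLogger(__name__)

FEATURES = ["speed_mps", "x_cm", "y_cm", "z_cm", "d_cm"]
LABEL = "group_code"


@dataclass(frozen=True)
class ClassifierConfig:
    n_trees: int = 30
    test_fraction: float = 0.20
    oversampling: str = "smote"  # or "none"
    k_neighbors: int = 5
    random_seed: int = 0
    split_unit: str = "frame"  # or "track"
    #: Practical cap on feature rows: long recordings at 100 fps yield
    #: millions of frames, far beyond what the exploratory forest needs.
    #: A seeded uniform subsample is drawn before splitting; None disables.
    max_rows: int | None = 50_000

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigError("test_fraction must be in (0, 1)")
        if self.n_trees < 1:
            raise ConfigError("n_trees must be >= 1")
        if self.oversampling not in ("none", "smote"):
            raise ConfigError(f"unknown oversampling {self.oversampling!r}")
        if self.split_unit not in ("frame", "track"):
            raise ConfigError(f"unknown split_unit {self.split_unit!r}")


def split_train_test(
    table: pd.DataFrame, config: ClassifierConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random train/test split at frame or track granularity.

    Track-level splitting keeps all frames of a track on one side,
    preventing within-track leakage; stratification is by class. The
    split is fully determined by ``config.random_seed``.
    """
    if table[LABEL].nunique() < 2:
        raise TrackDataError("classification needs >= 2 classes present")
    if config.split_unit == "frame":
        train, test = train_test_split(
            table,
            test_size=config.test_fraction,
            stratify=table[LABEL],
            random_state=config.random_seed,
        )
    else:
        per_track = table.groupby("track_id")[LABEL].first()
        tr_ids, te_ids = train_test_split(
            per_track.index.to_numpy(),
            test_size=config.test_fraction,
            stratify=per_track.to_numpy(),
            random_state=config.random_seed,
        )
        train = table[table["track_id"].isin(set(tr_ids))]
        test = table[table["track_id"].isin(set(te_ids))]
    missing = set(table[LABEL].unique()) - set(train[LABEL].unique())
    if missing:
        raise TrackDataError(f"classes {sorted(missing)} absent from the training split")
    return train.reset_index(drop=True), test.reset_index(drop=True)


def smote_oversample(
    X: np.ndarray, y: np.ndarray, k_neighbors: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling (SMOTE).

    Each synthetic sample lies uniformly on the segment between a
    minority-class sample and one of its k nearest same-class
    neighbours, until every class count equals the majority count.
    Classes smaller than k+1 get a reduced k (warned); singleton classes
    fall back to duplication (warned). Already balanced input is
    returned unchanged.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    if np.all(counts == n_max):
        return X, y
    new_X, new_y = [X], [y]
    for cls, cnt in zip(classes, counts):
        need = int(n_max - cnt)
        if need == 0:
            continue
        Xc = X[y == cls]
        if cnt == 1:
            log.warning("class %r has a single sample; duplicating instead of SMOTE", cls)
            new_X.append(np.repeat(Xc, need, axis=0))
            new_y.append(np.repeat(cls, need))
            continue
        k = min(k_neighbors, cnt - 1)
        if k < k_neighbors:
            log.warning("class %r: k_neighbors reduced from %d to %d", cls, k_neighbors, k)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, idx = nn.kneighbors(Xc)  # column 0 is the sample itself
        base = rng.integers(0, cnt, size=need)
        neigh = idx[base, rng.integers(1, k + 1, size=need)]
        gap = rng.random((need, 1))
        new_X.append(Xc[base] + gap * (Xc[neigh] - Xc[base]))
        new_y.append(np.repeat(cls, need))
    return np.vstack(new_X), np.concatenate(new_y)


def train_forest(
    X: np.ndarray, y: np.ndarray, config: ClassifierConfig
) -> RandomForestClassifier:
    """Fit the random forest: bootstrap trees with random feature subsetting,
    prediction by mean class probability across trees."""
    if np.unique(y).size < 2:
        raise TrackDataError("cannot train a classifier on a single class")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees, random_state=config.random_seed, n_jobs=1
    )
    forest.fit(X, y)
    return forest


def feature_importance(
    forest: RandomForestClassifier, feature_names: Sequence[str] = tuple(FEATURES)
) -> dict[str, float]:
    """Mean-decrease-in-impurity importances, normalised to sum to 1."""
    imp = np.asarray(forest.feature_importances_, float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return {name: float(v) for name, v in zip(feature_names, imp)}


@dataclass(frozen=True)
class ClassifierReport:
    """Evaluation bundle for one trained forest on one test split."""

    classes: list[int]
    confusion: np.ndarray  # rows = true class, columns = predicted
    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    auc: dict[int, float]  # one-vs-rest, NaN when a class is absent from test
    accuracy: float
    importances: dict[str, float]
    n_train: int
    n_test: int
    config: ClassifierConfig
    undefined_classes: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        def clean(d):
            return {str(k): (None if np.isnan(v) else round(float(v), 12)) for k, v in d.items()}

        return {
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "precision": clean(self.precision),
            "recall": clean(self.recall),
            "f1": clean(self.f1),
            "auc": clean(self.auc),
            "accuracy": round(float(self.accuracy), 12),
            "importances": {k: round(v, 12) for k, v in self.importances.items()},
            "n_train": self.n_train,
            "n_test": self.n_test,
            "config": self.config.__dict__,
            "undefined_classes": self.undefined_classes,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def evaluate(
    forest: RandomForestClassifier,
    X_test: np.ndarray,
    y_test: np.ndarray,
    config: ClassifierConfig,
    feature_names: Sequence[str] = tuple(FEATURES),
    n_train: int = 0,
) -> ClassifierReport:
    """Score the forest on the held-out split.

    Per-class metrics for classes absent from the test split are NaN and
    the class is listed in ``undefined_classes`` rather than silently
    zero-filled.
    """
    classes = [int(c) for c in forest.classes_]
    y_pred = forest.predict(X_test)
    proba = forest.predict_proba(X_test)
    cm = confusion_matrix(y_test, y_pred, labels=classes)
    prec, rec, f1, support = precision_recall_fscore_support(
        y_test, y_pred, labels=classes, zero_division=0
    )
    present = set(np.unique(y_test).tolist())
    undefined = [c for c in classes if c not in present]
    auc = {}
    for j, c in enumerate(classes):
        if c not in present or len(present) < 2:
            auc[c] = float("nan")
        else:
            auc[c] = float(roc_auc_score((np.asarray(y_test) == c).astype(int), proba[:, j]))
    nanify = lambda vals: {
        c: (float(v) if s > 0 else float("nan")) for c, v, s in zip(classes, vals, support)
    }
    return ClassifierReport(
        classes=classes,
        confusion=cm,
        precision=nanify(prec),
        recall=nanify(rec),
        f1=nanify(f1),
        auc=auc,
        accuracy=float(np.mean(np.asarray(y_test) == y_pred)),
        importances=feature_importance(forest, feature_names),
        n_train=n_train,
        n_test=int(len(y_test)),
        config=config,
        undefined_classes=undefined,
    )


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def run_classifier(
    table: pd.DataFrame, config: ClassifierConfig | None = None
) -> ClassifierReport:
    """Split, oversample the training side, train and evaluate in one call.

    Asserts that oversampling left the test partition byte-identical.
    """
    cfg = config or ClassifierConfig()
    if cfg.max_rows is not None and len(table) > cfg.max_rows:
        table = table.sample(n=cfg.max_rows, random_state=cfg.random_seed).reset_index(drop=True)
    train, test = split_train_test(table, cfg)
    test_digest = _digest(test)
    X_train = train[FEATURES].to_numpy(float)
    y_train = train[LABEL].to_numpy()
    if cfg.oversampling == "smote":
        X_train, y_train = smote_oversample(X_train, y_train, cfg.k_neighbors, cfg.random_seed)
    assert _digest(test) == test_digest, "oversampling must not touch the test partition"
    forest = train_forest(X_train, y_train, cfg)
    return evaluate(
        forest,
        test[FEATURES].to_numpy(float),
        test[LABEL].to_numpy(),
        cfg,
        n_train=int(len(y_train)),
    )
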