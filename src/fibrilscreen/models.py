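"""Classifier selection by stratified five-fold CV optimising macro F1.

Three families are tuned: logistic regression, k-nearest neighbours, and a
decision tree. All preprocessing — descriptor-column standardisation and
feature selection — is refit inside each training fold, so no statistics
leak from validation folds. Feature selection is two-stage: drop constant
and exactly duplicated columns, then rank by absolute coefficient of an
L1-penalised logistic fit, with the retained-set size chosen by CV macro
F1 over a small ladder.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import joblib
import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from fibrilscreen.chem import FeatureMatrix
from fibrilscreen.labeling import BINDER, NON_BINDER

logger = logging.getLogger(__name__)

LABELS = (BINDER, NON_BINDER)


# ---------------------------------------------------------------------------
# Classification report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass(frozen=True)
class ClassReport:
    """Per-class and aggregate precision/recall/F1 for binary binder labels.

    Zero-division cases (a class with no predicted positives, or no true
    members) score 0 and are listed in ``zero_division_flags``.
    """

    per_class: Mapping[str, ClassMetrics]
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    zero_division_flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "per_class": {
                c: vars(m).copy() for c, m in self.per_class.items()
            },
            "accuracy": self.accuracy,
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
            "weighted": {
                "precision": self.weighted_precision,
                "recall": self.weighted_recall,
                "f1": self.weighted_f1,
            },
            "zero_division_flags": list(self.zero_division_flags),
        }

    def to_text(self) -> str:
        """Render in the conventional report layout (rows Non-binder,
        Binder, Accuracy, Macro, Weighted; columns Precision, Recall, F1)."""
        rows = []
        header = f"{'':<12}{'Precision':>10}{'Recall':>10}{'F1':>10}"
        rows.append(header)
        for cls, title in ((NON_BINDER, "Non-binder"), (BINDER, "Binder")):
            m = self.per_class[cls]
            rows.append(
                f"{title:<12}{m.precision:>10.2f}{m.recall:>10.2f}{m.f1:>10.2f}"
            )
        rows.append(f"{'Accuracy':<12}{'':>10}{'':>10}{self.accuracy:>10.2f}")
        rows.append(
            f"{'Macro':<12}{self.macro_precision:>10.2f}"
            f"{self.macro_recall:>10.2f}{self.macro_f1:>10.2f}"
        )
        rows.append(
            f"{'Weighted':<12}{self.weighted_precision:>10.2f}"
            f"{self.weighted_recall:>10.2f}{self.weighted_f1:>10.2f}"
        )
        return "\n".join(rows)


def f1_score_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def classification_report(
    y_true: Sequence[str], y_pred: Sequence[str]
) -> ClassReport:
    """Compute a :class:`ClassReport` for binder/non-binder labels."""
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    unknown = set(y_true) | set(y_pred) - set(LABELS)
    unknown -= set(LABELS)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")

    n = len(y_true)
    flags: list[str] = []
    per_class: dict[str, ClassMetrics] = {}
    for cls in LABELS:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p == cls)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != cls and p == cls)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p != cls)
        support = tp + fn
        if tp + fp == 0:
            precision = 0.0
            flags.append(f"{cls}:precision")
        else:
            precision = tp / (tp + fp)
        if support == 0:
            recall = 0.0
            flags.append(f"{cls}:recall")
        else:
            recall = tp / support
        per_class[cls] = ClassMetrics(
            precision=precision,
            recall=recall,
            f1=f1_score_from_pr(precision, recall),
            support=support,
        )

    accuracy = sum(1 for t, p in zip(y_true, y_pred) if t == p) / n
    ms = list(per_class.values())
    w = np.array([m.support for m in ms], dtype=float)
    w = w / w.sum()
    return ClassReport(
        per_class=per_class,
        accuracy=accuracy,
        macro_precision=float(np.mean([m.precision for m in ms])),
        macro_recall=float(np.mean([m.recall for m in ms])),
        macro_f1=float(np.mean([m.f1 for m in ms])),
        weighted_precision=float(np.dot(w, [m.precision for m in ms])),
        weighted_recall=float(np.dot(w, [m.recall for m in ms])),
        weighted_f1=float(np.dot(w, [m.f1 for m in ms])),
        zero_division_flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Model families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelFamily:
    name: str
    grid: Mapping[str, tuple]

    def __post_init__(self) -> None:
        if self.name not in (
            "logistic_regression",
            "k_nearest_neighbors",
            "decision_tree",
        ):
            raise ValueError(f"unknown family {self.name!r}")
        for key, values in self.grid.items():
            if len(values) == 0:
                raise ValueError(f"empty grid for hyperparameter {key!r}")

    def param_combinations(self) -> list[dict]:
        keys = list(self.grid)
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(self.grid[k] for k in keys))
        ]


def default_families() -> list[ModelFamily]:
    """Modest desk-scale grids; regularisation over six log steps for the
    logistic model, odd neighbour counts to 25 for k-NN, depth/leaf/criterion
    for the tree."""
    return [
        ModelFamily(
            "logistic_regression",
            {
                "C": tuple(float(c) for c in np.logspace(-2, 3, 6)),
                "penalty": ("l1", "l2"),
                "class_weight": (None, "balanced"),
            },
        ),
        ModelFamily(
            "k_nearest_neighbors",
            {
                "n_neighbors": tuple(range(1, 26, 2)),
                "weights": ("uniform", "distance"),
                "metric": ("minkowski", "cosine"),
            },
        ),
        ModelFamily(
            "decision_tree",
            {
                "max_depth": (3, 5, 8, None),
                "min_samples_leaf": (1, 3, 5),
                "criterion": ("gini", "entropy"),
                "class_weight": (None, "balanced"),
            },
        ),
    ]


def _make_estimator(family: str, params: Mapping, seed: int):
    if family == "logistic_regression":
        params = dict(params)
        # grids name the penalty type; sklearn >=1.8 wants l1_ratio
        penalty = params.pop("penalty", "l2")
        return LogisticRegression(
            solver="liblinear",
            max_iter=5000,
            l1_ratio=1.0 if penalty == "l1" else 0.0,
            random_state=seed,  # liblinear L1 is stochastic otherwise
            **params,
        )
    if family == "k_nearest_neighbors":
        return KNeighborsClassifier(**params)
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# In-fold preprocessing: scaling + two-stage feature selection
# ---------------------------------------------------------------------------

def _binary_column_mask(X: np.ndarray) -> np.ndarray:
    return np.array(
        [np.isin(X[:, j], (0.0, 1.0)).all() for j in range(X.shape[1])]
    )


@dataclass
class _ScalerState:
    binary_mask: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_ScalerState":
        mask = _binary_column_mask(X)
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=0)
        sds = np.where(sds > 0, sds, 1.0)
        means[mask] = 0.0
        sds[mask] = 1.0
        return cls(binary_mask=mask, means=means, sds=sds)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.means) / self.sds


def _rank_features(Xs: np.ndarray, y01: np.ndarray, seed: int) -> np.ndarray:
    """Order all columns for top-k truncation.

    Constant and exactly duplicated columns (within the fitting rows) go to
    the back; the survivors are ranked by |coef| of an L1 logistic fit,
    ties broken by column variance then index.
    """
    n_cols = Xs.shape[1]
    variances = Xs.var(axis=0)
    alive = variances > 1e-12
    # drop exact duplicates, keeping the lowest index
    _, first_idx = np.unique(Xs.T, axis=0, return_index=True)
    dup_mask = np.zeros(n_cols, dtype=bool)
    dup_mask[first_idx] = True
    alive &= dup_mask

    coefs = np.zeros(n_cols)
    alive_idx = np.flatnonzero(alive)
    if alive_idx.size and len(np.unique(y01)) == 2:
        lr = LogisticRegression(
            l1_ratio=1.0,
            C=1.0,
            solver="liblinear",
            class_weight="balanced",
            max_iter=5000,
            random_state=seed,
        )
        lr.fit(Xs[:, alive_idx], y01)
        coefs[alive_idx] = np.abs(lr.coef_[0])

    order = sorted(
        range(n_cols),
        key=lambda j: (not alive[j], -coefs[j], -variances[j], j),
    )
    n_alive = int(alive.sum())
    return np.array(order[:n_alive], dtype=int)


@dataclass(frozen=True)
class SelectionConfig:
    k_grid: tuple[int, ...] = (32, 128, 512)


@dataclass
class _FoldState:
    train_idx: np.ndarray
    val_idx: np.ndarray
    scaler: _ScalerState
    ranking: np.ndarray  # alive columns, best first
    Xtr: np.ndarray
    Xva: np.ndarray
    ytr: np.ndarray
    yva: np.ndarray


def _prepare_folds(
    X: np.ndarray, y: np.ndarray, k_folds: int, seed: int
) -> list[_FoldState]:
    y01 = (y == BINDER).astype(int)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = []
    for train_idx, val_idx in skf.split(X, y01):
        if len(np.unique(y01[train_idx])) < 2:
            raise ValueError("a CV fold has a single class in training")
        scaler = _ScalerState.fit(X[train_idx])
        Xtr = scaler.transform(X[train_idx])
        ranking = _rank_features(Xtr, y01[train_idx], seed)
        folds.append(
            _FoldState(
                train_idx=train_idx,
                val_idx=val_idx,
                scaler=scaler,
                ranking=ranking,
                Xtr=Xtr,
                Xva=scaler.transform(X[val_idx]),
                ytr=y[train_idx],
                yva=y[val_idx],
            )
        )
    return folds


# ---------------------------------------------------------------------------
# Cross-validation and tuning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVResult:
    """Per-fold reports for one family at its evaluated configuration."""

    family: str
    params: Mapping
    n_features: int
    fold_reports: tuple[ClassReport, ...]

    @property
    def fold_macro_f1(self) -> np.ndarray:
        return np.array([r.macro_f1 for r in self.fold_reports])

    @property
    def fold_weighted_f1(self) -> np.ndarray:
        return np.array([r.weighted_f1 for r in self.fold_reports])

    @property
    def mean_macro_f1(self) -> float:
        return float(self.fold_macro_f1.mean())

    @property
    def std_macro_f1(self) -> float:
        return float(self.fold_macro_f1.std(ddof=0))

    @property
    def mean_weighted_f1(self) -> float:
        return float(self.fold_weighted_f1.mean())

    def summary(self) -> dict:
        return {
            "family": self.family,
            "params": dict(self.params),
            "n_features": self.n_features,
            "fold_macro_f1": self.fold_macro_f1.tolist(),
            "fold_weighted_f1": self.fold_weighted_f1.tolist(),
            "mean_macro_f1": self.mean_macro_f1,
            "std_macro_f1": self.std_macro_f1,
            "mean_weighted_f1": self.mean_weighted_f1,
        }


def _evaluate_config(
    folds: list[_FoldState],
    family: str,
    params: Mapping,
    k_features: Optional[int],
    seed: int,
) -> list[ClassReport]:
    reports = []
    for f in folds:
        cols = f.ranking if k_features is None else f.ranking[:k_features]
        est = _make_estimator(family, params, seed)
        est.fit(f.Xtr[:, cols], f.ytr)
        pred = _predict_labels(est, f.Xva[:, cols])
        reports.append(classification_report(list(f.yva), pred))
    return reports


def _predict_labels(est, X: np.ndarray, threshold: float = 0.5) -> list[str]:
    scores = _predict_scores(est, X)
    return [BINDER if s >= threshold else NON_BINDER for s in scores]


def _predict_scores(est, X: np.ndarray) -> np.ndarray:
    proba = est.predict_proba(X)
    binder_col = list(est.classes_).index(BINDER)
    return proba[:, binder_col]


def cross_validate(
    matrix: FeatureMatrix,
    labels: Sequence[str],
    family: ModelFamily | str,
    k_folds: int = 5,
    seed: int = 0,
    params: Optional[Mapping] = None,
    k_features: Optional[int] = None,
) -> CVResult:
    """Stratified k-fold CV of one family at fixed hyperparameters.

    Scaling and feature ranking are refit inside each training fold.
    ``params`` defaults to the estimator's library defaults; ``k_features``
    of None keeps every non-constant, non-duplicate column.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    name = family.name if isinstance(family, ModelFamily) else family
    y = np.asarray(labels)
    folds = _prepare_folds(matrix.X, y, k_folds, seed)
    reports = _evaluate_config(folds, name, params or {}, k_features, seed)
    n_feat = (
        min(k_features, len(folds[0].ranking))
        if k_features is not None
        else len(folds[0].ranking)
    )
    return CVResult(
        family=name,
        params=dict(params or {}),
        n_features=n_feat,
        fold_reports=tuple(reports),
    )


def select_features(
    matrix: FeatureMatrix,
    labels: Sequence[str],
    cv_seed: int = 0,
    k_folds: int = 5,
    selection: SelectionConfig = SelectionConfig(),
) -> list[str]:
    """Choose an ordered feature subset maximising mean CV macro F1.

    The retained-set size is picked from ``selection.k_grid`` using a
    reference L2 logistic model; the final ranking is refit on the full
    input. All-constant input yields an empty selection with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 features")
    y = np.asarray(labels)
    y01 = (y == BINDER).astype(int)
    scaler = _ScalerState.fit(matrix.X)
    Xs = scaler.transform(matrix.X)
    full_ranking = _rank_features(Xs, y01, cv_seed)
    if full_ranking.size == 0:
        logger.warning("all features constant; empty selection")
        return []

    folds = _prepare_folds(matrix.X, y, k_folds, cv_seed)
    ref_params = {"C": 1.0, "penalty": "l2", "class_weight": "balanced"}
    best_k, best_score = None, -1.0
    for k in selection.k_grid:
        reports = _evaluate_config(
            folds, "logistic_regression", ref_params, k, cv_seed
        )
        score = float(np.mean([r.macro_f1 for r in reports]))
        logger.info("feature selection: k=%d mean CV macro F1=%.4f", k, score)
        if score > best_score:
            best_k, best_score = k, score
    chosen = full_ranking[: best_k]
    return [matrix.feature_ids[j] for j in chosen]


@dataclass
class TrainedModel:
    """A fitted classifier with its preprocessing state.

    Prediction requires exactly ``selected_feature_ids`` (located by name
    in the incoming matrix), scales them with the stored training
    statistics, and thresholds the binder score at ``threshold``.
    """

    family: str
    hyperparameters: dict
    selected_feature_ids: list[str]
    scaler_means: np.ndarray
    scaler_sds: np.ndarray
    estimator: object
    threshold: float = 0.5

    def _locate_columns(self, matrix: FeatureMatrix) -> np.ndarray:
        index = {f: i for i, f in enumerate(matrix.feature_ids)}
        missing = [f for f in self.selected_feature_ids if f not in index]
        if missing:
            raise ValueError(f"matrix is missing model features: {missing[:10]}")
        return np.array([index[f] for f in self.selected_feature_ids], dtype=int)

    def predict_scores(self, matrix: FeatureMatrix) -> np.ndarray:
        cols = self._locate_columns(matrix)
        Xs = (matrix.X[:, cols] - self.scaler_means) / self.scaler_sds
        return _predict_scores(self.estimator, Xs)

    def predict(self, matrix: FeatureMatrix) -> tuple[list[str], np.ndarray]:
        scores = self.predict_scores(matrix)
        labels = [BINDER if s >= self.threshold else NON_BINDER for s in scores]
        return labels, scores

    def save(self, path: str) -> None:
        """Write a model bundle: a joblib payload plus a JSON sidecar with
        the family, hyperparameters and selected features."""
        joblib.dump(self, f"{path}.joblib")
        meta = {
            "family": self.family,
            "hyperparameters": self.hyperparameters,
            "n_selected_features": len(self.selected_feature_ids),
            "selected_feature_ids": self.selected_feature_ids,
            "threshold": self.threshold,
        }
        with open(f"{path}.json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @staticmethod
    def load(path: str) -> "TrainedModel":
        return joblib.load(f"{path}.joblib")


_FAMILY_ORDER = ("logistic_regression", "k_nearest_neighbors", "decision_tree")


def tune_and_train(
    matrix: FeatureMatrix,
    labels: Sequence[str],
    families: Optional[Sequence[ModelFamily]] = None,
    k_folds: int = 5,
    seed: int = 0,
    selection: SelectionConfig = SelectionConfig(),
    threshold: float = 0.5,
) -> tuple[TrainedModel, dict[str, CVResult]]:
    """Grid-search all families by mean CV macro F1; refit the winner.

    The retained-feature count is tuned jointly with the hyperparameters.
    Ties break on higher mean weighted F1, then fewer selected features,
    then fixed family order (logistic regression, k-NN, tree).
    """
    families = list(families) if families is not None else default_families()
    if not families:
        raise ValueError("families must be non-empty")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")

    folds = _prepare_folds(matrix.X, y, k_folds, seed)
    per_family: dict[str, CVResult] = {}
    for fam in families:
        best: Optional[CVResult] = None
        for params in fam.param_combinations():
            for k in selection.k_grid:
                reports = _evaluate_config(folds, fam.name, params, k, seed)
                cand = CVResult(
                    family=fam.name,
                    params=params,
                    n_features=min(k, len(folds[0].ranking)),
                    fold_reports=tuple(reports),
                )
                if best is None or _beats(cand, best):
                    best = cand
        per_family[fam.name] = best
        logger.info(
            "family %s: best mean CV macro F1 %.4f (params=%s, k=%d)",
            fam.name,
            best.mean_macro_f1,
            best.params,
            best.n_features,
        )

    order = {name: i for i, name in enumerate(_FAMILY_ORDER)}
    winner = min(
        per_family.values(),
        key=lambda r: (
            -r.mean_macro_f1,
            -r.mean_weighted_f1,
            r.n_features,
            order.get(r.family, 99),
        ),
    )

    # refit on the full training set
    y01 = (y == BINDER).astype(int)
    scaler = _ScalerState.fit(matrix.X)
    Xs = scaler.transform(matrix.X)
    ranking = _rank_features(Xs, y01, seed)
    cols = ranking[: winner.n_features]
    est = _make_estimator(winner.family, winner.params, seed)
    est.fit(Xs[:, cols], y)
    model = TrainedModel(
        family=winner.family,
        hyperparameters=dict(winner.params),
        selected_feature_ids=[matrix.feature_ids[j] for j in cols],
        scaler_means=scaler.means[cols],
        scaler_sds=scaler.sds[cols],
        estimator=est,
        threshold=threshold,
    )
    return model, per_family


def _beats(a: CVResult, b: CVResult) -> bool:
    order = {name: i for i, name in enumerate(_FAMILY_ORDER)}
    ka = (-a.mean_macro_f1, -a.mean_weighted_f1, a.n_features, order.get(a.family, 99))
    kb = (-b.mean_macro_f1, -b.mean_weighted_f1, b.n_features, order.get(b.family, 99))
    return ka < kb
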