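"""Feature selection, SVM training, evaluation and model persistence.

Feature selection is random-forest recursive feature elimination: fit a
forest, drop the feature with the lowest mean-decrease-in-impurity
importance, repeat until the requested number of features remains (top
eight by default).  The classifier is an RBF-kernel SVM on z-scored
features; reported metrics come from pooled out-of-fold predictions of a
stratified k-fold cross-validation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core import Metrics

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "ModelBundle",
    "rfe_select",
    "train_svm",
    "evaluate",
]

BUNDLE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Model hyperparameters.

    ``gamma='scale'`` is 1/(n_features × Var(X)), the standard RBF width
    for standardized features.  ``honest_cv`` re-runs feature selection
    inside every training fold so the cross-validated metrics carry no
    selection optimism (slower; default mirrors the simple pipeline and
    the optimism caveat is documented).
    """

    n_select: int = 8
    n_trees: int = 100
    cv_folds: int = 5
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"
    threshold: float = 0.5
    honest_cv: bool = False


def evaluate(tp: int, fn: int, tn: int, fp: int) -> Metrics:
    """Sensitivity/specificity/accuracy from a confusion table.

    Zero-denominator rates come back as NaN (undefined), never 0.
    """
    if tp + fn + tn + fp <= 0:
        raise ValueError("empty confusion table")
    return Metrics(tp=tp, fn=fn, tn=tn, fp=fp)


def _sorted_rows(X: np.ndarray) -> np.ndarray:
    """Row order canonicalized by feature values (input-order invariance)."""
    return np.lexsort(X.T[::-1])


def rfe_select(
    X: pd.DataFrame,
    y: np.ndarray,
    n_select: int = 8,
    n_trees: int = 100,
    seed: int = 0,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Recursive feature elimination under random-forest importance.

    Returns ``(selected, eliminated_in_order, importance_history)`` where
    the history has one row per elimination round (NaN for features
    already dropped).  Deterministic given ``seed`` and invariant to row
    order (rows are canonically sorted before each fit).
    """
    names = list(X.columns)
    if len(names) < 2:
        raise ValueError("need at least 2 features for elimination")
    if len(set(y)) < 2:
        raise ValueError("both classes must be present")
    if n_select >= len(names):
        warnings.warn(
            f"n_select={n_select} >= {len(names)} features; returning all features",
            stacklevel=2,
        )
        return names, [], pd.DataFrame(columns=names)

    Xv = X.to_numpy(dtype=np.float64)
    order = _sorted_rows(Xv)
    Xv, yv = Xv[order], np.asarray(y)[order]

    remaining = list(names)
    eliminated: list[str] = []
    history: list[dict[str, float]] = []
    while len(remaining) > n_select:
        cols = [names.index(n) for n in remaining]
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        rf.fit(Xv[:, cols], yv)
        imp = dict(zip(remaining, rf.feature_importances_))
        history.append(imp)
        worst = min(remaining, key=lambda n: (imp[n], n))
        remaining.remove(worst)
        eliminated.append(worst)
    return remaining, eliminated, pd.DataFrame(history, columns=names)


def _standardize_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0  # constant features pass through unscaled
    return mean, sd


def _fit_svc(Xz: np.ndarray, y: np.ndarray, config: ModelConfig, seed: int) -> SVC:
    with warnings.catch_warnings():
        # Platt-scaled SVC probabilities are deterministic given random_state;
        # newer sklearn deprecates the flag in favour of CalibratedClassifierCV
        warnings.simplefilter("ignore", FutureWarning)
        svc = SVC(
            kernel=config.kernel,
            C=config.C,
            gamma=config.gamma,
            probability=True,
            random_state=seed,
        )
        svc.fit(Xz, y)
    return svc


@dataclass
class ModelBundle:
    """A trained, self-contained TU pair classifier.

    Persistence stores JSON metadata plus the raw (selected-feature)
    training matrix in a single ``.npz`` archive; loading re-fits the SVM
    deterministically from the stored matrix and seed, so a bundle never
    depends on opaque serialized estimator state.
    """

    feature_pool: list[str]
    selected: list[str]
    elimination_order: list[str]
    mean: np.ndarray
    sd: np.ndarray
    config: ModelConfig
    metrics: Metrics
    seed: int
    gap_threshold: float
    X_train: np.ndarray  # raw (unstandardized) selected-feature matrix
    y_train: np.ndarray
    svc: SVC = field(repr=False, default=None)

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Positive-class probability for rows of selected features."""
        if isinstance(X, pd.DataFrame):
            missing = [n for n in self.selected if n not in X.columns]
            if missing:
                raise ValueError(f"missing model features: {missing}")
            X = X[self.selected].to_numpy(dtype=np.float64)
        Xz = (np.asarray(X, dtype=np.float64) - self.mean) / self.sd
        pos_col = int(np.flatnonzero(self.svc.classes_ == 1)[0])
        return self.svc.predict_proba(Xz)[:, pos_col]

    def save(self, path: str) -> None:
        meta = {
            "format_version": BUNDLE_FORMAT_VERSION,
            "feature_pool": self.feature_pool,
            "selected": self.selected,
            "elimination_order": self.elimination_order,
            "config": vars(self.config),
            "metrics": self.metrics.as_dict(),
            "seed": self.seed,
            "gap_threshold": self.gap_threshold,
        }
        np.savez(
            path,
            meta_json=np.array(json.dumps(meta)),
            mean=self.mean,
            sd=self.sd,
            X_train=self.X_train,
            y_train=self.y_train,
        )

    @classmethod
    def load(cls, path: str) -> "ModelBundle":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta_json"]))
            if meta["format_version"] != BUNDLE_FORMAT_VERSION:
                raise ValueError(
                    f"unsupported model bundle version {meta['format_version']}"
                )
            config = ModelConfig(**meta["config"])
            m = meta["metrics"]
            bundle = cls(
                feature_pool=meta["feature_pool"],
                selected=meta["selected"],
                elimination_order=meta["elimination_order"],
                mean=z["mean"],
                sd=z["sd"],
                config=config,
                metrics=Metrics(tp=m["tp"], fn=m["fn"], tn=m["tn"], fp=m["fp"]),
                seed=meta["seed"],
                gap_threshold=meta["gap_threshold"],
                X_train=z["X_train"],
                y_train=z["y_train"],
            )
        Xz = (bundle.X_train - bundle.mean) / bundle.sd
        bundle.svc = _fit_svc(Xz, bundle.y_train, config, bundle.seed)
        return bundle


def _cv_confusion(
    X: np.ndarray, y: np.ndarray, config: ModelConfig, seed: int
) -> tuple[int, int, int, int]:
    """Pooled out-of-fold confusion counts (fold-local standardization)."""
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    tp = fn = tn = fp = 0
    for train_idx, test_idx in skf.split(X, y):
        mean, sd = _standardize_params(X[train_idx])
        svc = _fit_svc((X[train_idx] - mean) / sd, y[train_idx], config, seed)
        pos_col = int(np.flatnonzero(svc.classes_ == 1)[0])
        proba = svc.predict_proba((X[test_idx] - mean) / sd)[:, pos_col]
        pred = (proba >= config.threshold).astype(int)
        truth = y[test_idx]
        tp += int(((pred == 1) & (truth == 1)).sum())
        fn += int(((pred == 0) & (truth == 1)).sum())
        tn += int(((pred == 0) & (truth == 0)).sum())
        fp += int(((pred == 1) & (truth == 0)).sum())
    return tp, fn, tn, fp


def train_svm(
    X: pd.DataFrame,
    y: np.ndarray,
    config: ModelConfig = ModelConfig(),
    seed: int = 0,
    selected: list[str] | None = None,
    elimination_order: list[str] | None = None,
    gap_threshold: float = 0.0,
) -> ModelBundle:
    """Train the SVM on the (already selected) features and cross-validate.

    ``X`` must be restricted to the selected features (pass ``selected``
    for bookkeeping; defaults to the columns of ``X``).  Metrics are
    pooled over stratified out-of-fold predictions; the final model is
    fitted on all rows with full-data standardization.
    """
    y = np.asarray(y, dtype=np.int64)
    counts = pd.Series(y).value_counts()
    if len(counts) < 2 or counts.min() < config.cv_folds:
        raise ValueError(
            f"each class needs at least cv_folds={config.cv_folds} members; got {dict(counts)}"
        )
    selected = list(selected if selected is not None else X.columns)
    Xv = X[selected].to_numpy(dtype=np.float64)

    tp, fn, tn, fp = _cv_confusion(Xv, y, config, seed)
    metrics = evaluate(tp, fn, tn, fp)
    logger.info(
        "CV (k=%d): sensitivity=%.3f specificity=%.3f accuracy=%.3f",
        config.cv_folds,
        metrics.sensitivity,
        metrics.specificity,
        metrics.accuracy,
    )

    mean, sd = _standardize_params(Xv)
    svc = _fit_svc((Xv - mean) / sd, y, config, seed)
    return ModelBundle(
        feature_pool=selected,
        selected=selected,
        elimination_order=list(elimination_order or []),
        mean=mean,
        sd=sd,
        config=config,
        metrics=metrics,
        seed=seed,
        gap_threshold=gap_threshold,
        X_train=Xv,
        y_train=y,
        svc=svc,
    )


def fit(
    X: pd.DataFrame,
    y: np.ndarray,
    config: ModelConfig = ModelConfig(),
    seed: int = 0,
    gap_threshold: float = 0.0,
) -> ModelBundle:
    """Feature selection + SVM training in one call.

    With ``honest_cv`` the reported metrics come from re-running RFE
    inside each training fold; the final fitted model still uses the
    full-data selection.
    """
    selected, eliminated, _ = rfe_select(
        X, y, n_select=config.n_select, n_trees=config.n_trees, seed=seed
    )
    bundle = train_svm(
        X[selected],
        y,
        config=config,
        seed=seed,
        selected=selected,
        elimination_order=eliminated,
        gap_threshold=gap_threshold,
    )
    if config.honest_cv:
        yv = np.asarray(y, dtype=np.int64)
        skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
        tp = fn = tn = fp = 0
        for train_idx, test_idx in skf.split(X, yv):
            sel_f, _, _ = rfe_select(
                X.iloc[train_idx], yv[train_idx], config.n_select, config.n_trees, seed
            )
            Xf = X[sel_f].to_numpy(dtype=np.float64)
            mean, sd = _standardize_params(Xf[train_idx])
            svc = _fit_svc((Xf[train_idx] - mean) / sd, yv[train_idx], config, seed)
            pos_col = int(np.flatnonzero(svc.classes_ == 1)[0])
            proba = svc.predict_proba((Xf[test_idx] - mean) / sd)[:, pos_col]
            pred = (proba >= config.threshold).astype(int)
            truth = yv[test_idx]
            tp += int(((pred == 1) & (truth == 1)).sum())
            fn += int(((pred == 0) & (truth == 1)).sum())
            tn += int(((pred == 0) & (truth == 0)).sum())
            fp += int(((pred == 1) & (truth == 0)).sum())
        bundle.metrics = evaluate(tp, fn, tn, fp)
    return bundle
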