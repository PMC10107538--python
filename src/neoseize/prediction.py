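"""Nested leave-one-out cross-validation and late-stage probability fusion.

The outer loop leaves one subject out; the inner loop runs a stratified
10-fold cross-validation repeated 5 times on the remaining subjects for each
candidate tree depth, selects the depth maximizing the mean inner Matthews
correlation coefficient (ties broken toward the shallower tree), refits on all
remaining subjects and scores the held-out one.  Mean-imputation statistics
are computed inside each outer training set only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

from .evaluation import ConfusionMatrix, mcc

__all__ = [
    "ModelSpec",
    "PredictionSet",
    "clinical_model_spec",
    "qualitative_model_spec",
    "quantitative_model_spec",
    "nested_loocv",
    "fuse",
]


@dataclass(frozen=True)
class ModelSpec:
    """Learner family and its (small) hyperparameter search space."""

    learner: str  # "random_forest" | "gradient_boosting"
    n_trees: int
    depth_grid: tuple[int, ...]
    learning_rate: float | None = None  # boosting only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learner not in ("random_forest", "gradient_boosting"):
            raise ValueError(f"unknown learner {self.learner!r}")
        if not self.depth_grid:
            raise ValueError("depth grid must be non-empty")

    def build(self, depth: int, seed: int):
        if self.learner == "random_forest":
            return RandomForestClassifier(
                n_estimators=self.n_trees, max_depth=depth, random_state=seed
            )
        return HistGradientBoostingClassifier(
            max_iter=self.n_trees,
            learning_rate=self.learning_rate or 0.1,
            max_depth=depth,
            early_stopping=False,
            random_state=seed,
        )


def clinical_model_spec(seed: int = 0) -> ModelSpec:
    """Random forest, 100 trees, depth grid {1, 2, 3, 4}."""
    return ModelSpec("random_forest", 100, (1, 2, 3, 4), seed=seed)


def qualitative_model_spec(seed: int = 0) -> ModelSpec:
    """Same family and grid as the clinical model."""
    return ModelSpec("random_forest", 100, (1, 2, 3, 4), seed=seed)


def quantitative_model_spec(seed: int = 0) -> ModelSpec:
    """Gradient boosting, 40 iterations, learning rate 0.1, depths {2,…,6}."""
    return ModelSpec("gradient_boosting", 40, (2, 3, 4, 5, 6), learning_rate=0.1, seed=seed)


@dataclass
class PredictionSet:
    """Out-of-fold probabilities: each subject scored by a model never trained
    on that subject."""

    subject_ids: np.ndarray
    probabilities: np.ndarray
    labels: np.ndarray
    chosen_depths: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject_ids,
                "probability": self.probabilities,
                "label": self.labels,
                "chosen_depth": self.chosen_depths,
            }
        )


def _as_matrix(X) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), X.index.to_numpy()
    X = np.asarray(X, dtype=float)
    return X, np.arange(X.shape[0])


def _impute_with(train_means: np.ndarray, X: np.ndarray) -> np.ndarray:
    out = X.copy()
    rows, cols = np.where(np.isnan(out))
    out[rows, cols] = train_means[cols]
    return out


def _binary_mcc(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    return mcc(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))


def nested_loocv(
    X,
    y,
    spec: ModelSpec,
    inner_splits: int = 10,
    inner_repeats: int = 5,
) -> PredictionSet:
    """Out-of-fold seizure probabilities under nested leave-one-out CV.

    ``inner_splits``/``inner_repeats`` control the inner stratified k-fold
    scheme used for depth selection (defaults follow the published protocol;
    reduce them for desk-scale runs).
    """
    Xm, ids = _as_matrix(X)
    y = np.asarray(y, dtype=int).ravel()
    n = Xm.shape[0]
    if n < 20:
        raise ValueError("nested LOOCV requires at least 20 subjects")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    min_class = int(np.bincount(y).min())
    splits = min(inner_splits, min_class)
    if splits < 2:
        raise ValueError("too few subjects in the minority class for inner CV")

    probs = np.empty(n)
    depths = np.empty(n, dtype=int)
    rng = np.random.default_rng(spec.seed)
    prior = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))

    for i in range(n):
        tr = np.arange(n) != i
        X_tr, y_tr = Xm[tr], y[tr]
        col_means = np.nanmean(
            np.where(np.isnan(X_tr).all(axis=0), 0.0, X_tr), axis=0
        )
        col_means = np.nan_to_num(col_means)
        X_tr_imp = _impute_with(col_means, X_tr)

        if len(spec.depth_grid) == 1:
            best_depth = spec.depth_grid[0]
        else:
            cv_seed = int(rng.integers(2**31 - 1))
            cv = RepeatedStratifiedKFold(
                n_splits=splits, n_repeats=inner_repeats, random_state=cv_seed
            )
            folds = list(cv.split(X_tr_imp, y_tr))
            scores = {}
            for depth in sorted(spec.depth_grid):
                fold_scores = []
                for fi, (itr, ival) in enumerate(folds):
                    model = spec.build(depth, seed=spec.seed + fi)
                    model.fit(X_tr_imp[itr], y_tr[itr])
                    pred = model.predict(X_tr_imp[ival])
                    fold_scores.append(_binary_mcc(y_tr[ival], pred))
                scores[depth] = float(np.mean(fold_scores))
            best_depth = max(sorted(scores), key=lambda d: (scores[d], -d))

        model = spec.build(best_depth, seed=spec.seed)
        model.fit(X_tr_imp, y_tr)
        X_te = _impute_with(col_means, Xm[i : i + 1])
        p = float(np.clip(model.predict_proba(X_te)[0, 1], 1e-6, 1 - 1e-6))
        # leave-one-out prior correction: holding a subject out shifts the
        # training prevalence against its own class, which anti-orders null
        # probabilities; re-reference each fold's prior to the cohort prior
        p_tr = float(np.clip(y_tr.mean(), 1e-6, 1 - 1e-6))
        z = np.log(p / (1 - p)) - np.log(p_tr / (1 - p_tr)) + np.log(prior / (1 - prior))
        probs[i] = 1.0 / (1.0 + np.exp(-z))
        depths[i] = best_depth

    return PredictionSet(
        subject_ids=ids, probabilities=probs, labels=y, chosen_depths=depths
    )


def fuse(p_a, p_b, eps: float = 1e-6):
    """Late-stage fusion: inverse logit of the mean of the two logits.

    Symmetric, monotone in each argument, identity on equal inputs, and maps
    complementary pairs (p, 1−p) to 0.5.
    """
    p_a = np.clip(np.asarray(p_a, dtype=float), eps, 1 - eps)
    p_b = np.clip(np.asarray(p_b, dtype=float), eps, 1 - eps)
    z = 0.5 * (np.log(p_a / (1 - p_a)) + np.log(p_b / (1 - p_b)))
    out = 1.0 / (1.0 + np.exp(-z))
    return float(out) if out.ndim == 0 else out
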