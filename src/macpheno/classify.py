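"""Multivariate phenotype classification from cytokine/marker features.

Two complementary routes mirror the combined-marker analysis:

* PCA projection of the feature matrix (default features: IL-1B, IL-6,
  IL-10 RQ) for visual separation of M0/M1/M2, and multinomial logistic
  regression whose *training* accuracy is the reported metric — no
  validation split is used because none was described for the original
  analysis; a cross-validation option exists but is off by default.
* a univariate membrane-order rule, :class:`GPThresholdClassifier`, cutting
  the reported GP scale at the midpoints of the published group means
  (60.27 and 66.78) so that lower order -> M0, intermediate -> M1,
  higher -> M2.

Both classifiers follow the scikit-learn estimator protocol (``fit`` /
``predict`` / ``get_params``) and compose with sklearn model selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

__all__ = [
    "ClassificationReport",
    "pca_project",
    "logistic_training_accuracy",
    "GPThresholdClassifier",
    "classify_by_gp",
    "feature_matrix_from_table",
    "DEFAULT_GP_THRESHOLDS",
]

# Midpoints of the published reported-scale GP group means
# (56.98, 63.56, 69.99): (56.98+63.56)/2 and (63.56+69.99)/2.
DEFAULT_GP_THRESHOLDS = (60.27, 66.775)

# Mild L2 ridge keeps the multinomial fit convergent even when the classes
# are perfectly separable (where the unpenalized MLE diverges).
LOGISTIC_C = 1e4
LOGISTIC_MAX_ITER = 20000


@dataclass(frozen=True)
class ClassificationReport:
    """Training-set performance of the multivariate classifier."""

    training_accuracy: float            # percent
    confusion_counts: pd.DataFrame      # true class x predicted class
    pc_variance_explained: np.ndarray   # fractions, non-increasing
    classes: tuple[str, ...]
    converged: bool
    cv_accuracy: float | None = None    # percent, only when cv requested


def feature_matrix_from_table(table: pd.DataFrame,
                              value_col: str = "value",
                              feature_col: str = "gene") -> pd.DataFrame:
    """Pivot a tidy replicate table into a sample x feature matrix.

    Expects columns ``sample, phenotype`` plus ``feature_col``/``value_col``;
    returns a frame indexed by sample with one column per feature and a
    ``phenotype`` column. Raises on missing combinations.
    """
    wide = table.pivot_table(index=["sample", "phenotype"], columns=feature_col,
                             values=value_col, aggfunc="mean")
    if wide.isna().any().any():
        raise ValueError("missing sample x feature combinations in table")
    wide = wide.reset_index().set_index("sample")
    wide.columns.name = None
    return wide


def _split_features(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if "phenotype" not in features.columns:
        raise ValueError("feature matrix must carry a 'phenotype' column")
    cols = [c for c in features.columns if c != "phenotype"]
    X = features[cols].to_numpy(float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains missing/non-finite values")
    y = features["phenotype"].to_numpy(str)
    return X, y, cols


def pca_project(features: pd.DataFrame, n_components: int | None = None,
                standardize: bool = True) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA scores and per-component variance fractions.

    Components are sign-fixed by making each component's largest-magnitude
    loading positive, so the projection is fully deterministic. With
    ``standardize`` on (default), a constant feature is an error (its z-score
    is undefined) and is reported by name.
    """
    X, y, cols = _split_features(features)
    if n_components is None:
        n_components = X.shape[1]
    if n_components > X.shape[1]:
        raise ValueError("n_components exceeds the number of features")
    if standardize:
        sd = X.std(axis=0)
        flat = [c for c, s in zip(cols, sd) if s == 0]
        if flat:
            raise ValueError(f"constant feature(s) cannot be standardized: {flat}")
        X = (X - X.mean(axis=0)) / sd
    else:
        X = X - X.mean(axis=0)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    comps = pca.components_
    for k in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[k]))
        if comps[k, j] < 0:
            comps[k] *= -1
            scores[:, k] *= -1
    out = pd.DataFrame(scores, index=features.index,
                       columns=[f"PC{k + 1}" for k in range(n_components)])
    out["phenotype"] = y
    return out, pca.explained_variance_ratio_.copy()


def logistic_training_accuracy(features: pd.DataFrame, seed: int = 0,
                               cv_folds: int | None = None) -> ClassificationReport:
    """Multinomial logistic regression on standardized features.

    Reports the training-set accuracy (percent) and the confusion matrix;
    ``cv_folds`` additionally reports stratified cross-validated accuracy.
    Non-convergence is flagged in the report, never silent.
    """
    X, y, _ = _split_features(features)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    clf = LogisticRegression(C=LOGISTIC_C, max_iter=LOGISTIC_MAX_ITER,
                             random_state=seed)
    pipe = make_pipeline(StandardScaler(), clf)
    import warnings as _w
    with _w.catch_warnings(record=True) as caught:
        _w.simplefilter("always")
        pipe.fit(X, y)
    converged = not any("ConvergenceWarning" in type(w.message).__name__
                        for w in caught)
    pred = pipe.predict(X)
    acc = 100.0 * float(np.mean(pred == y))
    cm = pd.DataFrame(confusion_matrix(y, pred, labels=classes),
                      index=classes, columns=classes)
    _, var_frac = pca_project(features)
    cv_acc = None
    if cv_folds:
        cv_acc = 100.0 * float(np.mean(cross_val_score(pipe, X, y, cv=cv_folds)))
    return ClassificationReport(training_accuracy=acc, confusion_counts=cm,
                                pc_variance_explained=var_frac,
                                classes=tuple(classes), converged=converged,
                                cv_accuracy=cv_acc)


class GPThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Phenotype call from reported-scale GP with two fixed cut points.

    ``reported GP < lower`` -> M0; ``lower <= GP < upper`` -> M1;
    ``GP >= upper`` -> M2 (a value exactly at a threshold goes to the higher
    class). ``fit`` only validates thresholds — the cut points are domain
    knowledge, not learned — so the estimator plugs into sklearn tooling
    without requiring labels.
    """

    def __init__(self, thresholds: tuple[float, float] = DEFAULT_GP_THRESHOLDS):
        self.thresholds = thresholds

    def fit(self, X, y=None):
        lo, hi = self.thresholds
        if not lo < hi:
            raise ValueError("thresholds must be strictly increasing")
        self.classes_ = np.array(["M0", "M1", "M2"])
        self.thresholds_ = (float(lo), float(hi))
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X, ensure_2d=False).reshape(-1)
        lo, hi = self.thresholds_
        out = np.where(X < lo, "M0", np.where(X < hi, "M1", "M2"))
        return out


def classify_by_gp(summaries, thresholds: tuple[float, float] = DEFAULT_GP_THRESHOLDS
                   ) -> pd.DataFrame:
    """Per-cell phenotype calls from reported GP summaries.

    ``summaries`` is a list of :class:`macpheno.gp.GPSummary` or a frame with
    ``cell_id`` and ``mean_gp_reported`` columns. Returns ``cell_id,
    mean_gp_reported, call``.
    """
    from .gp import summaries_to_frame

    frame = summaries if isinstance(summaries, pd.DataFrame) else \
        summaries_to_frame(summaries)
    clf = GPThresholdClassifier(thresholds).fit(None)
    calls = clf.predict(frame["mean_gp_reported"].to_numpy(float))
    out = frame[["cell_id", "mean_gp_reported"]].copy()
    if "phenotype" in frame.columns:
        out["phenotype"] = frame["phenotype"]
    out["call"] = calls
    return out
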