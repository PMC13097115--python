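"""Orthogonalized PLS-DA for two-class feature selection.

Orthogonal signal correction removes ``n_ortho`` components of X-variation
uncorrelated with the class vector; a single PLS component is then fit on the
filtered matrix.  The model is used calibration-only: R2cal and the LV1
feature ranking are the deliverables, with leave-one-out classification
error reported as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateLabelError, DomainError, RankError


@dataclass
class OplsdaModel:
    classes: tuple                       # (negative class, positive class)
    predictive_weights: np.ndarray       # w, unit norm
    predictive_loadings: np.ndarray      # p
    predictive_scores: np.ndarray        # t = X_filtered w
    y_loading: float                     # regression of y on t
    orthogonal_components: list = field(default_factory=list)  # (w_o, p_o, t_o)
    n_ortho: int = 0
    r2cal: float = np.nan
    loocv_error: float = np.nan
    feature_names: list = field(default_factory=list)
    feature_scores_lv1: pd.Series | None = None
    x_mean: np.ndarray | None = None
    x_sd: np.ndarray | None = None
    y_mean: float = 0.0

    def top_features(self, n: int = 10) -> pd.Series:
        """The n features with largest |LV1 contribution|, signed values kept."""
        s = self.feature_scores_lv1
        return s.reindex(s.abs().sort_values(ascending=False).index).head(n)


def _encode_labels(labels) -> tuple[np.ndarray, tuple]:
    labels = np.asarray(labels)
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) != 2:
        raise DegenerateLabelError(f"need exactly 2 classes, got {classes}")
    y = np.where(labels == classes[1], 1.0, -1.0)
    if min((y == 1).sum(), (y == -1).sum()) < 2:
        raise DegenerateLabelError("each class needs >= 2 subjects")
    return y, tuple(classes)


def _zscore(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd_safe, mu, sd_safe


def oplsda_fit(features, labels, n_ortho: int = 1) -> OplsdaModel:
    """Fit the two-class model; features are z-scored internally per analyte."""
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"x{i}" for i in range(X.shape[1])]
    if n_ortho < 0:
        raise DomainError("n_ortho must be >= 0")
    y, classes = _encode_labels(labels)

    Xz, mu, sd = _zscore(X)
    y_mean = float(y.mean())
    yc = y - y_mean
    if n_ortho >= np.linalg.matrix_rank(Xz):
        raise RankError(f"n_ortho={n_ortho} >= rank(X)={np.linalg.matrix_rank(Xz)}")

    Xf = Xz.copy()
    ortho = []
    for _ in range(n_ortho):
        w = Xf.T @ yc
        w /= np.linalg.norm(w)
        t = Xf @ w
        p = Xf.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            raise RankError("no orthogonal variation left to remove")
        w_o /= norm
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        ortho.append((w_o, p_o, t_o))

    w = Xf.T @ yc
    w /= np.linalg.norm(w)
    t = Xf @ w
    p = Xf.T @ t / (t @ t)
    c = float(yc @ t / (t @ t))
    yhat = t * c
    ss_tot = float(yc @ yc)
    r2cal = 1.0 - float((yc - yhat) @ (yc - yhat)) / ss_tot

    return OplsdaModel(
        classes=classes,
        predictive_weights=w,
        predictive_loadings=p,
        predictive_scores=t,
        y_loading=c,
        orthogonal_components=ortho,
        n_ortho=n_ortho,
        r2cal=r2cal,
        feature_names=names,
        feature_scores_lv1=pd.Series(p, index=names, name="lv1_loading"),
        x_mean=mu,
        x_sd=sd,
        y_mean=y_mean,
    )


def predict_scores(model: OplsdaModel, features) -> np.ndarray:
    """Continuous class predictions for new subjects (training scaling applied)."""
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    Xz = (X - model.x_mean) / model.x_sd
    for w_o, p_o, _ in model.orthogonal_components:
        t_o = Xz @ w_o
        Xz = Xz - np.outer(t_o, p_o)
    t = Xz @ model.predictive_weights
    return t * model.y_loading + model.y_mean


def loocv_classification_error(features, labels, n_ortho: int = 1) -> float:
    """Leave-one-out error: refit (re-z-scoring inside the fold) per held-out
    subject and classify by the sign of the prediction against the +-1 coding
    midpoint.  Folds that lose a class entirely are counted as misclassified.
    """
    if isinstance(features, pd.DataFrame):
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    y, classes = _encode_labels(labels)
    n = X.shape[0]
    errors = 0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        y_train = y[keep]
        if len(np.unique(y_train)) < 2:
            errors += 1  # degenerate fold: counted against the model
            continue
        train_labels = np.where(y_train > 0, classes[1], classes[0])
        model = oplsda_fit(X[keep], train_labels, n_ortho=n_ortho)
        pred = predict_scores(model, X[i:i + 1])[0]
        predicted_class = 1.0 if pred > 0 else -1.0
        if predicted_class != y[i]:
            errors += 1
    return errors / n
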