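"""Cell-state classification: LDA projection + unsupervised Gaussian mixture.

The classifier mirrors how cell states separate in feature space: each
state's 26-feature distribution is close to multivariate Gaussian, so a
supervised linear discriminant projection into d = min(3, K-1)
dimensions concentrates the between-state structure, and a K-component
Gaussian mixture fitted *without labels* in that subspace carves it into
states.  Mixture components are matched to states afterwards by optimal
one-to-one assignment on the training labels, which turns mixture
posteriors into per-state probabilities.

Both estimators follow the scikit-learn protocol (``fit``,
``predict_proba``, ``get_params``) and accept either DataFrames carrying
the canonical feature columns or plain arrays.

A deliberately weak baseline, :class:`GaussianBaselineClassifier`, fits
one Gaussian per state on a raw 1-3 feature subset (supervised, equal
priors) — the classical "thickness/area/volume gating" approach that the
full profile is measured against.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.mixture import GaussianMixture
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LDAGMMClassifier",
    "GaussianBaselineClassifier",
    "balance_bootstrap",
    "macro_accuracy",
]


def _as_matrix(X, feature_names: Sequence[str] | None) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [f for f in feature_names if f not in X.columns]
            if missing:
                raise ValueError(f"missing feature columns: {missing}")
            X = X[list(feature_names)]
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    return X


def balance_bootstrap(
    table: pd.DataFrame,
    labels: Sequence,
    n_per_class: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Bootstrap-sample ``n_per_class`` rows per class, with replacement.

    Training on clusters of comparable size keeps the mixture weights
    from encoding treatment group sizes instead of state structure.
    """
    rng = np.random.default_rng(rng)
    if isinstance(labels, pd.Series):
        labels = labels.to_numpy() if labels.dtype != "category" else pd.Categorical(labels)
    if isinstance(labels, pd.Categorical):
        classes = np.asarray(labels.categories)
        labels = np.asarray(labels)
    else:
        labels = np.asarray(labels)
        classes = np.unique(labels)
    if len(labels) != len(table):
        raise ValueError("labels and table length mismatch")
    parts, out_labels = [], []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if len(idx) == 0:
            raise ValueError(f"class {cls!r} is empty")
        pick = rng.choice(idx, size=n_per_class, replace=True)
        parts.append(table.iloc[pick])
        out_labels.append(np.full(n_per_class, cls))
    boot = pd.concat(parts, ignore_index=True)
    return boot, np.concatenate(out_labels)


def macro_accuracy(y_true: Sequence, y_pred: Sequence) -> tuple[dict, float]:
    """Per-class accuracies and their unweighted mean.

    Classes absent from the truth are excluded.  The macro average is
    the natural headline when training is class-balanced.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    per_class: dict = {}
    for cls in np.unique(y_true):
        m = y_true == cls
        per_class[cls] = float(np.mean(y_pred[m] == cls))
    return per_class, float(np.mean(list(per_class.values())))


def pooled_accuracy(y_true: Sequence, y_pred: Sequence) -> float:
    return float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))


class LDAGMMClassifier(BaseEstimator, ClassifierMixin):
    """Standardize -> LDA(d = min(3, K-1)) -> unsupervised GMM -> state map.

    Parameters
    ----------
    n_dims : int or "auto"
        Dimension of the discriminant subspace; "auto" gives
        ``min(3, n_classes - 1)``.
    n_init : int
        EM restarts for the mixture fit.
    tol : float
        EM convergence tolerance.
    random_state : int or None
        Seeds the mixture restarts; fitting is deterministic given it.
    feature_names : sequence of str or None
        Columns to use when X is a DataFrame; inferred from the
        DataFrame at fit time when None.
    """

    def __init__(
        self,
        n_dims: int | str = "auto",
        n_init: int = 10,
        tol: float = 1e-6,
        random_state: int | None = 0,
        feature_names: Sequence[str] | None = None,
    ) -> None:
        self.n_dims = n_dims
        self.n_init = n_init
        self.tol = tol
        self.random_state = random_state
        self.feature_names = feature_names

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y):
        feature_names = self.feature_names
        if feature_names is None and isinstance(X, pd.DataFrame):
            feature_names = list(X.columns)
        Xm = _as_matrix(X, feature_names)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        K = len(self.classes_)
        if K < 2:
            raise ValueError("need at least 2 classes")
        d = min(3, K - 1) if self.n_dims == "auto" else int(self.n_dims)
        if not 1 <= d <= K - 1:
            raise ValueError(f"n_dims must be in [1, {K - 1}]")
        for cls in self.classes_:
            if np.sum(y == cls) < d + 2:
                raise ValueError(f"class {cls!r} has fewer than {d + 2} cells")

        self.feature_names_ = list(feature_names) if feature_names is not None else None
        self.n_dims_ = d
        self.scaler_ = StandardScaler().fit(Xm)
        Xs = self.scaler_.transform(Xm)
        try:
            self.lda_ = LinearDiscriminantAnalysis(n_components=d).fit(Xs, y)
        except np.linalg.LinAlgError:
            # singular within-class scatter: shrinkage-regularized eigen solver
            import warnings

            warnings.warn("singular within-class scatter; using shrinkage LDA")
            self.lda_ = LinearDiscriminantAnalysis(
                n_components=d, solver="eigen", shrinkage=1e-6
            ).fit(Xs, y)
        # affine form of the LDA map (solver-agnostic); used for prediction
        # and serialization so that a saved/loaded classifier is bit-identical
        p = Xs.shape[1]
        self._proj_b = self.lda_.transform(np.zeros((1, p)))[0]
        self._proj_W = self.lda_.transform(np.eye(p)) - self._proj_b
        Z = self._project_scaled(Xs)

        self.gmm_ = GaussianMixture(
            n_components=K,
            covariance_type="full",
            n_init=self.n_init,
            tol=self.tol,
            random_state=self.random_state,
        ).fit(Z)  # labels unseen here

        # optimal one-to-one component <-> class matching on the training data
        resp = self.gmm_.predict_proba(Z)
        agreement = np.zeros((K, K))
        for ci, cls in enumerate(self.classes_):
            agreement[:, ci] = resp[y == cls].sum(axis=0)
        comp_idx, cls_idx = linear_sum_assignment(-agreement)
        mapping = np.empty(K, dtype=int)
        mapping[comp_idx] = cls_idx
        self.component_to_class_ = mapping
        return self

    # -- prediction -------------------------------------------------------
    def _project_scaled(self, Xs: np.ndarray) -> np.ndarray:
        return Xs @ self._proj_W + self._proj_b

    def _project(self, X) -> np.ndarray:
        Xm = _as_matrix(X, self.feature_names_)
        return self._project_scaled((Xm - self.scaler_.mean_) / self.scaler_.scale_)

    def predict_proba(self, X) -> np.ndarray:
        """Per-state posterior probabilities, columns ordered as ``classes_``."""
        check_is_fitted(self, "gmm_")
        resp = self.gmm_.predict_proba(self._project(X))
        K = len(self.classes_)
        out = np.zeros_like(resp)
        for comp in range(K):
            out[:, self.component_to_class_[comp]] += resp[:, comp]
        return out

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def transform(self, X) -> np.ndarray:
        """Coordinates in the discriminant subspace (for scatter plots)."""
        check_is_fitted(self, "lda_")
        return self._project(X)

    # -- persistence ------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize the fitted classifier to a single JSON document."""
        check_is_fitted(self, "gmm_")
        d = self.n_dims_
        W, b = self._proj_W, self._proj_b
        doc = {
            "format": "holocyte-lda-gmm-v1",
            "feature_names": self.feature_names_,
            "classes": [str(c) for c in self.classes_],
            "n_dims": d,
            "random_state": self.random_state,
            "scaler_mean": self.scaler_.mean_.tolist(),
            "scaler_scale": self.scaler_.scale_.tolist(),
            "projection_W": W.tolist(),
            "projection_b": b.tolist(),
            "gmm_weights": self.gmm_.weights_.tolist(),
            "gmm_means": self.gmm_.means_.tolist(),
            "gmm_covariances": self.gmm_.covariances_.tolist(),
            "component_to_class": self.component_to_class_.tolist(),
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "_FrozenLDAGMM":
        """Load a serialized classifier (prediction only)."""
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(source).read_text()
        doc = json.loads(text)
        if doc.get("format") != "holocyte-lda-gmm-v1":
            raise ValueError("not a holocyte classifier document")
        return _FrozenLDAGMM(doc)


class _FrozenLDAGMM:
    """Prediction-side view of a serialized :class:`LDAGMMClassifier`."""

    def __init__(self, doc: dict) -> None:
        self.doc = doc
        self.feature_names_ = doc["feature_names"]
        self.classes_ = np.asarray(doc["classes"])
        self._mean = np.asarray(doc["scaler_mean"])
        self._scale = np.asarray(doc["scaler_scale"])
        self._W = np.asarray(doc["projection_W"])
        self._b = np.asarray(doc["projection_b"])
        self.component_to_class_ = np.asarray(doc["component_to_class"], dtype=int)
        K = len(self.classes_)
        gmm = GaussianMixture(n_components=K, covariance_type="full")
        gmm.weights_ = np.asarray(doc["gmm_weights"])
        gmm.means_ = np.asarray(doc["gmm_means"])
        gmm.covariances_ = np.asarray(doc["gmm_covariances"])
        from sklearn.mixture._gaussian_mixture import _compute_precision_cholesky

        gmm.precisions_cholesky_ = _compute_precision_cholesky(gmm.covariances_, "full")
        self.gmm_ = gmm

    def _project(self, X) -> np.ndarray:
        Xm = _as_matrix(X, self.feature_names_)
        return ((Xm - self._mean) / self._scale) @ self._W + self._b

    def predict_proba(self, X) -> np.ndarray:
        resp = self.gmm_.predict_proba(self._project(X))
        out = np.zeros_like(resp)
        for comp in range(len(self.classes_)):
            out[:, self.component_to_class_[comp]] += resp[:, comp]
        return out

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


class GaussianBaselineClassifier(BaseEstimator, ClassifierMixin):
    """Per-class Gaussian on a raw 1-3 feature subset, equal priors.

    The supervised counterpart of classical gating on thickness, area,
    or volume: each condition gets its own Gaussian fitted with labels,
    and Bayes' rule with equal priors yields state posteriors.
    """

    def __init__(
        self,
        feature_subset: Sequence[str] | Sequence[int] | None = None,
        var_floor: float = 1e-12,
    ) -> None:
        self.feature_subset = feature_subset
        self.var_floor = var_floor

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame) and self.feature_subset is not None:
            Xm = _as_matrix(X, list(self.feature_subset))
        elif self.feature_subset is not None:
            Xm = np.asarray(X, float)[:, list(self.feature_subset)]
        else:
            Xm = _as_matrix(X, None)
        if Xm.shape[1] < 1:
            raise ValueError("feature subset must be non-empty")
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.means_, self.covariances_ = [], []
        for cls in self.classes_:
            Xc = Xm[y == cls]
            mu = Xc.mean(axis=0)
            cov = np.cov(Xc, rowvar=False, ddof=0).reshape(Xm.shape[1], Xm.shape[1])
            diag = np.diag(cov).copy()
            if np.any(diag <= self.var_floor):
                import warnings

                warnings.warn(f"zero-variance feature in class {cls!r}; variance floored")
                np.fill_diagonal(cov, np.maximum(diag, self.var_floor))
            self.means_.append(mu)
            self.covariances_.append(cov)
        self.means_ = np.asarray(self.means_)
        self.covariances_ = np.asarray(self.covariances_)
        return self

    def _select(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame) and self.feature_subset is not None:
            return _as_matrix(X, list(self.feature_subset))
        if self.feature_subset is not None and not isinstance(X, pd.DataFrame):
            return np.asarray(X, float)[:, list(self.feature_subset)]
        return _as_matrix(X, None)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "means_")
        from scipy.stats import multivariate_normal

        Xm = self._select(X)
        logp = np.column_stack(
            [
                multivariate_normal.logpdf(
                    Xm, mean=mu, cov=cov, allow_singular=True
                )
                for mu, cov in zip(self.means_, self.covariances_)
            ]
        )
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
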