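"""Comparison baselines: classical SVM without trimming, and PCA-assisted
SVM whose number of principal components is pre-trained by an inner
leave-one-out AUC sweep.

The classical baseline deliberately goes through the public
:class:`sklearn.svm.SVC` interface rather than the package's fast libsvm
path, so that its agreement with FloWPS restricted to the no-trimming
corner (m=0, k=N-1) is a genuine cross-check of two code routes.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from . import _svm
from .io import RESPONDER, ClassifierConfig, ExpressionDataset
from .metrics import MetricsReport, evaluate_scores, mann_whitney_auc


def _svc_score(model: SVC, x, mode: str) -> float:
    x = np.asarray(x, dtype=float)[None, :]
    if mode == "label":
        return float(model.predict(x)[0])
    return float(model.decision_function(x)[0])


def classical_svm_loo(
    ds: ExpressionDataset, config: ClassifierConfig
) -> tuple[np.ndarray, MetricsReport]:
    """Leave-one-out evaluation of a plain SVM on all features and samples.

    Equivalent by construction to FloWPS with the single-cell grid
    (m=0, k=N-1).  Returns the per-sample score vector and its metrics.
    """
    if ds.n_samples < 4:
        raise ValueError("leave-one-out evaluation needs at least 4 samples")
    if min(ds.class_counts()) < 2:
        raise ValueError("each class needs at least 2 samples")
    scores = np.empty(ds.n_samples)
    for i in range(ds.n_samples):
        keep = np.arange(ds.n_samples) != i
        model = SVC(kernel=config.kernel, C=config.C).fit(
            ds.values[keep], ds.labels[keep]
        )
        scores[i] = _svc_score(model, ds.values[i], config.prediction_mode)
    return scores, evaluate_scores(scores, ds.labels)


class PCASVMClassifier(ClassifierMixin, BaseEstimator):
    """SVM on a pre-trained number of principal components.

    ``fit`` centers the data on the training means, extracts principal
    directions from the training covariance (no variance scaling), and
    selects the PC count from ``n_pc_candidates`` that maximizes the inner
    leave-one-out AUC of SVMs on the truncated scores (smallest count on
    ties).  Prediction projects new points with the training loadings.

    Attributes (after fit): ``n_pc_`` (chosen count), ``inner_auc_``
    (candidate -> inner AUC), ``mean_``, ``components_``.
    """

    def __init__(self, kernel="linear", C=1.0, prediction_mode="label",
                 n_pc_candidates=None):
        self.kernel = kernel
        self.C = C
        self.prediction_mode = prediction_mode
        self.n_pc_candidates = n_pc_candidates

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        n, s = X.shape
        if set(np.unique(y)) <= {0, 1}:
            y = y * 100
        candidates = self.n_pc_candidates
        if candidates is None:
            candidates = list(range(1, min(10, n - 2, s) + 1))
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        # principal directions of the training covariance
        _, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank = int((sv > sv[0] * 1e-10).sum()) if sv.size else 0
        self.components_ = Vt
        scores_full = Xc @ Vt.T
        self.inner_auc_ = {}
        pos = y == RESPONDER
        for c in candidates:
            if c > rank:
                warnings.warn(f"skipping {c} PCs: exceeds training rank {rank}")
                continue
            Z = np.ascontiguousarray(scores_full[:, :c])
            inner = np.empty(n)
            for j in range(n):
                keep = np.arange(n) != j
                inner[j] = _svm.fit_predict_one(
                    Z[keep], y[keep], Z[j],
                    kernel=self.kernel, C=self.C, mode=self.prediction_mode,
                )
            self.inner_auc_[c] = mann_whitney_auc(inner, pos)
        if not self.inner_auc_:
            raise ValueError("no usable PC-count candidate (all exceed rank)")
        best = max(self.inner_auc_.items(), key=lambda kv: (kv[1], -kv[0]))
        self.n_pc_ = best[0]
        Z = np.ascontiguousarray(scores_full[:, : self.n_pc_])
        self._svc = SVC(kernel=self.kernel, C=self.C).fit(Z, y)
        self._train_scores = Z
        self.classes_ = np.array([0, RESPONDER])
        self.n_features_in_ = s
        return self

    def transform(self, X):
        """Project onto the chosen training principal components."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return (X - self.mean_) @ self.components_[: self.n_pc_].T

    def decision_function(self, X):
        Z = self.transform(X)
        if self.prediction_mode == "label":
            return self._svc.predict(Z).astype(float)
        return self._svc.decision_function(Z)

    def predict(self, X):
        scores = self.decision_function(X)
        cut = 50.0 if self.prediction_mode == "label" else 0.0
        return np.where(scores > cut, RESPONDER, 0)


def pca_svm_loo(
    ds: ExpressionDataset,
    config: ClassifierConfig,
    n_pc_candidates=None,
) -> tuple[np.ndarray, MetricsReport, list[int]]:
    """Leave-one-out evaluation of the PCA-assisted SVM.

    The PC count is re-selected inside every outer fold (loadings and the
    inner AUC sweep both use only that fold's N-1 training samples), so no
    information from the held-out sample leaks into the selection.  Returns
    the score vector, its metrics, and the chosen PC count per fold.
    """
    if ds.n_samples < 4:
        raise ValueError("leave-one-out evaluation needs at least 4 samples")
    if min(ds.class_counts()) < 2:
        raise ValueError("each class needs at least 2 samples")
    scores = np.empty(ds.n_samples)
    chosen = []
    for i in range(ds.n_samples):
        keep = np.arange(ds.n_samples) != i
        est = PCASVMClassifier(
            kernel=config.kernel, C=config.C,
            prediction_mode=config.prediction_mode,
            n_pc_candidates=n_pc_candidates,
        ).fit(ds.values[keep], ds.labels[keep])
        scores[i] = est.decision_function(ds.values[i])[0]
        chosen.append(est.n_pc_)
    return scores, evaluate_scores(scores, ds.labels), chosen
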