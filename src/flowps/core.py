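"""The FloWPS classifier.

For every validation point the method (1) builds, on the training samples
alone, the topogram AUC(m, k) by internal leave-one-out over the (m, k)
trimming lattice, (2) keeps the prediction-accountable set S of cells whose
AUC reaches p * max(AUC), and (3) averages the per-cell SVM predictions of
the validation point over S:  P_F = mean_S P(m, k).  The cell (m=0,
k=n_training) applies no trimming at all, so FloWPS restricted to that
corner reproduces a classical SVM exactly.

Predictions are hard class votes encoded 0/100 by default
(``prediction_mode="label"``), making P_F an ensemble vote fraction on a
0-100 scale; ``prediction_mode="decision"`` averages signed SVM margins
instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _svm
from .io import RESPONDER, ClassifierConfig, ExpressionDataset
from .metrics import MetricsReport, evaluate_scores
from .trimming import TrimGrid, TrimmedTrainingSet, default_grid, max_valid_m

__all__ = [
    "AUCTopogram", "AccountableSet", "PredictionRecord", "FloWPSClassifier",
    "svm_cell_predict", "auc_topogram", "accountable_set",
    "flowps_predict_one", "loo_evaluate",
]

_THETA_TOL = 1e-12  # float guard so the argmax cell always clears p * max


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class AUCTopogram:
    """Internally cross-validated AUC over the (m, k) lattice of one
    training set.  ``auc`` is defined wherever ``valid``; a cell is invalid
    when some inner point has no surviving feature at that m."""

    grid: TrimGrid
    auc: np.ndarray
    valid: np.ndarray

    def max_auc(self) -> float:
        return float(self.auc[self.valid].max())


@dataclass(frozen=True)
class AccountableSet:
    """The (m, k) cells whose topogram AUC reaches p * max(AUC)."""

    cells: tuple
    threshold_theta: float
    p: float

    def __post_init__(self):
        if not self.cells:
            raise ValueError("accountable set cannot be empty")


@dataclass(frozen=True)
class PredictionRecord:
    """One sample's FloWPS output: the averaged prediction P_F and the
    number of accountable cells actually used for it."""

    sample_id: str
    true_label: int
    p_f: float
    n_cells: int
    classifier: str
    config: str


# ---------------------------------------------------------------------------
# cell-level prediction


def _single_class_value(label: float, mode: str) -> float:
    if mode == "label":
        return float(label)
    return 1.0 if label == RESPONDER else -1.0


def _cell_value(Xtr, ytr, x_masked, mask, sel, config, memo, tags, point_tag):
    """SVM prediction of one point for one trimmed cell, with memoization.

    ``sel`` indexes rows of ``Xtr`` (already feature-masked).  Rows are
    sorted before fitting so the training order is the natural sample order
    regardless of the distance ranking (this is what makes the no-trimming
    corner bit-identical to a plain SVM on all data).
    """
    ysel = ytr[sel]
    if (ysel == ysel[0]).all():
        return _single_class_value(ysel[0], config.prediction_mode)
    key = None
    if memo is not None:
        key = (point_tag, mask.tobytes(), np.sort(tags[sel]).tobytes())
        hit = memo.get(key)
        if hit is not None:
            return hit
    rows = np.sort(sel)
    val = _svm.fit_predict_one(
        Xtr[rows], ytr[rows], x_masked,
        kernel=config.kernel, C=config.C, mode=config.prediction_mode,
    )
    if key is not None:
        memo[key] = val
    return val


def svm_cell_predict(
    trimmed: TrimmedTrainingSet,
    ds: ExpressionDataset,
    validation_index: int,
    config: ClassifierConfig,
) -> float:
    """Fit an SVM on the trimmed training set and score the validation sample.

    A single-class neighbor set short-circuits to that class without
    fitting.  Raises on an invalid trim (no surviving feature).
    """
    if not trimmed.valid:
        raise ValueError("cannot predict from an invalid trimmed set")
    T = np.delete(ds.values, validation_index, axis=0)
    y = np.delete(ds.labels, validation_index)
    x = ds.values[validation_index]
    mask = trimmed.feature_mask
    return _cell_value(
        T[:, mask], y, x[mask], mask, np.asarray(trimmed.neighbor_indices),
        config, None, None, None,
    )


# ---------------------------------------------------------------------------
# topogram


def auc_topogram(
    training_ds: ExpressionDataset,
    grid: TrimGrid,
    config: ClassifierConfig,
    *,
    memo: dict | None = None,
    sample_tags: np.ndarray | None = None,
) -> AUCTopogram:
    """AUC(m, k) by inner leave-one-out over the training samples.

    Each training sample is held out in turn, trimmed against the remaining
    ones at every (m, k) cell, and scored by the cell's SVM; the cell's AUC
    is the Mann-Whitney AUC of those held-out predictions against the true
    labels.  An m row is invalid when any inner point loses all features at
    that m (a conservative rule keeping cell AUCs comparable); k never
    invalidates because the selection saturates at the available samples.

    ``memo``/``sample_tags`` allow an outer leave-one-out harness to share
    identical cell fits across folds; they do not change results.
    """
    X = training_ds.values
    y = training_ds.labels
    Nt = X.shape[0]
    pos = y == RESPONDER
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("training data must contain both classes")
    if sample_tags is None:
        sample_tags = np.arange(Nt)
    m_vals = np.asarray(grid.m_values)
    k_vals = np.asarray(grid.k_values)

    # per-inner-point flank caps: mvm[j, f] = largest m feature f survives
    mvm_rows = np.empty((Nt, X.shape[1]), dtype=np.int64)
    for j in range(Nt):
        mvm_rows[j] = np.minimum((X > X[j]).sum(axis=0), (X < X[j]).sum(axis=0))
    caps = mvm_rows.max(axis=1)
    row_ok = m_vals <= caps.min()
    if not row_ok.any():
        raise ValueError("every (m, k) cell is invalid for this training set")
    valid_rows = np.flatnonzero(row_ok)

    preds = np.full((len(m_vals), len(k_vals), Nt), np.nan)
    all_idx = np.arange(Nt)
    for j in range(Nt):
        keep = all_idx != j
        Xtr = X[keep]
        ytr = y[keep]
        tags = sample_tags[keep]
        x = X[j]
        point_tag = sample_tags[j]
        # masks are step functions of m: group m rows sharing a mask
        groups: dict[bytes, list] = {}
        for ridx in valid_rows:
            mask = mvm_rows[j] >= m_vals[ridx]
            groups.setdefault(mask.tobytes(), [mask, []])[1].append(ridx)
        for mask, rows in groups.values():
            rows = np.asarray(rows)
            sub = Xtr[:, mask]
            xm = x[mask]
            order = np.argsort(((sub - xm) ** 2).sum(axis=1), kind="stable")
            for ki, k in enumerate(k_vals):
                sel = order[: min(k, Nt - 1)]
                preds[rows, ki, j] = _cell_value(
                    sub, ytr, xm, mask, sel, config, memo, tags, point_tag
                )

    auc = np.full(grid.shape, np.nan)
    flat = preds[valid_rows].reshape(-1, Nt)
    ranks = rankdata(flat, axis=1)
    auc_flat = (ranks[:, pos].sum(axis=1) - n1 * (n1 + 1) / 2) / (n1 * n0)
    auc[valid_rows] = auc_flat.reshape(len(valid_rows), len(k_vals))
    valid = np.zeros(grid.shape, dtype=bool)
    valid[valid_rows] = True
    return AUCTopogram(grid=grid, auc=auc, valid=valid)


def accountable_set(topogram: AUCTopogram, p: float) -> AccountableSet:
    """All valid cells with AUC >= p * max(valid AUC); never empty."""
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    theta = p * topogram.max_auc()
    keep = topogram.valid & (topogram.auc >= theta - _THETA_TOL)
    cells = tuple(
        (topogram.grid.m_values[i], topogram.grid.k_values[j])
        for i, j in np.argwhere(keep)
    )
    return AccountableSet(cells=cells, threshold_theta=theta, p=p)


# ---------------------------------------------------------------------------
# point prediction over an accountable set


def _predict_point(x, Xtr, ytr, cells, config, *, memo=None, tags=None, point_tag=None):
    """Average the per-cell SVM predictions of ``x`` over the accountable
    cells; cells whose trim is invalid for ``x`` are skipped.  Returns
    (P_F, n_cells_used).  If no cell is usable, falls back to the
    no-trimming corner (m=0, all samples) with n_cells reported as 0.
    """
    if tags is None:
        tags = np.arange(len(Xtr))
    mvm = max_valid_m(x, Xtr)
    groups: dict[bytes, list] = {}
    for m, k in cells:
        mask = mvm >= m
        if not mask.any():
            continue
        groups.setdefault(mask.tobytes(), [mask, []])[1].append(k)
    values = []
    for mask, ks in groups.values():
        sub = Xtr[:, mask]
        xm = x[mask]
        order = np.argsort(((sub - xm) ** 2).sum(axis=1), kind="stable")
        for k in ks:
            sel = order[: min(k, len(Xtr))]
            values.append(
                _cell_value(sub, ytr, xm, mask, sel, config, memo, tags, point_tag)
            )
    if not values:
        mask = np.ones(Xtr.shape[1], dtype=bool)
        sel = np.arange(len(Xtr))
        fallback = _cell_value(Xtr, ytr, x, mask, sel, config, memo, tags, point_tag)
        return fallback, 0
    return float(np.mean(values)), len(values)


# ---------------------------------------------------------------------------
# estimator


class FloWPSClassifier(ClassifierMixin, BaseEstimator):
    """SVM with per-validation-point data trimming (FloWPS).

    Fitting stores the training data and precomputes the AUC(m, k) topogram
    (inner leave-one-out) together with the prediction-accountable set S at
    confidence ``p``.  Each predicted point is then trimmed individually:
    for every cell of S, features failing the m-condition are dropped, the
    k nearest training samples in the surviving space are kept, and the
    resulting SVM votes; ``decision_function`` returns the averaged vote
    P_F on a 0-100 scale (or a mean signed margin in decision mode) and
    ``predict`` thresholds it at its midpoint.

    Parameters mirror :class:`flowps.io.ClassifierConfig`; ``grid``
    overrides the default (m, k) lattice, e.g. ``TrimGrid((0,), (n,))`` for
    the classical-SVM corner.

    Attributes (after fit): ``topogram_``, ``accountable_set_``,
    ``classes_``, ``n_features_in_``.
    """

    def __init__(self, kernel="linear", C=1.0, p=0.90, k_min=20, m_max="auto",
                 prediction_mode="label", seed=0, grid=None):
        self.kernel = kernel
        self.C = C
        self.p = p
        self.k_min = k_min
        self.m_max = m_max
        self.prediction_mode = prediction_mode
        self.seed = seed
        self.grid = grid

    def _config(self) -> ClassifierConfig:
        return ClassifierConfig(
            kernel=self.kernel, C=self.C, p=self.p, k_min=self.k_min,
            m_max=self.m_max, seed=self.seed, prediction_mode=self.prediction_mode,
        )

    def fit(self, X, y, *, _memo=None, _sample_tags=None, _m_cap_hint=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        if set(np.unique(y)) <= {0, 1}:
            y = y * 100
        if not set(np.unique(y)) <= {0, RESPONDER}:
            raise ValueError("labels must be binary {0,100} (or {0,1})")
        config = self._config()
        grid = self.grid
        if grid is None:
            grid = default_grid(
                X.shape[0], k_min=config.k_min, m_max=config.m_max,
                m_cap_hint=_m_cap_hint,
            )
        train = ExpressionDataset(
            X,
            tuple(f"s{i}" for i in range(X.shape[0])),
            tuple(f"g{j}" for j in range(X.shape[1])),
            y.astype(np.int64),
        )
        self._memo = {} if _memo is None else _memo
        self._tags = np.arange(X.shape[0]) if _sample_tags is None else _sample_tags
        self.topogram_ = auc_topogram(
            train, grid, config, memo=self._memo, sample_tags=self._tags
        )
        self.accountable_set_ = accountable_set(self.topogram_, config.p)
        self.X_ = X
        self.y_ = y.astype(np.float64)
        self.classes_ = np.array([0, RESPONDER])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X, *, _point_tags=None):
        """P_F for each row of X (0-100 vote scale in label mode)."""
        if not hasattr(self, "topogram_"):
            raise AttributeError("this FloWPSClassifier instance is not fitted yet")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        config = self._config()
        out = np.empty(X.shape[0])
        self.n_cells_used_ = np.empty(X.shape[0], dtype=int)
        for i, x in enumerate(X):
            tag = None if _point_tags is None else _point_tags[i]
            out[i], self.n_cells_used_[i] = _predict_point(
                x, self.X_, self.y_, self.accountable_set_.cells, config,
                memo=self._memo, tags=self._tags, point_tag=tag,
            )
        return out

    def predict(self, X):
        scores = self.decision_function(X)
        cut = 50.0 if self.prediction_mode == "label" else 0.0
        return np.where(scores > cut, RESPONDER, 0)


# ---------------------------------------------------------------------------
# leave-one-out harness


def flowps_predict_one(
    ds: ExpressionDataset,
    validation_index: int,
    config: ClassifierConfig,
    *,
    grid: TrimGrid | None = None,
    memo: dict | None = None,
) -> PredictionRecord:
    """FloWPS prediction for one held-out sample of a dataset.

    The topogram and accountable set are built on the other N-1 samples;
    the m grid's "auto" cap adapts to the held-out point (the largest m at
    which it keeps any feature).  Deterministic given the configuration.
    """
    i = validation_index
    x = ds.values[i]
    keep = np.arange(ds.n_samples) != i
    Xtr = ds.values[keep]
    ytr = ds.labels[keep].astype(np.float64)
    counts = (ytr == 0).sum(), (ytr == RESPONDER).sum()
    if 0 in counts:
        raise ValueError(
            f"removing sample {ds.sample_ids[i]!r} leaves a single-class training set"
        )
    if grid is None:
        cap_hint = int(max_valid_m(x, Xtr).max())
        grid = default_grid(len(Xtr), k_min=config.k_min, m_max=config.m_max,
                            m_cap_hint=cap_hint)
    train = ds.subset_samples(np.flatnonzero(keep))
    tags = np.flatnonzero(keep)
    topo = auc_topogram(train, grid, config, memo=memo, sample_tags=tags)
    cells = accountable_set(topo, config.p)
    p_f, n_used = _predict_point(
        x, Xtr, ytr, cells.cells, config, memo=memo, tags=tags, point_tag=i
    )
    return PredictionRecord(
        sample_id=ds.sample_ids[i],
        true_label=int(ds.labels[i]),
        p_f=p_f,
        n_cells=n_used,
        classifier="flowps",
        config=config.digest(),
    )


def loo_evaluate(
    ds: ExpressionDataset,
    config: ClassifierConfig,
    *,
    grid: TrimGrid | None = None,
) -> tuple[list[PredictionRecord], MetricsReport]:
    """Leave-one-out evaluation of FloWPS over a whole dataset.

    Returns the per-sample prediction records and the metrics report of the
    P_F vector against the true labels (threshold tau minimizing FP + FN).
    Identical SVM subproblems are shared across folds through a memo; the
    per-sample work is order-independent.
    """
    if ds.n_samples < 4:
        raise ValueError("leave-one-out evaluation needs at least 4 samples")
    n0, n1 = ds.class_counts()
    if min(n0, n1) < 2:
        raise ValueError("each class needs at least 2 samples")
    memo: dict = {}
    records = [
        flowps_predict_one(ds, i, config, grid=grid, memo=memo)
        for i in range(ds.n_samples)
    ]
    scores = np.array([r.p_f for r in records])
    report = evaluate_scores(scores, ds.labels)
    return records, report
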