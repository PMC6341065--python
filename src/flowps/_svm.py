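"""Thin, fast wrapper around libsvm for the many tiny fits of the (m, k) sweep.

The nested leave-one-out topogram needs O(10^5) SVM fits on matrices of a few
dozen rows; the per-call overhead of the public :class:`sklearn.svm.SVC`
wrapper dominates at that size.  This module calls scikit-learn's bundled
libsvm binding directly while reproducing ``SVC`` semantics exactly:

* labels are encoded as sorted class indices, as ``SVC`` does internally;
* ``gamma="scale"`` uses the same ``1 / (n_features * X.var())`` formula;
* binary decision values carry sklearn's sign convention (positive means the
  larger class), which is the negation of raw libsvm output.

If the private binding is unavailable the code falls back to ``SVC`` with
identical results.  tests/test_svm_backend.py asserts bit-for-bit agreement
of predictions (and decision values to 1e-12) against ``SVC`` on random
problems for both kernels across the C range used here.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by the whole suite
    from sklearn.svm import _libsvm as _lib

    _lib.set_verbosity_wrap(0)
    _HAVE_FAST = True
except ImportError:  # pragma: no cover
    _lib = None
    _HAVE_FAST = False

from sklearn.svm import SVC

KERNELS = ("linear", "poly")
#: accepted spellings for the polynomial kernel
_KERNEL_ALIASES = {"linear": "linear", "poly": "poly", "polynomial": "poly"}


def canonical_kernel(kernel: str) -> str:
    try:
        return _KERNEL_ALIASES[kernel]
    except KeyError:
        raise ValueError(
            f"unknown kernel {kernel!r}; expected one of {sorted(_KERNEL_ALIASES)}"
        ) from None


def _scale_gamma(X: np.ndarray) -> float:
    # mirrors sklearn's gamma="scale"
    var = X.var()
    return 1.0 / (X.shape[1] * var) if var != 0 else 1.0


def fit_predict(
    X: np.ndarray,
    y: np.ndarray,
    X_new: np.ndarray,
    *,
    kernel: str = "linear",
    C: float = 1.0,
    mode: str = "label",
) -> np.ndarray:
    """Fit a soft-margin SVC on (X, y) and score the rows of ``X_new``.

    Parameters
    ----------
    X, y
        Training matrix and binary labels (two distinct values, e.g. 0/100).
    X_new
        Points to score, shape (n_points, n_features).
    kernel
        "linear" or "poly" (libsvm defaults otherwise: degree 3, coef0 0,
        gamma "scale").
    C
        Soft-margin cost.
    mode
        "label" returns hard class labels on the scale of ``y``; "decision"
        returns the signed margin (positive = larger class).
    """
    kernel = canonical_kernel(kernel)
    if mode not in ("label", "decision"):
        raise ValueError(f"mode must be 'label' or 'decision', got {mode!r}")
    X = np.ascontiguousarray(X, dtype=np.float64)
    X_new = np.ascontiguousarray(X_new, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("fit_predict needs exactly two classes in y")

    if _HAVE_FAST:
        y_idx = np.ascontiguousarray(y == classes[1], dtype=np.float64)
        gamma = _scale_gamma(X) if kernel != "linear" else 0.1
        model = _lib.fit(
            X, y_idx, svm_type=0, kernel=kernel, C=float(C),
            degree=3, gamma=gamma, coef0=0.0,
        )
        if mode == "label":
            idx = _lib.predict(
                X_new, *model[:5], svm_type=0, kernel=kernel,
                degree=3, gamma=gamma, coef0=0.0,
            )
            return classes[idx.astype(np.intp)]
        df = _lib.decision_function(
            X_new, *model[:5], svm_type=0, kernel=kernel,
            degree=3, gamma=gamma, coef0=0.0,
        )
        return -df.ravel()  # sklearn's binary sign convention

    svc = SVC(kernel=kernel, C=float(C)).fit(X, y)
    if mode == "label":
        return svc.predict(X_new)
    return svc.decision_function(X_new)


def fit_predict_one(X, y, x, *, kernel="linear", C=1.0, mode="label") -> float:
    """Single-point convenience wrapper; returns a scalar."""
    return float(fit_predict(X, y, np.asarray(x)[None, :], kernel=kernel, C=C, mode=mode)[0])
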