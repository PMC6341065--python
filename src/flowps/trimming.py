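"""The floating window: per-validation-point feature filtering (m-condition)
and k-nearest-neighbor training-sample selection.

A feature survives the m-condition for a validation point when at least m
training projections lie strictly below AND at least m strictly above the
point's value on that feature's axis — the point must sit inside the
training cloud with m flanking observations on each side.  Training values
exactly equal to the validation value count as neither.  After masking,
only the k nearest training samples (Euclidean distance in the masked
space) are kept to build the local SVM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionDataset


@dataclass(frozen=True)
class TrimGrid:
    """The (m, k) lattice swept when building an AUC topogram."""

    m_values: tuple
    k_values: tuple

    def __post_init__(self):
        m = tuple(int(v) for v in self.m_values)
        k = tuple(int(v) for v in self.k_values)
        object.__setattr__(self, "m_values", m)
        object.__setattr__(self, "k_values", k)
        if not m or not k:
            raise ValueError("grid must be non-empty")
        if any(v < 0 for v in m) or list(m) != sorted(set(m)):
            raise ValueError("m_values must be ascending non-negative integers")
        if any(v < 1 for v in k) or list(k) != sorted(set(k)):
            raise ValueError("k_values must be ascending integers >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.m_values), len(self.k_values)

    def cells(self):
        for m in self.m_values:
            for k in self.k_values:
                yield m, k


@dataclass(frozen=True)
class TrimmedTrainingSet:
    """The surviving features and selected neighbors for one (validation
    point, m, k) combination.  ``neighbor_indices`` index the training
    matrix (validation sample excluded); ``valid`` is False iff no feature
    survived the m-condition."""

    m: int
    k: int
    feature_mask: np.ndarray
    neighbor_indices: np.ndarray
    valid: bool


def feature_mask(validation_point, training, m: int) -> np.ndarray:
    """Boolean mask of features passing the m-condition.

    ``mask[j]`` is True iff at least m training values on feature j are
    strictly greater than the validation value and at least m strictly
    smaller.  m = 0 keeps every feature.
    """
    if m < 0:
        raise ValueError("m must be non-negative")
    v = np.asarray(validation_point, dtype=float)
    T = np.asarray(training, dtype=float)
    above = (T > v).sum(axis=0)
    below = (T < v).sum(axis=0)
    return (above >= m) & (below >= m)


def max_valid_m(validation_point, training) -> np.ndarray:
    """Per-feature largest m for which the m-condition holds:
    min(#strictly below, #strictly above).  ``feature_mask(v, T, m)`` equals
    ``max_valid_m(v, T) >= m`` for every m."""
    v = np.asarray(validation_point, dtype=float)
    T = np.asarray(training, dtype=float)
    return np.minimum((T > v).sum(axis=0), (T < v).sum(axis=0))


def knn_select(validation_point, training, mask, k: int) -> np.ndarray:
    """Indices of the k training samples nearest the validation point,
    with distances computed over masked features only.

    Returns fewer than k indices only when fewer training samples exist.
    Distance ties are broken by ascending training index.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("all features masked out; cell is invalid")
    v = np.asarray(validation_point, dtype=float)[mask]
    T = np.asarray(training, dtype=float)[:, mask]
    d2 = ((T - v) ** 2).sum(axis=1)
    order = np.argsort(d2, kind="stable")  # stable => ties by ascending index
    return order[: min(k, len(order))]


def trim(ds: ExpressionDataset, validation_index: int, m: int, k: int) -> TrimmedTrainingSet:
    """Compose the m-condition mask and kNN selection for one sample of a
    dataset, treating the other N-1 samples as training data."""
    if not 0 <= validation_index < ds.n_samples:
        raise IndexError(f"validation_index {validation_index} out of range")
    v = ds.values[validation_index]
    T = np.delete(ds.values, validation_index, axis=0)
    mask = feature_mask(v, T, m)
    if not mask.any():
        return TrimmedTrainingSet(
            m=m, k=k, feature_mask=mask, neighbor_indices=np.empty(0, dtype=np.intp),
            valid=False,
        )
    neigh = knn_select(v, T, mask, k)
    return TrimmedTrainingSet(m=m, k=k, feature_mask=mask, neighbor_indices=neigh, valid=True)


def default_grid(
    n_training: int,
    *,
    k_min: int = 20,
    m_max: int | str = "auto",
    m_cap_hint: int | None = None,
) -> TrimGrid:
    """The default (m, k) lattice for a training set of ``n_training`` samples.

    k runs from ``k_min`` to ``n_training``; when the training set is smaller
    than ``k_min`` the range falls back to max(3, n_training - 10)..n_training
    so small datasets stay usable.  m runs from 0 to ``m_max``; "auto" uses
    ``m_cap_hint`` (the largest m at which any feature survives for the
    validation point at hand) bounded by half the training size.
    """
    if n_training < 2:
        raise ValueError("need at least 2 training samples")
    if n_training >= k_min:
        k_values = range(k_min, n_training + 1)
    else:
        k_values = range(max(3, n_training - 10), n_training + 1)
    cap = n_training // 2
    if m_max == "auto":
        top = cap if m_cap_hint is None else min(int(m_cap_hint), cap)
    else:
        top = int(m_max)
    return TrimGrid(m_values=tuple(range(top + 1)), k_values=tuple(k_values))
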