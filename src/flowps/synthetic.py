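"""Seeded generators for the data regimes the trimming argument relies on.

Three structures are provided:

* ``global_linear`` — two Gaussian classes separated along a few informative
  coordinates: the positive control where a plain linear SVM should excel.
* ``checkerboard`` — tight clusters on a 2-D grid whose class alternates
  between adjacent cells: locally ordered but with no global linear order,
  the regime where per-point trimming should beat a global SVM.
* ``expression_like`` — log2-scale gene values with sample-specific
  baselines and a small set of informative genes shifted in responders,
  emulating a normalized transcriptomic cohort (tens of samples, a handful
  of markers among thousands of genes).

All generators are pure functions of their spec (seed included) and emit
exactly class-balanced datasets with labels encoded {0, 100}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RESPONDER, ExpressionDataset

STRUCTURES = ("global_linear", "checkerboard", "expression_like")


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic dataset.

    ``effect_size`` is the class separation on informative coordinates in
    the units of the structure's own scale (Gaussian sd for the numeric
    structures, log2 units for expression_like); ``noise_sd`` scales the
    uninformative variation.
    """

    n_samples: int = 40
    n_features: int = 10
    n_informative: int = 3
    effect_size: float = 2.0
    noise_sd: float = 1.0
    structure: str = "global_linear"
    seed: int = 0
    grid_size: int = 4           # checkerboard only: cells per side
    cluster_sd: float = 0.1      # checkerboard only: cluster sd in cell widths

    def __post_init__(self):
        if self.n_samples < 2 or self.n_samples % 2:
            raise ValueError("n_samples must be an even positive integer")
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must be in [0, n_features]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.structure not in STRUCTURES:
            raise ValueError(f"structure must be one of {STRUCTURES}")


def _package(values, labels, seed_tag, rng) -> ExpressionDataset:
    n = values.shape[0]
    # shuffle rows so class blocks are not contiguous
    perm = rng.permutation(n)
    return ExpressionDataset(
        values[perm],
        tuple(f"sample_{seed_tag}_{i:03d}" for i in range(n)),
        tuple(f"gene_{j:04d}" for j in range(values.shape[1])),
        labels[perm],
    )


def _balanced_labels(n: int) -> np.ndarray:
    y = np.zeros(n, dtype=np.int64)
    y[n // 2:] = RESPONDER
    return y


def make_global_linear(spec: GeneratorSpec) -> ExpressionDataset:
    """Two Gaussian classes separated by ``effect_size`` along the first
    ``n_informative`` coordinates, isotropic ``noise_sd`` elsewhere."""
    if spec.n_informative < 1:
        raise ValueError("global_linear needs n_informative >= 1")
    rng = np.random.default_rng(spec.seed)
    n, s = spec.n_samples, spec.n_features
    y = _balanced_labels(n)
    X = rng.normal(scale=spec.noise_sd, size=(n, s))
    X[y == RESPONDER, : spec.n_informative] += spec.effect_size
    return _package(X, y, f"gl{spec.seed}", rng)


def make_checkerboard(spec: GeneratorSpec) -> ExpressionDataset:
    """Alternating-class Gaussian clusters on a ``grid_size``-squared lattice.

    The two informative features hold the checkerboard plane (unit cell
    width, cluster sd ``cluster_sd`` cell widths); remaining features are
    pure measurement jitter on the cluster-scatter scale
    (``noise_sd * cluster_sd``), so the lattice geometry — not the noise —
    dominates distances.  Adjacent cells always differ in class: the
    classes are locally separated but admit no global linear separator
    (whenever more than one cell per class exists).
    """
    if spec.n_informative != 2:
        raise ValueError("checkerboard uses exactly 2 informative features")
    if spec.n_features < 2:
        raise ValueError("checkerboard needs n_features >= 2")
    g = spec.grid_size
    if g < 1:
        raise ValueError("grid_size must be >= 1")
    rng = np.random.default_rng(spec.seed)
    n, s = spec.n_samples, spec.n_features
    cells = [(i, j) for i in range(g) for j in range(g)]
    cls0 = [c for c in cells if (c[0] + c[1]) % 2 == 0]
    cls1 = [c for c in cells if (c[0] + c[1]) % 2 == 1]
    if not cls1:  # 1x1 grid: degenerate two-cluster limit, one cell per class
        cls1 = [(1, 0)]
    y = _balanced_labels(n)
    X = rng.normal(scale=spec.noise_sd * spec.cluster_sd, size=(n, s))
    half = n // 2
    for rows, cellset in ((range(half), cls0), (range(half, n), cls1)):
        for r, row in enumerate(rows):
            ci, cj = cellset[r % len(cellset)]
            X[row, 0] = ci + 0.5 + rng.normal(scale=spec.cluster_sd)
            X[row, 1] = cj + 0.5 + rng.normal(scale=spec.cluster_sd)
    return _package(X, y, f"cb{spec.seed}", rng)


def make_expression_like(spec: GeneratorSpec) -> ExpressionDataset:
    """Log2-scale expression with per-sample baselines and informative genes.

    Gene baselines are uniform on [2, 12] log2 units; every sample carries
    a global baseline shift (N(0, 0.3)) so quantile normalization has work
    to do; measurement noise is N(0, noise_sd).  Informative genes are
    shifted by ``effect_size`` in responders with alternating sign, so both
    up- and down-regulated markers occur.
    """
    rng = np.random.default_rng(spec.seed)
    n, s = spec.n_samples, spec.n_features
    y = _balanced_labels(n)
    base = rng.uniform(2.0, 12.0, size=s)
    sample_shift = rng.normal(scale=0.3, size=(n, 1))
    X = base + sample_shift + rng.normal(scale=spec.noise_sd, size=(n, s))
    info = rng.choice(s, size=spec.n_informative, replace=False)
    signs = np.where(np.arange(spec.n_informative) % 2 == 0, 1.0, -1.0)
    X[np.ix_(y == RESPONDER, info)] += spec.effect_size * signs
    ds = _package(X, y, f"ex{spec.seed}", rng)
    return ds


_MAKERS = {
    "global_linear": make_global_linear,
    "checkerboard": make_checkerboard,
    "expression_like": make_expression_like,
}


def make_dataset(spec: GeneratorSpec) -> ExpressionDataset:
    """Dispatch on ``spec.structure``."""
    return _MAKERS[spec.structure](spec)


def informative_genes(spec: GeneratorSpec) -> tuple:
    """Gene IDs of the informative features of ``make_expression_like(spec)``
    (recomputed from the same seed stream)."""
    if spec.structure != "expression_like":
        raise ValueError("informative_genes applies to expression_like specs")
    rng = np.random.default_rng(spec.seed)
    rng.uniform(2.0, 12.0, size=spec.n_features)
    rng.normal(scale=0.3, size=(spec.n_samples, 1))
    rng.normal(scale=spec.noise_sd, size=(spec.n_samples, spec.n_features))
    info = rng.choice(spec.n_features, size=spec.n_informative, replace=False)
    return tuple(f"gene_{j:04d}" for j in sorted(info))
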