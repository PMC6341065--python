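"""Single-gene ROC-AUC marker ranking and the leave-one-out core-gene set.

Each gene is scored by the Mann-Whitney AUC of its expression against the
responder/non-responder split, taken one gene at a time.  By default genes
are ranked by the *oriented* AUC max(AUC, 1-AUC) so strongly down-regulated
markers compete equally with up-regulated ones; ``orient=False`` restores
raw-AUC ranking.  The "core" marker set is the intersection of the top-n
lists over all N leave-one-out subdatasets, a stability filter for the
final feature space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io import RESPONDER, ExpressionDataset
from .metrics import mann_whitney_auc


@dataclass(frozen=True)
class GeneRanking:
    """Genes ordered by decreasing (oriented) AUC.

    ``auc_values`` holds the ranking score (oriented by default, hence in
    [0.5, 1]); ``raw_auc`` the unoriented AUC of each listed gene.
    """

    gene_ids: tuple
    auc_values: np.ndarray
    raw_auc: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "auc_values", np.asarray(self.auc_values, dtype=float))
        object.__setattr__(self, "raw_auc", np.asarray(self.raw_auc, dtype=float))
        if np.any(np.diff(self.auc_values) > 1e-12):
            raise ValueError("auc_values must be non-increasing")


def gene_auc(values, labels) -> float:
    """Mann-Whitney AUC of one gene's expression for the responder class."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = labels == RESPONDER
    if pos.all() or not pos.any():
        raise ValueError("gene_auc needs both classes present")
    return mann_whitney_auc(values, pos)


def _auc_all_genes(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized per-column Mann-Whitney AUC."""
    pos = labels == RESPONDER
    n1 = int(pos.sum())
    n0 = pos.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(values, axis=0)
    return (ranks[pos].sum(axis=0) - n1 * (n1 + 1) / 2) / (n1 * n0)


def rank_genes(ds: ExpressionDataset, orient: bool = True) -> GeneRanking:
    """Rank all genes; ties broken by gene ID for reproducibility."""
    raw = _auc_all_genes(ds.values, ds.labels)
    score = np.maximum(raw, 1 - raw) if orient else raw
    order = sorted(range(ds.n_features), key=lambda j: (-score[j], ds.gene_ids[j]))
    order = np.asarray(order, dtype=np.intp)
    return GeneRanking(
        gene_ids=tuple(ds.gene_ids[j] for j in order),
        auc_values=score[order],
        raw_auc=raw[order],
    )


def top_n_genes(ds: ExpressionDataset, n: int = 30, orient: bool = True) -> GeneRanking:
    """The n best marker genes by (oriented) single-gene AUC."""
    if not 1 <= n <= ds.n_features:
        raise ValueError(f"n must be in [1, {ds.n_features}], got {n}")
    ranking = rank_genes(ds, orient=orient)
    return GeneRanking(
        gene_ids=ranking.gene_ids[:n],
        auc_values=ranking.auc_values[:n],
        raw_auc=ranking.raw_auc[:n],
    )


def core_genes(ds: ExpressionDataset, n: int = 30, orient: bool = True) -> set:
    """Intersection of the top-n marker lists over all leave-one-out subdatasets.

    For each sample i the ranking is recomputed on the dataset without i;
    the core set is the intersection of the N resulting top-n lists (so it
    has at most n members and is contained in every per-subdataset list).
    """
    if ds.n_samples < 3:
        raise ValueError("core_genes needs at least 3 samples")
    core: set | None = None
    for i in range(ds.n_samples):
        sub = ds.drop_sample(i)
        counts = sub.class_counts()
        if 0 in counts:
            raise ValueError(
                f"removing sample {ds.sample_ids[i]!r} leaves a single-class dataset"
            )
        top = set(top_n_genes(sub, n, orient=orient).gene_ids)
        core = top if core is None else core & top
        if not core:
            break
    return core or set()
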