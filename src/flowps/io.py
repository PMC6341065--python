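"""Data structures, file I/O, quantile normalization and run configuration.

Expression matrices are plain delimited text (tab or comma, auto-detected)
with a header row of IDs and a leading ID column; labels are a two-column
table mapping sample IDs to the binary response status.  Responders are
encoded 100 and non-responders 0 throughout the package, so that averaged
predictions live on the same 0-100 scale.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

RESPONDER = 100
NON_RESPONDER = 0
VALID_LABELS = (NON_RESPONDER, RESPONDER)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ExpressionDataset:
    """A samples x genes expression matrix with binary response labels.

    Attributes
    ----------
    values : ndarray, shape (n_samples, n_features)
        Normalized expression values (arbitrary scale, no missing entries).
    sample_ids, gene_ids : list of str
        Unique identifiers for rows and columns.
    labels : ndarray of int, shape (n_samples,)
        Response status per sample: 100 = responder, 0 = non-responder.
    """

    values: np.ndarray
    sample_ids: tuple
    gene_ids: tuple
    labels: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, s = values.shape
        if len(self.sample_ids) != n or labels.shape != (n,):
            raise ValueError(
                f"row mismatch: {n} rows, {len(self.sample_ids)} sample_ids, "
                f"{labels.shape[0]} labels"
            )
        if len(self.gene_ids) != s:
            raise ValueError(f"column mismatch: {s} columns, {len(self.gene_ids)} gene_ids")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicated sample IDs")
        if len(set(self.gene_ids)) != s:
            raise ValueError("duplicated gene IDs")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"missing/non-finite value at sample {self.sample_ids[bad[0]]!r}, "
                f"gene {self.gene_ids[bad[1]]!r}"
            )
        if not np.isin(labels, VALID_LABELS).all():
            bad = labels[~np.isin(labels, VALID_LABELS)][0]
            raise ValueError(f"labels must be 0 or 100, found {bad}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """(non-responders, responders)."""
        return int((self.labels == NON_RESPONDER).sum()), int((self.labels == RESPONDER).sum())

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionDataset":
        idx = np.asarray(indices, dtype=np.intp)
        return ExpressionDataset(
            self.values[idx],
            tuple(self.sample_ids[i] for i in idx),
            self.gene_ids,
            self.labels[idx],
        )

    def drop_sample(self, index: int) -> "ExpressionDataset":
        keep = [i for i in range(self.n_samples) if i != index]
        return self.subset_samples(keep)

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionDataset":
        wanted = list(gene_ids)
        pos = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in wanted if g not in pos]
        if missing:
            raise KeyError(f"unknown gene IDs: {missing[:5]}")
        cols = np.asarray([pos[g] for g in wanted], dtype=np.intp)
        return ExpressionDataset(
            self.values[:, cols], self.sample_ids, tuple(wanted), self.labels
        )


@dataclass(frozen=True)
class ClassifierConfig:
    """Settings shared by FloWPS and the baselines.

    kernel : "linear" or "poly" (libsvm defaults otherwise).
    C : soft-margin cost, > 0.
    p : confidence threshold in (0, 1] defining the prediction-accountable
        set S = {(m, k) : AUC(m, k) >= p * max AUC}.
    k_min : smallest neighbor count in the k grid (default 20).
    m_max : upper bound of the m grid, or "auto" (largest m at which any
        feature survives for the validation point, capped at half the
        training size).
    prediction_mode : "label" (hard 0/100 votes, default) or "decision"
        (signed SVM margins).
    seed : used wherever subsampling occurs (class equalization).
    """

    kernel: str = "linear"
    C: float = 1.0
    p: float = 0.90
    k_min: int = 20
    m_max: int | str = "auto"
    seed: int = 0
    prediction_mode: str = "label"

    def __post_init__(self):
        from ._svm import canonical_kernel

        object.__setattr__(self, "kernel", canonical_kernel(self.kernel))
        if not self.C > 0:
            raise ValueError("C must be positive")
        if not 0 < self.p <= 1:
            raise ValueError("p must lie in (0, 1]")
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")
        if self.m_max != "auto" and (int(self.m_max) < 0):
            raise ValueError("m_max must be non-negative or 'auto'")
        if self.prediction_mode not in ("label", "decision"):
            raise ValueError("prediction_mode must be 'label' or 'decision'")

    def digest(self) -> str:
        """Short stable digest identifying this configuration in output files."""
        text = "|".join(
            f"{k}={getattr(self, k)}"
            for k in ("kernel", "C", "p", "k_min", "m_max", "seed", "prediction_mode")
        )
        return hashlib.md5(text.encode()).hexdigest()[:10]


# ---------------------------------------------------------------------------
# readers / writers


def _check_header_duplicates(path, what: str) -> None:
    # pandas silently renames duplicated header entries, so inspect the raw
    # header line (delimiter: whichever of tab/comma splits it further)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
    tokens = max((header.split("\t"), header.split(",")), key=len)[1:]
    seen = set()
    for t in tokens:
        if t in seen:
            raise ValueError(f"{path}: duplicated {what} {t!r}")
        seen.add(t)


def _read_delimited(path) -> pd.DataFrame:
    # delimiter auto-detected between tab and comma; UTF-8
    return pd.read_csv(path, sep=None, engine="python", index_col=0, encoding="utf-8")


def read_labels(path) -> dict[str, int]:
    """Read a two-column (sample_id, label) table; {0,1} is rescaled to {0,100}."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, encoding="utf-8")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample_id, label)")
    # tolerate an optional header line
    first = str(df.iloc[0, 1])
    try:
        float(first)
    except ValueError:
        df = df.iloc[1:]
    ids = df.iloc[:, 0].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated sample ID {dup!r}")
    raw = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if raw.isna().any():
        bad = ids[int(np.where(raw.isna())[0][0])]
        raise ValueError(f"{path}: non-numeric label for sample {bad!r}")
    vals = raw.to_numpy(dtype=float)
    uniq = set(np.unique(vals))
    if uniq <= {0.0, 1.0}:
        vals = vals * 100
    elif not uniq <= {0.0, 100.0}:
        raise ValueError(f"{path}: labels must be in {{0,100}} (or {{0,1}}), got {sorted(uniq)}")
    return dict(zip(ids, vals.astype(int)))


def read_expression_dataset(
    matrix_path,
    labels_path,
    orientation: str = "samples_by_genes",
) -> ExpressionDataset:
    """Load a delimited expression matrix plus a sample->label table.

    ``orientation="genes_by_samples"`` transposes the matrix on read.
    Duplicated IDs, ID mismatches between files, non-numeric cells and
    missing values are all rejected with the offending ID reported.
    """
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    _check_header_duplicates(
        matrix_path, "gene ID" if orientation == "samples_by_genes" else "sample ID"
    )
    df = _read_delimited(matrix_path)
    if orientation == "genes_by_samples":
        df = df.T
    if df.index.duplicated().any():
        raise ValueError(f"{matrix_path}: duplicated sample ID {df.index[df.index.duplicated()][0]!r}")
    if df.columns.duplicated().any():
        raise ValueError(f"{matrix_path}: duplicated gene ID {df.columns[df.columns.duplicated()][0]!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        row, col = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{matrix_path}: non-numeric or missing value at sample "
            f"{df.index[row]!r}, gene {df.columns[col]!r}"
        )
    labels = read_labels(labels_path)
    sample_ids = [str(s) for s in df.index]
    missing = [s for s in sample_ids if s not in labels]
    if missing:
        raise ValueError(f"{labels_path}: no label for sample {missing[0]!r}")
    y = np.array([labels[s] for s in sample_ids], dtype=np.int64)
    return ExpressionDataset(
        numeric.to_numpy(dtype=np.float64),
        tuple(sample_ids),
        tuple(str(g) for g in df.columns),
        y,
    )


def write_expression_dataset(ds: ExpressionDataset, matrix_path, labels_path) -> None:
    """Write the matrix and labels in the formats `read_expression_dataset` accepts."""
    pd.DataFrame(ds.values, index=list(ds.sample_ids), columns=list(ds.gene_ids)).to_csv(
        matrix_path, sep="\t"
    )
    pd.DataFrame({"sample_id": list(ds.sample_ids), "label": ds.labels}).to_csv(
        labels_path, sep="\t", index=False, header=False
    )


PREDICTION_COLUMNS = ("sample_id", "true_label", "p_f", "n_cells", "classifier", "config")


def write_predictions(records, path) -> None:
    """Write per-sample prediction records as TSV (stable column order).

    ``records`` is an iterable of objects or mappings exposing the
    PREDICTION_COLUMNS fields.
    """
    rows = []
    for r in records:
        get = r.get if isinstance(r, dict) else lambda k, _r=r: getattr(_r, k)
        rows.append({c: get(c) for c in PREDICTION_COLUMNS})
    pd.DataFrame(rows, columns=list(PREDICTION_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "classifier": str, "config": str})
    return df


def write_topogram(topogram, path) -> None:
    """Dense TSV dump of an AUC(m, k) topogram; invalid cells are empty."""
    auc = np.where(topogram.valid, topogram.auc, np.nan)
    pd.DataFrame(
        auc,
        index=pd.Index(topogram.grid.m_values, name="m"),
        columns=pd.Index(topogram.grid.k_values, name="k"),
    ).to_csv(path, sep="\t")


def write_metrics(reports: dict, path) -> None:
    """One row per named classifier configuration."""
    rows = []
    for name, rep in reports.items():
        d = rep.as_dict()
        d["classifier"] = name
        rows.append(d)
    cols = ["classifier", "auc", "fdr", "sn", "sp", "acc", "mcc", "tau",
            "n", "tp", "fp", "tn", "fn"]
    pd.DataFrame(rows)[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# preprocessing


def quantile_normalize(values: np.ndarray, axis: str = "per_sample") -> np.ndarray:
    """Quantile-normalize so every sample (row) shares one value distribution.

    The reference distribution is the rank-wise mean across samples; ties
    within a sample receive the mean of the reference values at their tied
    ranks (the standard rank-wise-mean construction).  Idempotent.
    """
    if axis != "per_sample":
        raise ValueError("only axis='per_sample' is supported")
    X = np.asarray(values, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if not np.isfinite(X).all():
        raise ValueError("missing values are not allowed")
    n, s = X.shape
    if n < 2:
        warnings.warn("quantile_normalize: fewer than 2 samples, returning input unchanged")
        return X.copy()
    reference = np.sort(X, axis=1).mean(axis=0)
    out = np.empty_like(X)
    for i in range(n):
        order = np.argsort(X[i], kind="stable")
        row = np.empty(s)
        row[order] = reference
        # ties: average the reference values assigned within each tie group
        uniq, inv = np.unique(X[i], return_inverse=True)
        if uniq.size != s:
            sums = np.bincount(inv, weights=row, minlength=uniq.size)
            counts = np.bincount(inv, minlength=uniq.size)
            row = (sums / counts)[inv]
        out[i] = row
    return out


def quantile_normalize_dataset(ds: ExpressionDataset) -> ExpressionDataset:
    return replace(ds, values=quantile_normalize(ds.values))


def equalize_classes(ds: ExpressionDataset, seed: int) -> ExpressionDataset:
    """Balance the two classes: keep the full smaller class, subsample the bigger.

    The subsample is a seeded uniform draw without replacement; retained
    samples keep their original order.  Deterministic given ``seed``.
    """
    n0, n1 = ds.class_counts()
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present to equalize")
    if n0 == n1:
        return ds
    small = RESPONDER if n1 < n0 else NON_RESPONDER
    big = NON_RESPONDER if small == RESPONDER else RESPONDER
    n_small = min(n0, n1)
    big_idx = np.flatnonzero(ds.labels == big)
    rng = np.random.default_rng(seed)
    keep_big = set(rng.choice(big_idx, size=n_small, replace=False).tolist())
    keep = [i for i in range(ds.n_samples) if ds.labels[i] == small or i in keep_big]
    return ds.subset_samples(keep)
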