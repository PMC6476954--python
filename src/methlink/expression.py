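"""FPKM matrix handling, tissue-specific gene selection and clustering.

The expression matrix is a genes x tissues pandas DataFrame of FPKM
(non-negative).  Tissue-specific genes (TSGs) are those exceeding a large
fold change between at least one tissue pair; their z-scored profiles are
grouped by Ward-initialised k-means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering, KMeans


def read_fpkm(path: str | Path) -> pd.DataFrame:
    """Read a genes x tissues FPKM matrix TSV (header = tissue names)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_expression(df)
    return df


def write_fpkm(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def validate_expression(df: pd.DataFrame) -> None:
    if (df.to_numpy(dtype=float) < 0).any():
        raise ValueError("FPKM values must be non-negative")
    if df.columns.duplicated().any():
        raise ValueError("tissue names must be unique")


def filter_low_expression(df: pd.DataFrame, min_row_sum: float = 3.0) -> pd.DataFrame:
    """Drop genes whose FPKM row sum is below ``min_row_sum`` (idempotent)."""
    return df[df.sum(axis=1) >= min_row_sum]


def tissue_correlation(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tissue x tissue Pearson r with two-sided p-values.

    p is computed from the t transform ``t = r * sqrt((n-2)/(1-r^2))`` with
    n - 2 degrees of freedom, n being the number of genes.  Constant columns
    yield NaN with a warning.
    """
    if len(df) < 3:
        raise ValueError("need at least 3 genes")
    x = df.to_numpy(dtype=float)
    n = x.shape[0]
    sd = x.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant expression column(s): {list(df.columns[constant])}; r set to NaN"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, np.where(constant, np.nan, 1.0))
    rc = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rc * np.sqrt((n - 2) / (1.0 - rc**2))
    p = np.where(np.abs(rc) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    p = np.where(np.isnan(rc), np.nan, p)
    r_df = pd.DataFrame(r, index=df.columns, columns=df.columns)
    p_df = pd.DataFrame(p, index=df.columns, columns=df.columns)
    return r_df, p_df


def select_tsg(
    df: pd.DataFrame, fold_change: float = 16.0, pseudocount: float = 1.0
) -> list[str]:
    """Genes with a >= ``fold_change`` FPKM ratio between some tissue pair.

    The pairwise criterion reduces to ``(max + pc) / (min + pc) >=
    fold_change``; the pseudocount guards against zero FPKM.
    """
    hi = df.max(axis=1) + pseudocount
    lo = df.min(axis=1) + pseudocount
    selected = df.index[(hi / lo) >= fold_change]
    return list(selected)


def zscore_rows(df: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per-gene z-scores (x - mean) / sd, sample sd by default.

    Zero-variance rows are dropped with a warning.
    """
    x = df.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} zero-variance gene row(s)")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    return pd.DataFrame(z, index=df.index, columns=df.columns)[~constant]


@dataclass
class TsgClustering:
    """k-means clustering of z-scored tissue-specific genes."""

    zscores: pd.DataFrame
    labels: pd.Series  # gene -> cluster label in 1..k
    k: int

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"gene_id": self.labels.index, "cluster": self.labels.to_numpy()}).to_csv(
            path, sep="\t", index=False
        )


def cluster_tsg(z_matrix: pd.DataFrame, k: int = 12, seed: int = 0) -> TsgClustering:
    """Ward-initialised k-means on z-scored expression rows.

    Ward agglomeration on Euclidean distances is cut at ``k``; the cluster
    means seed a standard k-means refinement (tol 1e-6, max 300 iterations).
    Deterministic given the data and seed, and invariant to row order.
    """
    x = z_matrix.to_numpy(dtype=float)
    n = x.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows ({n})")
    if k == n:
        labels = np.arange(1, n + 1)
        return TsgClustering(z_matrix, pd.Series(labels, index=z_matrix.index), k)
    ward = AgglomerativeClustering(n_clusters=k, linkage="ward").fit(x)
    centroids = np.vstack([x[ward.labels_ == c].mean(axis=0) for c in range(k)])
    km = KMeans(
        n_clusters=k, init=centroids, n_init=1, max_iter=300, tol=1e-6,
        random_state=seed,
    ).fit(x)
    # canonical label order: clusters numbered by their first gene in the input
    first_seen = {}
    for lab in km.labels_:
        if lab not in first_seen:
            first_seen[lab] = len(first_seen) + 1
    labels = pd.Series([first_seen[lab] for lab in km.labels_], index=z_matrix.index)
    return TsgClustering(z_matrix, labels, k)


def deg_network(deg_counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Summarise an externally produced tissue-pair DEG count table.

    ``deg_counts`` must be a symmetric tissue x tissue matrix with zero
    diagonal.  Returns node weights (sum of incident edge counts) and an
    edge list (source, target, weight) over unordered pairs.
    """
    if list(deg_counts.index) != list(deg_counts.columns):
        raise ValueError("DEG table must have identical row and column labels")
    arr = deg_counts.to_numpy()
    if not np.array_equal(arr, arr.T):
        raise ValueError("DEG table must be symmetric")
    nodes = deg_counts.sum(axis=1)
    names = list(deg_counts.index)
    edges = [
        (names[i], names[j], arr[i, j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
    ]
    return nodes, pd.DataFrame(edges, columns=["source", "target", "weight"])
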