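"""Pairwise per-site differential methylation screening (DMS).

With one sample per tissue the natural per-site test is Fisher's exact test
on the 2x2 methylated/unmethylated count table; significance is controlled
by Benjamini-Hochberg FDR over all sites shared by the pair after depth
filtering.  The two-sided p-value is the exact hypergeometric tail: the sum
of point probabilities not exceeding that of the observed table.

``site_test`` handles one table; ``fisher_exact_many`` batches millions of
tables by deduplicating them and caching the hypergeometric pmf per margin
configuration, which is what makes the all-pairs tissue screen tractable.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from methlink.methylation import filter_sites_by_depth

# relative tolerance when comparing point probabilities, as in the classical
# implementations, to absorb floating-point noise in the pmf
_REL_TOL = 1.0 + 1e-7


def _fisher_p_single(a: int, b: int, c: int, d: int) -> float:
    n1 = a + b
    n2 = c + d
    if n1 == 0 or n2 == 0:
        warnings.warn("zero total in one sample; p undefined")
        return float("nan")
    big_n = n1 + n2
    k = a + c
    kmin = max(0, k - n2)
    kmax = min(k, n1)
    support = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(support, big_n, k, n1)
    p_obs = pmf[a - kmin]
    p = float(pmf[pmf <= p_obs * _REL_TOL].sum())
    # the full-support sum is exactly 1; absorb float summation noise
    return 1.0 if p >= 1.0 - 1e-12 else p


def site_test(a_counts: tuple[int, int], b_counts: tuple[int, int]) -> float:
    """Two-sided Fisher's exact p for one site.

    ``a_counts`` and ``b_counts`` are (n_meth, n_unmeth) for the two
    tissues.  Symmetric in its arguments; returns NaN (with a warning) when
    either sample has zero total depth.
    """
    a, b = a_counts
    c, d = b_counts
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    return _fisher_p_single(a, b, c, d)


def fisher_exact_many(
    n_meth_a: np.ndarray,
    n_unmeth_a: np.ndarray,
    n_meth_b: np.ndarray,
    n_unmeth_b: np.ndarray,
) -> np.ndarray:
    """Two-sided Fisher's exact p-values for many 2x2 tables at once.

    Equivalent to calling :func:`site_test` per table; unique tables are
    evaluated once.
    """
    tables = np.column_stack(
        [
            np.asarray(n_meth_a, dtype=np.int64),
            np.asarray(n_unmeth_a, dtype=np.int64),
            np.asarray(n_meth_b, dtype=np.int64),
            np.asarray(n_unmeth_b, dtype=np.int64),
        ]
    )
    if tables.size and tables.min() < 0:
        raise ValueError("counts must be non-negative")
    uniq, inverse = np.unique(tables, axis=0, return_inverse=True)
    p_uniq = np.empty(len(uniq))
    for i, (a, b, c, d) in enumerate(uniq):
        p_uniq[i] = _fisher_p_single(int(a), int(b), int(c), int(d))
    return p_uniq[inverse]


def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def dms_screen(
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    q_max: float = 0.05,
    min_depth: int = 10,
    min_diff: float = 0.0,
    tissue_a: str = "a",
    tissue_b: str = "b",
) -> pd.DataFrame:
    """Differentially methylated sites between two tissues.

    Both site tables are depth-filtered at ``min_depth``; only CpG positions
    present in both tissues are tested (this shared set is the BH family).
    Records with BH q <= ``q_max`` and |meth_diff| >= ``min_diff`` are
    returned sorted by position, ``meth_diff`` being the percentage-point
    difference b - a.  The total number of tested sites is available as
    ``result.attrs["n_tested"]``.
    """
    a = filter_sites_by_depth(sites_a[sites_a["context"] == "CpG"], min_depth)
    b = filter_sites_by_depth(sites_b[sites_b["context"] == "CpG"], min_depth)
    merged = a.merge(
        b, on=["chrom", "pos"], suffixes=("_a", "_b"), how="inner", sort=True
    )
    cols = [
        "chrom", "pos", "tissue_a", "tissue_b",
        "n_meth_a", "n_unmeth_a", "n_meth_b", "n_unmeth_b",
        "meth_diff", "p", "q",
    ]
    if merged.empty:
        warnings.warn(f"no shared CpG sites between {tissue_a!r} and {tissue_b!r}")
        out = pd.DataFrame(columns=cols)
        out.attrs["n_tested"] = 0
        return out
    depth_a = merged["n_meth_a"] + merged["n_unmeth_a"]
    depth_b = merged["n_meth_b"] + merged["n_unmeth_b"]
    level_a = 100.0 * merged["n_meth_a"] / depth_a
    level_b = 100.0 * merged["n_meth_b"] / depth_b
    p = fisher_exact_many(
        merged["n_meth_a"].to_numpy(),
        merged["n_unmeth_a"].to_numpy(),
        merged["n_meth_b"].to_numpy(),
        merged["n_unmeth_b"].to_numpy(),
    )
    q = bh_adjust(p)
    result = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "pos": merged["pos"],
            "tissue_a": tissue_a,
            "tissue_b": tissue_b,
            "n_meth_a": merged["n_meth_a"],
            "n_unmeth_a": merged["n_unmeth_a"],
            "n_meth_b": merged["n_meth_b"],
            "n_unmeth_b": merged["n_unmeth_b"],
            "meth_diff": level_b - level_a,
            "p": p,
            "q": q,
        }
    )
    n_tested = len(result)
    keep = (result["q"] <= q_max) & (result["meth_diff"].abs() >= min_diff)
    out = result[keep].sort_values(["chrom", "pos"]).reset_index(drop=True)
    out.attrs["n_tested"] = n_tested
    return out


def dms_count_matrix(
    samples: Mapping[str, pd.DataFrame],
    q_max: float = 0.05,
    min_depth: int = 10,
    min_diff: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DMS counts for every tissue pair, as a symmetric matrix + edge list.

    Cell (i, j) holds the number of DMS between tissues i and j (diagonal
    0).  The edge list has columns ``source, target, weight``; node weight
    (row sum) can be recovered as ``matrix.sum(axis=1)``.
    """
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least two tissues")
    matrix = pd.DataFrame(0, index=names, columns=names, dtype=int)
    edges = []
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            dms = dms_screen(
                samples[na], samples[nb],
                q_max=q_max, min_depth=min_depth, min_diff=min_diff,
                tissue_a=na, tissue_b=nb,
            )
            n = len(dms)
            matrix.loc[na, nb] = n
            matrix.loc[nb, na] = n
            edges.append((na, nb, n))
    edge_df = pd.DataFrame(edges, columns=["source", "target", "weight"])
    return matrix, edge_df
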