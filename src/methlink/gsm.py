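"""Gene-silencing methylation (GSM) screen.

The headline analysis: each CGI-gene unit pairs the methylation profile of
a promoter CpG island with the expression profile of its downstream gene
across tissues.  Units with a significantly negative Pearson correlation
(r < 0, p <= 0.05) are called GSMs; a hard filter (p <= 0.001) marks the
high-significance subset.  No multiple-testing correction enters the
classification (a BH column is emitted for transparency only), and
expression is log2(FPKM + 1)-transformed by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from methlink.annotation import CgiGeneUnit
from methlink.diffmeth import bh_adjust
from methlink.methylation import MethylationMatrix


@dataclass
class UnitVectors:
    """Aligned per-tissue (methylation %, FPKM) observations for one unit."""

    unit: CgiGeneUnit
    tissues: list[str]
    meth: np.ndarray  # percent, [0, 100]
    expr: np.ndarray  # raw FPKM

    @property
    def n_tissues(self) -> int:
        return len(self.tissues)


def build_units(
    meth: MethylationMatrix | pd.DataFrame,
    expr: pd.DataFrame,
    units: Sequence[CgiGeneUnit],
    min_tissues: int = 8,
) -> tuple[list[UnitVectors], dict]:
    """Align methylation and expression vectors per CGI-gene unit.

    For each unit, tissues present in both matrices where both values are
    non-missing are kept; units with fewer than ``min_tissues`` such
    tissues are excluded, and units referencing an unknown CGI or gene id
    are skipped with a warning.  Returns the surviving units' vectors and a
    report of the exclusion counts.
    """
    meth_values = meth.values if isinstance(meth, MethylationMatrix) else meth
    shared = [t for t in meth_values.columns if t in expr.columns]
    report = {
        "n_units_in": len(units),
        "n_shared_tissues": len(shared),
        "n_skipped_unknown_id": 0,
        "n_failed_min_tissues": 0,
    }
    if len(shared) < min_tissues:
        raise ValueError(
            f"only {len(shared)} shared tissues; min_tissues={min_tissues}"
        )
    m = meth_values[shared]
    e = expr[shared]
    out: list[UnitVectors] = []
    n_unknown = 0
    for unit in units:
        if unit.cgi_id not in m.index or unit.gene_id not in e.index:
            n_unknown += 1
            continue
        mv = m.loc[unit.cgi_id].to_numpy(dtype=float)
        ev = e.loc[unit.gene_id].to_numpy(dtype=float)
        ok = np.isfinite(mv) & np.isfinite(ev)
        if ok.sum() < min_tissues:
            report["n_failed_min_tissues"] += 1
            continue
        out.append(
            UnitVectors(unit, [t for t, k in zip(shared, ok) if k], mv[ok], ev[ok])
        )
    if n_unknown:
        warnings.warn(f"skipped {n_unknown} unit(s) referencing unknown CGI or gene ids")
    report["n_skipped_unknown_id"] = n_unknown
    report["n_units_tested"] = len(out)
    return out, report


def correlate_unit(
    meth_vec: np.ndarray,
    expr_vec: np.ndarray,
    log_transform: bool = True,
) -> tuple[float, float]:
    """Pearson (r, p) between a methylation and an expression vector.

    Expression is mapped to log2(FPKM + 1) first unless ``log_transform``
    is off.  The two-sided p derives from t = r sqrt((n-2)/(1-r^2)) with
    n - 2 df; |r| = 1 gives p = 0.  Vectors shorter than 3 or with zero
    variance yield (NaN, NaN) with a warning.
    """
    m = np.asarray(meth_vec, dtype=float)
    e = np.asarray(expr_vec, dtype=float)
    if m.shape != e.shape:
        raise ValueError("vectors must be aligned")
    if log_transform:
        e = np.log2(e + 1.0)
    if m.size < 3:
        warnings.warn("fewer than 3 tissues; correlation undefined")
        return float("nan"), float("nan")
    if np.ptp(m) == 0 or np.ptp(e) == 0:
        warnings.warn("zero variance in a unit vector; correlation undefined")
        return float("nan"), float("nan")
    res = stats.pearsonr(m, e)
    r, p = float(res.statistic), float(res.pvalue)
    if abs(r) >= 1.0 - 1e-12:  # exact collinearity up to float noise
        return float(np.sign(r)), 0.0
    return r, p


def select_gsms(results: pd.DataFrame, p_max: float = 0.05) -> pd.DataFrame:
    """GSMs: units with r < 0 and p <= ``p_max``."""
    keep = (results["r"] < 0) & (results["p"] <= p_max)
    return results[keep.fillna(False)]


def hard_filter(gsms: pd.DataFrame, p_max: float = 0.001) -> pd.DataFrame:
    """High-significance GSMs: p <= ``p_max`` within the GSM set."""
    return gsms[gsms["p"] <= p_max]


def gsm_screen(
    meth: MethylationMatrix | pd.DataFrame,
    expr: pd.DataFrame,
    units: Sequence[CgiGeneUnit],
    min_tissues: int = 8,
    p_max: float = 0.05,
    hard_p_max: float = 0.001,
    log_transform: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Run the full GSM screen over all CGI-gene units.

    Returns a per-unit result table (r, p, BH q and class in
    {candidate, gsm, gsm_high}) and a run report with stage counts, the
    pooled correlation across all unit-tissue observations, and coarse
    density summaries of methylation and expression.
    """
    vectors, report = build_units(meth, expr, units, min_tissues=min_tissues)
    rows = []
    pooled_m: list[np.ndarray] = []
    pooled_e: list[np.ndarray] = []
    for uv in vectors:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r, p = correlate_unit(uv.meth, uv.expr, log_transform=log_transform)
        prom = uv.unit.promoter
        rows.append(
            (
                uv.unit.cgi_id, uv.unit.gene_id, prom.chrom, prom.start, prom.end,
                uv.n_tissues, r, p,
            )
        )
        pooled_m.append(uv.meth)
        pooled_e.append(np.log2(uv.expr + 1.0) if log_transform else uv.expr)
    results = pd.DataFrame(
        rows,
        columns=[
            "cgi_id", "gene_id", "chrom", "promoter_start", "promoter_end",
            "n_tissues", "r", "p",
        ],
    )
    results["q_bh"] = bh_adjust(results["p"]) if len(results) else np.nan

    cls = np.where(
        (results["r"] < 0) & (results["p"] <= hard_p_max), "gsm_high",
        np.where((results["r"] < 0) & (results["p"] <= p_max), "gsm", "candidate"),
    )
    results["class"] = cls

    if pooled_m:
        all_m = np.concatenate(pooled_m)
        all_e = np.concatenate(pooled_e)
        pooled = stats.pearsonr(all_m, all_e)
        pooled_r, pooled_p = float(pooled.statistic), float(pooled.pvalue)
        meth_density = {
            "hypo_frac": float((all_m <= 20).mean()),
            "intermediate_frac": float(((all_m > 20) & (all_m < 80)).mean()),
            "hyper_frac": float((all_m >= 80).mean()),
        }
        expr_density = {
            "q25": float(np.quantile(all_e, 0.25)),
            "median": float(np.quantile(all_e, 0.5)),
            "q75": float(np.quantile(all_e, 0.75)),
        }
    else:
        pooled_r = pooled_p = float("nan")
        meth_density = {}
        expr_density = {}

    report.update(
        {
            "n_gsm": int((results["class"] != "candidate").sum()),
            "n_gsm_high": int((results["class"] == "gsm_high").sum()),
            "pooled_r": pooled_r,
            "pooled_p": pooled_p,
            "log_transform": log_transform,
            "methylation_density": meth_density,
            "expression_density": expr_density,
        }
    )
    return results, report


def write_gsm_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False, na_rep="NA")
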