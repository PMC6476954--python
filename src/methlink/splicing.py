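"""Exon inclusion ratio (psi) estimation and switch-like exon detection.

For a cassette (skipped) exon, inclusion is supported by two splice
junctions (upstream and downstream of the exon) and skipping by one, so
with I = IJC_up + IJC_dn inclusion-junction reads and S skipping-junction
reads the inclusion ratio is

    psi = (I/2) / (I/2 + S)

Cells with fewer than 10 supporting junction reads are treated as missing.
A switch-like exon is near-completely included in one tissue (psi >= 0.7)
and near-completely skipped in another (psi <= 0.3).  Differential exon
usage (DEU) between two conditions is tested by Fisher's exact test on the
rounded (inclusion events, skipping events) table with BH control.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from methlink.diffmeth import bh_adjust, fisher_exact_many

JUNCTION_COLUMNS = [
    "event_id", "gene_id", "chrom", "exon_start", "exon_end", "strand",
    "tissue", "ijc_up", "ijc_dn", "sjc",
]


def read_junction_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(JUNCTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing junction columns {sorted(missing)}")
    return df


def write_junction_counts(df: pd.DataFrame, path: str | Path) -> None:
    df[JUNCTION_COLUMNS].to_csv(path, sep="\t", index=False)


def compute_psi(ijc_up, ijc_dn, sjc):
    """Inclusion ratio psi = (I/2) / (I/2 + S); NaN where I + S = 0.

    Accepts scalars or arrays.  Invariant to scaling all three counts by a
    common positive factor.
    """
    up = np.asarray(ijc_up, dtype=float)
    dn = np.asarray(ijc_dn, dtype=float)
    s = np.asarray(sjc, dtype=float)
    if (up < 0).any() or (dn < 0).any() or (s < 0).any():
        raise ValueError("junction counts must be non-negative")
    inc = (up + dn) / 2.0
    denom = inc + s
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(denom > 0, inc / denom, np.nan)
    return float(psi) if psi.ndim == 0 else psi


@dataclass
class PsiMatrix:
    """events x tissues inclusion ratios with junction coverage."""

    psi: pd.DataFrame       # in [0, 1], NaN for missing
    coverage: pd.DataFrame  # I + S junction reads per cell

    def to_tsv(self, path: str | Path) -> None:
        self.psi.to_csv(path, sep="\t", na_rep="NA", index_label="event_id")


def build_psi_matrix(junctions: pd.DataFrame, min_reads: int = 10) -> PsiMatrix:
    """Pivot long junction counts into a coverage-filtered psi matrix.

    A cell is missing when its total junction coverage I + S is below
    ``min_reads``; events missing in every tissue are dropped.  Idempotent
    in the sense that re-filtering the surviving counts changes nothing.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    df = junctions.copy()
    df["_cov"] = df["ijc_up"] + df["ijc_dn"] + df["sjc"]
    df["_psi"] = compute_psi(df["ijc_up"], df["ijc_dn"], df["sjc"])
    psi = df.pivot_table(index="event_id", columns="tissue", values="_psi", sort=True)
    cov = (
        df.pivot_table(index="event_id", columns="tissue", values="_cov", sort=True)
        .fillna(0)
        .astype(int)
    )
    psi = psi.where(cov >= min_reads)
    keep = psi.notna().any(axis=1)
    return PsiMatrix(psi[keep], cov[keep])


def detect_switch_like(
    psi: pd.DataFrame, low: float = 0.3, high: float = 0.7
) -> list[str]:
    """Events with psi <= ``low`` in one tissue and >= ``high`` in another.

    Both thresholds are inclusive; missing cells are ignored.  Monotone:
    widening the thresholds never removes a flagged event.
    """
    if not low < high:
        raise ValueError("require low < high")
    has_low = (psi <= low).any(axis=1)
    has_high = (psi >= high).any(axis=1)
    return list(psi.index[has_low & has_high])


def _round_half_even(x: np.ndarray) -> np.ndarray:
    return np.rint(x).astype(np.int64)


def deu_test(
    junctions: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    min_reads: int = 10,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Differential exon usage between two conditions (tissues).

    Per event, a two-sided Fisher's exact test on the 2x2 table
    ``[round(I_a/2), S_a; round(I_b/2), S_b]`` (round half to even), over
    events passing the junction-coverage filter in both conditions.
    Returns one row per tested event with psi in each condition, p and the
    BH q; ``significant`` marks q <= ``q_max``.
    """
    sub = junctions[junctions["tissue"].isin([condition_a, condition_b])]
    wide = sub.pivot_table(
        index="event_id", columns="tissue",
        values=["ijc_up", "ijc_dn", "sjc"], sort=True,
    )
    for cond in (condition_a, condition_b):
        if ("sjc", cond) not in wide.columns:
            raise ValueError(f"condition {cond!r} absent from junction table")
    ia = wide[("ijc_up", condition_a)].fillna(0) + wide[("ijc_dn", condition_a)].fillna(0)
    ib = wide[("ijc_up", condition_b)].fillna(0) + wide[("ijc_dn", condition_b)].fillna(0)
    sa = wide[("sjc", condition_a)].fillna(0)
    sb = wide[("sjc", condition_b)].fillna(0)
    cov_ok = ((ia + sa) >= min_reads) & ((ib + sb) >= min_reads)
    ia, ib, sa, sb = ia[cov_ok], ib[cov_ok], sa[cov_ok], sb[cov_ok]
    inc_a = _round_half_even(ia.to_numpy() / 2.0)
    inc_b = _round_half_even(ib.to_numpy() / 2.0)
    p = fisher_exact_many(
        inc_a, sa.to_numpy(dtype=np.int64), inc_b, sb.to_numpy(dtype=np.int64)
    )
    q = bh_adjust(p)
    with np.errstate(invalid="ignore", divide="ignore"):
        psi_a = np.where(ia + sa > 0, (ia / 2) / (ia / 2 + sa), np.nan)
        psi_b = np.where(ib + sb > 0, (ib / 2) / (ib / 2 + sb), np.nan)
    out = pd.DataFrame(
        {
            "event_id": ia.index,
            "psi_a": psi_a,
            "psi_b": psi_b,
            "delta_psi": psi_b - psi_a,
            "p": p,
            "q": q,
            "significant": q <= q_max,
        }
    ).reset_index(drop=True)
    return out
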