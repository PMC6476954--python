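"""Bisulfite site-call handling and CGI methylation quantification.

Site calls are held in a pandas DataFrame with columns
``chrom, pos, strand, context, n_meth, n_unmeth`` (``pos`` 0-based).  A CGI's
representative methylation is the median of the per-site percent levels of
the depth-filtered CpG sites inside it; CGIs are assembled into a
CGI x tissue :class:`MethylationMatrix` with explicit missing values.

Calls on the two strands of a CpG dinucleotide are kept as separate sites by
default; :func:`merge_strands` provides the optional collapsed view.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from methlink.annotation import CpGIsland, GeneModel

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]

#: sentinel written for missing matrix cells
NA_REP = "NA"


def _empty_sites() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "context": pd.Series(dtype=str),
            "n_meth": pd.Series(dtype=np.int64),
            "n_unmeth": pd.Series(dtype=np.int64),
        }
    )


def parse_site_calls(path: str | Path) -> pd.DataFrame:
    """Parse per-cytosine bisulfite calls.

    Two tab-separated formats are recognised by column count:

    * 6 columns, Bismark coverage style: chrom, start (1-based), end,
      methylation %, count methylated, count unmethylated.  Context is
      assumed CpG.
    * 7 columns, cytosine-report style: chrom, pos (1-based), strand,
      count methylated, count unmethylated, context, trinucleotide.

    Returns a DataFrame with :data:`SITE_COLUMNS`; positions are converted
    to 0-based.  A warning is issued when the percent column disagrees with
    the counts by more than 0.5; negative counts raise ``ValueError``.
    """
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return _empty_sites()
    if raw.shape[1] == 6:
        df = pd.DataFrame(
            {
                "chrom": raw[0].astype(str),
                "pos": raw[1].astype(np.int64) - 1,
                "strand": ".",
                "context": "CpG",
                "n_meth": raw[4].astype(np.int64),
                "n_unmeth": raw[5].astype(np.int64),
            }
        )
        depth = df["n_meth"] + df["n_unmeth"]
        with np.errstate(invalid="ignore", divide="ignore"):
            implied = 100.0 * df["n_meth"] / depth
        stated = raw[3].astype(float)
        bad = (depth > 0) & (np.abs(implied - stated) > 0.5)
        if bad.any():
            warnings.warn(
                f"{path}: {int(bad.sum())} line(s) have a percent column inconsistent "
                "with the counts by > 0.5"
            )
    elif raw.shape[1] == 7:
        df = pd.DataFrame(
            {
                "chrom": raw[0].astype(str),
                "pos": raw[1].astype(np.int64) - 1,
                "strand": raw[2].astype(str),
                "context": raw[5].astype(str),
                "n_meth": raw[3].astype(np.int64),
                "n_unmeth": raw[4].astype(np.int64),
            }
        )
    else:
        raise ValueError(f"{path}: expected 6 or 7 columns, got {raw.shape[1]}")
    if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
        raise ValueError(f"{path}: negative methylation counts")
    return df


def write_site_calls(sites: pd.DataFrame, path: str | Path) -> None:
    """Write site calls in the 6-column Bismark coverage format."""
    depth = (sites["n_meth"] + sites["n_unmeth"]).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(depth > 0, 100.0 * sites["n_meth"].to_numpy() / depth, 0.0)
    out = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["pos"] + 1,
            "end": sites["pos"] + 1,
            "pct": np.round(pct, 6),
            "n_meth": sites["n_meth"],
            "n_unmeth": sites["n_unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def site_depth(sites: pd.DataFrame) -> pd.Series:
    return sites["n_meth"] + sites["n_unmeth"]


def site_levels(sites: pd.DataFrame) -> pd.Series:
    """Percent methylation per site, NaN where depth is zero."""
    depth = site_depth(sites)
    with np.errstate(invalid="ignore", divide="ignore"):
        lev = 100.0 * sites["n_meth"] / depth
    return lev.where(depth > 0)


def filter_sites_by_depth(sites: pd.DataFrame, min_depth: int = 10) -> pd.DataFrame:
    """Retain sites with total read depth >= ``min_depth`` (idempotent)."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    return sites[site_depth(sites) >= min_depth].reset_index(drop=True)


def merge_strands(sites: pd.DataFrame) -> pd.DataFrame:
    """Collapse +/- strand CpG calls at a dinucleotide into one site.

    A - strand call at position p is attributed to the + strand cytosine at
    p - 1; counts are summed.  Non-CpG contexts are passed through unchanged.
    """
    cpg = sites[sites["context"] == "CpG"].copy()
    other = sites[sites["context"] != "CpG"]
    minus = cpg["strand"] == "-"
    cpg.loc[minus, "pos"] = cpg.loc[minus, "pos"] - 1
    grouped = (
        cpg.groupby(["chrom", "pos"], as_index=False, sort=True)
        .agg(n_meth=("n_meth", "sum"), n_unmeth=("n_unmeth", "sum"))
        .assign(strand="+", context="CpG")
    )
    return pd.concat([grouped[SITE_COLUMNS], other], ignore_index=True)


def qc_filter_samples(
    samples: Mapping[str, pd.DataFrame], min_mean_depth: float = 10.0
) -> tuple[list[str], pd.DataFrame]:
    """Drop samples whose mean CpG site depth is below ``min_mean_depth``.

    Returns the retained sample names (input order) and a per-sample report
    with columns ``sample, n_sites, mean_depth, retained``.
    """
    if not samples:
        raise ValueError("need at least one sample")
    rows = []
    kept: list[str] = []
    for name, sites in samples.items():
        cpg = sites[sites["context"] == "CpG"]
        n = len(cpg)
        if n == 0:
            warnings.warn(f"sample {name!r} has no CpG sites; dropped")
            rows.append((name, 0, float("nan"), False))
            continue
        mean_depth = float(site_depth(cpg).mean())
        retained = mean_depth >= min_mean_depth
        if retained:
            kept.append(name)
        rows.append((name, n, mean_depth, retained))
    report = pd.DataFrame(rows, columns=["sample", "n_sites", "mean_depth", "retained"])
    return kept, report


def _sites_in_interval(sites: pd.DataFrame, chrom: str, start: int, end: int) -> pd.DataFrame:
    mask = (sites["chrom"] == chrom) & (sites["pos"] >= start) & (sites["pos"] < end)
    return sites[mask]


def quantify_cgi(sites: pd.DataFrame, cgi: CpGIsland, min_sites: int = 1) -> float:
    """Median percent methylation of CpG sites within one CGI.

    ``sites`` should already be depth-filtered.  Returns NaN when fewer than
    ``min_sites`` qualifying CpG sites fall inside the island.  An even site
    count yields the mean of the two central values.
    """
    iv = cgi.interval
    sub = _sites_in_interval(sites, iv.chrom, iv.start, iv.end)
    sub = sub[sub["context"] == "CpG"]
    levels = site_levels(sub).dropna()
    if len(levels) < max(1, min_sites):
        return float("nan")
    return float(np.median(levels.to_numpy()))


@dataclass
class MethylationMatrix:
    """CGI x tissue percent-methylation with explicit missing values.

    ``values`` holds percentages in [0, 100] with NaN for missing;
    ``n_sites`` the per-cell supporting CpG site count.
    """

    values: pd.DataFrame
    n_sites: pd.DataFrame

    def __post_init__(self) -> None:
        self.values.index.name = "cgi_id"
        self.n_sites.index.name = "cgi_id"
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("methylation values must lie in [0, 100]")

    def complete_cases(self) -> "MethylationMatrix":
        """Restrict to CGIs quantified in every tissue ("without missing data")."""
        keep = self.values.notna().all(axis=1)
        return MethylationMatrix(self.values[keep], self.n_sites[keep])

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", na_rep=NA_REP, index_label="cgi_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MethylationMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_REP])
        n_sites = values.notna().astype(int)
        return cls(values, n_sites)


def _assign_sites_to_cgis(
    sites: pd.DataFrame, cgis: Sequence[CpGIsland]
) -> np.ndarray:
    """Index of the containing CGI per site (-1 if none).

    CGIs must be non-overlapping (as in UCSC cpgIslandExt annotations).
    """
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, cgi in enumerate(cgis):
        by_chrom.setdefault(cgi.interval.chrom, []).append(
            (cgi.interval.start, cgi.interval.end, idx)
        )
    out = np.full(len(sites), -1, dtype=np.int64)
    pos_all = sites["pos"].to_numpy()
    chrom_all = sites["chrom"].to_numpy()
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = np.array([s for s, _e, _i in ivs])
        ends = np.array([e for _s, e, _i in ivs])
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping CGIs on {chrom}; CGI annotation must be disjoint")
        idxs = np.array([i for _s, _e, i in ivs])
        mask = chrom_all == chrom
        pos = pos_all[mask]
        slot = np.searchsorted(starts, pos, side="right") - 1
        ok = (slot >= 0) & (pos < ends[np.clip(slot, 0, len(ends) - 1)])
        res = np.where(ok, idxs[np.clip(slot, 0, len(idxs) - 1)], -1)
        out[np.flatnonzero(mask)] = res
    return out


def build_methylation_matrix(
    samples: Mapping[str, pd.DataFrame],
    cgis: Sequence[CpGIsland],
    min_sites: int = 1,
    complete_cases: bool = False,
) -> MethylationMatrix:
    """Quantify every CGI in every tissue into a :class:`MethylationMatrix`.

    Each cell is the median per-site CpG methylation level of that tissue's
    (already depth-filtered) sites inside the CGI, or NaN when fewer than
    ``min_sites`` sites support it.  ``complete_cases=True`` drops CGIs with
    any missing cell.
    """
    if not samples:
        raise ValueError("need at least one sample")
    cgi_ids = [c.cgi_id for c in cgis]
    values = pd.DataFrame(np.nan, index=cgi_ids, columns=list(samples), dtype=float)
    counts = pd.DataFrame(0, index=cgi_ids, columns=list(samples), dtype=int)
    for name, sites in samples.items():
        cpg = sites[sites["context"] == "CpG"]
        assign = _assign_sites_to_cgis(cpg, cgis)
        levels = site_levels(cpg).to_numpy(dtype=float)
        ok = (assign >= 0) & np.isfinite(levels)
        sub = pd.DataFrame({"cgi": assign[ok], "level": levels[ok]})
        med = sub.groupby("cgi")["level"].median()
        n = sub.groupby("cgi")["level"].size()
        enough = n[n >= max(1, min_sites)].index
        col_vals = values[name].to_numpy()
        col_vals[med.loc[enough].index.to_numpy()] = med.loc[enough].to_numpy()
        values[name] = col_vals
        col_counts = counts[name].to_numpy()
        col_counts[n.index.to_numpy()] = n.to_numpy()
        counts[name] = col_counts
    matrix = MethylationMatrix(values, counts)
    return matrix.complete_cases() if complete_cases else matrix


def classify_state(level: float, hypo_max: float = 20.0, hyper_min: float = 80.0) -> str:
    """Classify a percent level as ``hypo``, ``intermediate`` or ``hyper``.

    Boundaries are inclusive: hypo iff level <= hypo_max, hyper iff
    level >= hyper_min.
    """
    if hypo_max >= hyper_min:
        raise ValueError("hypo_max must be < hyper_min")
    if not 0 <= level <= 100:
        raise ValueError("level must lie in [0, 100]")
    if level <= hypo_max:
        return "hypo"
    if level >= hyper_min:
        return "hyper"
    return "intermediate"


@dataclass
class TrendProfile:
    """TSS/TES-anchored methylation meta-profile.

    ``bin_labels`` runs upstream flank -> length-normalised gene body ->
    downstream flank in 5'->3' gene orientation; ``mean`` is the mean site
    level per bin (NaN where no sites) and ``n_sites`` the site count.
    """

    bin_labels: list[str]
    mean: np.ndarray
    n_sites: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin": self.bin_labels, "mean_level": self.mean, "n_sites": self.n_sites}
        )


def methylation_trend(
    sites: pd.DataFrame,
    genes: Iterable[GeneModel],
    flank_bp: int = 2000,
    n_flank_bins: int = 20,
    n_body_bins: int = 40,
) -> TrendProfile:
    """Mean methylation in strand-oriented bins around and along gene bodies.

    Flank bins are fixed-width (``flank_bp / n_flank_bins``); gene-body bins
    are fractional (length-normalised).  Sites outside every window are
    ignored; a site in the window of several genes contributes to each.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("genes must be non-empty")
    if n_flank_bins < 1 or n_body_bins < 1:
        raise ValueError("bin counts must be >= 1")
    n_bins = 2 * n_flank_bins + n_body_bins
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    cpg = sites[sites["context"] == "CpG"]
    levels_all = site_levels(cpg).to_numpy()
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in cpg.assign(_lev=levels_all).groupby("chrom"):
        order = np.argsort(sub["pos"].to_numpy(), kind="stable")
        by_chrom[str(chrom)] = (
            sub["pos"].to_numpy()[order],
            sub["_lev"].to_numpy()[order],
        )

    for gene in genes:
        chrom = gene.interval.chrom
        if chrom not in by_chrom:
            continue
        pos, lev = by_chrom[chrom]
        g0, g1 = gene.interval.start, gene.interval.end
        lo = np.searchsorted(pos, g0 - flank_bp, side="left")
        hi = np.searchsorted(pos, g1 + flank_bp, side="left")
        if lo == hi:
            continue
        p = pos[lo:hi]
        lv = lev[lo:hi]
        ok = np.isfinite(lv)
        p, lv = p[ok], lv[ok]
        if p.size == 0:
            continue
        # orient relative to the gene: "before" = upstream of the TSS
        if gene.strand == "+":
            before = p < g0
            after = p >= g1
            frac = (p - g0) / (g1 - g0)
        else:
            before = p >= g1  # upstream of a - gene lies at higher coordinates
            after = p < g0
            frac = (g1 - 1 - p) / (g1 - g0)
        body = ~(before | after)

        bin_idx = np.full(p.size, -1, dtype=np.int64)
        width = flank_bp / n_flank_bins
        if gene.strand == "+":
            upstream_pos = (p[before] - (g0 - flank_bp)) / width
            downstream_pos = (p[after] - g1) / width
        else:
            upstream_pos = ((g1 + flank_bp - 1) - p[before]) / width
            downstream_pos = ((g0 - 1) - p[after]) / width
        bin_idx[before] = np.clip(upstream_pos.astype(np.int64), 0, n_flank_bins - 1)
        bin_idx[body] = n_flank_bins + np.clip(
            (frac[body] * n_body_bins).astype(np.int64), 0, n_body_bins - 1
        )
        bin_idx[after] = (
            n_flank_bins
            + n_body_bins
            + np.clip(downstream_pos.astype(np.int64), 0, n_flank_bins - 1)
        )
        np.add.at(sums, bin_idx, lv)
        np.add.at(counts, bin_idx, 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / counts, np.nan)
    labels = (
        [f"up_{i}" for i in range(n_flank_bins)]
        + [f"body_{i}" for i in range(n_body_bins)]
        + [f"down_{i}" for i in range(n_flank_bins)]
    )
    return TrendProfile(labels, mean, counts)


def write_bedgraph(sites: pd.DataFrame, path: str | Path) -> None:
    """Export per-site levels as bedGraph (chrom, start, end, level)."""
    levels = site_levels(sites)
    out = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["pos"],
            "end": sites["pos"] + 1,
            "level": np.round(levels.to_numpy(), 6),
        }
    ).dropna()
    out.to_csv(path, sep="\t", header=False, index=False)
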