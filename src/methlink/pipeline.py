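"""End-to-end driver chaining all analysis stages over one dataset directory.

Stages communicate through files in the output directory, so a completed
stage can be skipped on resume and the rerun output is bit-for-bit equal to
a fresh run.  The run report collects per-stage counters, the full
configuration, its hash and the seed.

Expected dataset layout (as produced by :func:`methlink.simulate.write_dataset`):
``annotation.gtf``, ``cgis.bed``, ``methylomes/*.cov``, ``fpkm.tsv``,
``junctions.tsv``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from methlink import annotation as ann
from methlink import diffmeth, expression, gsm, netcluster, splicing
from methlink import methylation as meth

STAGE_ORDER = [
    "units", "methylation", "diffmeth", "expression", "splicing", "gsm", "netcluster",
]


class ValidationError(ValueError):
    """Invalid configuration or unreadable inputs (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All thresholds of the pipeline; defaults are the standard screen settings."""

    data_dir: str = "."
    out_dir: str = "results"
    min_depth: int = 10           # per-site coverage filter
    min_mean_depth: float = 10.0  # sample-level QC
    min_sites: int = 1            # CpG sites required per CGI cell
    upstream_bp: int = 2000       # promoter span upstream of the TSS
    min_row_sum: float = 3.0      # FPKM row-sum expression filter
    fold_change: float = 16.0     # TSG selection fold change
    pseudocount: float = 1.0
    k: int = 12                   # TSG clusters
    psi_low: float = 0.3          # switch-like exon thresholds (inclusive)
    psi_high: float = 0.7
    min_junction_reads: int = 10
    q_max: float = 0.05           # BH FDR for DMS and DEU screens
    min_diff: float = 0.0         # optional methylation-difference cutoff
    gsm_p: float = 0.05
    gsm_hard_p: float = 0.001
    min_tissues: int = 8
    log_transform: bool = True
    r_min: float = 0.85           # methylation network edge threshold
    inflation: float = 1.3        # MCL inflation
    deu_condition_a: str = "T03"
    deu_condition_b: str = "T04"
    run_dms: bool = True          # the all-pairs DMS screen is the slowest stage
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_depth < 1 or self.min_junction_reads < 1:
            raise ValidationError("coverage thresholds must be >= 1")
        if not (0 < self.q_max <= 1 and 0 < self.gsm_p <= 1 and 0 < self.gsm_hard_p <= 1):
            raise ValidationError("significance thresholds must lie in (0, 1]")
        if not self.psi_low < self.psi_high:
            raise ValidationError("psi_low must be < psi_high")
        if not -1.0 <= self.r_min < 1.0:
            raise ValidationError("r_min must lie in [-1, 1)")
        if self.inflation <= 1.0:
            raise ValidationError("inflation must be > 1")
        if self.k < 1 or self.min_tissues < 3:
            raise ValidationError("k must be >= 1 and min_tissues >= 3")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _coverage_files(data_dir: Path) -> dict[str, Path]:
    meth_dir = data_dir / "methylomes"
    if not meth_dir.is_dir():
        raise FileNotFoundError(f"no methylomes/ directory under {data_dir}")
    files = sorted(meth_dir.glob("*.cov"))
    return {p.stem: p for p in files}


def _load_units(path: Path) -> list[ann.CgiGeneUnit]:
    df = pd.read_csv(path, sep="\t")
    return [
        ann.CgiGeneUnit(
            row.cgi_id,
            row.gene_id,
            ann.GenomicInterval(row.chrom, row.promoter_start, row.promoter_end, row.strand),
            int(row.overlap_bp),
        )
        for row in df.itertuples()
    ]


def stage_units(cfg: RunConfig, out: Path) -> dict:
    genes = ann.load_gene_models(Path(cfg.data_dir) / "annotation.gtf")
    cgis = ann.load_cgis(Path(cfg.data_dir) / "cgis.bed")
    units = ann.map_cgis_to_genes(cgis, genes, upstream_bp=cfg.upstream_bp)
    rows = [
        (u.cgi_id, u.gene_id, u.promoter.chrom, u.promoter.start, u.promoter.end,
         u.promoter.strand, u.overlap_bp)
        for u in units
    ]
    pd.DataFrame(
        rows,
        columns=["cgi_id", "gene_id", "chrom", "promoter_start", "promoter_end",
                 "strand", "overlap_bp"],
    ).to_csv(out / "units.tsv", sep="\t", index=False)
    return {"n_genes": len(genes), "n_cgis": len(cgis), "n_units": len(units)}


def stage_methylation(cfg: RunConfig, out: Path) -> dict:
    files = _coverage_files(Path(cfg.data_dir))
    if not files:
        raise ValueError("empty methylome input: no .cov files found")
    samples = {name: meth.parse_site_calls(path) for name, path in files.items()}
    n_sites_read = {name: len(df) for name, df in samples.items()}
    kept, qc = meth.qc_filter_samples(samples, min_mean_depth=cfg.min_mean_depth)
    if not kept:
        raise ValueError("all samples failed the mean-depth QC")
    filtered = {
        name: meth.filter_sites_by_depth(samples[name], cfg.min_depth) for name in kept
    }
    cgis = ann.load_cgis(Path(cfg.data_dir) / "cgis.bed")
    matrix = meth.build_methylation_matrix(filtered, cgis, min_sites=cfg.min_sites)
    qc.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    matrix.to_tsv(out / "methylation_matrix.tsv")
    return {
        "n_samples": len(samples),
        "n_samples_retained": len(kept),
        "samples_dropped": sorted(set(samples) - set(kept)),
        "n_sites_read": sum(n_sites_read.values()),
        "n_sites_after_depth_filter": int(sum(len(df) for df in filtered.values())),
        "n_cgis_quantified_somewhere": int(matrix.values.notna().any(axis=1).sum()),
    }


def stage_diffmeth(cfg: RunConfig, out: Path) -> dict:
    if not cfg.run_dms:
        pd.DataFrame(columns=["source", "target", "weight"]).to_csv(
            out / "dms_edges.tsv", sep="\t", index=False
        )
        return {"skipped": True}
    files = _coverage_files(Path(cfg.data_dir))
    qc = pd.read_csv(out / "qc_report.tsv", sep="\t")
    kept = list(qc[qc["retained"]]["sample"])
    samples = {name: meth.parse_site_calls(files[name]) for name in kept}
    matrix, edges = diffmeth.dms_count_matrix(
        samples, q_max=cfg.q_max, min_depth=cfg.min_depth, min_diff=cfg.min_diff
    )
    matrix.to_csv(out / "dms_matrix.tsv", sep="\t", index_label="tissue")
    edges.to_csv(out / "dms_edges.tsv", sep="\t", index=False)
    return {
        "n_tissues": len(kept),
        "n_pairs": len(edges),
        "dms_total": int(edges["weight"].sum()),
        "dms_min": int(edges["weight"].min()) if len(edges) else 0,
        "dms_max": int(edges["weight"].max()) if len(edges) else 0,
    }


def stage_expression(cfg: RunConfig, out: Path) -> dict:
    fpkm = expression.read_fpkm(Path(cfg.data_dir) / "fpkm.tsv")
    filtered = expression.filter_low_expression(fpkm, cfg.min_row_sum)
    filtered.to_csv(out / "expression_filtered.tsv", sep="\t", index_label="gene_id")
    r, _p = expression.tissue_correlation(filtered)
    r.round(8).to_csv(out / "tissue_correlation_r.tsv", sep="\t", index_label="tissue")
    tsg = expression.select_tsg(filtered, cfg.fold_change, cfg.pseudocount)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z = expression.zscore_rows(filtered.loc[tsg])
    z.round(8).to_csv(out / "tsg_zscores.tsv", sep="\t", index_label="gene_id")
    counters = {
        "n_genes": len(fpkm),
        "n_genes_after_filter": len(filtered),
        "n_tsg": len(tsg),
    }
    if len(z) >= cfg.k:
        clustering = expression.cluster_tsg(z, k=cfg.k, seed=cfg.seed)
        clustering.to_tsv(out / "tsg_clusters.tsv")
        counters["n_tsg_clusters"] = int(clustering.labels.nunique())
        counters["cluster_sizes"] = clustering.cluster_sizes.to_dict()
    else:
        counters["n_tsg_clusters"] = 0
    return counters


def stage_splicing(cfg: RunConfig, out: Path) -> dict:
    junctions = splicing.read_junction_counts(Path(cfg.data_dir) / "junctions.tsv")
    psi = splicing.build_psi_matrix(junctions, min_reads=cfg.min_junction_reads)
    psi.to_tsv(out / "psi_matrix.tsv")
    switch = splicing.detect_switch_like(psi.psi, low=cfg.psi_low, high=cfg.psi_high)
    pd.DataFrame({"event_id": switch}).to_csv(
        out / "switch_candidates.tsv", sep="\t", index=False
    )
    counters = {
        "n_events": int(psi.psi.shape[0]),
        "n_switch_like": len(switch),
    }
    tissues = set(junctions["tissue"])
    if {cfg.deu_condition_a, cfg.deu_condition_b} <= tissues:
        deu = splicing.deu_test(
            junctions, cfg.deu_condition_a, cfg.deu_condition_b,
            min_reads=cfg.min_junction_reads, q_max=cfg.q_max,
        )
        deu.round(10).to_csv(out / "deu_results.tsv", sep="\t", index=False, na_rep="NA")
        counters["n_deu_tested"] = len(deu)
        counters["n_deu_significant"] = int(deu["significant"].sum())
    return counters


def stage_gsm(cfg: RunConfig, out: Path) -> dict:
    matrix = meth.MethylationMatrix.from_tsv(out / "methylation_matrix.tsv")
    expr = expression.read_fpkm(out / "expression_filtered.tsv")
    units = _load_units(out / "units.tsv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results, report = gsm.gsm_screen(
            matrix, expr, units,
            min_tissues=cfg.min_tissues, p_max=cfg.gsm_p,
            hard_p_max=cfg.gsm_hard_p, log_transform=cfg.log_transform,
        )
    gsm.write_gsm_results(results.round(10), out / "gsm_results.tsv")
    return report


def stage_netcluster(cfg: RunConfig, out: Path) -> dict:
    matrix = meth.MethylationMatrix.from_tsv(out / "methylation_matrix.tsv")
    units = pd.read_csv(out / "units.tsv", sep="\t")
    unit_cgis = [c for c in units["cgi_id"].unique() if c in matrix.values.index]
    profiles = matrix.values.loc[unit_cgis]
    profiles = profiles[profiles.notna().sum(axis=1) >= 3]
    graph = netcluster.build_correlation_graph(profiles, r_min=cfg.r_min)
    netcluster.write_edge_list(graph, out / "network_edges.tsv")
    counters = {
        "n_candidate_profiles": int(len(profiles)),
        "n_network_nodes": graph.number_of_nodes(),
        "n_network_edges": graph.number_of_edges(),
    }
    if graph.number_of_nodes():
        labels, converged = netcluster.mcl_cluster(graph, inflation=cfg.inflation)
        netcluster.write_clusters(labels, out / "network_clusters.tsv")
        counters["n_network_clusters"] = len(set(labels.values()))
        counters["mcl_converged"] = bool(converged)
    else:
        counters["n_network_clusters"] = 0
    return counters


_STAGE_FUNCS = {
    "units": stage_units,
    "methylation": stage_methylation,
    "diffmeth": stage_diffmeth,
    "expression": stage_expression,
    "splicing": stage_splicing,
    "gsm": stage_gsm,
    "netcluster": stage_netcluster,
}

# primary outputs per stage, used for resume detection
_STAGE_OUTPUTS = {
    "units": ["units.tsv"],
    "methylation": ["methylation_matrix.tsv", "qc_report.tsv"],
    "diffmeth": ["dms_edges.tsv"],
    "expression": ["expression_filtered.tsv", "tsg_zscores.tsv"],
    "splicing": ["psi_matrix.tsv", "switch_candidates.tsv"],
    "gsm": ["gsm_results.tsv"],
    "netcluster": ["network_edges.tsv"],
}


def run_pipeline(cfg: RunConfig, resume: bool = False) -> dict:
    """Execute all stages in dependency order and write ``report.json``.

    On a stage failure the partial outputs are kept, a ``FAILED`` marker
    naming the stage is written, and :class:`StageError` is raised.  With
    ``resume=True`` stages whose outputs already exist are skipped.
    """
    data_dir = Path(cfg.data_dir)
    if not data_dir.is_dir():
        raise ValidationError(f"data directory {data_dir} does not exist")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": cfg.to_dict(),
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "stages": {},
    }
    for stage in STAGE_ORDER:
        outputs = [out / f for f in _STAGE_OUTPUTS[stage]]
        if resume and all(p.exists() for p in outputs):
            report["stages"][stage] = {"resumed": True}
            continue
        try:
            report["stages"][stage] = _STAGE_FUNCS[stage](cfg, out)
        except Exception as exc:  # noqa: BLE001 - converted to a stage failure
            (out / "FAILED").write_text(f"{stage}: {exc}\n")
            raise StageError(stage, exc) from exc
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
    return report
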