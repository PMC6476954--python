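"""Seeded synthetic datasets with known ground truth.

Emulates a 20-tissue paired methylome/transcriptome design: RRBS-style
CpG site counts clustered inside CpG islands (Poisson depth, binomial
methylation calls around a hypo/hyper bimodal beta mixture), an FPKM
matrix with planted negatively coupled CGI-gene units (the silencing
link ``log2(FPKM+1) = a - b * pi + noise``), planted tissue-specific gene
blocks, planted differentially methylated sites between two designated
tissues, and exon-skipping junction counts with planted switch-like and
differential-usage events.  A fixed number of tissues is simulated at low
coverage to exercise the sample-level depth QC.

Everything is driven by one integer seed; identical config + seed gives
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from methlink.annotation import (
    CgiGeneUnit,
    CpGIsland,
    GeneModel,
    GenomicInterval,
    write_cgis_bed,
    write_gene_models_gtf,
)
from methlink.methylation import SITE_COLUMNS, write_site_calls
from methlink.splicing import JUNCTION_COLUMNS, write_junction_counts

# rng stream ids per stage, so each stage is reproducible in isolation
_STREAM_ANNOTATION = 1
_STREAM_METHYLOME = 2
_STREAM_EXPRESSION = 3
_STREAM_JUNCTIONS = 4


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study design (defaults: full-scale run)."""

    n_genes: int = 3400
    n_cgis: int = 4000
    cgi_promoter_fraction: float = 0.75
    n_tissues: int = 20
    n_low_depth_tissues: int = 6      # simulated below the 10x mean-depth QC bar
    mean_depth: float = 12.0          # CpG read depth of qualifying tissues
    low_depth_mean: float = 5.0
    # beta mixture for per-CGI baseline methylation: hypo, hyper, mid components
    beta_hypo: tuple[float, float] = (1.0, 12.0)
    beta_hyper: tuple[float, float] = (12.0, 1.5)
    beta_mid: tuple[float, float] = (20.0, 20.0)
    mixture_weights: tuple[float, float, float] = (0.6, 0.3, 0.1)
    tissue_jitter_sd: float = 0.02    # tissue-to-tissue wobble of null CGIs
    site_jitter_sd: float = 0.03      # site-to-site wobble within a CGI
    # planted gene-silencing methylations
    n_planted_gsms: int = 120
    coupling_slope: float = 6.0       # log2 units per methylation fraction
    coupling_intercept: float = 8.0
    expression_noise_sd: float = 1.17  # gives true |r| ~ 0.8 for planted units
    # non-planted expression
    null_log_mean: float = 3.0
    null_log_sd: float = 1.5
    null_tissue_sd: float = 0.6
    # tissue-specific gene blocks
    n_tsg_clusters: int = 12
    tsg_block_size: tuple[int, int] = (60, 200)
    tsg_spike_log2fc: float = 6.0
    # RRBS site layout
    sites_per_cgi: tuple[int, int] = (8, 14)
    n_background_sites: int = 2000
    # planted differential methylation between the designated tissue pair
    n_planted_dms: int = 50
    dms_low: float = 0.1
    dms_effect: float = 0.8
    # splicing
    n_skipping_events: int = 1000
    n_planted_switch_exons: int = 50
    n_planted_deu: int = 30
    deu_delta: float = 0.6
    junction_depth_mean: float = 100.0
    switch_low_range: tuple[float, float] = (0.02, 0.15)
    switch_high_range: tuple[float, float] = (0.85, 0.98)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_cgis, self.n_tissues) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.cgi_promoter_fraction <= 1.0:
            raise ValueError("cgi_promoter_fraction must lie in [0, 1]")
        if self.n_promoter_cgis > self.n_genes:
            raise ValueError("more promoter CGIs than genes")
        if self.n_planted_gsms > self.n_promoter_cgis:
            raise ValueError("more planted GSMs than promoter CGIs")
        if self.n_low_depth_tissues >= self.n_tissues:
            raise ValueError("n_low_depth_tissues must be < n_tissues")
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise ValueError("mixture_weights must sum to 1")

    @property
    def n_promoter_cgis(self) -> int:
        return round(self.cgi_promoter_fraction * self.n_cgis)

    @property
    def tissues(self) -> list[str]:
        return [f"T{i + 1:02d}" for i in range(self.n_tissues)]

    @property
    def low_depth_tissues(self) -> list[str]:
        return self.tissues[self.n_tissues - self.n_low_depth_tissues:] if self.n_low_depth_tissues else []

    @property
    def dms_pair(self) -> tuple[str, str]:
        return self.tissues[0], self.tissues[1]

    @property
    def deu_pair(self) -> tuple[str, str]:
        """Two full-depth conditions compared for differential exon usage."""
        return self.tissues[2], self.tissues[3]

    @classmethod
    def small(cls, seed: int = 0) -> "SimulationConfig":
        """A fast small-scale preset for smoke tests and determinism checks."""
        return cls(
            n_genes=300,
            n_cgis=360,
            n_planted_gsms=20,
            tsg_block_size=(8, 16),
            n_background_sites=300,
            n_planted_dms=20,
            n_skipping_events=150,
            n_planted_switch_exons=12,
            n_planted_deu=10,
            seed=seed,
        )

    @classmethod
    def full_scale(cls, seed: int = 0) -> "SimulationConfig":
        """The full 20-tissue study design (~3,000 CGI-gene units)."""
        return cls(seed=seed)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Planted signals of one synthetic dataset, resolvable against its files."""

    planted_gsm: list[tuple[str, str]] = field(default_factory=list)  # (cgi_id, gene_id)
    true_unit_r: dict[str, float] = field(default_factory=dict)       # cgi_id -> realized r
    pi: pd.DataFrame | None = None            # latent CGI x tissue methylation fraction
    dms_positions: list[tuple[str, int]] = field(default_factory=list)
    tsg_labels: dict[str, int] = field(default_factory=dict)          # gene -> block
    tsg_spike_tissue: dict[int, str] = field(default_factory=dict)    # block -> tissue
    planted_switch: list[str] = field(default_factory=list)
    switch_true_psi: pd.DataFrame | None = None  # planted events x tissues
    deu_events: list[str] = field(default_factory=list)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "planted_gsm": [list(t) for t in self.planted_gsm],
            "true_unit_r": self.true_unit_r,
            "dms_positions": [list(t) for t in self.dms_positions],
            "tsg_labels": self.tsg_labels,
            "tsg_spike_tissue": {str(k): v for k, v in self.tsg_spike_tissue.items()},
            "planted_switch": self.planted_switch,
            "deu_events": self.deu_events,
            "pi": None if self.pi is None else self.pi.round(8).to_dict(orient="index"),
            "switch_true_psi": None
            if self.switch_true_psi is None
            else self.switch_true_psi.round(8).to_dict(orient="index"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[list[GeneModel], list[CpGIsland], GroundTruth]:
    """Place genes and CGIs on synthetic chromosomes.

    Genes are packed without overlap with >= 6 kbp intergenic gaps; a
    configured fraction of CGIs is placed to intersect a distinct gene's
    promoter (these are GSM-eligible), the rest fall mid-gap away from all
    promoters.  Raises when the intergenic CGIs do not fit.
    """
    rng = _rng(config, _STREAM_ANNOTATION)
    n_chroms = max(1, round(config.n_genes / 200))
    per_chrom = [len(a) for a in np.array_split(np.arange(config.n_genes), n_chroms)]

    genes: list[GeneModel] = []
    gaps: list[tuple[str, int, int]] = []  # (chrom, gap_start, gap_end) between genes
    gidx = 0
    for ci, n_on_chrom in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        cursor = 3000
        prev_end = 0
        for _ in range(n_on_chrom):
            gap = int(rng.integers(6000, 12001))
            length = int(rng.integers(2000, 8001))
            start = cursor + gap
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(2, 7))
            span = np.arange(start + 50, end - 50)
            pts = np.sort(rng.choice(span, size=2 * (n_ex - 1), replace=False))
            bounds = [start, *pts.tolist(), end]
            exons = tuple(
                GenomicInterval(chrom, bounds[2 * i], bounds[2 * i + 1], strand)
                for i in range(n_ex)
            )
            gid = f"G{gidx:05d}"
            genes.append(
                GeneModel(gid, gid, GenomicInterval(chrom, start, end, strand), exons)
            )
            gaps.append((chrom, prev_end, start))
            prev_end = end
            cursor = end
            gidx += 1
        gaps.append((chrom, prev_end, prev_end + 15000))  # chromosome tail

    # promoter CGIs on a random subset of genes
    n_prom = config.n_promoter_cgis
    prom_gene_idx = np.sort(rng.choice(config.n_genes, size=n_prom, replace=False))
    raw_cgis: list[tuple[str, int, int, str | None]] = []  # chrom, start, end, gene
    for gi in prom_gene_idx:
        gene = genes[int(gi)]
        length = int(rng.integers(300, 1201))
        offset = int(rng.integers(0, 401))
        if gene.strand == "+":
            cgi_end = gene.tss - offset
            cgi_start = cgi_end - length
        else:
            cgi_start = gene.tss + 1 + offset
            cgi_end = cgi_start + length
        raw_cgis.append((gene.interval.chrom, cgi_start, cgi_end, gene.gene_id))

    # intergenic CGIs mid-gap, clear of every promoter and promoter CGI
    n_inter = config.n_cgis - n_prom
    margin = 2600
    slots = []
    for chrom, gs, ge in gaps:
        length = int(rng.integers(200, 801))
        lo = gs + margin
        hi = ge - margin - length
        if hi > lo:
            slots.append((chrom, lo, hi, length))
    if n_inter > len(slots):
        raise ValueError(
            f"infeasible density: {n_inter} intergenic CGIs but only {len(slots)} slots"
        )
    chosen = rng.choice(len(slots), size=n_inter, replace=False)
    for si in np.sort(chosen):
        chrom, lo, hi, length = slots[int(si)]
        start = int(rng.integers(lo, hi + 1))
        raw_cgis.append((chrom, start, start + length, None))

    raw_cgis.sort(key=lambda t: (t[0], t[1]))
    cgis: list[CpGIsland] = []
    cgi_gene: dict[str, str | None] = {}
    for i, (chrom, start, end, gene_id) in enumerate(raw_cgis):
        cgi_id = f"CGI_{i:05d}"
        cgis.append(CpGIsland(cgi_id, GenomicInterval(chrom, start, end)))
        cgi_gene[cgi_id] = gene_id

    promoter_pairs = [(cid, g) for cid, g in cgi_gene.items() if g is not None]
    planted_idx = rng.choice(len(promoter_pairs), size=config.n_planted_gsms, replace=False)
    planted = sorted(promoter_pairs[int(i)] for i in np.sort(planted_idx))

    truth = GroundTruth(planted_gsm=planted, seed=config.seed)
    return genes, cgis, truth


def _chrom_lengths(genes: Sequence[GeneModel], cgis: Sequence[CpGIsland]) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for gene in genes:
        iv = gene.interval
        lengths[iv.chrom] = max(lengths.get(iv.chrom, 0), iv.end)
    for cgi in cgis:
        iv = cgi.interval
        lengths[iv.chrom] = max(lengths.get(iv.chrom, 0), iv.end)
    return {c: ln + 15000 for c, ln in lengths.items()}


def _draw_mixture_pi(rng: np.random.Generator, config: SimulationConfig, size: int) -> np.ndarray:
    comp = rng.choice(3, size=size, p=list(config.mixture_weights))
    params = [config.beta_hypo, config.beta_hyper, config.beta_mid]
    out = np.empty(size)
    for k in range(3):
        mask = comp == k
        a, b = params[k]
        out[mask] = rng.beta(a, b, size=int(mask.sum()))
    return out


def simulate_methylome(
    config: SimulationConfig,
    truth: GroundTruth,
    genes: Sequence[GeneModel],
    cgis: Sequence[CpGIsland],
) -> dict[str, pd.DataFrame]:
    """Per-tissue Bismark-style CpG site calls.

    Null CGIs draw one baseline methylation fraction from the bimodal beta
    mixture with small tissue jitter; planted GSM CGIs vary uniformly over
    tissues spanning hypo to hyper.  Depth is Poisson at the tissue's mean
    (low for the designated low-depth tissues); planted DMS positions among
    the background sites separate the designated tissue pair by a fixed
    effect.  Updates ``truth`` with the latent pi matrix and DMS positions.
    """
    rng = _rng(config, _STREAM_METHYLOME)
    tissues = config.tissues
    low = set(config.low_depth_tissues)
    planted_cgis = {cid for cid, _g in truth.planted_gsm}

    # latent per-CGI, per-tissue methylation fraction
    pi = np.empty((len(cgis), config.n_tissues))
    base = _draw_mixture_pi(rng, config, len(cgis))
    for i, cgi in enumerate(cgis):
        if cgi.cgi_id in planted_cgis:
            pi[i] = rng.uniform(0.05, 0.95, size=config.n_tissues)
        else:
            pi[i] = np.clip(
                base[i] + rng.normal(0.0, config.tissue_jitter_sd, size=config.n_tissues),
                0.001, 0.999,
            )
    truth.pi = pd.DataFrame(pi, index=[c.cgi_id for c in cgis], columns=tissues)

    # CpG site layout: dense inside CGIs, sparse background elsewhere
    site_chrom: list[str] = []
    site_pos: list[int] = []
    site_cgi: list[int] = []
    for i, cgi in enumerate(cgis):
        iv = cgi.interval
        n_sites = int(rng.integers(config.sites_per_cgi[0], config.sites_per_cgi[1] + 1))
        n_sites = min(n_sites, iv.length)
        pos = np.sort(rng.choice(np.arange(iv.start, iv.end), size=n_sites, replace=False))
        site_chrom.extend([iv.chrom] * n_sites)
        site_pos.extend(pos.tolist())
        site_cgi.extend([i] * n_sites)

    lengths = _chrom_lengths(genes, cgis)
    chrom_names = sorted(lengths)
    cgi_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cgi in cgis:
        cgi_by_chrom.setdefault(cgi.interval.chrom, ([], []))  # type: ignore[arg-type]
    for chrom in list(cgi_by_chrom):
        ivs = sorted(
            (c.interval.start, c.interval.end) for c in cgis if c.interval.chrom == chrom
        )
        cgi_by_chrom[chrom] = (
            np.array([s for s, _ in ivs]), np.array([e for _, e in ivs])
        )

    bg_chrom: list[str] = []
    bg_pos: list[int] = []
    want = config.n_background_sites
    while len(bg_pos) < want:
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        pos = int(rng.integers(0, lengths[chrom]))
        starts, ends = cgi_by_chrom.get(chrom, (np.array([]), np.array([])))
        k = np.searchsorted(starts, pos, side="right") - 1
        if k >= 0 and pos < ends[k]:
            continue  # inside a CGI; background sites must not disturb CGI medians
        bg_chrom.append(chrom)
        bg_pos.append(pos)

    n_cgi_sites = len(site_pos)
    all_chrom = np.array(site_chrom + bg_chrom)
    all_pos = np.array(site_pos + bg_pos, dtype=np.int64)
    cgi_index = np.array(site_cgi + [-1] * len(bg_pos), dtype=np.int64)

    # background baseline methylation; planted DMS among the first positions
    bg_base = _draw_mixture_pi(rng, config, len(bg_pos))
    n_dms = min(config.n_planted_dms, len(bg_pos))
    dms_slots = np.sort(rng.choice(len(bg_pos), size=n_dms, replace=False))
    dms_mask_bg = np.zeros(len(bg_pos), dtype=bool)
    dms_mask_bg[dms_slots] = True
    bg_base[dms_mask_bg] = config.dms_low
    truth.dms_positions = [
        (bg_chrom[int(i)], int(bg_pos[int(i)])) for i in dms_slots
    ]

    samples: dict[str, pd.DataFrame] = {}
    tissue_a, tissue_b = config.dms_pair
    for t_idx, tissue in enumerate(tissues):
        mean_depth = config.low_depth_mean if tissue in low else config.mean_depth
        pi_cgi_sites = np.clip(
            pi[cgi_index[:n_cgi_sites], t_idx]
            + rng.normal(0.0, config.site_jitter_sd, size=n_cgi_sites),
            0.001, 0.999,
        )
        pi_bg = bg_base.copy()
        if tissue == tissue_b:
            pi_bg[dms_mask_bg] = config.dms_low + config.dms_effect
        pi_sites = np.concatenate([pi_cgi_sites, np.clip(pi_bg, 0.001, 0.999)])
        depth = rng.poisson(mean_depth, size=len(all_pos))
        n_meth = rng.binomial(depth, pi_sites)
        covered = depth > 0
        samples[tissue] = pd.DataFrame(
            {
                "chrom": all_chrom[covered],
                "pos": all_pos[covered],
                "strand": ".",
                "context": "CpG",
                "n_meth": n_meth[covered],
                "n_unmeth": (depth - n_meth)[covered],
            }
        ).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)[SITE_COLUMNS]
    return samples


def simulate_expression(
    config: SimulationConfig,
    truth: GroundTruth,
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """FPKM matrix implementing the planted silencing link.

    Planted GSM genes follow ``log2(FPKM+1) = a - b*pi + noise`` against
    their CGI's latent methylation; tissue-specific blocks receive a large
    expression spike in one tissue each; all other genes draw
    tissue-independent log-normal FPKM.  Updates ``truth`` with realized
    per-unit correlations and the TSG block labels.
    """
    if truth.pi is None:
        raise ValueError("methylome must be simulated before expression")
    rng = _rng(config, _STREAM_EXPRESSION)
    tissues = config.tissues
    gene_ids = [g.gene_id for g in genes]
    n = len(gene_ids)
    y = np.empty((n, config.n_tissues))

    # everyone starts as a null (tissue-independent) gene
    mu = np.clip(rng.normal(config.null_log_mean, config.null_log_sd, size=n), 0.2, None)
    y[:] = mu[:, None] + rng.normal(0.0, config.null_tissue_sd, size=y.shape)

    gene_row = {g: i for i, g in enumerate(gene_ids)}
    planted_genes = {g for _c, g in truth.planted_gsm}

    # tissue-specific blocks on genes not already planted as GSM targets
    free = [g for g in gene_ids if g not in planted_genes]
    free_idx = rng.permutation(len(free))
    cursor = 0
    truth.tsg_labels = {}
    truth.tsg_spike_tissue = {}
    for block in range(1, config.n_tsg_clusters + 1):
        size = int(rng.integers(config.tsg_block_size[0], config.tsg_block_size[1] + 1))
        members = [free[int(i)] for i in free_idx[cursor:cursor + size]]
        cursor += size
        if len(members) < size:
            raise ValueError("not enough genes for the configured TSG blocks")
        spike_tissue = tissues[(block - 1) % config.n_tissues]
        truth.tsg_spike_tissue[block] = spike_tissue
        t_col = tissues.index(spike_tissue)
        for g in members:
            truth.tsg_labels[g] = block
            i = gene_row[g]
            y[i] = np.clip(rng.normal(1.5, 0.5), 0.2, None) + rng.normal(
                0.0, 0.5, size=config.n_tissues
            )
            y[i, t_col] += config.tsg_spike_log2fc

    # planted silencing links
    truth.true_unit_r = {}
    for cgi_id, gene_id in truth.planted_gsm:
        i = gene_row[gene_id]
        pi_vec = truth.pi.loc[cgi_id].to_numpy()
        y[i] = np.clip(
            config.coupling_intercept
            - config.coupling_slope * pi_vec
            + rng.normal(0.0, config.expression_noise_sd, size=config.n_tissues),
            0.0, None,
        )
        truth.true_unit_r[cgi_id] = float(np.corrcoef(pi_vec, y[i])[0, 1])

    fpkm = np.maximum(np.exp2(y) - 1.0, 0.0)
    return pd.DataFrame(np.round(fpkm, 6), index=gene_ids, columns=tissues)


def simulate_junctions(
    config: SimulationConfig,
    truth: GroundTruth,
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """Exon-skipping junction counts per event and tissue.

    For an event with true inclusion ratio psi and total junction depth d
    (Poisson), inclusion events are Binomial(d, psi); the doubled inclusion
    count splits binomially into upstream/downstream inclusion junctions,
    and the remainder supports skipping.  Planted switch-like events are
    near-completely skipped in a few tissues and near-completely included
    elsewhere; planted differential-usage events separate the designated
    condition pair by ``deu_delta``; null events hold psi constant.
    """
    rng = _rng(config, _STREAM_JUNCTIONS)
    tissues = config.tissues
    n_events = config.n_skipping_events
    order = rng.permutation(n_events)
    switch_set = set(order[: config.n_planted_switch_exons].tolist())
    deu_set = set(
        order[
            config.n_planted_switch_exons: config.n_planted_switch_exons + config.n_planted_deu
        ].tolist()
    )

    deu_a, deu_b = config.deu_pair
    event_ids = [f"SE_{i:05d}" for i in range(n_events)]
    true_psi = np.empty((n_events, config.n_tissues))
    for e in range(n_events):
        if e in switch_set:
            hi = rng.uniform(*config.switch_high_range)
            true_psi[e] = hi
            n_low = int(rng.integers(1, 5))
            low_tissues = rng.choice(config.n_tissues, size=n_low, replace=False)
            true_psi[e, low_tissues] = rng.uniform(
                *config.switch_low_range, size=n_low
            )
        elif e in deu_set:
            true_psi[e] = 0.5
            true_psi[e, tissues.index(deu_a)] = 0.2
            true_psi[e, tissues.index(deu_b)] = 0.2 + config.deu_delta
        else:
            true_psi[e] = rng.uniform(0.25, 0.75)

    gene_pick = rng.integers(0, len(genes), size=n_events)
    rows = []
    for e in range(n_events):
        gene = genes[int(gene_pick[e])]
        iv = gene.interval
        exon_len = int(rng.integers(50, 301))
        exon_start = int(rng.integers(iv.start, max(iv.start + 1, iv.end - exon_len)))
        depth = rng.poisson(config.junction_depth_mean, size=config.n_tissues)
        n_inc = rng.binomial(depth, true_psi[e])
        ijc_up = rng.binomial(2 * n_inc, 0.5)
        ijc_dn = 2 * n_inc - ijc_up
        sjc = depth - n_inc
        for t_idx, tissue in enumerate(tissues):
            rows.append(
                (
                    event_ids[e], gene.gene_id, iv.chrom, exon_start,
                    exon_start + exon_len, gene.strand, tissue,
                    int(ijc_up[t_idx]), int(ijc_dn[t_idx]), int(sjc[t_idx]),
                )
            )

    truth.planted_switch = sorted(event_ids[e] for e in switch_set)
    truth.deu_events = sorted(event_ids[e] for e in deu_set)
    truth.switch_true_psi = pd.DataFrame(
        true_psi[sorted(switch_set)],
        index=[event_ids[e] for e in sorted(switch_set)],
        columns=tissues,
    )
    return pd.DataFrame(rows, columns=JUNCTION_COLUMNS)


@dataclass
class SyntheticDataset:
    """One fully simulated study: annotation, methylomes, expression, junctions."""

    config: SimulationConfig
    genes: list[GeneModel]
    cgis: list[CpGIsland]
    methylomes: dict[str, pd.DataFrame]
    fpkm: pd.DataFrame
    junctions: pd.DataFrame
    truth: GroundTruth


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run all four generators in dependency order."""
    genes, cgis, truth = simulate_annotation(config)
    methylomes = simulate_methylome(config, truth, genes, cgis)
    fpkm = simulate_expression(config, truth, genes)
    junctions = simulate_junctions(config, truth, genes)
    return SyntheticDataset(config, genes, cgis, methylomes, fpkm, junctions, truth)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a dataset in exactly the formats the pipeline consumes.

    Layout: ``annotation.gtf``, ``cgis.bed``, ``methylomes/<tissue>.cov``,
    ``fpkm.tsv``, ``junctions.tsv``, ``truth.json``, ``config.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "methylomes").mkdir(exist_ok=True)
    paths = {
        "gtf": outdir / "annotation.gtf",
        "cgis": outdir / "cgis.bed",
        "fpkm": outdir / "fpkm.tsv",
        "junctions": outdir / "junctions.tsv",
        "truth": outdir / "truth.json",
        "config": outdir / "config.json",
    }
    write_gene_models_gtf(dataset.genes, paths["gtf"])
    write_cgis_bed(dataset.cgis, paths["cgis"])
    dataset.fpkm.to_csv(paths["fpkm"], sep="\t", index_label="gene_id")
    write_junction_counts(dataset.junctions, paths["junctions"])
    for tissue in dataset.config.tissues:
        write_site_calls(dataset.methylomes[tissue], outdir / "methylomes" / f"{tissue}.cov")
    dataset.truth.to_json(paths["truth"])
    with open(paths["config"], "w") as fh:
        json.dump(dataset.config.to_dict(), fh, sort_keys=True, indent=1)
    return paths


def simulate_dms_pair(
    n_null: int,
    n_planted: int,
    depth_mean: float = 50.0,
    effect: float = 0.8,
    low: float = 0.1,
    seed: int = 0,
    equal_pi_range: tuple[float, float] = (0.05, 0.95),
) -> tuple[pd.DataFrame, pd.DataFrame, list[int]]:
    """Two single-chromosome site tables for differential-methylation tests.

    Null positions share one methylation fraction between the two tissues
    (drawn uniformly from ``equal_pi_range``); planted positions sit at
    ``low`` in tissue A and ``low + effect`` in tissue B.  Returns both
    tables and the planted 0-based positions.
    """
    rng = np.random.default_rng([seed, 97])
    n = n_null + n_planted
    pos = np.arange(n, dtype=np.int64)
    pi_a = rng.uniform(*equal_pi_range, size=n)
    pi_b = pi_a.copy()
    planted = rng.choice(n, size=n_planted, replace=False) if n_planted else np.array([], dtype=int)
    pi_a[planted] = low
    pi_b[planted] = low + effect

    def draw(pi: np.ndarray) -> pd.DataFrame:
        depth = np.maximum(rng.poisson(depth_mean, size=n), 1)
        n_meth = rng.binomial(depth, pi)
        return pd.DataFrame(
            {
                "chrom": "chrS",
                "pos": pos,
                "strand": ".",
                "context": "CpG",
                "n_meth": n_meth,
                "n_unmeth": depth - n_meth,
            }
        )

    return draw(pi_a), draw(pi_b), sorted(int(p) for p in planted)
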