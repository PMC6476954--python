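"""Ground-truth fidelity and determinism of the synthetic-data generator."""

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from methlink import methylation as meth
from methlink.annotation import map_cgis_to_genes
from methlink.expression import read_fpkm, select_tsg
from methlink.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_dataset,
    write_dataset,
)
from methlink.splicing import read_junction_counts


def tree_digest(root: Path) -> dict[str, str]:
    return {
        str(p.relative_to(root)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


class TestConfig:
    def test_rejects_inconsistent_design(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=10, n_cgis=100, cgi_promoter_fraction=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_planted_gsms=10_000)
        with pytest.raises(ValueError):
            SimulationConfig(n_tissues=4, n_low_depth_tissues=4)

    def test_low_depth_tissues_are_a_minority_suffix(self):
        cfg = SimulationConfig.small()
        assert len(cfg.low_depth_tissues) == 6
        assert set(cfg.low_depth_tissues) <= set(cfg.tissues)


class TestAnnotationGeneration:
    def test_promoter_fraction_recounted_by_mapping(self):
        cfg = SimulationConfig(
            n_genes=100, n_cgis=100, cgi_promoter_fraction=0.5,
            n_planted_gsms=10, tsg_block_size=(4, 6), n_tsg_clusters=4, seed=3,
        )
        genes, cgis, _truth = simulate_annotation(cfg)
        units = map_cgis_to_genes(cgis, genes)
        assert len(units) == 50  # every placed promoter CGI maps to exactly one gene

    def test_zero_fraction_yields_no_units(self):
        cfg = SimulationConfig(
            n_genes=80, n_cgis=60, cgi_promoter_fraction=0.0,
            n_planted_gsms=0, tsg_block_size=(4, 6), n_tsg_clusters=4, seed=4,
        )
        genes, cgis, _ = simulate_annotation(cfg)
        assert map_cgis_to_genes(cgis, genes) == []

    def test_genes_do_not_overlap(self, small_dataset):
        by_chrom = {}
        for g in small_dataset.genes:
            by_chrom.setdefault(g.interval.chrom, []).append(g.interval)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: iv.start)
            assert all(a.end <= b.start for a, b in zip(ivs, ivs[1:]))

    def test_infeasible_density_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            simulate_annotation(
                SimulationConfig(
                    n_genes=10, n_cgis=500, cgi_promoter_fraction=0.0,
                    n_planted_gsms=0, tsg_block_size=(2, 3), n_tsg_clusters=4, seed=5,
                )
            )


class TestMethylomeGroundTruth:
    def test_planted_cgi_quantification_within_binomial_interval(self):
        """A CGI at latent level pi, quantified at depth ~50, lands inside the
        exact binomial 99% interval of pi for the vast majority of cells."""
        cfg = SimulationConfig(
            n_genes=60, n_cgis=60, cgi_promoter_fraction=0.5, n_planted_gsms=10,
            tsg_block_size=(4, 6), n_tsg_clusters=4, mean_depth=50.0, site_jitter_sd=0.0,
            tissue_jitter_sd=0.0, seed=6,
        )
        dataset = simulate_dataset(cfg)
        matrix = meth.build_methylation_matrix(
            {t: meth.filter_sites_by_depth(s, 10) for t, s in dataset.methylomes.items()
             if t not in cfg.low_depth_tissues},
            dataset.cgis,
        )
        pi = dataset.truth.pi
        inside = total = 0
        for cgi_id in matrix.values.index:
            for tissue in matrix.values.columns:
                got = matrix.values.loc[cgi_id, tissue]
                if np.isnan(got):
                    continue
                p = pi.loc[cgi_id, tissue]
                lo, hi = stats.binom.interval(0.99, 50, p)
                total += 1
                inside += (100 * lo / 50 - 2) <= got <= (100 * hi / 50 + 2)
        assert total > 500
        assert inside / total >= 0.95

    def test_depth_qc_drops_exactly_the_low_depth_tissues(self, small_dataset, small_config):
        kept, _ = meth.qc_filter_samples(small_dataset.methylomes)
        assert sorted(set(small_config.tissues) - set(kept)) == sorted(
            small_config.low_depth_tissues
        )

    def test_dms_positions_differ_between_designated_pair(self, small_dataset, small_config):
        a, b = small_config.dms_pair
        sa = small_dataset.methylomes[a].set_index(["chrom", "pos"])
        sb = small_dataset.methylomes[b].set_index(["chrom", "pos"])
        diffs = []
        for key in small_dataset.truth.dms_positions:
            key = tuple(key)
            if key in sa.index and key in sb.index:
                la = 100 * sa.loc[key, "n_meth"] / (sa.loc[key, "n_meth"] + sa.loc[key, "n_unmeth"])
                lb = 100 * sb.loc[key, "n_meth"] / (sb.loc[key, "n_meth"] + sb.loc[key, "n_unmeth"])
                diffs.append(lb - la)
        assert np.median(diffs) > 60


class TestExpressionGroundTruth:
    def test_noise_free_coupling_gives_perfect_anticorrelation(self):
        cfg = SimulationConfig(
            n_genes=60, n_cgis=60, cgi_promoter_fraction=0.5, n_planted_gsms=10,
            tsg_block_size=(4, 6), n_tsg_clusters=4, expression_noise_sd=0.0, seed=7,
        )
        dataset = simulate_dataset(cfg)
        for cgi_id, r in dataset.truth.true_unit_r.items():
            assert r == pytest.approx(-1.0, abs=1e-9)

    def test_zero_slope_decouples_planted_units(self):
        cfg = SimulationConfig(
            n_genes=200, n_cgis=200, cgi_promoter_fraction=0.9, n_planted_gsms=60,
            tsg_block_size=(4, 6), n_tsg_clusters=4, coupling_slope=0.0, seed=8,
        )
        dataset = simulate_dataset(cfg)
        rs = np.array(list(dataset.truth.true_unit_r.values()))
        assert abs(np.mean(rs)) < 0.2  # centred on zero rather than -0.8

    def test_realized_coupling_strength_matches_design(self, small_dataset):
        rs = np.array(list(small_dataset.truth.true_unit_r.values()))
        assert np.mean(np.abs(rs)) == pytest.approx(0.8, abs=0.1)

    def test_spiked_genes_pass_fold_change_selection(self, small_dataset):
        selected = set(select_tsg(small_dataset.fpkm))
        planted = set(small_dataset.truth.tsg_labels)
        assert len(planted & selected) / len(planted) >= 0.99


class TestJunctionGroundTruth:
    def test_full_inclusion_means_zero_skipping_reads(self):
        cfg = SimulationConfig(
            n_genes=40, n_cgis=40, cgi_promoter_fraction=0.5, n_planted_gsms=5,
            tsg_block_size=(3, 4), n_tsg_clusters=4, n_skipping_events=30, n_planted_switch_exons=30,
            n_planted_deu=0, switch_low_range=(1.0, 1.0), switch_high_range=(1.0, 1.0),
            seed=9,
        )
        dataset = simulate_dataset(cfg)
        assert (dataset.junctions["sjc"] == 0).all()

    def test_high_depth_psi_close_to_planted(self, small_dataset):
        from methlink.splicing import build_psi_matrix

        psi = build_psi_matrix(small_dataset.junctions)
        truth = small_dataset.truth.switch_true_psi
        est = psi.psi.loc[truth.index, truth.columns]
        err = (est - truth).abs().to_numpy()
        assert np.nanmean(err) < 0.06  # depth ~100 -> sd ~0.03


class TestDeterminismAndRoundTrip:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig.small(seed=11)
        for name in ("a", "b"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                write_dataset(simulate_dataset(cfg), tmp_path / name)
        assert tree_digest(tmp_path / "a") == tree_digest(tmp_path / "b")

    def test_different_seed_changes_output(self, tmp_path):
        for seed, name in [(11, "a"), (12, "b")]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                write_dataset(simulate_dataset(SimulationConfig.small(seed=seed)), tmp_path / name)
        assert tree_digest(tmp_path / "a") != tree_digest(tmp_path / "b")

    def test_files_round_trip_through_readers(self, small_dataset, small_dataset_dir):
        from methlink.annotation import load_cgis, load_gene_models

        genes = load_gene_models(small_dataset_dir / "annotation.gtf")
        assert len(genes) == len(small_dataset.genes)
        cgis = load_cgis(small_dataset_dir / "cgis.bed")
        assert cgis == small_dataset.cgis
        fpkm = read_fpkm(small_dataset_dir / "fpkm.tsv")
        assert fpkm.shape == small_dataset.fpkm.shape
        junctions = read_junction_counts(small_dataset_dir / "junctions.tsv")
        assert len(junctions) == len(small_dataset.junctions)
        tissue = small_dataset.config.tissues[0]
        sites = meth.parse_site_calls(small_dataset_dir / "methylomes" / f"{tissue}.cov")
        assert len(sites) == len(small_dataset.methylomes[tissue])

    def test_mixture_marginals_match_config(self):
        """Null-CGI baselines reproduce the configured bimodal mixture."""
        cfg = SimulationConfig(
            n_genes=600, n_cgis=700, cgi_promoter_fraction=0.5, n_planted_gsms=0,
            tsg_block_size=(4, 6), seed=13,
        )
        dataset = simulate_dataset(cfg)
        base = dataset.truth.pi.iloc[:, 0].to_numpy()
        hypo_frac = (base <= 0.2).mean()
        hyper_frac = (base >= 0.8).mean()
        # hypo component Beta(1,12): P(<=.2) ~ 0.93 -> ~0.56 overall;
        # hyper Beta(12,1.5): P(>=.8) ~ 0.72 -> ~0.22 overall
        assert hypo_frac == pytest.approx(0.56, abs=0.08)
        assert hyper_frac == pytest.approx(0.22, abs=0.08)
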