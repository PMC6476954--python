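"""Site-call parsing, depth filtering, CGI quantification and trend profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methlink.annotation import CpGIsland, GeneModel, GenomicInterval
from methlink.methylation import (
    SITE_COLUMNS,
    MethylationMatrix,
    build_methylation_matrix,
    classify_state,
    filter_sites_by_depth,
    merge_strands,
    methylation_trend,
    parse_site_calls,
    qc_filter_samples,
    quantify_cgi,
    site_levels,
    write_site_calls,
)


def make_sites(rows):
    """rows: (chrom, pos, n_meth, n_unmeth)"""
    return pd.DataFrame(
        [(c, p, ".", "CpG", m, u) for c, p, m, u in rows], columns=SITE_COLUMNS
    )


class TestParseSiteCalls:
    def test_coverage_format_line(self, tmp_path):
        path = tmp_path / "a.cov"
        path.write_text("chr1\t101\t101\t70.0\t7\t3\n")
        df = parse_site_calls(path)
        assert len(df) == 1
        row = df.iloc[0]
        assert (row.pos, row.n_meth, row.n_unmeth) == (100, 7, 3)
        assert site_levels(df).iloc[0] == 70.0

    def test_zero_meth_level(self, tmp_path):
        path = tmp_path / "a.cov"
        path.write_text("chr1\t5\t5\t0.0\t0\t12\n")
        assert site_levels(parse_site_calls(path)).iloc[0] == 0.0

    def test_file_of_100_lines_order_independent(self, tmp_path):
        rng = np.random.default_rng(0)
        rows = [
            f"chr1\t{p}\t{p}\t{100 * m / (m + u):.4f}\t{m}\t{u}"
            for p, m, u in zip(
                rng.permutation(np.arange(1, 101)),
                rng.integers(0, 20, 100),
                rng.integers(1, 20, 100),
            )
        ]
        (tmp_path / "a.cov").write_text("\n".join(rows) + "\n")
        (tmp_path / "b.cov").write_text("\n".join(sorted(rows)) + "\n")
        a = parse_site_calls(tmp_path / "a.cov").sort_values("pos").reset_index(drop=True)
        b = parse_site_calls(tmp_path / "b.cov").sort_values("pos").reset_index(drop=True)
        assert len(a) == 100
        pd.testing.assert_frame_equal(a, b)

    def test_inconsistent_percent_warns(self, tmp_path):
        path = tmp_path / "a.cov"
        path.write_text("chr1\t101\t101\t95.0\t7\t3\n")
        with pytest.warns(UserWarning, match="inconsistent"):
            parse_site_calls(path)

    def test_negative_counts_raise(self, tmp_path):
        path = tmp_path / "a.cov"
        path.write_text("chr1\t101\t101\t70.0\t-7\t3\n")
        with pytest.raises(ValueError, match="negative"):
            parse_site_calls(path)

    def test_cytosine_report_format_carries_context(self, tmp_path):
        path = tmp_path / "a.txt"
        path.write_text("chr1\t101\t+\t7\t3\tCpG\tCGG\nchr1\t150\t-\t1\t9\tCHH\tCAT\n")
        df = parse_site_calls(path)
        assert list(df["context"]) == ["CpG", "CHH"]
        assert list(df["strand"]) == ["+", "-"]

    def test_round_trip(self, tmp_path):
        sites = make_sites([("chr1", 10, 3, 7), ("chr2", 5, 0, 9)])
        write_site_calls(sites, tmp_path / "rt.cov")
        back = parse_site_calls(tmp_path / "rt.cov")
        pd.testing.assert_frame_equal(back, sites)


class TestDepthFilter:
    def test_threshold_boundary(self):
        sites = make_sites([("chr1", 1, 4, 5), ("chr1", 2, 5, 5), ("chr1", 3, 6, 5)])
        kept = filter_sites_by_depth(sites, 10)
        assert list(kept["pos"]) == [2, 3]

    def test_min_depth_one_keeps_covered(self):
        sites = make_sites([("chr1", 1, 1, 0), ("chr1", 2, 0, 0)])
        assert list(filter_sites_by_depth(sites, 1)["pos"]) == [1]

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        sites = make_sites(
            [("chr1", i, int(m), int(u)) for i, (m, u) in enumerate(zip(rng.integers(0, 15, 50), rng.integers(0, 15, 50)))]
        )
        once = filter_sites_by_depth(sites)
        pd.testing.assert_frame_equal(filter_sites_by_depth(once), once)


class TestSampleQc:
    def test_mean_depth_boundary(self):
        samples = {
            "low": make_sites([("chr1", 1, 4, 5), ("chr1", 2, 5, 5)]),   # mean 9.5
            "ok": make_sites([("chr1", 1, 5, 5), ("chr1", 2, 5, 5)]),    # mean 10.0
        }
        kept, report = qc_filter_samples(samples)
        assert kept == ["ok"]
        assert report.set_index("sample").loc["low", "mean_depth"] == 9.5

    def test_all_retained_at_depth_12(self):
        samples = {f"s{i}": make_sites([("chr1", p, 6, 6) for p in range(5)]) for i in range(3)}
        kept, _ = qc_filter_samples(samples)
        assert kept == ["s0", "s1", "s2"]

    def test_means_equal_direct_summation(self):
        rng = np.random.default_rng(3)
        samples = {}
        expected = {}
        for i in range(3):
            m = rng.integers(0, 20, 30)
            u = rng.integers(0, 20, 30)
            samples[f"s{i}"] = make_sites([("chr1", p, int(a), int(b)) for p, (a, b) in enumerate(zip(m, u))])
            expected[f"s{i}"] = (m.sum() + u.sum()) / 30
        _, report = qc_filter_samples(samples)
        for name, mean in expected.items():
            assert report.set_index("sample").loc[name, "mean_depth"] == pytest.approx(mean)

    def test_empty_sample_dropped_with_warning(self):
        samples = {"empty": make_sites([]), "ok": make_sites([("chr1", 1, 6, 6)])}
        with pytest.warns(UserWarning, match="no CpG"):
            kept, _ = qc_filter_samples(samples)
        assert kept == ["ok"]


CGI = CpGIsland("c", GenomicInterval("chr1", 0, 1000))


class TestQuantifyCgi:
    @pytest.mark.parametrize(
        "levels,expected",
        [([10, 20, 90], 20.0), ([10, 20, 80, 90], 50.0)],
        ids=["odd-count", "even-count"],
    )
    def test_median(self, levels, expected):
        sites = make_sites([("chr1", i, lev, 100 - lev) for i, lev in enumerate(levels)])
        assert quantify_cgi(sites, CGI) == expected

    def test_no_qualifying_sites_is_missing(self):
        sites = make_sites([("chr1", 5000, 10, 0)])  # outside the island
        assert np.isnan(quantify_cgi(sites, CGI))

    def test_single_site_equals_its_level(self):
        sites = make_sites([("chr1", 5, 3, 7)])
        assert quantify_cgi(sites, CGI) == 30.0

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 100), min_size=1, max_size=15))
    def test_permutation_invariant_and_bounded(self, levels):
        sites = make_sites([("chr1", i, lev, 100 - lev) for i, lev in enumerate(levels)])
        shuffled = sites.sample(frac=1, random_state=0).reset_index(drop=True)
        v = quantify_cgi(sites, CGI)
        assert v == quantify_cgi(shuffled, CGI)
        assert min(levels) <= v <= max(levels)


class TestMethylationMatrix:
    def test_cells_equal_per_call_quantification(self):
        cgis = [
            CpGIsland("c1", GenomicInterval("chr1", 0, 100)),
            CpGIsland("c2", GenomicInterval("chr1", 200, 300)),
        ]
        samples = {
            "t1": make_sites([("chr1", 5, 1, 9), ("chr1", 250, 9, 1)]),
            "t2": make_sites([("chr1", 5, 5, 5), ("chr1", 250, 2, 8), ("chr1", 260, 4, 6)]),
        }
        matrix = build_methylation_matrix(samples, cgis)
        for cgi in cgis:
            for t in samples:
                assert matrix.values.loc[cgi.cgi_id, t] == pytest.approx(
                    quantify_cgi(samples[t], cgi)
                )
        assert matrix.n_sites.loc["c2", "t2"] == 2

    def test_complete_case_mode_drops_rows_with_missing(self):
        cgis = [
            CpGIsland("c1", GenomicInterval("chr1", 0, 100)),
            CpGIsland("c2", GenomicInterval("chr1", 200, 300)),
        ]
        samples = {
            "t1": make_sites([("chr1", 5, 1, 9)]),
            "t2": make_sites([("chr1", 5, 5, 5), ("chr1", 250, 2, 8)]),
        }
        matrix = build_methylation_matrix(samples, cgis, complete_cases=True)
        assert list(matrix.values.index) == ["c1"]

    def test_matches_per_row_oracle_on_synthetic_data(self, small_dataset):
        cgis = small_dataset.cgis[:100]
        samples = {t: small_dataset.methylomes[t] for t in list(small_dataset.methylomes)[:6]}
        matrix = build_methylation_matrix(samples, cgis)
        rng = np.random.default_rng(0)
        for _ in range(50):
            cgi = cgis[int(rng.integers(len(cgis)))]
            t = list(samples)[int(rng.integers(len(samples)))]
            expected = quantify_cgi(samples[t], cgi)
            got = matrix.values.loc[cgi.cgi_id, t]
            assert (np.isnan(expected) and np.isnan(got)) or got == pytest.approx(expected)

    def test_column_subsetting_commutes(self, small_dataset):
        cgis = small_dataset.cgis[:50]
        names = list(small_dataset.methylomes)[:4]
        samples = {t: small_dataset.methylomes[t] for t in names}
        full = build_methylation_matrix(samples, cgis)
        sub = build_methylation_matrix({n: samples[n] for n in names[:2]}, cgis)
        pd.testing.assert_frame_equal(full.values[names[:2]], sub.values)

    def test_tsv_round_trip(self, tmp_path):
        cgis = [CpGIsland("c1", GenomicInterval("chr1", 0, 100))]
        samples = {"t1": make_sites([("chr1", 5, 1, 2)]), "t2": make_sites([])}
        matrix = build_methylation_matrix(samples, cgis)
        matrix.to_tsv(tmp_path / "m.tsv")
        back = MethylationMatrix.from_tsv(tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(back.values, matrix.values)

    def test_rejects_out_of_range_values(self):
        with pytest.raises(ValueError):
            MethylationMatrix(pd.DataFrame({"t": [101.0]}), pd.DataFrame({"t": [1]}))


class TestMergeStrands:
    def test_dinucleotide_counts_sum(self):
        sites = pd.DataFrame(
            [("chr1", 10, "+", "CpG", 3, 1), ("chr1", 11, "-", "CpG", 2, 4)],
            columns=SITE_COLUMNS,
        )
        merged = merge_strands(sites)
        assert len(merged) == 1
        assert (merged.iloc[0].pos, merged.iloc[0].n_meth, merged.iloc[0].n_unmeth) == (10, 5, 5)


class TestClassifyState:
    @pytest.mark.parametrize(
        "level,expected", [(0, "hypo"), (100, "hyper"), (50, "intermediate"), (20, "hypo"), (80, "hyper")]
    )
    def test_default_thresholds_inclusive(self, level, expected):
        assert classify_state(level) == expected

    def test_custom_boundary_inclusive(self):
        assert classify_state(30, hypo_max=30, hyper_min=70) == "hypo"

    def test_invalid_configuration(self):
        with pytest.raises(ValueError):
            classify_state(50, hypo_max=80, hyper_min=20)


class TestMethylationTrend:
    def plus_gene(self):
        return GeneModel("g", "g", GenomicInterval("chr1", 10_000, 14_000, "+"))

    def test_single_upstream_site_fills_one_bin(self):
        sites = make_sites([("chr1", 9000, 40, 60)])  # tss - 1000
        prof = methylation_trend(sites, [self.plus_gene()], n_flank_bins=4, n_body_bins=4)
        assert prof.mean[2] == 40.0  # [-1000, -500) is the third upstream bin
        assert np.isnan(np.delete(prof.mean, 2)).all()

    def test_minus_strand_mirrors_plus(self):
        gp = self.plus_gene()
        gm = GeneModel("g", "g", GenomicInterval("chr1", 10_000, 14_000, "-"))
        sp = make_sites([("chr1", 9000, 40, 60)])            # 1000 bp upstream of +
        sm = make_sites([("chr1", 14_999, 40, 60)])          # 1000 bp upstream of -
        p = methylation_trend(sp, [gp], n_flank_bins=4, n_body_bins=4)
        m = methylation_trend(sm, [gm], n_flank_bins=4, n_body_bins=4)
        np.testing.assert_array_equal(np.isnan(p.mean), np.isnan(m.mean))
        assert m.mean[2] == 40.0

    def test_recovers_step_profile(self):
        rows = []
        for p in range(8000, 16_000, 20):
            lev = 80 if 10_000 <= p < 14_000 else 10
            rows.append(("chr1", p, lev, 100 - lev))
        prof = methylation_trend(make_sites(rows), [self.plus_gene()], n_flank_bins=4, n_body_bins=6)
        np.testing.assert_allclose(prof.mean[:4], 10.0)
        np.testing.assert_allclose(prof.mean[4:10], 80.0)
        np.testing.assert_allclose(prof.mean[10:], 10.0)
        assert prof.n_sites.sum() == len(rows)
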