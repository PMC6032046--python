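"""Summary-statistics I/O, allele harmonisation, panel filtering, LD pruning."""

import numpy as np
import pandas as pd
import pytest

from sphmm import gwas_io
from sphmm.gwas_io import (
    EmptyInputError,
    GwasFormatError,
    LdTable,
    count_significant,
    filter_to_panel,
    harmonize_to_derived,
    ld_prune,
    read_allele_map,
    read_ld_table,
    read_panel,
    read_summary_table,
)

# two-sided standard-normal quantile at p = 0.05, frozen from standard tables
Z_095 = 1.959963985


def _write(path, text):
    path.write_text(text)
    return path


class TestReadSummaryTable:
    CMAP = {"snp": "SNP", "a1": "A1", "a2": "A2", "beta": "BETA", "se": "SE"}

    def test_parses_well_formed_tsv(self, tmp_path):
        p = _write(
            tmp_path / "s.tsv",
            "SNP\tA1\tA2\tBETA\tSE\n"
            "rs1\tA\tG\t0.01\t0.02\n"
            "rs2\tC\tT\t-0.03\t0.015\n"
            "rs3\tG\tA\t0.00\t0.02\n",
        )
        table, report = read_summary_table(p, self.CMAP, 100, 100)
        assert table.m == 3
        assert report.total == 0
        assert np.all(table.v > 0)
        np.testing.assert_allclose(table.v, [0.02**2, 0.015**2, 0.02**2])

    def test_comma_delimited_and_or_column(self, tmp_path):
        p = _write(
            tmp_path / "s.csv",
            "SNP,A1,A2,OR,SE\nrs1,A,G,1.05,0.02\n",
        )
        cmap = {"snp": "SNP", "a1": "A1", "a2": "A2", "or": "OR", "se": "SE"}
        table, _ = read_summary_table(p, cmap, 100, 100)
        assert table.y[0] == pytest.approx(np.log(1.05), rel=1e-12)

    def test_variance_from_p_value(self, tmp_path):
        # var = (beta / z)^2 with z the two-sided normal quantile of p
        p = _write(
            tmp_path / "s.tsv",
            "SNP\tA1\tA2\tBETA\tP\nrs1\tA\tG\t0.1\t0.05\n",
        )
        cmap = {"snp": "SNP", "a1": "A1", "a2": "A2", "beta": "BETA", "p": "P"}
        table, _ = read_summary_table(p, cmap, 100, 100)
        assert table.v[0] == pytest.approx((0.1 / Z_095) ** 2, rel=1e-6)

    def test_variance_precedence_var_over_se_over_p(self, tmp_path):
        p = _write(
            tmp_path / "s.tsv",
            "SNP\tA1\tA2\tBETA\tVAR\tSE\tP\nrs1\tA\tG\t0.1\t0.0004\t0.5\t0.5\n",
        )
        cmap = {"snp": "SNP", "a1": "A1", "a2": "A2", "beta": "BETA",
                "var": "VAR", "se": "SE", "p": "P"}
        table, _ = read_summary_table(p, cmap, 100, 100)
        assert table.v[0] == 0.0004

    @pytest.mark.parametrize(
        "row, reason",
        [
            ("rs9\tA\tG\t0.1\t0", "nonpositive_variance"),
            ("rs9\tA\tA\t0.1\t0.02", "invalid_alleles"),
            ("rs9\tA\tG\tnan\t0.02", "nonfinite_beta"),
        ],
    )
    def test_invalid_rows_dropped_and_counted(self, tmp_path, row, reason):
        body = "SNP\tA1\tA2\tBETA\tSE\nrs1\tA\tG\t0.01\t0.02\n" + row + "\n"
        table, report = read_summary_table(
            _write(tmp_path / "s.tsv", body), self.CMAP, 100, 100
        )
        assert table.m == 1
        assert report.counts[reason] == 1

    def test_var_column_zero_dropped(self, tmp_path):
        cmap = {"snp": "SNP", "a1": "A1", "a2": "A2", "beta": "BETA", "var": "VAR"}
        p = _write(
            tmp_path / "s.tsv",
            "SNP\tA1\tA2\tBETA\tVAR\nrs1\tA\tG\t0.01\t0.0004\nrs2\tA\tG\t0.1\t0\n",
        )
        table, report = read_summary_table(p, cmap, 100, 100)
        assert table.m == 1
        assert report.total == 1

    @pytest.mark.parametrize("bad_p", ["0", "1"])
    def test_degenerate_p_dropped(self, tmp_path, bad_p):
        cmap = {"snp": "SNP", "a1": "A1", "a2": "A2", "beta": "BETA", "p": "P"}
        p = _write(
            tmp_path / "s.tsv",
            f"SNP\tA1\tA2\tBETA\tP\nrs1\tA\tG\t0.1\t0.05\nrs2\tA\tG\t0.1\t{bad_p}\n",
        )
        table, report = read_summary_table(p, cmap, 100, 100)
        assert table.m == 1
        assert report.counts["undefined_p_variance"] == 1

    def test_zero_beta_with_p_dropped(self, tmp_path):
        cmap = {"snp": "SNP", "a1": "A1", "a2": "A2", "beta": "BETA", "p": "P"}
        p = _write(
            tmp_path / "s.tsv",
            "SNP\tA1\tA2\tBETA\tP\nrs1\tA\tG\t0\t0.05\nrs2\tA\tG\t0.1\t0.5\n",
        )
        table, report = read_summary_table(p, cmap, 100, 100)
        assert table.m == 1
        assert report.total == 1

    def test_missing_columns_raise_format_error(self, tmp_path):
        p = _write(tmp_path / "s.tsv", "SNP\tA1\tA2\tBETA\tSE\nrs1\tA\tG\t0.1\t0.02\n")
        with pytest.raises(GwasFormatError):
            read_summary_table(p, {"snp": "SNP", "a1": "A1", "a2": "A2"}, 100, 100)
        with pytest.raises(GwasFormatError):
            read_summary_table(
                p, {"snp": "NOPE", "a1": "A1", "a2": "A2", "beta": "BETA", "se": "SE"},
                100, 100,
            )

    def test_all_rows_invalid_raises_empty_input(self, tmp_path):
        p = _write(tmp_path / "s.tsv", "SNP\tA1\tA2\tBETA\tSE\nrs1\tA\tG\t0.1\t0\n")
        with pytest.raises(EmptyInputError):
            read_summary_table(p, self.CMAP, 100, 100)


class TestHarmonize:
    def test_orientation_cases(self, make_table):
        table = make_table([0.1, -0.2, 0.3], [1e-4] * 3, ids=["rs1", "rs2", "rs3"])
        # rs1 already effect=derived(A); rs2 effect=ancestral -> flip; rs3 absent
        amap = {"rs1": ("G", "A"), "rs2": ("A", "G")}
        out, report = harmonize_to_derived(table, amap)
        assert out.snp_ids == ["rs1", "rs2"]
        assert out.y[0] == 0.1
        assert out.y[1] == 0.2
        row = out.df.iloc[1]
        assert (row.effect_allele, row.other_allele) == ("G", "A")
        assert report.counts["not_in_allele_map"] == 1

    def test_inconsistent_alleles_dropped(self, make_table):
        table = make_table([0.1, 0.2], [1e-4] * 2, ids=["rs1", "rs2"])
        amap = {"rs1": ("G", "A"), "rs2": ("C", "T")}  # rs2 is A/G in the table
        out, report = harmonize_to_derived(table, amap)
        assert out.snp_ids == ["rs1"]
        assert report.counts["alleles_inconsistent_with_map"] == 1

    def test_idempotent_after_orientation(self, make_table):
        table = make_table([0.1, -0.2], [1e-4] * 2, ids=["rs1", "rs2"])
        amap = {"rs1": ("G", "A"), "rs2": ("A", "G")}
        once, _ = harmonize_to_derived(table, amap)
        twice, rep = harmonize_to_derived(once, amap)
        pd.testing.assert_frame_equal(once.df, twice.df)
        assert rep.total == 0

    def test_empty_intersection_raises(self, make_table):
        table = make_table([0.1], [1e-4], ids=["rs1"])
        with pytest.raises(EmptyInputError):
            harmonize_to_derived(table, {"other": ("A", "G")})


class TestPanelFilter:
    def test_subset_and_identity_and_disjoint(self, make_table):
        table = make_table([0.1, 0.2, 0.3], [1e-4] * 3, ids=["rs1", "rs2", "rs3"])
        assert filter_to_panel(table, {"rs1", "rs3"}).snp_ids == ["rs1", "rs3"]
        assert filter_to_panel(table, {"rs1", "rs2", "rs3", "rs4"}).snp_ids == table.snp_ids
        with pytest.raises(EmptyInputError):
            filter_to_panel(table, {"rsX"})


def _ld(pairs):
    return LdTable(pairs=pd.DataFrame(pairs, columns=["snp_a", "snp_b", "r2"]))


class TestLdPrune:
    def test_single_pair_above_threshold(self, make_table):
        table = make_table([0.1, 0.2, 0.3], [1e-4] * 3, ids=["rs1", "rs2", "rs3"])
        ld = _ld([("rs1", "rs2", 0.5)])
        # rs1-rs2 collapse to one; rs3 always kept: size 2 for every seed
        for seed in range(10):
            pruned = ld_prune(table, ld, 0.1, seed=seed)
            assert pruned.m == 2
            assert "rs3" in pruned.snp_ids

    def test_no_pair_above_threshold_keeps_all(self, make_table):
        table = make_table([0.1, 0.2], [1e-4] * 2, ids=["rs1", "rs2"])
        pruned = ld_prune(table, _ld([("rs1", "rs2", 0.05)]), 0.1, seed=0)
        assert pruned.m == 2

    def test_clique_collapses_to_one(self, make_table):
        ids = [f"rs{i}" for i in range(5)]
        table = make_table(np.zeros(5), np.full(5, 1e-4), ids=ids)
        pairs = [(a, b, 0.9) for i, a in enumerate(ids) for b in ids[i + 1:]]
        for seed in range(5):
            assert ld_prune(table, _ld(pairs), 0.1, seed=seed).m == 1

    def test_no_retained_pair_above_threshold(self, make_table):
        rng = np.random.default_rng(42)
        ids = [f"rs{i}" for i in range(60)]
        table = make_table(np.zeros(60), np.full(60, 1e-4), ids=ids)
        pairs = []
        for _ in range(300):
            a, b = rng.choice(60, 2, replace=False)
            pairs.append((ids[a], ids[b], float(rng.random())))
        ld = _ld(pairs)
        pruned = ld_prune(table, ld, 0.1, seed=7)
        kept = set(pruned.snp_ids)
        for a, b, r2 in pairs:
            if r2 > 0.1:
                assert not (a in kept and b in kept)

    def test_idempotent_and_seed_deterministic(self, make_table):
        ids = [f"rs{i}" for i in range(30)]
        table = make_table(np.zeros(30), np.full(30, 1e-4), ids=ids)
        rng = np.random.default_rng(3)
        pairs = [
            (ids[a], ids[b], 0.8)
            for a, b in rng.choice(30, size=(40, 2), replace=True)
            if a != b
        ]
        ld = _ld(pairs)
        p1 = ld_prune(table, ld, 0.1, seed=5)
        p2 = ld_prune(table, ld, 0.1, seed=5)
        assert p1.snp_ids == p2.snp_ids
        again = ld_prune(p1, ld, 0.1, seed=99)
        assert again.snp_ids == p1.snp_ids


class TestCountSignificant:
    def test_strong_signal_counted_at_genome_wide_threshold(self, make_table):
        v = 1e-4
        table = make_table([6 * np.sqrt(v)], [v])
        assert count_significant(table, 5e-8) == 1

    def test_null_effects_not_counted(self, make_table):
        table = make_table(np.zeros(10), np.full(10, 1e-4))
        assert count_significant(table, 5e-8) == 0
        assert count_significant(table, 1.0) == 10

    def test_monotone_in_threshold(self, make_table):
        rng = np.random.default_rng(0)
        table = make_table(rng.normal(0, 0.02, 500), np.full(500, 1e-4))
        counts = [count_significant(table, pc) for pc in (1e-8, 1e-6, 1e-4, 1e-2, 1.0)]
        assert counts == sorted(counts)


class TestLdTableReaders:
    def test_three_column_csv_with_and_without_header(self, tmp_path):
        with_h = tmp_path / "a.csv"
        with_h.write_text("id_a,id_b,r2\nrs1,rs2,0.5\n")
        without = tmp_path / "b.csv"
        without.write_text("rs1,rs2,0.5\nrs2,rs3,0.05\n")
        for path, n in ((with_h, 1), (without, 2)):
            ld = read_ld_table(path)
            assert len(ld.pairs) == n
            assert ld.pairs.iloc[0].tolist() == ["rs1", "rs2", 0.5]

    def test_whitespace_pairwise_report_dialect(self, tmp_path):
        p = tmp_path / "plink.ld"
        p.write_text(
            " CHR_A   BP_A  SNP_A  CHR_B   BP_B  SNP_B     R2\n"
            "     1  10000    rs1      1  20000    rs2   0.75\n"
            "     1  10000    rs1      1  30000    rs3   0.05\n"
        )
        ld = read_ld_table(p)
        assert len(ld.pairs) == 2
        adj = ld.neighbors_above(0.1)
        assert adj == {"rs1": {"rs2"}, "rs2": {"rs1"}}

    def test_self_pairs_ignored_and_bad_r2_rejected(self):
        ld = _ld([("rs1", "rs1", 0.9), ("rs1", "rs2", 0.5)])
        assert len(ld.pairs) == 1
        with pytest.raises(ValueError):
            _ld([("rs1", "rs2", 1.5)])

    def test_panel_and_allele_map_readers(self, tmp_path):
        panel = tmp_path / "panel.txt"
        panel.write_text("rs1\nrs2\n")
        assert read_panel(panel) == {"rs1", "rs2"}
        amap_path = tmp_path / "amap.tsv"
        amap_path.write_text("snp_id\tancestral\tderived\nrs1\tG\tA\n")
        assert read_allele_map(amap_path) == {"rs1": ("G", "A")}
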