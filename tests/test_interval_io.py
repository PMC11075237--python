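"""Input parsing, harmonization, filtering, and table round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_profile, write_run_inputs
from ocrenrich import (GenomeBuild, read_chrom_sizes, read_loci_folder,
                      read_mask, read_ocr_folder, write_enrichment_table)
from ocrenrich.enrichment_pipeline import EnrichmentMatrix, annotate_significance
from ocrenrich.errors import InputError


class TestChromSizes:
    def test_basic_two_rows(self, tmp_path):
        f = tmp_path / "sizes.csv"
        f.write_text("chr1,305000\nchr2,100000\n")
        b = read_chrom_sizes(f)
        assert len(b) == 2 and b.total_bp == 405000

    def test_header_auto_skipped(self, tmp_path):
        f = tmp_path / "sizes.csv"
        f.write_text("chrom,size\nchr1,305000\nchr2,100000\n")
        b = read_chrom_sizes(f)
        assert b.names == ("chr1", "chr2")

    def test_zero_length_row_rejected(self, tmp_path):
        f = tmp_path / "sizes.csv"
        f.write_text("chr1,0\nchr2,100\n")
        b = read_chrom_sizes(f)
        assert b.names == ("chr2",)

    def test_no_parseable_rows_fatal(self, tmp_path):
        f = tmp_path / "sizes.csv"
        f.write_text("chr1,0\n")
        with pytest.raises(InputError, match="sizes.csv"):
            read_chrom_sizes(f)

    @given(st.sampled_from(["chr1", "1", "CHR1", "chrX", "X", "weird"]))
    def test_harmonization_is_an_involution(self, name):
        b = GenomeBuild(("chr1", "chrX"), (100, 100))
        once = b.harmonize(name)
        assert b.harmonize(once) == once


class TestOcrFolder:
    def test_overlapping_peaks_merged(self, tmp_path, build):
        (tmp_path / "a.txt").write_text("chr1\t10\t20\nchr1\t15\t30\n")
        profs = read_ocr_folder(tmp_path, build)
        assert profs[0].n_peaks() == 1
        assert profs[0].peaks["chr1"].tolist() == [[10, 30]]

    def test_peak_clipped_to_chromosome_end(self, tmp_path, build):
        (tmp_path / "a.txt").write_text("chr1\t900\t2000\n")
        profs = read_ocr_folder(tmp_path, build)
        assert profs[0].peaks["chr1"].tolist() == [[900, 1000]]

    def test_one_profile_per_file_named_by_stem(self, tmp_path, build):
        for stem in ("alpha", "beta", "gamma"):
            (tmp_path / f"{stem}.txt").write_text("chr1\t0\t10\n")
        profs = read_ocr_folder(tmp_path, build)
        assert [p.name for p in profs] == ["alpha", "beta", "gamma"]

    def test_empty_folder_fatal(self, tmp_path, build):
        with pytest.raises(InputError):
            read_ocr_folder(tmp_path, build)

    def test_unparseable_file_skipped_with_warning(self, tmp_path, build, caplog):
        (tmp_path / "good.txt").write_text("chr1\t0\t10\n")
        (tmp_path / "bad.txt").write_text("no intervals here\n")
        profs = read_ocr_folder(tmp_path, build)
        assert [p.name for p in profs] == ["good"]
        assert any("bad" in r.message for r in caplog.records)

    def test_chr_prefix_harmonized_to_build_dialect(self, tmp_path):
        b = GenomeBuild(("1", "2"), (1000, 1000))
        (tmp_path / "a.txt").write_text("chr1\t0\t10\n2\t5\t15\n")
        profs = read_ocr_folder(tmp_path, b)
        assert set(profs[0].peaks) == {"1", "2"}

    def test_loading_is_idempotent(self, tmp_path, build):
        (tmp_path / "in").mkdir()
        (tmp_path / "in" / "a.txt").write_text(
            "chr1\t10\t20\nchr1\t20\t40\nchr2\t5\t9\n")
        first = read_ocr_folder(tmp_path / "in", build)[0]
        # write the loaded profile back out and reload it
        (tmp_path / "out").mkdir()
        with (tmp_path / "out" / "a.txt").open("w") as fh:
            for c, arr in first.peaks.items():
                for s, e in arr:
                    fh.write(f"{c}\t{s}\t{e}\n")
        second = read_ocr_folder(tmp_path / "out", build)[0]
        for c in first.peaks:
            assert np.array_equal(first.peaks[c], second.peaks[c])
        assert first.total_bp() <= build.total_bp


class TestLociFolder:
    def _write(self, folder, name, rows, header="chr\tpos"):
        folder.mkdir(exist_ok=True)
        (folder / name).write_text(
            (header + "\n" if header else "") + "\n".join(rows) + "\n")

    def test_small_set_excluded_by_min_loci(self, tmp_path, build):
        rows = [f"chr1\t{i + 1}" for i in range(150)]
        self._write(tmp_path / "loci", "s.tsv", rows)
        with pytest.raises(InputError, match="min_loci=200"):
            read_loci_folder(tmp_path / "loci", build, min_loci=200)

    def test_min_loci_zero_retains_everything(self, tmp_path, build):
        self._write(tmp_path / "loci", "s.tsv", ["chr1\t5"])
        sets = read_loci_folder(tmp_path / "loci", build, min_loci=0)
        assert sets[0].n == 1

    def test_pvalue_filter_applied_before_counting(self, tmp_path, build):
        # 300 loci of which 120 reach genome-wide significance: the set is
        # excluded at min_loci=200 after filtering (120 < 200)
        rows = [f"chr1\t{i + 1}\t{'4e-8' if i < 120 else '1e-6'}"
                for i in range(300)]
        self._write(tmp_path / "loci", "s.tsv", rows, header="chr\tpos\tp")
        with pytest.raises(InputError):
            read_loci_folder(tmp_path / "loci", build, min_loci=200,
                             pvalue_threshold=5e-8)
        sets = read_loci_folder(tmp_path / "loci", build, min_loci=100,
                                pvalue_threshold=5e-8)
        assert sets[0].n == 120

    def test_single_position_column_is_one_based(self, tmp_path, build):
        self._write(tmp_path / "loci", "s.tsv", ["chr1\t100"])
        ls = read_loci_folder(tmp_path / "loci", build, min_loci=0)[0]
        assert ls.loci["chr1"].tolist() == [[99, 100]]

    def test_start_end_columns_are_bed_like(self, tmp_path, build):
        self._write(tmp_path / "loci", "s.tsv", ["chr1\t99\t104"],
                    header="chrom\tstart\tend")
        ls = read_loci_folder(tmp_path / "loci", build, min_loci=0)[0]
        assert ls.loci["chr1"].tolist() == [[99, 104]]
        assert ls.max_length() == 5

    def test_headerless_positional_columns(self, tmp_path, build):
        self._write(tmp_path / "loci", "s.csv", ["chr1,100", "chr2,7"],
                    header=None)
        ls = read_loci_folder(tmp_path / "loci", build, min_loci=0)[0]
        assert ls.n == 2

    def test_duplicates_collapsed_and_offbuild_dropped(self, tmp_path, build):
        rows = ["chr1\t10", "chr1\t10", "chrUn\t5"]
        self._write(tmp_path / "loci", "s.tsv", rows)
        ls = read_loci_folder(tmp_path / "loci", build, min_loci=0)[0]
        assert ls.n == 1


class TestMask:
    def test_mask_reads_bed(self, tmp_path, build):
        (tmp_path / "m.bed").write_text("chr1\t0\t500\n")
        m = read_mask(tmp_path / "m.bed", build)
        assert m["chr1"].tolist() == [[0, 500]]

    def test_empty_mask_fatal(self, tmp_path, build):
        (tmp_path / "m.bed").write_text("\n")
        with pytest.raises(InputError):
            read_mask(tmp_path / "m.bed", build)


class TestEnrichmentTable:
    def _matrix(self):
        p = np.array([[7.22e-12, 0.4], [0.03, 1.0]])
        tiers = annotate_significance(p, 0.05, "bonferroni")
        return EnrichmentMatrix(["ct1", "ct2"], ["s1", "s2"], p,
                                np.full((2, 2), "exact", dtype=object),
                                tiers, ["ct1", "ct2"], None)

    def test_long_table_shape_and_round_trip(self, tmp_path):
        m = self._matrix()
        long_path, wide_path = write_enrichment_table(m, tmp_path)
        long_df = pd.read_csv(long_path)
        assert len(long_df) == 4
        wide = pd.read_csv(wide_path, index_col=0,
                           float_precision="round_trip")
        # bit-exact round trip, including the 7.22e-12 entry
        assert np.array_equal(wide.to_numpy(), m.p)
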