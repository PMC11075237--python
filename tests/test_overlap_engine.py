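"""Window statistics, overlap counting, mask and uniqueness filtering."""

import numpy as np
import pytest

from conftest import make_loci, make_profile, profile_mask
from ocrenrich import (GenomeBuild, apply_mask, assign_loci, count_overlaps,
                      effective_coverage, partition_genome,
                      peak_uniqueness_filter, peak_uniqueness_values,
                      window_statistics)
from ocrenrich.genome_windows import Window
from ocrenrich.interval_io import Interval, Locus
from ocrenrich.errors import ParameterError


class TestAssignLoci:
    def test_loci_counted_in_containing_window(self):
        build = GenomeBuild(("chr1",), (100,))
        plan = partition_genome(build, 100)
        ls = make_loci("s", [("chr1", 10), ("chr1", 50), ("chr1", 80)])
        counts = assign_loci(ls, plan)
        assert list(counts.values()) == [3]

    def test_boundary_locus_goes_to_right_window(self):
        build = GenomeBuild(("chr1",), (200,))
        plan = partition_genome(build, 100)
        ls = make_loci("s", [("chr1", 100)])
        (w, n), = assign_loci(ls, plan).items()
        assert w.index == 1 and n == 1

    def test_counts_conserve_total(self):
        build = GenomeBuild(("chr1",), (1000,))
        plan = partition_genome(build, 100)
        rng = np.random.default_rng(42)
        pos = rng.integers(0, 1000, size=1000)
        ls = make_loci("s", [("chr1", int(p)) for p in pos])
        # exact duplicates collapse in from_intervals? no: LociSet keeps all
        counts = assign_loci(ls, plan)
        assert sum(counts.values()) == ls.n
        # brute-force recount per window
        for w, n in counts.items():
            assert n == int(((pos >= w.start) & (pos < w.end)).sum())


class TestEffectiveCoverage:
    def test_snv_coverage_is_plain_fraction(self):
        prof = make_profile("p", {"chr1": [(0, 10), (40, 55)]})
        w = Window("chr1", 0, 100, 0)
        assert effective_coverage(prof, w, []) == pytest.approx(0.25)

    def test_no_peaks_gives_zero_probability(self):
        prof = make_profile("p", {"chr1": [(500, 600)]})
        w = Window("chr2", 0, 100, 0)
        assert effective_coverage(prof, w, []) == 0.0

    def test_indel_extension_matches_enumeration_oracle(self):
        # window [0,100), peak [50,60), locus length 5: every start position
        # from which a 5-bp locus touches the peak counts as a success
        prof = make_profile("p", {"chr1": [(50, 60)]})
        w = Window("chr1", 0, 100, 0)
        locus = Locus("chr1", 0, 5)
        got = effective_coverage(prof, w, [locus])
        starts = [s for s in range(100)
                  if max(s, 50) < min(s + 5, 60)]  # brute-force enumeration
        assert len(starts) == 14
        assert got == pytest.approx(len(starts) / 100)

    def test_extension_capped_at_one(self):
        prof = make_profile("p", {"chr1": [(50, 100)]})
        w = Window("chr1", 0, 100, 0)
        assert effective_coverage(prof, w, [Locus("chr1", 0, 51)]) == 1.0

    def test_fragmented_peaks_leave_coverage_unchanged(self):
        whole = make_profile("a", {"chr1": [(20, 80)]})
        split = make_profile("b", {"chr1": [(20, 50), (50, 80)]})
        w = Window("chr1", 0, 100, 0)
        for loci in ([], [Locus("chr1", 0, 7)]):
            assert (effective_coverage(whole, w, loci)
                    == effective_coverage(split, w, loci))


class TestCountOverlaps:
    def test_boundary_semantics(self):
        prof = make_profile("p", {"chr1": [(50, 60)]})
        inside = make_loci("a", [("chr1", 50)])
        adjacent = make_loci("b", [("chr1", 49)])
        assert count_overlaps(inside, prof).total == 1
        assert count_overlaps(adjacent, prof).total == 0

    def test_empty_profile_counts_zero(self):
        prof = make_profile("p", {})
        ls = make_loci("a", [("chr1", 10)])
        assert count_overlaps(ls, prof).total == 0

    def test_matches_quadratic_oracle_on_random_fixture(self, build):
        rng = np.random.default_rng(7)
        peaks = {"chr1": [(int(s), int(s) + int(l)) for s, l in
                          zip(rng.integers(0, 950, 25), rng.integers(1, 50, 25))],
                 "chr2": [(int(s), int(s) + int(l)) for s, l in
                          zip(rng.integers(0, 750, 25), rng.integers(1, 50, 25))]}
        prof = make_profile("p", peaks)
        triples = []
        for _ in range(200):
            c = "chr1" if rng.random() < 0.5 else "chr2"
            s = int(rng.integers(0, 700))
            triples.append((c, s, s + int(rng.integers(1, 6))))
        ls = make_loci("s", triples)
        brute = 0
        for c, s, e in triples:
            hit = any(max(s, ps) < min(e, pe) for ps, pe in peaks[c])
            brute += hit
        assert count_overlaps(ls, prof).total == brute

    def test_adding_a_peak_never_decreases_count_or_coverage(self, build):
        plan = partition_genome(build, 100)
        base = make_profile("p", {"chr1": [(100, 150)]})
        more = make_profile("p", {"chr1": [(100, 150), (400, 420)]})
        ls = make_loci("s", [("chr1", i * 37 % 1000) for i in range(50)])
        assert (count_overlaps(ls, more).total
                >= count_overlaps(ls, base).total)
        sb = {st.window.index: st.p_w for st in window_statistics(base, ls, plan)}
        sm = {st.window.index: st.p_w for st in window_statistics(more, ls, plan)}
        assert all(sm[i] >= sb[i] for i in sb)


class TestWindowStatistics:
    def test_stats_cover_only_occupied_windows(self, build):
        plan = partition_genome(build, 100)
        prof = make_profile("p", {"chr1": [(0, 50)]})
        ls = make_loci("s", [("chr1", 10), ("chr1", 110)])
        stats = window_statistics(prof, ls, plan)
        assert [(s.window.index, s.n_w) for s in stats] == [(0, 1), (1, 1)]
        assert stats[0].p_w == pytest.approx(0.5)
        assert stats[1].p_w == 0.0

    def test_sum_nw_equals_on_build_loci(self, build):
        plan = partition_genome(build, 64)
        prof = make_profile("p", {"chr1": [(0, 10)]})
        rng = np.random.default_rng(3)
        ls = make_loci("s", [("chr1", int(p)) for p in rng.integers(0, 1000, 300)])
        stats = window_statistics(prof, ls, plan)
        assert sum(s.n_w for s in stats) == ls.n


class TestMask:
    def test_whole_genome_mask_is_identity(self, build):
        prof = make_profile("p", {"chr1": [(10, 30), (500, 600)]})
        mask = {"chr1": np.array([[0, 1000]]), "chr2": np.array([[0, 800]])}
        out = apply_mask([prof], mask)[0]
        assert np.array_equal(out.peaks["chr1"], prof.peaks["chr1"])

    def test_disjoint_peak_removed(self):
        prof = make_profile("p", {"chr1": [(10, 30), (500, 600)]})
        out = apply_mask([prof], [Interval("chr1", 0, 100)])[0]
        assert out.peaks["chr1"].tolist() == [[10, 30]]

    def test_one_bp_overlap_keeps_full_peak(self):
        prof = make_profile("p", {"chr1": [(10, 30)]})
        for mask_iv, kept in [(Interval("chr1", 29, 40), True),
                              (Interval("chr1", 30, 40), False),
                              (Interval("chr1", 5, 11), True)]:
            out = apply_mask([prof], [mask_iv])[0]
            if kept:
                assert out.peaks["chr1"].tolist() == [[10, 30]]  # untrimmed
            else:
                assert "chr1" not in out.peaks

    def test_empty_mask_fatal(self):
        prof = make_profile("p", {"chr1": [(10, 30)]})
        with pytest.raises(ParameterError):
            apply_mask([prof], [])


class TestPeakUniqueness:
    def _fixture(self):
        # chr1 layout: peak A [0,10) present in 4 profiles; B [20,30) in 2;
        # C [40,50) private to profile 0
        shared4 = [(0, 10)]
        shared2 = [(20, 30)]
        profs = [
            make_profile("p0", {"chr1": shared4 + shared2 + [(40, 50)]}),
            make_profile("p1", {"chr1": shared4 + shared2}),
            make_profile("p2", {"chr1": shared4}),
            make_profile("p3", {"chr1": [(5, 12)]}),      # overlaps A
            make_profile("p4", {"chr1": [(100, 120)]}),   # isolated
        ]
        return profs

    def test_uniqueness_values_match_bruteforce_matrix(self):
        profs = self._fixture()
        values = peak_uniqueness_values(profs)
        for prof in profs:
            for chrom, peaks in prof.peaks.items():
                for row, (s, e) in enumerate(peaks):
                    brute = sum(
                        any(max(s, ps) < min(e, pe)
                            for ps, pe in other.peaks.get(chrom, []))
                        for other in profs)
                    assert values[prof.name][chrom][row] == brute

    def test_k3_removes_peaks_shared_by_four_or_more(self):
        profs = self._fixture()
        out = peak_uniqueness_filter(profs, 3)
        # peak A (uniqueness 4) must vanish from every profile
        for prof in out:
            for s, e in prof.peaks.get("chr1", []):
                assert not (max(s, 0) < min(e, 10))
        # peak B (uniqueness 2) and C (uniqueness 1) survive in p0
        assert out[0].peaks["chr1"].tolist() == [[20, 30], [40, 50]]

    def test_k_equal_profile_count_removes_nothing(self):
        profs = self._fixture()
        out = peak_uniqueness_filter(profs, len(profs))
        for a, b in zip(profs, out):
            for c in a.peaks:
                assert np.array_equal(a.peaks[c], b.peaks[c])

    def test_k1_keeps_only_private_peaks(self):
        profs = self._fixture()
        out = peak_uniqueness_filter(profs, 1)
        assert out[0].peaks["chr1"].tolist() == [[40, 50]]
        assert out[4].peaks["chr1"].tolist() == [[100, 120]]

    def test_invalid_k_rejected(self):
        with pytest.raises(ParameterError):
            peak_uniqueness_filter(self._fixture(), 0)
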