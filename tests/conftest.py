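import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("deterministic")

from ocrenrich import CellTypeProfile, GenomeBuild, Interval, LociSet  # noqa: E402


@pytest.fixture
def build():
    return GenomeBuild(("chr1", "chr2"), (1000, 800))


def make_profile(name, peaks_by_chrom):
    """Profile from {chrom: [(start, end), ...]} (merged on construction)."""
    items = [Interval(c, s, e)
             for c, pairs in peaks_by_chrom.items() for s, e in pairs]
    return CellTypeProfile.from_intervals(name, items)


def make_loci(name, triples):
    """Loci set from (chrom, start[, end]) tuples; end defaults to start+1."""
    items = []
    for t in triples:
        c, s = t[0], t[1]
        e = t[2] if len(t) > 2 else s + 1
        items.append(Interval(c, s, e))
    return LociSet.from_intervals(name, items)


def profile_mask(profile, build):
    """bp-level boolean masks per chromosome — brute-force coverage oracle."""
    masks = {}
    for name, length in build:
        m = np.zeros(length, dtype=bool)
        for s, e in profile.peaks.get(name, []):
            m[s:e] = True
        masks[name] = m
    return masks


def write_run_inputs(tmp_path, build, profiles, loci_sets):
    """Write sizes/ocr/loci files for pipeline and CLI tests."""
    sizes = tmp_path / "sizes.csv"
    with sizes.open("w") as fh:
        fh.write("chrom,size\n")
        for n, l in build:
            fh.write(f"{n},{l}\n")
    ocr = tmp_path / "ocr"
    ocr.mkdir(exist_ok=True)
    for p in profiles:
        with (ocr / f"{p.name}.txt").open("w") as fh:
            for c, a in p.peaks.items():
                for s, e in a:
                    fh.write(f"{c}\t{s}\t{e}\n")
    loci = tmp_path / "loci"
    loci.mkdir(exist_ok=True)
    for ls in loci_sets:
        with (loci / f"{ls.name}.tsv").open("w") as fh:
            fh.write("chrom\tstart\tend\n")
            for l in ls.iter_loci():
                fh.write(f"{l.chrom}\t{l.start}\t{l.end}\n")
    return ocr, loci, sizes
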