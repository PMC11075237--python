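"""Readers and writers for the four required inputs and the tabular outputs.

The analysis needs (1) a folder of open-chromatin (OCR / peak) files, one per
cell type, BED-like with at least three columns; (2) a folder of
loci-of-interest files, one per study, tab- or comma-separated; (3) a
chromosome-sizes ``.csv``; and (4) an output folder.  This module turns the
first three into validated in-memory containers and writes the enrichment
tables back out.

Coordinate conventions
----------------------
OCR and mask files follow the BED dialect: 0-based, half-open.  Loci files
carrying only a chromosome and a single position column are read as 1-based
positions (the dominant GWAS-catalog dialect) and converted to 1-bp half-open
intervals; files that also carry an end column are read as 0-based half-open.
Chromosome names are harmonized to the dialect of the chromosome-sizes file
(``chr1`` vs ``1``) before any comparison.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import intervals as iv
from .errors import InputError

log = logging.getLogger(__name__)

CHROM_TOKENS = {"chr", "chrom", "chromosome", "chr_id", "chr_name", "seqnames"}
POS_TOKENS = {"pos", "position", "chr_pos", "bp", "start", "base_pair_location"}
END_TOKENS = {"end", "stop", "chr_end"}
PVAL_TOKENS = {"p", "pvalue", "p_value", "p-value", "pval", "p.value"}


@dataclass(frozen=True)
class Interval:
    """A half-open genomic interval [start, end), 0-based."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


class Locus(Interval):
    """A query locus: length 1 for SNVs, > 1 for small indels."""


@dataclass
class GenomeBuild:
    """Ordered chromosome name -> length map; the coordinate authority.

    Iteration order is file order, so every downstream container and output
    table is deterministic for a given sizes file.
    """

    names: Tuple[str, ...]
    lengths: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise InputError("duplicate chromosome names in genome build")
        if any(l < 1 for l in self.lengths):
            raise InputError("chromosome lengths must be >= 1")
        self._sizes = dict(zip(self.names, self.lengths))

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[Tuple[str, int]]:
        return iter(zip(self.names, self.lengths))

    def __contains__(self, name: str) -> bool:
        return name in self._sizes

    def length_of(self, name: str) -> int:
        return self._sizes[name]

    @property
    def total_bp(self) -> int:
        return sum(self.lengths)

    def harmonize(self, name: str) -> str:
        """Map a chromosome name onto this build's dialect.

        Adds or strips a leading ``chr`` as needed; idempotent.  Names that
        cannot be matched are returned unchanged (callers drop them).
        """
        name = str(name).strip()
        if name in self._sizes:
            return name
        if name.lower().startswith("chr"):
            alt = name[3:]
        else:
            alt = "chr" + name
        if alt in self._sizes:
            return alt
        return name


@dataclass
class CellTypeProfile:
    """One cell type's OCR set, stored merged per chromosome."""

    name: str
    peaks: Dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, name: str, items: Sequence[Interval]) -> "CellTypeProfile":
        per: Dict[str, list] = {}
        for it in items:
            per.setdefault(it.chrom, []).append((it.start, it.end))
        return cls(name, {c: iv.merge(iv.as_array(v)) for c, v in per.items()})

    def total_bp(self) -> int:
        return sum(iv.total_bp(a) for a in self.peaks.values())

    def n_peaks(self) -> int:
        return sum(len(a) for a in self.peaks.values())

    def coverage_fraction(self, build: GenomeBuild) -> float:
        return self.total_bp() / build.total_bp

    def intervals(self) -> Iterator[Interval]:
        for chrom, a in self.peaks.items():
            for s, e in a:
                yield Interval(chrom, int(s), int(e))


@dataclass
class LociSet:
    """One study's query loci (SNVs and small indels), sorted per chromosome."""

    name: str
    loci: Dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, name: str, items: Sequence[Interval]) -> "LociSet":
        per: Dict[str, list] = {}
        for it in items:
            per.setdefault(it.chrom, []).append((it.start, it.end))
        out = {}
        for c, v in per.items():
            a = iv.as_array(v)
            a = a[np.lexsort((a[:, 1], a[:, 0]))]
            out[c] = a
        return cls(name, out)

    @property
    def n(self) -> int:
        return sum(len(a) for a in self.loci.values())

    def max_length(self) -> int:
        if self.n == 0:
            return 1
        return max(int((a[:, 1] - a[:, 0]).max()) for a in self.loci.values() if len(a))

    def iter_loci(self) -> Iterator[Locus]:
        for chrom, a in self.loci.items():
            for s, e in a:
                yield Locus(chrom, int(s), int(e))


def read_chrom_sizes(path) -> GenomeBuild:
    """Parse a chromosome-sizes table (name, length), optional header.

    Rows whose length field does not parse as a positive integer are skipped,
    which auto-skips header rows; an input with no usable row is fatal.
    """
    path = Path(path)
    names: List[str] = []
    lengths: List[int] = []
    try:
        text = path.read_text()
    except OSError as exc:
        raise InputError(f"cannot read chromosome sizes file {path}: {exc}") from exc
    for line in text.splitlines():
        parts = [p for p in re.split(r"[,\t ]+", line.strip()) if p]
        if len(parts) < 2:
            continue
        try:
            n = int(parts[1])
        except ValueError:
            continue
        if n < 1:
            log.warning("chromosome sizes: rejected row %r (non-positive length)", line)
            continue
        if parts[0] in names:
            log.warning("chromosome sizes: duplicate name %s, keeping first", parts[0])
            continue
        names.append(parts[0])
        lengths.append(n)
    if not names:
        raise InputError(f"no parseable chromosome rows in {path}")
    return GenomeBuild(tuple(names), tuple(lengths))


def _read_table(path: Path, sep: str) -> Optional[pd.DataFrame]:
    try:
        df = pd.read_csv(path, sep=sep, header=None, dtype=str,
                         comment="#", skip_blank_lines=True)
    except (pd.errors.EmptyDataError, pd.errors.ParserError):
        return None
    if df.empty:
        return None
    return df


def _read_bed_like(path: Path, build: GenomeBuild) -> Dict[str, np.ndarray]:
    """Read the first three BED columns of a file, clip, and merge per chrom."""
    df = _read_table(path, sep="\t")
    if df is None or df.shape[1] < 3:
        df = _read_table(path, sep=r"\s+")
    if df is None or df.shape[1] < 3:
        return {}
    chrom = df.iloc[:, 0].astype(str).str.strip()
    start = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    end = pd.to_numeric(df.iloc[:, 2], errors="coerce")
    ok = start.notna() & end.notna()
    chrom, start, end = chrom[ok], start[ok].astype(np.int64), end[ok].astype(np.int64)
    harmonized = chrom.map(build.harmonize)
    out: Dict[str, np.ndarray] = {}
    n_dropped = 0
    for name in build.names:
        m = (harmonized == name).to_numpy()
        if not m.any():
            continue
        a = np.column_stack([start.to_numpy()[m], end.to_numpy()[m]])
        a = iv.clip(a, build.length_of(name))
        if len(a):
            out[name] = iv.merge(a)
    n_dropped = int((~harmonized.isin(build.names)).sum())
    if n_dropped:
        log.warning("%s: dropped %d intervals on chromosomes absent from the build",
                    path.name, n_dropped)
    return out


def read_ocr_folder(path, build: GenomeBuild) -> List[CellTypeProfile]:
    """Load one OCR profile per file; peaks clipped, sorted and merged.

    Profile names are the file stems.  A file that yields no valid interval is
    skipped with a warning; an empty folder is fatal.
    """
    folder = Path(path)
    if not folder.is_dir():
        raise InputError(f"OCR folder {folder} does not exist")
    files = sorted(p for p in folder.iterdir()
                   if p.is_file() and not p.name.startswith("."))
    if not files:
        raise InputError(f"OCR folder {folder} contains no files")
    profiles: List[CellTypeProfile] = []
    for f in files:
        peaks = _read_bed_like(f, build)
        if not peaks:
            log.warning("OCR file %s has no valid interval; profile skipped", f.name)
            continue
        profiles.append(CellTypeProfile(f.stem, peaks))
    if not profiles:
        raise InputError(f"no OCR file in {folder} produced a usable profile")
    return profiles


def read_mask(path, build: GenomeBuild) -> Dict[str, np.ndarray]:
    """Read a BED3 mask; an unusable mask file is fatal (ambiguous intent)."""
    peaks = _read_bed_like(Path(path), build)
    if not peaks:
        raise InputError(f"mask file {path} contains no valid interval")
    return peaks


def _detect_columns(row0: Sequence[str]):
    """Return (has_header, chrom_idx, pos_idx, end_idx, pval_idx)."""
    cells = [str(x).strip().lower() for x in row0]
    ci = pi = ei = qi = None
    for i, c in enumerate(cells):
        if ci is None and c in CHROM_TOKENS:
            ci = i
        elif pi is None and c in POS_TOKENS:
            pi = i
        elif ei is None and c in END_TOKENS:
            ei = i
        elif qi is None and c in PVAL_TOKENS:
            qi = i
    if ci is not None and pi is not None:
        return True, ci, pi, ei, qi
    # no recognizable header: positional columns; row 0 is a header iff its
    # position field does not parse as an integer
    has_header = True
    if len(row0) >= 2:
        try:
            int(str(row0[1]).strip())
            has_header = False
        except ValueError:
            has_header = True
    return has_header, 0, 1, None, None


def read_loci_folder(path, build: GenomeBuild, min_loci: int = 200,
                     pvalue_threshold: Optional[float] = None) -> List[LociSet]:
    """Load loci sets from .tsv/.csv files, applying the size cutoff.

    Per file: detect chromosome/position(/end/p-value) columns, harmonize
    chromosomes, drop off-build loci and exact duplicates, optionally filter
    on the association p-value, then drop the whole set if fewer than
    ``min_loci`` loci remain (a conservative default of 200).
    """
    folder = Path(path)
    if not folder.is_dir():
        raise InputError(f"loci folder {folder} does not exist")
    files = sorted(p for p in folder.iterdir()
                   if p.suffix.lower() in {".tsv", ".csv", ".txt"}
                   and not p.name.startswith("."))
    if not files:
        raise InputError(f"loci folder {folder} contains no .tsv/.csv files")
    sets: List[LociSet] = []
    for f in files:
        sep = "," if f.suffix.lower() == ".csv" else "\t"
        df = _read_table(f, sep)
        if df is None or df.shape[1] < 2:
            log.warning("loci file %s unreadable or too few columns; skipped", f.name)
            continue
        has_header, ci, pi, ei, qi = _detect_columns(df.iloc[0])
        data = df.iloc[1:] if has_header else df
        chrom = data.iloc[:, ci].astype(str).str.strip().map(build.harmonize)
        pos = pd.to_numeric(data.iloc[:, pi], errors="coerce")
        if ei is not None:
            end = pd.to_numeric(data.iloc[:, ei], errors="coerce")
            start = pos
        else:
            start = pos - 1  # 1-based single position -> 0-based start
            end = pos
        pval = (pd.to_numeric(data.iloc[:, qi], errors="coerce")
                if qi is not None else None)
        ok = start.notna() & end.notna() & (start >= 0) & (end > start)
        on_build = chrom.isin(build.names)
        n_off = int((ok & ~on_build).sum())
        if n_off:
            log.warning("%s: dropped %d loci on chromosomes absent from the build",
                        f.name, n_off)
        ok &= on_build
        if pvalue_threshold is not None and pval is not None:
            ok &= pval.notna() & (pval <= pvalue_threshold)
        chrom_a = chrom[ok].to_numpy()
        s_a = start[ok].astype(np.int64).to_numpy()
        e_a = end[ok].astype(np.int64).to_numpy()
        # exact-duplicate collapse
        trip = pd.DataFrame({"c": chrom_a, "s": s_a, "e": e_a})
        before = len(trip)
        trip = trip.drop_duplicates()
        if len(trip) < before:
            log.info("%s: collapsed %d duplicate loci", f.name, before - len(trip))
        loci: Dict[str, np.ndarray] = {}
        for name in build.names:
            m = (trip["c"] == name).to_numpy()
            if not m.any():
                continue
            a = np.column_stack([trip["s"].to_numpy()[m], trip["e"].to_numpy()[m]])
            a = iv.clip(a, build.length_of(name))
            a = a[np.lexsort((a[:, 1], a[:, 0]))]
            if len(a):
                loci[name] = a
        ls = LociSet(f.stem, loci)
        if ls.n < min_loci:
            log.warning("loci set %s excluded: %d loci < min_loci=%d",
                        f.stem, ls.n, min_loci)
            continue
        sets.append(ls)
    if not sets:
        raise InputError(
            f"all loci sets in {folder} were filtered out (min_loci={min_loci})")
    return sets


def write_enrichment_table(matrix, out_dir) -> Tuple[Path, Path]:
    """Write the long-format tier table and the wide p-value matrix.

    Floats are serialized at 17 significant digits so that re-reading the
    tables reproduces the p-values bit-exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, ct in enumerate(matrix.cell_types):
        for j, ls in enumerate(matrix.loci_sets):
            rows.append((ct, ls, matrix.p[i, j], matrix.methods[i, j],
                         matrix.tiers[i, j]))
    long_df = pd.DataFrame(rows, columns=["cell_type", "loci_set", "p_value",
                                          "method", "tier"])
    long_path = out / "enrichment_long.csv"
    long_df.to_csv(long_path, index=False, float_format="%.17g")
    wide_df = pd.DataFrame(matrix.p, index=matrix.cell_types,
                           columns=matrix.loci_sets)
    wide_path = out / "pvalues_wide.csv"
    wide_df.to_csv(wide_path, float_format="%.17g", index_label="cell_type")
    return long_path, wide_path
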