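"""Synthetic chromatin landscapes and the null/power simulation harness.

The generator builds a small multi-chromosome genome with per-cell-type peak
sets (controllable density, mean peak length, and pairwise sharing) and a
fixed, seeded background SNP set from which null and enriched loci sets are
drawn.  On top of it, :func:`estimate_fpr` and :func:`estimate_tpr` measure
false/true positive rates of the windowed test across window sizes,
including a "naive" setting that treats the whole genome as one window (a
plain genome-wide binomial test).

Colocalization of the background with open chromatin -- the mechanism that
inflates the naive test on real data -- is emulated at chromosome scale:
per-chromosome peak density varies across chromosomes and the background
SNP density co-varies with it, while positions stay uniform within each
chromosome.  Windows never cross chromosomes, so the windowed null remains
exactly calibrated at every window size, whereas the genome-wide binomial
ignores the covariation and its false positive rate grows with the number
of SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import intervals as iv
from .errors import InputError, ParameterError
from .genome_windows import partition_genome
from .interval_io import CellTypeProfile, GenomeBuild, LociSet
from .null_model import tail_pvalue

log = logging.getLogger(__name__)

#: sentinel window size: one genome-wide window (plain binomial test)
NAIVE = "naive"

#: the window-size sweep used by default, in bp, plus the naive comparator
DEFAULT_WINDOW_SWEEP: List[Union[int, str]] = [
    25_000, 50_000, 100_000, 250_000, 500_000, 1_000_000, NAIVE]


@dataclass
class SyntheticGenome:
    """A seeded synthetic genome: build, peak profiles, and SNP background."""

    build: GenomeBuild
    profiles: List[CellTypeProfile]
    seed: int
    background: Dict[str, np.ndarray] = field(default_factory=dict)

    def profile(self, name: str) -> CellTypeProfile:
        for p in self.profiles:
            if p.name == name:
                return p
        raise KeyError(name)

    def coverage_fraction(self, profile: CellTypeProfile) -> float:
        return profile.total_bp() / self.build.total_bp

    def background_flat(self):
        """Background positions flattened genome-order: (chroms, positions)."""
        chroms, pos = [], []
        for name in self.build.names:
            a = self.background.get(name)
            if a is None or len(a) == 0:
                continue
            chroms.append(np.full(len(a), name, dtype=object))
            pos.append(a)
        return np.concatenate(chroms), np.concatenate(pos)


def generate_genome(seed: int,
                    n_chrom: int = 4,
                    chrom_length: int = 2_500_000,
                    peak_density: float = 1e-4,
                    mean_peak_len: float = 500.0,
                    n_profiles: int = 5,
                    sharing: float = 0.3,
                    density_gradient: float = 0.6,
                    background_size: int = 500_000,
                    colocalization: float = 0.2) -> SyntheticGenome:
    """Generate a seeded synthetic chromatin landscape.

    Peaks are placed by a Poisson point process at ``peak_density`` peaks/bp
    with exponential lengths of mean ``mean_peak_len``; a ``sharing``
    fraction of each profile's peaks comes from a pool common to all
    profiles.  Per-chromosome densities are scaled linearly across
    chromosomes by ``1 +/- density_gradient`` and the background SNP weights
    follow the same gradient with strength ``colocalization`` (0 = uniform
    background).  Everything is reproducible from ``seed``.
    """
    if peak_density <= 0 or mean_peak_len <= 0:
        raise ParameterError("peak density and mean length must be positive")
    if not 0.0 <= sharing <= 1.0:
        raise ParameterError("sharing must lie in [0, 1]")
    if peak_density * mean_peak_len > 0.5:
        raise InputError(
            f"requested coverage {peak_density * mean_peak_len:.2f} exceeds "
            "half the genome; reduce peak_density or mean_peak_len")
    rng = np.random.default_rng(seed)
    names = tuple(f"chr{i + 1}" for i in range(n_chrom))
    build = GenomeBuild(names, tuple([chrom_length] * n_chrom))
    if n_chrom > 1:
        mult = 1.0 + density_gradient * np.linspace(-1, 1, n_chrom)
    else:
        mult = np.ones(1)

    def place(n_peaks: int, length: int) -> np.ndarray:
        starts = rng.integers(0, length, size=n_peaks)
        lens = np.maximum(1, rng.exponential(mean_peak_len, size=n_peaks)
                          .astype(np.int64))
        return iv.clip(np.column_stack([starts, starts + lens]), length)

    shared: Dict[str, np.ndarray] = {}
    privates: List[Dict[str, np.ndarray]] = [dict() for _ in range(n_profiles)]
    for c, name in enumerate(names):
        lam = peak_density * chrom_length * mult[c]
        n_shared = rng.poisson(lam * sharing)
        shared[name] = place(n_shared, chrom_length)
        for k in range(n_profiles):
            n_priv = rng.poisson(lam * (1.0 - sharing))
            privates[k][name] = place(n_priv, chrom_length)
    profiles = []
    for k in range(n_profiles):
        peaks = {name: iv.merge(np.vstack([shared[name], privates[k][name]]))
                 for name in names}
        peaks = {c: a for c, a in peaks.items() if len(a)}
        profiles.append(CellTypeProfile(f"celltype_{k:02d}", peaks))

    # seeded background: per-chromosome weights covary with peak density
    union = {name: iv.merge(np.vstack([p.peaks.get(name, iv.EMPTY)
                                       for p in profiles]))
             for name in names}
    peak_bp = np.array([iv.total_bp(union[name]) for name in names], float)
    len_share = np.full(n_chrom, 1.0 / n_chrom)
    peak_share = (peak_bp / peak_bp.sum()) if peak_bp.sum() > 0 else len_share
    weights = (1.0 - colocalization) * len_share + colocalization * peak_share
    counts = rng.multinomial(background_size, weights / weights.sum())
    background = {name: np.sort(rng.integers(0, chrom_length, size=counts[c]))
                  for c, name in enumerate(names)}
    return SyntheticGenome(build, profiles, seed, background)


def _positions_to_set(name: str, chroms: np.ndarray, pos: np.ndarray,
                      build: GenomeBuild) -> LociSet:
    loci: Dict[str, np.ndarray] = {}
    for cname in build.names:
        m = chroms == cname
        if not m.any():
            continue
        p = np.sort(pos[m])
        loci[cname] = np.column_stack([p, p + 1]).astype(np.int64)
    return LociSet(name, loci)


def sample_null_snps(genome: SyntheticGenome, n: int, seed: int) -> LociSet:
    """Draw ``n`` SNVs uniformly from the fixed background position set."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    chroms, pos = genome.background_flat()
    replace = n > len(pos)
    if replace:
        log.warning("requested %d SNPs from a background of %d: sampling "
                    "with replacement", n, len(pos))
    idx = rng.choice(len(pos), size=n, replace=replace)
    return _positions_to_set(f"null_n{n}_s{seed}", chroms[idx], pos[idx],
                             genome.build)


def _inside_flags(genome: SyntheticGenome, profile: CellTypeProfile,
                  chroms: np.ndarray, pos: np.ndarray) -> np.ndarray:
    flags = np.zeros(len(pos), dtype=bool)
    for cname in genome.build.names:
        m = chroms == cname
        peaks = profile.peaks.get(cname)
        if peaks is None or not m.any():
            continue
        flags[m] = iv.overlaps_any(peaks, pos[m], pos[m] + 1)
    return flags


def sample_enriched_snps(genome: SyntheticGenome, profile: CellTypeProfile,
                         n: int, enrichment_pct: float, seed: int) -> LociSet:
    """Draw SNVs with a planted overlap proportion.

    With ``q`` the profile's genome coverage fraction, the target overlap
    proportion is ``min(1, q * (1 + enrichment_pct / 100))``; the matching
    fixed numbers of SNPs are drawn from the background positions inside and
    outside the profile's peaks, so the constructed set's overlap count is
    exact by construction.
    """
    if enrichment_pct < 0:
        raise ParameterError("enrichment_pct must be >= 0")
    q = genome.coverage_fraction(profile)
    if q == 0 and enrichment_pct > 0:
        raise InputError("profile has zero coverage: enrichment is undefined")
    target = min(1.0, q * (1.0 + enrichment_pct / 100.0))
    n_in = int(round(target * n))
    n_out = n - n_in
    rng = np.random.default_rng(seed)
    chroms, pos = genome.background_flat()
    inside = _inside_flags(genome, profile, chroms, pos)
    in_idx = np.flatnonzero(inside)
    out_idx = np.flatnonzero(~inside)
    if n_in > 0 and len(in_idx) == 0:
        raise InputError("no background positions inside the profile's peaks")
    pick_in = rng.choice(in_idx, size=n_in, replace=n_in > len(in_idx))
    pick_out = rng.choice(out_idx, size=n_out, replace=n_out > len(out_idx))
    idx = np.concatenate([pick_in, pick_out])
    return _positions_to_set(f"enriched_{enrichment_pct:g}_n{n}_s{seed}",
                             chroms[idx], pos[idx], genome.build)


class _FastTester:
    """Precomputed per-(genome, profile, window size) replicate machinery."""

    def __init__(self, genome: SyntheticGenome, profile: CellTypeProfile,
                 window_size: Union[int, str]):
        self.naive = window_size == NAIVE
        chroms, pos = genome.background_flat()
        self.n_background = len(pos)
        self.inside = _inside_flags(genome, profile, chroms, pos)
        self.q = genome.coverage_fraction(profile)
        if not self.naive:
            plan = partition_genome(genome.build, int(window_size))
            widx = np.empty(len(pos), dtype=np.int64)
            for cname in genome.build.names:
                m = chroms == cname
                if not m.any():
                    continue
                e = plan.edges[cname]
                widx[m] = (plan.offsets[cname]
                           + np.searchsorted(e, pos[m], side="right") - 1)
            self.widx = widx
            from .overlap_engine import base_window_coverage
            self.pws = base_window_coverage(profile, plan)
            self.n_windows = plan.n_windows

    def pvalue(self, idx: np.ndarray) -> float:
        observed = int(self.inside[idx].sum())
        n = len(idx)
        if self.naive:
            return tail_pvalue([n], [self.q], observed).value
        counts = np.bincount(self.widx[idx], minlength=self.n_windows)
        occ = counts > 0
        return tail_pvalue(counts[occ], self.pws[occ], observed).value


def estimate_fpr(genome: SyntheticGenome, profile: CellTypeProfile,
                 n_snps: int, window_size: Union[int, str],
                 alpha: float = 0.05, n_reps: int = 2000,
                 seed: int = 0) -> float:
    """Fraction of null replicates with p <= alpha."""
    tester = _FastTester(genome, profile, window_size)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7919]))
    hits = 0
    replace = n_snps > tester.n_background
    for _ in range(n_reps):
        idx = rng.choice(tester.n_background, size=n_snps, replace=replace)
        if tester.pvalue(idx) <= alpha:
            hits += 1
    return hits / n_reps


def estimate_tpr(genome: SyntheticGenome, profile: CellTypeProfile,
                 n_snps: int, enrichment_pct: float,
                 window_size: Union[int, str], alpha: float = 0.05,
                 n_reps: int = 1000, seed: int = 0) -> float:
    """Fraction of planted-enrichment replicates with p <= alpha."""
    tester = _FastTester(genome, profile, window_size)
    target = min(1.0, tester.q * (1.0 + enrichment_pct / 100.0))
    if tester.q == 0 and enrichment_pct > 0:
        raise InputError("profile has zero coverage: enrichment is undefined")
    n_in = int(round(target * n_snps))
    n_out = n_snps - n_in
    in_idx = np.flatnonzero(tester.inside)
    out_idx = np.flatnonzero(~tester.inside)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 104729]))
    hits = 0
    for _ in range(n_reps):
        pick_in = rng.choice(in_idx, size=n_in, replace=n_in > len(in_idx))
        pick_out = rng.choice(out_idx, size=n_out,
                              replace=n_out > len(out_idx))
        idx = np.concatenate([pick_in, pick_out])
        if tester.pvalue(idx) <= alpha:
            hits += 1
    return hits / n_reps


@dataclass
class SimResult:
    """Tidy container for a sweep of FPR/TPR cells."""

    rows: List[dict] = field(default_factory=list)

    def add(self, **kw) -> None:
        self.rows.append(kw)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> Path:
        self.to_dataframe().to_csv(path, index=False)
        return Path(path)


def run_sweep(genome: SyntheticGenome, profile: CellTypeProfile,
              window_sizes: Optional[Sequence[Union[int, str]]] = None,
              snp_counts: Sequence[int] = (300, 1000, 3000),
              enrichment_pcts: Sequence[float] = (0.0, 30.0, 50.0),
              alpha: float = 0.05, n_reps: int = 2000,
              seed: int = 0) -> SimResult:
    """FPR/TPR rates for every (window size, snp count, enrichment) cell.

    ``enrichment_pct = 0`` cells are null simulations (the rate is an FPR);
    positive cells are power simulations (TPR).
    """
    window_sizes = list(window_sizes or DEFAULT_WINDOW_SWEEP)
    result = SimResult()
    for ws in window_sizes:
        for n in snp_counts:
            for e in enrichment_pcts:
                if e == 0:
                    rate = estimate_fpr(genome, profile, n, ws, alpha,
                                        n_reps, seed)
                else:
                    rate = estimate_tpr(genome, profile, n, e, ws, alpha,
                                        n_reps, seed)
                result.add(window_size=ws, n_snps=n, enrichment_pct=e,
                           rate=rate, n_reps=n_reps, alpha=alpha, seed=seed)
    return result


def plot_rates(result: SimResult, path, enrichment_pct: float = 0.0) -> Path:
    """Line plot of rate vs SNP count, one line per window size."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.to_dataframe()
    df = df[df["enrichment_pct"] == enrichment_pct]
    fig, ax = plt.subplots(figsize=(6, 4))
    for ws, sub in df.groupby("window_size", sort=False):
        sub = sub.sort_values("n_snps")
        style = dict(color="black", lw=2) if ws == NAIVE else {}
        ax.plot(sub["n_snps"], sub["rate"], marker="o", label=str(ws),
                **style)
    kind = "FPR" if enrichment_pct == 0 else f"TPR ({enrichment_pct:g}%)"
    ax.set_xlabel("number of SNPs")
    ax.set_ylabel(kind)
    ax.set_xscale("log")
    ax.legend(title="window size", fontsize=8)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
    return Path(path)
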