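"""End-to-end orchestration: load, filter, window, test, annotate, render.

Pipeline order: load inputs -> optional mask -> optional peak-uniqueness
filter -> window plan -> per (cell type, loci set): window statistics,
overlap count, one-sided p-value -> significance tiers -> relatedness weight
matrix and dendrogram -> heatmap and tables.  The loci sets are always
tested against the post-mask, post-uniqueness profiles, the same profiles
the weight matrix sees, and everything is deterministic for a given config.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .errors import ParameterError
from .genome_windows import DEFAULT_WINDOW_SIZE, WindowPlan, partition_genome
from .interval_io import (CellTypeProfile, LociSet, read_chrom_sizes,
                          read_loci_folder, read_mask, read_ocr_folder,
                          write_enrichment_table)
from .null_model import EXACT_CUTOFF, tail_pvalue
from .overlap_engine import (apply_mask, base_window_coverage, count_overlaps,
                             peak_uniqueness_filter, window_statistics)
from .relatedness import DendrogramOrder, cluster_profiles, weight_matrix

log = logging.getLogger(__name__)

TIER_CORRECTED = "corrected"
TIER_NOMINAL = "nominal"
TIER_NS = "ns"


@dataclass
class RunConfig:
    """All options of one enrichment run; the four paths are required."""

    ocr_folder: Path
    loci_folder: Path
    chrom_sizes: Path
    output_folder: Path
    window_size: int = DEFAULT_WINDOW_SIZE
    min_loci: int = 200
    uniqueness_k: Optional[int] = None
    mask_path: Optional[Path] = None
    pvalue_threshold: Optional[float] = None
    alpha: float = 0.05
    correction: str = "bonferroni"  # or "none"
    seed: int = 0
    debug_components: bool = False


@dataclass
class EnrichmentMatrix:
    """n cell types x m loci sets of one-sided p-values with annotations."""

    cell_types: List[str]
    loci_sets: List[str]
    p: np.ndarray
    methods: np.ndarray
    tiers: np.ndarray = None
    leaf_order: List[str] = field(default_factory=list)
    dendrogram: Optional[DendrogramOrder] = None


def annotate_significance(p_matrix: np.ndarray, alpha: float = 0.05,
                          correction: str = "bonferroni") -> np.ndarray:
    """Tier each cell: survives multiple-testing correction, nominal, or ns.

    Bonferroni corrects over all n*m tests in the matrix; cells with
    ``p <= alpha / (n*m)`` are ``corrected``, cells with ``p <= alpha`` are
    ``nominal``, the rest ``ns``.
    """
    if correction not in ("bonferroni", "none"):
        raise ParameterError("correction must be 'bonferroni' or 'none'")
    thr = alpha / p_matrix.size if correction == "bonferroni" else alpha
    tiers = np.full(p_matrix.shape, TIER_NS, dtype=object)
    tiers[p_matrix <= alpha] = TIER_NOMINAL
    tiers[p_matrix <= thr] = TIER_CORRECTED
    return tiers


def compute_enrichment(profiles: Sequence[CellTypeProfile],
                       loci_sets: Sequence[LociSet],
                       plan: WindowPlan,
                       exact_cutoff: int = EXACT_CUTOFF,
                       ) -> Tuple[np.ndarray, np.ndarray, list]:
    """p-value matrix (cell types x loci sets) plus per-cell components.

    Returns ``(p, methods, components)`` where ``components[i][j]`` is the
    list of occupied-window statistics behind ``p[i, j]`` (for debugging and
    external re-verification).
    """
    n, m = len(profiles), len(loci_sets)
    p = np.empty((n, m))
    methods = np.empty((n, m), dtype=object)
    components = [[None] * m for _ in range(n)]
    for i, prof in enumerate(profiles):
        cov = base_window_coverage(prof, plan)
        for j, ls in enumerate(loci_sets):
            stats = window_statistics(prof, ls, plan, base_cov=cov)
            obs = count_overlaps(ls, prof)
            tp = tail_pvalue([s.n_w for s in stats], [s.p_w for s in stats],
                             obs.total, exact_cutoff=exact_cutoff)
            p[i, j] = tp.value
            methods[i, j] = tp.method
            components[i][j] = stats
    return p, methods, components


def run_rlea(config: RunConfig) -> EnrichmentMatrix:
    """Execute the full analysis and write all artifacts.

    Artifacts in ``config.output_folder``: the wide p-value matrix and long
    tier table (csv), the weight matrix (csv), the clustered heatmap
    (png + svg), the dendrogram as a Newick-style string, and a run log.
    """
    out = Path(config.output_folder)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage: load inputs")
    build = read_chrom_sizes(config.chrom_sizes)
    profiles = read_ocr_folder(config.ocr_folder, build)
    if config.mask_path is not None:
        log.info("stage: mask filter")
        mask = read_mask(config.mask_path, build)
        profiles = apply_mask(profiles, mask)
    if config.uniqueness_k is not None:
        log.info("stage: peak-uniqueness filter (k=%d)", config.uniqueness_k)
        profiles = peak_uniqueness_filter(profiles, config.uniqueness_k)
    loci_sets = read_loci_folder(config.loci_folder, build,
                                 min_loci=config.min_loci,
                                 pvalue_threshold=config.pvalue_threshold)

    log.info("stage: window plan (requested %d bp)", config.window_size)
    plan = partition_genome(build, config.window_size)

    log.info("stage: enrichment testing (%d cell types x %d loci sets)",
             len(profiles), len(loci_sets))
    p, methods, components = compute_enrichment(profiles, loci_sets, plan)
    tiers = annotate_significance(p, config.alpha, config.correction)

    log.info("stage: relatedness clustering")
    if len(profiles) >= 2:
        wm = weight_matrix(profiles)
        dendro = cluster_profiles(wm)
        leaf_order = dendro.leaf_order
        pd.DataFrame(wm.W, index=wm.names, columns=wm.names).to_csv(
            out / "weight_matrix.csv", float_format="%.17g",
            index_label="cell_type")
        (out / "dendrogram.newick").write_text(dendro.to_newick() + "\n")
    else:
        dendro = None
        leaf_order = [pr.name for pr in profiles]

    matrix = EnrichmentMatrix([pr.name for pr in profiles],
                              [ls.name for ls in loci_sets],
                              p, methods, tiers, leaf_order, dendro)

    log.info("stage: write tables and heatmap")
    write_enrichment_table(matrix, out)
    render_heatmap(matrix, out / "heatmap.png")
    render_heatmap(matrix, out / "heatmap.svg")
    if config.debug_components:
        _write_component_tables(matrix, components, out)
    _write_run_log(config, matrix, out)
    return matrix


def _write_component_tables(matrix: EnrichmentMatrix, components,
                            out: Path) -> None:
    comp_dir = out / "components"
    comp_dir.mkdir(exist_ok=True)
    for i, ct in enumerate(matrix.cell_types):
        for j, ls in enumerate(matrix.loci_sets):
            rows = [(s.window.chrom, s.window.start, s.window.end,
                     s.n_w, s.p_w) for s in components[i][j]]
            pd.DataFrame(rows, columns=["chrom", "start", "end",
                                        "n_w", "p_w"]).to_csv(
                comp_dir / f"{ct}__{ls}.csv", index=False,
                float_format="%.17g")


def _write_run_log(config: RunConfig, matrix: EnrichmentMatrix,
                   out: Path) -> None:
    import matplotlib
    import scipy
    lines = [f"ocrenrich {__version__}",
             f"python {sys.version.split()[0]}",
             f"numpy {np.__version__} scipy {scipy.__version__} "
             f"pandas {pd.__version__} matplotlib {matplotlib.__version__}",
             "config:"]
    for k, v in vars(config).items():
        lines.append(f"  {k} = {v}")
    lines.append(f"cell_types = {len(matrix.cell_types)}")
    lines.append(f"loci_sets = {len(matrix.loci_sets)}")
    (out / "run_log.txt").write_text("\n".join(lines) + "\n")


def render_heatmap(matrix: EnrichmentMatrix, path, return_fig: bool = False):
    """Render the clustered significance heatmap.

    Rows follow the dendrogram leaf order, with the dendrogram drawn on the
    left; dark red marks cells surviving multiple-testing correction, pink
    nominally significant cells, white the rest.  Row labels of cell types
    with any corrected cell are bold.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

    if matrix.tiers is None:
        raise ParameterError("annotate significance before rendering")
    order = [matrix.cell_types.index(n) for n in matrix.leaf_order]
    codes = np.zeros(matrix.p.shape, dtype=int)
    codes[matrix.tiers == TIER_NOMINAL] = 1
    codes[matrix.tiers == TIER_CORRECTED] = 2
    codes = codes[order]
    n, m = codes.shape

    fig = plt.figure(figsize=(max(4.0, 0.55 * m + 3.0),
                              max(3.0, 0.3 * n + 2.0)))
    gs = fig.add_gridspec(1, 2, width_ratios=[1, 4], wspace=0.02)
    axd = fig.add_subplot(gs[0])
    axh = fig.add_subplot(gs[1])
    if matrix.dendrogram is not None and matrix.dendrogram.Z is not None:
        scipy_dendrogram(matrix.dendrogram.Z, orientation="left", ax=axd,
                         no_labels=True,
                         link_color_func=lambda _: "black")
    axd.axis("off")

    cmap = ListedColormap(["white", "#f6a9bd", "#a50f15"])
    # dendrogram leaves sit at y = 5, 15, 25, ... from the bottom
    axh.imshow(codes, aspect="auto", cmap=cmap, vmin=0, vmax=2,
               origin="lower", extent=(0, m, 0, 10 * n))
    axh.set_xticks(np.arange(m) + 0.5)
    axh.set_xticklabels(matrix.loci_sets, rotation=90, fontsize=8)
    axh.set_yticks(10 * np.arange(n) + 5)
    bold = {matrix.cell_types[i]
            for i in range(len(matrix.cell_types))
            if (matrix.tiers[i] == TIER_CORRECTED).any()}
    axh.yaxis.tick_right()
    labels = axh.set_yticklabels(matrix.leaf_order, fontsize=8)
    for lab in labels:
        if lab.get_text() in bold:
            lab.set_fontweight("bold")
    for x in range(1, m):
        axh.axvline(x, color="0.85", lw=0.5)
    for i in range(1, n):
        axh.axhline(10 * i, color="0.85", lw=0.5)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    if return_fig:
        return fig
    plt.close(fig)
    return Path(path)
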