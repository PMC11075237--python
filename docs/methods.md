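# Methods

## Model

For one cell type and one loci set, the genome is partitioned into
near-equal windows and every window *w* that contains at least one locus
contributes a binomial component `B(n_w, p_w)`: `n_w` loci "attempt" to land
in open chromatin, each succeeding with probability `p_w`, the fraction of
the window covered by the cell type's merged OCRs. The null for the
genome-wide overlap count is the sum `S = Σ_w B(n_w, p_w)` of these
independent, non-identical binomials, and enrichment is the one-sided upper
tail `P[S ≥ s_obs]` at the observed count. Conditioning on the windows'
occupancy (`n_w`) is what distinguishes this from the naive genome-wide
binomial: any co-variation of locus density with regulatory density at
scales coarser than the window is absorbed into the null rather than read
as signal.

Assumptions worth stating: loci are treated as exchangeable within their
window (uniform placement given the window), windows are independent, and a
window with no open chromatin contributes zero overlap probability — a
locus there can never count as a success. Loci sets should therefore be
reasonably LD-pruned or deduplicated; the loader collapses exact duplicate
coordinates but does nothing about correlated nearby hits.

## Window partition

A chromosome of length `L` at requested size `g` (default 100,000 bp) is cut
into `ceil(L/g)` windows; the base length is `floor(L / count)` and the
remainder is distributed one bp at a time. We place the extra base pairs on
the lowest-index windows; only the multiset of lengths is anchored by the
method's definition, and the choice is documented here for determinism. All
arithmetic is in integer bp. Requested sizes under 1 kb are allowed (for
testing) but warned about, since per-window coverage fractions become
statistically meaningless.

## Coverage, overlaps, and indels

Peaks are merged (overlapping or abutting intervals coalesce) at load time,
so every coverage quantity is fragmentation-invariant. A locus belongs to
the window containing its start coordinate — a multi-bp locus spanning a
boundary is not split, which preserves `Σ n_w = |loci|`. The observed
statistic counts a locus once if any of its base pairs intersects any peak.

When a window contains loci longer than 1 bp, each peak `[s, e)` is extended
leftward to `[s − (L−1), e)` with `L` the maximum locus length in the
window, then re-merged and intersected with the window. This makes `p_w`
the fraction of in-window start positions from which a length-`L` locus
would touch open chromatin. Heterogeneous locus lengths within one window
cannot be represented in a single binomial success probability, so the
maximum is used — a slightly conservative-for-SNVs, anti-conservative-for-
short-indels compromise; with SNV-only input the extension is exactly a
no-op. The extension affects only `p_w`, never the stored profile, the
relatedness weights, or the observed overlap count.

The mask filter keeps whole peaks that touch ≥ 1 bp of any mask interval
(a filter, not an intersection). The peak-uniqueness value of a peak is the
number of cell types, *including its own*, with an overlapping peak, so the
minimum is 1 and `k = 1` keeps only strictly private peaks; filtering at
`k` removes peaks with value > k from every profile simultaneously,
computed on the pre-filter profiles.

## Tail evaluation

The exact route convolves the component pmfs iteratively
(`O(N · Σ n_w)` for `N = Σ n_w` total loci) and is used for `N ≤ 5000`;
below that bound it is fast and removes any approximation concern. Beyond
it, the tail is approximated from the cumulant generating function
`K(u) = Σ n_w log(1 − p_w + p_w e^u)`: the saddlepoint `û` solves
`K′(û) = s − 1/2` (continuity correction for the integer lattice, solved by
bracketed Brent iteration to near machine precision), and the
Lugannani–Rice tail form is applied with Daniels' lattice correction
`u₁ = 2 sinh(û/2) √K″(û)`:

    P[S ≥ s] ≈ 1 − Φ(ŵ) − φ(ŵ) (1/ŵ − 1/u₁),
    ŵ = sign(û) √(2(û(s−½) − K(û))).

We evaluated the printed second-order Gaussian-base correction term against
the exact convolution on thousands of random component ensembles and found
it *less* accurate for these bounded lattice sums than the form above,
which stays within 0.1% relative error; the package therefore uses the
corrected first-order form. Three routings guard the approximation's known
failure regimes, with the exact route as arbiter in each:

- `s` at or below the null mean: delegate to the exact tail (the p-value is
  ≥ 0.5 and the ŵ, u₁ terms cancel catastrophically near the mean);
  likewise when `|ŵ| < 0.05`.
- `s` within 64 counts of the support endpoint `N`: sum the *failure* side
  exactly — `P[S ≥ s] = P[Σ B(n_w, 1−p_w) ≤ N−s]` via truncated
  convolution, `O((N−s)²)` at any `N`.
- Components with `p_w = 0` are dropped (they contribute no overlap mass);
  `p_w = 1` components add a deterministic shift subtracted from `s`. If
  all components are degenerate the null is a point mass: the p-value is 1
  at or below the shift, and a larger observation raises a consistency
  error, since overlap counting and coverage then disagree.

Tail probabilities are floored at the smallest positive normal double and
never reported as exactly zero. An observed count of zero has p-value
exactly 1.

## Significance tiers

Bonferroni over all `n × m` (cell type, loci set) tests at level α
(default 0.05): cells at or below `α/(n·m)` are tiered `corrected`, cells at
or below α `nominal`, the rest `ns`. The correction family is the whole
matrix; a per-column family would be defensible too, but the whole-matrix
rule is the conservative default and the one the heatmap encodes (dark red
/ pink / white). Adding a loci set never changes another column's p-values,
only the corrected threshold.

## Relatedness weights and clustering

`Weight_ij = 1 − (ov/|i|)(ov/|j|)` with `ov` the intersection bp of the
merged peak sets and `|i|` the total merged bp of profile *i* — identical
profiles weigh 0, disjoint ones 1. Base pairs rather than peak counts are
used for both numerator and denominators because bp measures are invariant
to peak fragmentation while counts are not. A profile with zero total bp
weighs 1 against everything (logged). Rows of the weight matrix are treated
as feature vectors; cell types are clustered agglomeratively on Euclidean
distances between rows (scipy), average linkage by default (complete and
ward are accepted). When all rows are indistinguishable the leaf order is
defined as the input order; other ties follow scipy's deterministic merge
order, so repeated runs are always identical.

## Synthetic landscapes and the simulation harness

The generator emulates the study conditions at desk scale: a 4 × 2.5 Mb
genome, peaks from a Poisson point process at 10⁻⁴ peaks/bp with
exponential lengths of mean 500 bp (≈5% OCR coverage — typical of ATAC-seq
peak sets), 5 cell types, and a 0.3 sharing fraction drawn from a common
peak pool (cell types share a substantial minority of their regulatory
landscape). A fixed, seeded background of 500,000 positions stands in for a
genotyping panel; null sets draw from it uniformly, and planted-enrichment
sets draw fixed numbers of inside-peak and outside-peak background
positions so that the overlap proportion is `min(1, q(1 + e/100))` for
coverage `q` and enrichment `e`%, exact by construction.

Background colocalization with open chromatin — the mechanism that inflates
the naive genome-wide test — is emulated at chromosome scale: peak density
varies linearly across chromosomes (±60%) and the background SNP density
co-varies with it (strength 0.2), while positions remain uniform within
each chromosome. Real colocalization is finer-grained (genic regions), but
the chromosome-scale form is the clean limit in which the windowed null
stays *exactly* calibrated at every window size — windows never span
chromosomes — while the naive test's false positive rate grows with SNP
count. Passing calibration and inflation checks on this landscape therefore
demonstrates the mechanism, not the magnitude, of the naive test's failure
on real data; fine-scale colocalization below the window size would
inflate the windowed test as well, and no synthetic check here addresses
LD structure, mappability, or peak-calling noise.

Rates are estimated over seeded replicates (defaults: 2,000 for FPR sweeps,
1,000 for TPR; replicate counts are a knob) across the window sweep
{25 kb, 50 kb, 100 kb, 250 kb, 500 kb, 1 Mb, naive}, where "naive" is a
single genome-wide window. The acceptance-level checks run 2,000 null
replicates at 1,000 SNPs (calibration within three Monte-Carlo standard
errors of α, naive strictly inflated) and 1,000 power replicates per cell
at {300, 3,000} SNPs × {30, 50}% enrichment (monotone within three MC
standard errors). The scale smoke test runs 44 profiles × 12,000 loci on a
100 Mb genome through the full pipeline; it completes in well under a
minute on one CPU, and the test budget of 15 minutes is a generous
upper bound.

## Input conventions and edge cases

OCR and mask files are BED-dialect (0-based half-open, first three
columns); loci files with a single position column are 1-based
(GWAS-catalog style), while files with detected start *and* end columns are
read as 0-based half-open. Column detection prefers header names
({chr, chrom, chromosome, …} / {pos, position, start, …} / {end, stop} /
{p, pvalue, …}) and falls back to the first two columns. Chromosome names
are harmonized to the sizes file's `chr` dialect; loci on chromosomes
absent from the build are dropped with a logged count. Loci sets smaller
than `min_loci` (default 200, settable to 0) are excluded — small sets are
dominated by their least-stable windows. Peaks are clipped to chromosome
bounds; files yielding no valid intervals are skipped with a warning, and
an empty input folder, an unusable sizes file, or an empty mask is fatal.
Output floats are serialized at 17 significant digits so tables round-trip
bit-exactly (read them back with pandas' `float_precision="round_trip"`).

## Known limitations

- The binomial null ignores LD: correlated loci violate within-window
  exchangeability and make p-values anti-conservative for clumped GWAS
  input. Pruning is the user's responsibility.
- The max-length indel extension is a scalar compromise for mixed-length
  windows (see above); sets dominated by long indels deserve scrutiny.
- Bonferroni over the full matrix is conservative when cell types are
  correlated — which the relatedness clustering makes visible but the
  correction does not exploit.
- The simulation harness demonstrates mechanisms on an idealized landscape;
  its rates are not predictions for any real genome.
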