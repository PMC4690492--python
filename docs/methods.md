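# Methods

## Data model and coordinates

All coordinates are 0-based, half-open internally; 1-based dialects
(Bismark coverage, cytosine reports, VCF) are converted at the file
boundary. A CpG dyad is represented by the plus-strand C position; the two
strands' counts are summed (symmetric CpG methylation is assumed, as is
standard for WGBS), and the ≥ 5-read coverage filter is applied to the
summed counts. A minus-strand cytosine with no plus-strand partner in the
input still anchors at its dyad position (pos − 1). Per-strand records can
be kept with `read_methylome(..., collapse=False)` for users who want to
filter before collapsing.

The site filters — coverage in every tissue, autosome, SNP mask,
mappability — are independent per-position predicates, so the cascade is
order-independent by construction (verified by test). A SNP at either base
of the dyad removes the whole dyad, because a C→T allele corrupts both
strands' calls. The mappability track is treated as opaque 0–100 scores;
positions not covered by the track default to 100 (fully mappable), so a
sparse track only ever removes what it explicitly marks.

## Island detection

Detection parameters (window 200 bp, step 50 bp, ≥ 10 CpGs, sparse means
m < 0.2 strictly, qualification needs a sparse fraction ≥ 0.8) are the
standard settings for this analysis; all are exposed.

The under-specified part of any seed-and-extend rule is the extension
semantics. The implemented rule: candidate seeds are anchored at multiples
of the step (not at CpGs), which makes the caller deterministic and
translation-equivariant; from each qualifying seed the right edge grows one
step at a time while the *entire enlarged window* still satisfies both
criteria; growth is capped one step past the last retained CpG of the
chromosome (further growth could never change any count); all maximal
extents, including book-ended ones, are unioned into disjoint islands.
Left extension needs no special case — it emerges from seeds at earlier
anchors. Relaxing any threshold can only lengthen extensions and add seeds,
so called bases grow monotonically, and an exhaustive window-enumeration
oracle reproduces the caller exactly on random inputs.

Window-derived boundaries land on the 50 bp grid and systematically
overshoot the underlying hypomethylated run: with island CpG density ρ_i, a
maximal extent keeps growing until it has swallowed about one methylated
flank CpG per four island CpGs, i.e. an overshoot of roughly
ρ_i·L/(4·ρ_bg) bp — hundreds of bp whenever islands are CpG-denser than
their flanks, which is the defining situation. Because island boundaries
should follow the local methylation values, `detect_islands` therefore
offers three boundary modes: `none` (raw window coordinates, length
≥ 200 bp guaranteed), `cpg` (trim to the outermost retained CpG) and
`sparse` (trim to the outermost *hypomethylated* CpG). The pipeline default
is `sparse`; trimmed islands may be shorter than the seed window, and their
sparse fraction is recomputed over the trimmed interval (it can only
increase, since trimming removes non-sparse edge CpGs).

## Catalog

Merging across tissues takes connected components of the ≥ 1 bp overlap
graph (the threshold is configurable); book-ended islands do not merge,
mirroring the fact that a single uncovered CpG can split an island. The
presence vector is recomputed against the merged entries, so with a larger
minimum overlap an input island may mark several entries. `merge_adjacent`
(gap ≤ max_gap) is provided for the coarser view and is idempotent after
one pass. Entropy uses −P log₂ P with the continuous extension 0 at P = 0;
its analytic maximum log₂(e)/e at P = 1/e is pinned by a test. The
saturation curve reports, for k = 1..T, the mean fraction of final catalog
entries already hit by the first k tissues of a random ordering (seeded);
on pairwise-disjoint equal-size tissue sets it equals k/T exactly.

## Sequence features

`seq_stats` counts C, G and overlapping CG dinucleotides; N bases count
toward length but not composition, which biases GC and O/E of masked
sequence downward rather than inventing composition that is not there.
Island prediction is a windowed composition scan: every `min_len`-bp window
(step 1) is tested against GC ≥ 0.5 (inclusive, a "minimum") and O/E > 0.6
(strict, "above"); overlapping qualifying windows are unioned, so reported
intervals are maximal and never shorter than `min_len`. This is *not* the
maximal-scoring-segment algorithm used by the UCSC annotation — the two
agree on clearly CpG-rich sequence but can draw different boundaries around
marginal flanks — and the concordance analysis accepts an externally
supplied island BED for users who want the canonical set. Soft-masked
(lowercase) bases are treated as N only when `mask_repeats` is set,
mirroring the convention that transposable elements are masked for island
prediction.

## Annotation

Context labels use precedence promoter > gene body > downstream >
intergenic with strand-aware 3 kb windows on both sides of each gene
("downstream" is strand-aware by decision; the genomic-left convention is
recovered by passing unstranded genes). Gene body entries are sub-labelled
exon if they touch any exon of any overlapping gene. GTF input keeps the
longest transcript per gene. Shore (2 kb) and shelf (2 kb) widths follow
the field convention — they are not part of the detection rule — and are
flags. Flank profiles aggregate GC, CpG O/E, hypomethylation breadth
(tissues whose mean bin methylation < 0.2) and entropy per bin across
anchors, truncating flanks at chromosome ends. Expression breadth counts
tissues strictly above a global quantile cutoff (default the median over
all cells), so a constant matrix yields breadth 0 everywhere.

## Enrichment

The bootstrap null preserves the number and the width multiset of the
observed islands and randomizes only location, uniformly over the eligible
space per chromosome (weighted by valid start positions). Resampled
intervals may overlap each other — the null constrains width and count
only — with rejection sampling available via `non_overlapping`. The
empirical P uses the add-one estimator (1 + #{null ≥ obs})/(n + 1), which
cannot return 0 at finite n; upper and lower tails are both reported, and
the statistic is either total bp of overlap (default) or the number of
overlapping islands. Fold is exactly 1 when the feature set covers the
whole eligible space. Under a uniform null the empirical P is approximately
uniform *provided the statistic has no atom at zero*; with very sparse
features the observed overlap is often 0 and P piles up at 1, which is a
property of the statistic, not a calibration error. The χ² overlap test
compares observed overlap counts with the expectation
p₀ = footprint/(mappable_fraction · autosomal_bp) on 1 df, with the
mappable fraction defaulting to 0.89.

## Synthetic data

The generator emulates the study design the pipeline targets: T = 10
tissues, per-dyad read depth Poisson with mean 12 split over two strands,
bimodal methylation (background beta mean 0.85, islands 0.05,
concentration 30 — mild biological overdispersion on top of binomial
sampling), 200 planted islands of 300–900 bp split 40% constitutive / 35%
tissue-specific / 25% random shared subsets, on 4 × 350 kb autosomes plus a
100 kb chrX that exercises the autosome filter. Background sequence is
CpG-depleted (all accidental CG dinucleotides broken, then CG planted at an
exact 0.02/bp rate, GC 0.40); islands get 0.12/bp and GC 0.60, so
composition-based prediction has signal to find. SNPs hit 0.3% of dyads
(calls forced toward zero, the C→T read-through artifact); 20% of them
carry allele frequencies below the 1% mask threshold and therefore survive
the SNP filter, as rare variants do in real masks. Low-mappability
intervals (2% of the genome, scores < 50) receive uniform-random
methylation to mimic mismapping; islands are placed clear of them so the
planted truth stays assessable after filtering. Islands are separated by
≥ 2 kb so distinct planted islands never merge.

What passing tests on this generator do **not** show: robustness to
partially methylated domains, long-range CpG-density autocorrelation,
cell-type heterogeneity within a tissue, conversion-rate artifacts, or the
composition of real repeat families — the generator's feature tracks are
structural stand-ins, not biological models.

Recovery scoring calls a planted island recovered when a call overlaps it
reciprocally by ≥ 50%; planted islands with fewer than `min_cpgs` retained
CpGs are excluded from the recall denominator (they are undetectable by
construction). Boundary error per island is the larger endpoint deviation
of the best-overlapping call; the summary reports mean, median and max.
The mean/median are the stable aggregates — the max has a long tail
because a single rare sub-threshold SNP-corrupted CpG near an island edge
can extend one trimmed boundary.

## Determinism and problem sizes

Every stochastic component (generator, bootstrap, saturation orderings)
takes an explicit seed and uses its own `numpy` Generator; detection and
merging are seed-free. Outputs are written with fixed float formatting and
gzip (when requested) with zeroed mtime, so identical inputs give
byte-identical files; the run manifest stores parameters and SHA-256
checksums but no wall-clock data, and stages are skipped when their inputs
and parameters are unchanged. The bundled study sizes (≈1.5 Mb genome,
≈40 000 dyads × 10 tissues) were chosen so a complete end-to-end run takes
a few seconds while every per-window decision path in the caller is still
exercised thousands of times; all algorithms are linear or n log n in
sites and scale to whole-genome inputs.
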