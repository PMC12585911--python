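# Methods

This note documents the models, conventions and numerical choices
behind `repairscape`, in the spirit of a methods supplement: what each
stage assumes, which parameters matter, and what the synthetic tests do
and do not establish about real data.

## Coordinates and read model

All intervals are 0-based half-open (BED convention); GFF3 annotations
are converted on read. Reads are modelled as ungapped stranded
intervals with a mapping quality — the BED6 view of an alignment. The
"length" of a read is its aligned span; soft-clipping and split
alignments are outside the model (the pipeline consumes aligned
intervals, it does not align).

## Post-alignment filters

XR-seq reads are kept when mapping quality is strictly greater than 20
(the boundary is deliberately strict, not ≥), the chromosome is in the
allowed set (defaults to the six nuclear chromosomes I–V, X), and the
aligned length lies in [21, 28] nt inclusive — the excised-
oligonucleotide size range that still carries the lesion at a fixed
3′ offset. Paired-end RNA-seq reads must satisfy all six retention
criteria (MAPQ ≥ 30, proper pair, insert ≤ 500 kb inward-oriented,
CIGAR match segment, ≤ 10 reported hits, non-mitochondrial); a missing
metadata field raises rather than silently passing. Duplicate
alignments collapse on (chrom, start, end, strand), first occurrence
kept, before any window inference.

## Damage-site inference

For a `+` read with 5′ end at `p` the lesion dinucleotide is `[p−2, p)`
and the reported window `[p−6, p+4)` — the read trimmed to its first
4 nt and extended 6 nt upstream, so the lesion occupies oriented
positions 5–6 of the 10-mer. `−` reads mirror this. Reads whose window
would leave the chromosome are dropped and counted, never clipped: a
clipped window cannot satisfy the fixed-width invariant.

**Lesion-strand convention.** The lesion dinucleotide's *coordinates*
are identical whether the lesion is booked on the read strand or its
complement (positions 5–6 of a 10-mer map onto themselves under
reverse complement); only the strand label and the orientation of the
extracted sequence differ. The package defaults to `convention="read"`
— the lesion on the read's strand — which is the bookkeeping used by
published Damage-seq pipelines and the only choice under which the
dipyrimidine filter, the strand-specific TS/NTS intersections, and the
emit-geometry of the synthetic generator are mutually consistent (under
the opposite convention the filter would reject every well-formed
simulated read). `convention="opposite"` is available for analyses that
prefer to label the chemically damaged template strand.

The dipyrimidine filter keeps windows whose oriented middle two bases
are both C/T; N at either position rejects. On simulated data with
lesions planted only at dipyrimidines it retains 100% of reads, and
with a planted non-dipyrimidine fraction it removes exactly that
fraction — both are asserted in the tests.

## Composition-matched background

For each input read the simulator emits one pseudo-read of equal length
at a random genomic position whose sequence has the identical multiset
of overlapping k-mers (k = 2: the same dinucleotide content in any
order). Sampling is two-phase: up to `sens` (default 20) blind
candidates (chromosome ∝ length, start uniform, strand uniform; windows
containing N are rejected without consuming an attempt), then an
exhaustive index of every genomic window of that length keyed by k-mer
count vector, from which a matching position is drawn uniformly. The
index fallback is the blind sampler's own limiting distribution; it
exists because an exact dinucleotide-multiset match for a ~24-mer is
rare enough (order 10⁻⁶ per candidate on a 1-Mb genome) that a bounded
rejection loop alone would almost never succeed. A read is flagged only
when no matching window exists on either strand anywhere in the genome
(impossible for reads extracted from that genome); flagged reads
receive the last blind candidate so the output always has exactly one
pseudo-read per input read, as the downstream one-to-one normalization
requires. A single seeded generator drives all sampling; fixed seed
gives byte-identical output.

## Counting, units and strand conventions

A read is counted in a region when at least `min_overlap_fraction`
(default 0.5) of the **read** lies inside it, boundary inclusive — a
24-nt read with exactly 12 nt inside counts. TS (transcribed-strand)
signal of a gene is carried by reads mapping opposite the gene's
strand, NTS by same-strand reads: excision products lie on the damaged,
repaired strand, which for transcription-coupled repair is the
template. Units follow the printed formulas: RPM = count × 10⁶/library;
RPKM = (count / gene kb)/(library/10⁶); TPM normalizes length-corrected
rates to 10⁶ (ΣTPM = 10⁶ for any input).

For periodicity profiles the counted objects are the 2-nt damage
*sites*, not whole reads: a 30-nt read cannot place ≥ 50% of itself in
a 10-bp bin, and read-length box-filtering would cancel 10-bp structure
outright (a 30-bp boxcar has a null at period 10).

## Profiles

Gene metaprofiles span `upstream` bp before to `downstream` bp after
the TSS or TES in transcription direction (defaults 1000/500, 100
bins), with per-gene vectors oriented 5′→3′ and the mean reported with
a ±1.96·SEM band. Summit- and dyad-centered profiles use an odd bin
count with the central bin centered on the anchor; bin width is
2·flank/(n_bins−1), giving 201 × 10 bp for ±1 kb and 81 × 2 bp for
±80 bp. (An even bin count is allowed with a warning; there is then no
exact center bin.) With `orient=True` the plus-strand bin order is
reversed while minus-strand order is unchanged, so transcription reads
left to right on both strands; the operation is an involution.
Scale-region mode extends interval anchors by `flank` on both sides and
divides each region into `n_bins` equal, region-dependent bins.

The normalization chain for damage maps divides RPM profiles by the
mock-treated control, then by the scalar mean of the naked-DNA control,
then by the composition simulation, smooths with a centered 11-bin
rolling mean truncated at the edges (no padding — the window shrinks
rather than inventing data), and takes log₂. Repair maps divide by the
simulation only, optionally further by the simulation-normalized damage
profile to express repair relative to the local damage landscape. Bins
with nonpositive denominators are masked, propagate as missing through
the smoothing (window means over non-missing members), are excluded
from statistics, and are counted in the return value.

## Stratification and statistics

Ranking is ascending and stable with ties broken by item identifier, so
grouping is deterministic; groups differ in size by at most one, the
extra items going to the lower groups. Zero-key items can be excluded
first (expression quartiles), and a top fraction can be trimmed before
grouping (default 0.5% for chromatin-signal tertiles, to contain
outliers). Box statistics report median, quartiles and whiskers at the
12.5th/87.5th percentiles using linear interpolation between closest
ranks — whisker values depend on this rule, hence it is fixed and
tested. Paired comparisons (TS vs NTS per gene; a timepoint vs the
reference within a tertile) use the two-sided Wilcoxon signed-rank test
with zero-differences dropped (identical pairs everywhere yields
p = 1); unpaired tertile contrasts use the Wilcoxon rank-sum
(Mann–Whitney) test. Benjamini–Hochberg correction is applied across
all tests emitted by one invocation — one analysis, one family.
Genome-wide sample clustering uses 1 − Spearman ρ over binned RPM as
the distance and Ward linkage; a zero-variance sample has no rank
correlation and raises, naming the sample.

## Periodicity

Power at period p (bins) is |Σₙ x̃ₙ e^(−2πin/p)|²/N for the
mean-centered signal x̃, evaluated at a candidate grid in bp and
converted through the bin size, so the same rule covers 160 bp on 10-bp
bins (16 bins) and 10 bp on 2-bp bins (5 bins); non-integer bin periods
are evaluated directly. Candidates at or below 2 bins are rejected
(sub-Nyquist). Relative power divides by the mean over the candidate
set (dimensionless, mean 1). Default grids: 100–250 bp step 5 (target
160) and 5–20 bp step 0.5 (target 10) — the analysis is restricted to a
candidate set by design, to focus on biologically meaningful periods;
the grids are parameters. Missing bins are mean-imputed (count
reported) so N stays fixed.

SNR is the power at the target period over the mean power at all other
candidates; the ratio is identical for raw and relative power. The
permutation test shuffles bin values uniformly (imputed bins shuffle
with their values), recomputes the SNR per shuffle, and reports the
strict exceedance fraction #{SNR_perm > SNR_obs}/n_perm, with the
(k+1)/(n+1) estimator alongside as the conservative variant; a constant
signal has undefined SNR and is assigned p = 1. For genotypes where
repair is transcription-driven and asymmetric, the spectrum can be
computed on the downstream sub-window only (bins whose start is at or
beyond +250 bp for summit windows, +20 bp for dyad windows).

## Synthetic data: what it emulates, and what it does not

The generator produces an iid-base genome at worm-like GC (0.36), a
packed gene annotation (lengths 2.5–6 kb, ≥ 600 bp gaps), lognormal TPM
with a zero-expressed fraction, and summit/dyad anchor sets. XR-like
reads have lengths on 10–32 nt peaking at 24 (discretized Gaussian,
σ ≈ 2.2, matching the observed excision-product size profile), carry a
pyrimidine dimer at a fixed 3′ offset (default 6, i.e. read positions
L−7 and L−6), and map to the transcribed strand with a quartile-
dependent probability (defaults 0.5/0.55/0.65/0.75, rising with
expression as transcription-coupled repair predicts). Genes are chosen
proportional to length, so damage load scales with target size.
Damage-like reads are emitted one per planted lesion with the 5′ end
exactly 2 nt downstream of the lesion dinucleotide — the exact inverse
of the window inference, making the round-trip testable to the base
pair. Lesion density carries a multiplicative cosine at the planted
periods (amplitude 0.5 around summits at 160 bp and dyads at 10 bp — an
amplitude chosen for test power, as real-data amplitudes are not
calibrated), a Gaussian accessibility dip at summits (depth 0.5,
σ = 75 bp), and per-timepoint Bernoulli survival with reduced survival
at cosine troughs (linkers), so the periodic pattern sharpens over the
time course as linker lesions are preferentially repaired.

Deliberately absent: mappability structure and repeats (reads are
emitted as alignments, so alignment artifacts are out of scope),
sequencing errors, fragment-length chemistry, cell-type mixtures, and
realistic chromatin. Passing recovery tests therefore establishes the
*bookkeeping* — geometry, strand conventions, units, statistics — not
that biological effect sizes in real data are detectable at these
sample sizes.

## Problem sizes and determinism

Tests and the acceptance script run on toy genomes of 0.3–1 Mb with
10k–100k reads, 100-seed repetition for recovery/calibration claims,
and 200–1000 permutations per test — sizes chosen so the full suite
runs in minutes on one CPU while keeping binomial error bands narrow
enough for the stated tolerances. Every stochastic stage takes an
explicit seed and is byte-reproducible; the acceptance script derives
all sub-seeds from its single `--seed` argument.
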