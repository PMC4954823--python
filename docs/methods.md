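# Methods

`ploidymeth` re-implements, as a tested pipeline over synthetic data with
known ground truth, a MeDIP-seq study design comparing genetically
identical monoploid, diploid and triploid plants (a "ploidy series",
1N/2N/3N). This note documents the models, the parameters that matter, and
what the synthetic experiments do and do not show.

## The measurement model

MeDIP-seq read density is taken as a proxy for regional DNA methylation.
Input to the analysis is the set of *uniquely mapped* read intervals per
sample (alignment itself is out of scope; BED files of mapped reads are the
interface). Because the three samples carry 1, 2 and 3 genome copies,
their usable sequencing depth scales roughly 1:2:3; every cross-sample
comparison therefore works on reads-per-million-uniquely-mapped (RPM),
which divides that ratio out exactly.

## Peak calling

Windows of `window` = 200 bp tile each chromosome at `step` = 50 bp. The
count of read starts per window is tested against a genome-wide uniform
Poisson null with

    lambda = total_reads x window / genome_length,

one-sided upper tail, threshold `alpha` = 1e-5 on the *raw* p-value (no
multiple-testing correction — the raw cut is the operating definition of a
peak; BH-adjusted q-values can be derived from the emitted per-peak
p-values if wanted). Significant windows separated by at most
`merge_gap` = 100 bp are merged; merged spans shorter than
`min_length` = 200 bp are discarded. Reads are assigned to windows by
their start coordinate, so at `step == window` the window counts partition
the reads and are independent under the null. Truncated windows at
chromosome ends keep the full-window lambda (slightly conservative). The
caller is verified against a definitional oracle — every window tested by
direct pmf summation, merging done by an explicit loop — on random
chromosomes up to 50 kb.

Window size, step and merge gap are method choices, not published facts;
they are consistent with the 200 bp minimum peak length the design implies.
Peak mean length is defined as total length / peak count.

## Gene-level methylation

A gene is **methylated** when at least one peak overlaps, by >= 1 bp, its
*methylation region*: 1.5 kb upstream of the TSS through the TES, in the
gene's own orientation and clipped to the chromosome. Per-gene quantitative
levels are RPM of reads overlapping the gene body. Feature-class densities
(promoter = 1.5 kb upstream, 5'UTR, exon, intron, 3'UTR, downstream 2 kb,
intergenic) assign every base to exactly one class via a deterministic
paint order (flanks, then intron, then exon, then UTRs; genes painted in id
order), so class lengths always sum to the genome length. Flanking
profiles count read starts in 100 bp bins over +/-4 kb of the TSS/TES,
strand-oriented, excluding bins that fall off the chromosome from a gene's
average.

## Differential methylation and trends

Pure fold-change semantics on RPM levels with a pseudocount
`epsilon` = 0.5 RPM guarding zeros: a gene is differentially methylated
between two samples when max(a+e,b+e)/min(a+e,b+e) >= 2, and shows a ploidy
trend when its levels are monotone across 1N <= 2N <= 3N (or >=) with a
1N-to-3N span >= 1.5. No significance test is attached — with one library
per ploidy there is no replicate variance to estimate, and the fold
threshold is the published operating rule. Exclusive pairwise sets are
reported as percentages of the union of all called genes, rounded half-up
to one decimal (note: one published exclusive share appears truncated
rather than rounded; this implementation rounds).

## Differential expression

Digital gene expression (DGE) tag counts are absolute per-gene abundances
from one library per ploidy. Expression strata follow raw tag counts:
high > 200, moderate 30-200 inclusive, weak < 30. Between two libraries,
differential expression uses the classical two-library exact test
(Audic-Claverie style): conditional on n = a + b tags for a gene, the split
is Binomial(n, T_a/(T_a+T_b)) under the null (T = library totals), tested
two-sided, BH-adjusted across genes, and combined with a >= 2-fold
requirement on per-million-normalised counts. This replaces
replicate-based DE machinery, which the single-library design cannot
support. The test's type-I error is calibrated by simulation: under
identical libraries across 2000 genes the raw p <= 0.05 fraction sits
within 3 binomial SE of 0.05 (the exact test is mildly conservative,
~0.043-0.047 at tag depths of 50-500, a property of discrete exact tests).

## Integration

Cross-sample concordance is the Pearson correlation of per-gene gene-body
RPM vectors. Metagene profiles stratified by expression (high / moderate /
weak) use the same +/-4 kb, 100 bp binning, normalised per million mapped
reads. The differential-methylation x differential-expression cross-tab
re-expresses the methylation direction relative to the higher-ploidy sample
of the pair so both dimensions share the up/down convention; genes called
in only one dimension are excluded. The joint monotone screen intersects
methylation and expression trend calls and labels the four direction
combinations.

## Small RNA

Collapsed small-RNA reads are assigned to a user-supplied miRNA reference
by fewest mismatches (Hamming for equal lengths, edit distance otherwise,
via edlib), at most 2, ties discarded for reproducible integer counts. A
miRNA is *expressed* with > 50 reads (strictly) in at least one sample.
Cross-ploidy comparison normalises by whole small-RNA library totals (not
by the sum of miRNA counts — miRNAs are a small library fraction, and
normalising by their own sum would cancel coherent shifts). 5'-RACE clone
positions are 1-based within a 21-nt target site, position p meaning
cleavage between p and p+1; the canonical miRNA-guided site is position 10
(the 10-11 duplex position).

## The synthetic-data generator

The generator defines the study conditions; it is deliberately simple and
piecewise-constant:

- **Genome**: 2 chromosomes x 2.4 Mb, 1000 non-overlapping stranded genes
  of 800-1200 bp with exon/UTR structure, placed with >= 1.6 kb gaps so one
  gene's 1.5 kb flanking windows never reach a neighbour's body.
- **Landscape**: background propensity 1 per base. Half the genes are
  methylated; each gets independent lognormal multipliers centred at 10x
  (1.5 kb upstream of TSS), 8x (1.5 kb downstream of TES) and 5x (gene
  body). Upstream exceeds downstream because promoter enrichment dominates
  in the system being emulated; upstream and body multipliers are drawn
  independently so expression can couple to them with opposite signs.
- **Planted differential methylation**: 50 genes scale their whole
  footprint monotonically across 1N/2N/3N with total span 2.5 (half
  increasing, half decreasing).
- **Reads**: fixed 50 bp; counts Poisson around the configured depths
  (default 0.4M/0.8M/1.2M, the 1:2:3 ratio); starts drawn categorically
  with probability proportional to propensity. No fragment-size model, no
  sequence, no mismatches.
- **Expression**: per-gene lognormal baseline (median 60 tags, sd_log 1.2);
  log-mean adds +0.8 x z(upstream methylation) and -0.8 x z(body
  methylation) per sample; 30 planted DE genes (drawn first from the
  methylation-differential set) scale 3-fold monotonically; Poisson counts
  (negative binomial optional via `dispersion`).
- **Small RNA**: 20 miRNAs, base mean 400 reads; 13 planted up in 1N vs 2N,
  of which 4 up and 9 down in 3N vs 2N (2.5-fold); library totals ~1.5M.
  Clone plans replicate canonical-site patterns (11/11, 8/8, 4/5).

Everything is deterministic given the seed: each stage and sample draws
from its own numbered substream.

### What the synthetic experiments show — and what they do not

Passing tests demonstrate that the *pipeline* recovers what was planted
under a favourable, known-truth landscape: >= 90% sensitivity and <= 10%
FDR for 2.5-fold planted genes once regional coverage reaches ~100x
(depths 4.5M/9M/13.5M in the recovery experiment); RPM concordance
r >= 0.95 across the 1:2:3 depths; the stratified metagene contrast with
the planted coupling signs. They do not demonstrate performance on real
MeDIP data, which has CpG-density bias, fragment-length structure,
mappability holes and biological replication noise that the generator
deliberately omits. At the default desk-scale depth the 1N library is
depth-limited, so methylated-gene counts rise with ploidy — a coverage
artifact worth remembering when reading the demo outputs. At the default
gene density, neighbouring genes' flanks enter the +/-4 kb metagene window
and lift distal bins; the upstream-maximum property is asserted on a
sparser 200-gene landscape.

## Numerical choices and degenerate inputs

- Percentages reported by summary functions are rounded half-up to one
  decimal (`decimal.Decimal`); all comparisons happen on unrounded values.
- Poisson tails come from `scipy.stats.poisson.sf(count-1, lam)`, verified
  against direct pmf partial sums to < 1e-10 relative error for counts
  0-50 and lambda in 0.1-20.
- Fold changes with both levels zero return 1 (pseudocount regularisation);
  zero-variance vectors make Pearson correlation an error, not a NaN.
- Empty peak sets, empty strata (warned and omitted), empty clone tables
  and zero depth all produce well-defined empty outputs.
- Problem sizes in the test-suite experiments (1000 genes, 4.8 Mb genome,
  up to 13.5M reads per sample, 5 seeds) were chosen so the planted-signal
  conditions (>= 100x regional coverage) hold while the whole suite stays
  desk-scale.

## Known limitations

- No CpG coupling-factor correction of MeDIP enrichment; no absolute
  methylation calibration; no per-cytosine context (MeDIP has none).
- Single library per condition: all differential calls are descriptive
  thresholds (methylation) or two-library exact tests (expression), not
  replicate-aware inference.
- The published genome-scale counts (tens of thousands of peaks and genes)
  arise from a 370+ Mb genome at production depth and are not reproduced at
  desk scale; the pipeline reproduces the *arithmetic* of the published
  summaries exactly and the *properties* of the method on synthetic truth.
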