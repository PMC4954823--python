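"""Gene-level methylation: the methylated-gene rule, per-gene levels,
feature-class peak densities, TSS/TES flanking profiles, and the
three-sample Venn summary.

A gene is *methylated* when at least one peak overlaps (>= 1 bp) its
methylation region, defined as 1.5 kb upstream of the TSS through the TES
in the gene's own orientation. Per-gene levels are reads per million
uniquely mapped reads (RPM) over the gene body, which divides out the
1:2:3 depth of the ploidy series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import pct
from .genome import SAMPLES, GeneModel, GenomeAnnotation, ReadSet

FEATURE_CLASSES = (
    "intergenic", "promoter", "5utr", "exon", "intron", "3utr", "downstream2kb",
)


@dataclass(frozen=True)
class VennSummary:
    """Three-set Venn regions for methylated-gene sets (1N/2N/3N)."""

    totals: dict[str, int]
    exclusive: dict[str, int]
    pairwise_only: dict[tuple[str, str], int]
    shared_all: int
    exclusive_pct: dict[str, float]

    @property
    def union_size(self) -> int:
        return (sum(self.exclusive.values())
                + sum(self.pairwise_only.values()) + self.shared_all)


def methylation_region(
    gene: GeneModel, upstream: int = 1500, chrom_length: int | None = None
) -> tuple[int, int]:
    """Half-open genomic interval from 1.5 kb upstream of the TSS to the TES."""
    if gene.strand == "+":
        start, end = gene.start - upstream, gene.end
    else:
        start, end = gene.start, gene.end + upstream
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return start, end


def call_methylated_genes(
    peaks: pd.DataFrame, annotation: GenomeAnnotation, upstream: int = 1500
) -> set[str]:
    """Gene ids with >=1 bp overlap between any peak and the methylation region."""
    out: set[str] = set()
    by_chrom = {
        chrom: sub.sort_values("start")
        for chrom, sub in peaks.groupby("chrom", sort=False)
    }
    for chrom, sub in by_chrom.items():
        p_start = sub["start"].to_numpy()
        p_end = sub["end"].to_numpy()
        # peaks are non-overlapping after merging, so ends sorted too
        for g in annotation.genes_by_chrom(chrom):
            a, b = methylation_region(g, upstream, annotation.chrom_lengths[chrom])
            i = np.searchsorted(p_start, b, side="left")
            if np.any(p_end[:i] > a):
                out.add(g.gene_id)
    return out


def gene_level(reads: ReadSet, gene: GeneModel, library_total: int) -> float:
    """RPM of reads overlapping the gene body [TSS, TES)."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    n = reads.count_overlapping(gene.chrom, gene.start, gene.end)
    return n * 1e6 / library_total


def gene_levels(
    reads: ReadSet, annotation: GenomeAnnotation,
    library_total: int | None = None, region: str = "body",
    upstream: int = 1500,
) -> pd.Series:
    """Vectorised per-gene RPM over the gene body or methylation region."""
    total = reads.total if library_total is None else library_total
    if total <= 0:
        raise ValueError("library_total must be positive")
    levels = {}
    for chrom, L in annotation.chrom_lengths.items():
        starts = reads.starts.get(chrom, np.empty(0, dtype=np.int64))
        ends = reads.ends.get(chrom, np.empty(0, dtype=np.int64))
        for g in annotation.genes_by_chrom(chrom):
            if region == "body":
                a, b = g.start, g.end
            elif region == "methylation":
                a, b = methylation_region(g, upstream, L)
            else:
                raise ValueError(f"unknown region {region!r}")
            i = np.searchsorted(starts, b, side="left")
            n = int(np.count_nonzero(ends[:i] > a))
            levels[g.gene_id] = n * 1e6 / total
    return pd.Series(levels, name=reads.sample).sort_index()


def build_methylation_table(
    annotation: GenomeAnnotation,
    readsets: dict[str, ReadSet],
    peaksets: dict[str, pd.DataFrame] | None = None,
    upstream: int = 1500,
) -> pd.DataFrame:
    """Per-gene table: RPM level per sample, methylated flag per sample."""
    cols = {}
    for sample, rs in readsets.items():
        cols[f"level_{sample}"] = gene_levels(rs, annotation)
    table = pd.DataFrame(cols)
    table.index.name = "gene_id"
    if peaksets is not None:
        for sample, pk in peaksets.items():
            meth = call_methylated_genes(pk, annotation, upstream=upstream)
            table[f"methylated_{sample}"] = table.index.isin(sorted(meth))
    return table


# --------------------------------------------------------- feature classes
def feature_class_arrays(
    annotation: GenomeAnnotation, promoter: int = 1500, downstream: int = 2000
) -> dict[str, np.ndarray]:
    """Assign every base to exactly one class (uint8 into FEATURE_CLASSES).

    Paint order per gene: flanks (downstream2kb, promoter) first, then the
    body as intron, then exons, then UTRs, so structurally finer classes win
    within a gene; genes are processed in id order, later genes overwriting
    earlier ones where models overlap.
    """
    code = {name: i for i, name in enumerate(FEATURE_CLASSES)}
    arrays = {
        chrom: np.zeros(L, dtype=np.uint8)
        for chrom, L in annotation.chrom_lengths.items()
    }
    genes = sorted(annotation.genes, key=lambda g: g.gene_id)
    for g in genes:
        arr = arrays[g.chrom]
        L = arr.size
        if g.strand == "+":
            prom = (max(0, g.start - promoter), g.start)
            down = (g.end, min(L, g.end + downstream))
        else:
            prom = (g.end, min(L, g.end + promoter))
            down = (max(0, g.start - downstream), g.start)
        arr[down[0]:down[1]] = code["downstream2kb"]
        arr[prom[0]:prom[1]] = code["promoter"]
        arr[g.start:g.end] = code["intron"]
        for s, e in g.exons:
            arr[s:e] = code["exon"]
        for s, e in g.utr5:
            arr[s:e] = code["5utr"]
        for s, e in g.utr3:
            arr[s:e] = code["3utr"]
    return arrays


def feature_density(
    peaks: pd.DataFrame, annotation: GenomeAnnotation,
    promoter: int = 1500, downstream: int = 2000,
) -> pd.DataFrame:
    """Per feature class: class length, peak-overlap bp, density ratio."""
    arrays = feature_class_arrays(annotation, promoter, downstream)
    n_classes = len(FEATURE_CLASSES)
    class_len = np.zeros(n_classes, dtype=np.int64)
    overlap = np.zeros(n_classes, dtype=np.int64)
    for chrom, arr in arrays.items():
        class_len += np.bincount(arr, minlength=n_classes)
        covered = np.zeros(arr.size, dtype=bool)
        sub = peaks[peaks["chrom"] == chrom]
        for row in sub.itertuples(index=False):
            covered[max(0, row.start):min(arr.size, row.end)] = True
        if covered.any():
            overlap += np.bincount(arr[covered], minlength=n_classes)
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(class_len > 0, overlap / class_len, 0.0)
    return pd.DataFrame({
        "feature": FEATURE_CLASSES,
        "class_length": class_len,
        "overlap_length": overlap,
        "density": density,
    })


# ------------------------------------------------------------ flank profile
def flank_profile(
    intervals: ReadSet | pd.DataFrame,
    annotation: GenomeAnnotation,
    flank: int = 4000,
    bins: int = 80,
    anchor: str = "TSS",
) -> pd.DataFrame:
    """Mean per-bp density of interval starts around TSS or TES, oriented by
    gene strand (negative relative positions are upstream).

    ``intervals`` may be a ReadSet (all reads) or a peak DataFrame (reads of
    peaks / peak intervals); in both cases the element's start position is
    the counted point. Bins fully outside the chromosome are excluded from a
    gene's contribution to the average.
    """
    if (2 * flank) % bins != 0:
        raise ValueError("bins must divide 2*flank")
    width = 2 * flank // bins
    edges = np.arange(-flank, flank + width, width)
    totals = np.zeros(bins, dtype=np.float64)
    gene_bin_n = np.zeros(bins, dtype=np.int64)

    if isinstance(intervals, ReadSet):
        pos_by_chrom = {c: intervals.starts[c] for c in intervals.chromosomes()}
    else:
        pos_by_chrom = {
            str(chrom): np.sort(sub["start"].to_numpy())
            for chrom, sub in intervals.groupby("chrom", sort=False)
        }

    for chrom, L in annotation.chrom_lengths.items():
        pos = pos_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
        for g in annotation.genes_by_chrom(chrom):
            a = g.tss if anchor == "TSS" else g.tes
            if g.strand == "+":
                lo, hi = a - flank, a + flank
                sel = pos[np.searchsorted(pos, lo):np.searchsorted(pos, hi)]
                rel = sel - a
            else:
                lo, hi = a - flank, a + flank
                sel = pos[np.searchsorted(pos, lo):np.searchsorted(pos, hi)]
                rel = a - sel  # reflect: genomic downstream is gene-upstream
            idx = (rel + flank) // width
            idx = idx[(idx >= 0) & (idx < bins)]
            np.add.at(totals, idx.astype(np.int64), 1.0)
            # which bins lie fully inside the chromosome for this gene?
            if g.strand == "+":
                bin_lo = a + edges[:-1]
                bin_hi = a + edges[1:]
            else:
                bin_hi = a - edges[:-1]
                bin_lo = a - edges[1:]
            inside = (bin_lo >= 0) & (bin_hi <= L)
            gene_bin_n += inside.astype(np.int64)

    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(gene_bin_n > 0, totals / (gene_bin_n * width), 0.0)
    return pd.DataFrame({
        "rel_start": edges[:-1],
        "rel_end": edges[1:],
        "density": density,
    })


# ------------------------------------------------------------------- Venn
def venn_summary(sets: dict[str, set[str]]) -> VennSummary:
    """Seven-region Venn decomposition of the three methylated-gene sets."""
    if set(sets) != set(SAMPLES):
        raise ValueError("need exactly the samples 1N, 2N, 3N")
    a, b, c = (sets[s] for s in SAMPLES)
    only = {
        "1N": len(a - b - c),
        "2N": len(b - a - c),
        "3N": len(c - a - b),
    }
    pair_only = {
        ("1N", "2N"): len((a & b) - c),
        ("1N", "3N"): len((a & c) - b),
        ("2N", "3N"): len((b & c) - a),
    }
    shared = len(a & b & c)
    totals = {s: len(sets[s]) for s in SAMPLES}
    excl_pct = {
        s: (pct(only[s], totals[s]) if totals[s] else 0.0) for s in SAMPLES
    }
    return VennSummary(totals=totals, exclusive=only, pairwise_only=pair_only,
                       shared_all=shared, exclusive_pct=excl_pct)
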