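"""Sliding-window Poisson peak calling for MeDIP-seq read enrichment.

Windows (default 200 bp, step 50 bp) tile each chromosome; the count of
read starts in a window is tested against a genome-wide uniform Poisson
null with rate lambda = total_reads * window / genome_length. Windows with
upper-tail p < alpha (default 1e-5) are merged when separated by at most
``merge_gap`` bp, and merged regions shorter than ``min_length`` (default
200 bp) are discarded. No multiple-testing correction is applied to the
calling threshold: the raw p-value cut is the operating definition of a
methylation peak here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import pct
from .genome import GenomeAnnotation, ReadSet

PEAK_COLUMNS = ["chrom", "start", "end", "count", "pvalue"]


@dataclass
class WindowCounts:
    """Read-start counts in tiled windows, one array per chromosome."""

    window: int
    step: int
    chrom_lengths: dict[str, int]
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def window_bounds(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        L = self.chrom_lengths[chrom]
        starts = np.arange(0, L, self.step, dtype=np.int64)
        ends = np.minimum(starts + self.window, L)
        return starts, ends


@dataclass(frozen=True)
class PeakStats:
    """Summary of one sample's peak set (count/length/coverage/genes)."""

    n_peaks: int
    mean_length: float
    total_length: int
    coverage_pct: float
    genes_involved: int


@dataclass(frozen=True)
class MappingStats:
    """Read-mapping bookkeeping with reported percentages."""

    raw: float
    mapped: float
    unique: float
    mapped_pct: float
    unique_pct: float


def compute_window_counts(
    reads: ReadSet, annotation: GenomeAnnotation, window: int, step: int
) -> WindowCounts:
    """Count read starts per tiled window (a start lands in every window
    containing it; with step == window this partitions the reads)."""
    if not (window >= step > 0):
        raise ValueError("need window >= step > 0")
    for chrom in reads.chromosomes():
        if chrom not in annotation.chrom_lengths:
            raise ValueError(f"reads on unknown chromosome {chrom!r}")
    wc = WindowCounts(window=window, step=step,
                      chrom_lengths=dict(annotation.chrom_lengths))
    for chrom, L in annotation.chrom_lengths.items():
        ws, we = wc.window_bounds(chrom)
        starts = reads.starts.get(chrom, np.empty(0, dtype=np.int64))
        wc.counts[chrom] = (
            np.searchsorted(starts, we, side="left")
            - np.searchsorted(starts, ws, side="left")
        ).astype(np.int64)
    return wc


def poisson_window_pvalue(count: float, expected: float) -> float:
    """Upper-tail Poisson probability P(X >= count | lambda = expected)."""
    if count < 0 or expected < 0:
        raise ValueError("count and expected must be non-negative")
    if count == 0:
        return 1.0
    if expected == 0:
        return 0.0
    return float(stats.poisson.sf(count - 1, expected))


def call_peaks(
    wc: WindowCounts,
    genome_read_total: int,
    genome_length: int,
    alpha: float = 1e-5,
    min_length: int = 200,
    merge_gap: int = 100,
) -> pd.DataFrame:
    """Merge significant windows into peaks.

    Returns a DataFrame with columns chrom/start/end/count/pvalue, where
    count is the number of read starts in the merged span and pvalue the
    minimum constituent window p-value.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0,1)")
    # one uniform null rate for every window, truncated ones included
    lam = genome_read_total * wc.window / genome_length
    rows = []
    for chrom in wc.chrom_lengths:
        counts = wc.counts[chrom]
        ws, we = wc.window_bounds(chrom)
        pvals = stats.poisson.sf(counts - 1, lam)
        pvals = np.where(counts == 0, 1.0, pvals)
        if lam == 0:
            pvals = np.where(counts > 0, 0.0, 1.0)
        sig = pvals < alpha
        if not sig.any():
            continue
        idx = np.flatnonzero(sig)
        # merge window spans separated by <= merge_gap bp
        span_start, span_end = int(ws[idx[0]]), int(we[idx[0]])
        min_p = float(pvals[idx[0]])
        merged: list[tuple[int, int, float]] = []
        for i in idx[1:]:
            if int(ws[i]) - span_end <= merge_gap:
                span_end = max(span_end, int(we[i]))
                min_p = min(min_p, float(pvals[i]))
            else:
                merged.append((span_start, span_end, min_p))
                span_start, span_end, min_p = int(ws[i]), int(we[i]), float(pvals[i])
        merged.append((span_start, span_end, min_p))
        for s, e, p in merged:
            if e - s < min_length:
                continue
            rows.append((chrom, s, e, 0, p))
    peaks = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    if len(peaks):
        peaks["start"] = peaks["start"].astype(np.int64)
        peaks["end"] = peaks["end"].astype(np.int64)
    return peaks


def annotate_peak_counts(peaks: pd.DataFrame, reads: ReadSet) -> pd.DataFrame:
    """Fill the ``count`` column with read starts falling in each peak."""
    peaks = peaks.copy()
    counts = np.zeros(len(peaks), dtype=np.int64)
    for i, row in enumerate(peaks.itertuples(index=False)):
        starts = reads.starts.get(row.chrom, np.empty(0, dtype=np.int64))
        counts[i] = np.searchsorted(starts, row.end, side="left") - np.searchsorted(
            starts, row.start, side="left")
    peaks["count"] = counts
    return peaks


def peak_stats(
    peaks: pd.DataFrame, genome_length: int, annotation: GenomeAnnotation,
    upstream: int = 1500,
) -> PeakStats:
    """Count / mean length / total length / coverage %, plus the number of
    genes with >=1 peak overlapping their methylation region."""
    from .gene_methylation import call_methylated_genes  # local: avoids cycle

    n = len(peaks)
    if n == 0:
        return PeakStats(0, 0.0, 0, 0.0, 0)
    lengths = (peaks["end"] - peaks["start"]).to_numpy()
    total = int(lengths.sum())
    genes = call_methylated_genes(peaks, annotation, upstream=upstream)
    return PeakStats(
        n_peaks=n,
        mean_length=float(total / n),
        total_length=total,
        coverage_pct=100.0 * total / genome_length,
        genes_involved=len(genes),
    )


def mapping_stats(raw: float, mapped: float, unique: float) -> MappingStats:
    """Mapped % of raw and uniquely-mapped % of mapped, rounded half-up to
    one decimal as reported."""
    if not (0 <= unique <= mapped <= raw):
        raise ValueError("need unique <= mapped <= raw, all non-negative")
    return MappingStats(
        raw=raw, mapped=mapped, unique=unique,
        mapped_pct=pct(mapped, raw),
        unique_pct=pct(unique, mapped),
    )


def peaks_to_bed(peaks: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        for i, row in enumerate(peaks.itertuples(index=False)):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tpeak{i}\t0\t.\n")


def peaks_from_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"],
                     dtype={"chrom": str, "start": np.int64, "end": np.int64})
    df["count"] = 0
    df["pvalue"] = np.nan
    return df[PEAK_COLUMNS]
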