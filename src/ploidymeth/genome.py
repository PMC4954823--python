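"""Genome annotation and aligned-read containers.

Coordinates are 0-based half-open everywhere in memory; GFF3 is written
1-based inclusive per the standard. Genes are stranded; MeDIP reads are
strandless intervals. TSS/TES are the strand-oriented transcription start
and end coordinates of a gene model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


Interval = tuple[int, int]


@dataclass(frozen=True)
class GeneModel:
    """One gene: stranded span with exon and UTR structure.

    ``start``/``end`` are the genomic half-open span. On the + strand the TSS
    is ``start`` and the TES is ``end``; on the - strand they swap, so that
    "upstream of the TSS" always means 5' of the gene in its own orientation.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int
    exons: tuple[Interval, ...] = ()
    utr5: tuple[Interval, ...] = ()
    utr3: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad span for {self.gene_id}")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"exon outside gene span in {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus the gene models anchored on them."""

    chrom_lengths: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.chrom not in self.chrom_lengths:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > self.chrom_lengths[g.chrom]:
                raise ValueError(f"gene {g.gene_id} extends past chromosome end")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def genes_by_chrom(self, chrom: str) -> list[GeneModel]:
        return sorted(
            (g for g in self.genes if g.chrom == chrom), key=lambda g: g.start
        )

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    # ---------------------------------------------------------------- GFF3
    def to_gff3(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom, length in self.chrom_lengths.items():
                fh.write(f"##sequence-region {chrom} 1 {length}\n")
            for g in sorted(self.genes, key=lambda g: (g.chrom, g.start)):
                fh.write(_gff3_line(g.chrom, "gene", g.start, g.end, g.strand,
                                    f"ID={g.gene_id}"))
                for i, (s, e) in enumerate(g.exons, 1):
                    fh.write(_gff3_line(g.chrom, "exon", s, e, g.strand,
                                        f"ID={g.gene_id}.exon{i};Parent={g.gene_id}"))
                for i, (s, e) in enumerate(g.utr5, 1):
                    fh.write(_gff3_line(g.chrom, "five_prime_UTR", s, e, g.strand,
                                        f"ID={g.gene_id}.5utr{i};Parent={g.gene_id}"))
                for i, (s, e) in enumerate(g.utr3, 1):
                    fh.write(_gff3_line(g.chrom, "three_prime_UTR", s, e, g.strand,
                                        f"ID={g.gene_id}.3utr{i};Parent={g.gene_id}"))

    @classmethod
    def from_gff3(cls, path: str) -> "GenomeAnnotation":
        import gffutils

        chrom_lengths: dict[str, int] = {}
        with open(path) as fh:
            text = fh.read()
        for line in text.splitlines():
            if line.startswith("##sequence-region"):
                _, chrom, _one, length = line.split()
                chrom_lengths[chrom] = int(length)
        db = gffutils.create_db(
            text, ":memory:", from_string=True,
            merge_strategy="create_unique", keep_order=True,
        )
        genes: list[GeneModel] = []
        for feat in db.features_of_type("gene"):
            exons, u5, u3 = [], [], []
            for child in db.children(feat.id):
                iv = (child.start - 1, child.end)
                if child.featuretype == "exon":
                    exons.append(iv)
                elif child.featuretype == "five_prime_UTR":
                    u5.append(iv)
                elif child.featuretype == "three_prime_UTR":
                    u3.append(iv)
            genes.append(GeneModel(
                gene_id=feat.id, chrom=feat.seqid, strand=feat.strand,
                start=feat.start - 1, end=feat.end,
                exons=tuple(sorted(exons)), utr5=tuple(sorted(u5)),
                utr3=tuple(sorted(u3)),
            ))
        if not chrom_lengths:
            for g in genes:
                chrom_lengths[g.chrom] = max(chrom_lengths.get(g.chrom, 0), g.end)
        genes.sort(key=lambda g: (g.chrom, g.start))
        return cls(chrom_lengths=chrom_lengths, genes=genes)

    # ---------------------------------------------------------------- BED12
    def to_bed12(self, path: str) -> None:
        with open(path, "w") as fh:
            for g in sorted(self.genes, key=lambda g: (g.chrom, g.start)):
                exons = g.exons or ((g.start, g.end),)
                sizes = ",".join(str(e - s) for s, e in exons) + ","
                offs = ",".join(str(s - g.start) for s, e in exons) + ","
                fh.write(
                    f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}"
                    f"\t{g.start}\t{g.end}\t0\t{len(exons)}\t{sizes}\t{offs}\n"
                )


def _gff3_line(chrom: str, ftype: str, start: int, end: int, strand: str,
               attrs: str) -> str:
    return f"{chrom}\tploidymeth\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"


@dataclass
class ReadSet:
    """Uniquely mapped, strandless read intervals for one sample.

    Reads are stored per chromosome as parallel start/end arrays sorted by
    start, which keeps window counting and per-gene overlap counting to a
    pair of searchsorted calls.
    """

    sample: str
    starts: dict[str, np.ndarray] = field(default_factory=dict)
    ends: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom in self.starts:
            s = np.asarray(self.starts[chrom], dtype=np.int64)
            e = np.asarray(self.ends[chrom], dtype=np.int64)
            if s.shape != e.shape:
                raise ValueError("start/end arrays differ in length")
            if s.size and (np.any(s < 0) or np.any(e <= s)):
                raise ValueError("invalid read interval (need 0 <= start < end)")
            order = np.argsort(s, kind="stable")
            self.starts[chrom] = s[order]
            self.ends[chrom] = e[order]

    @property
    def total(self) -> int:
        return int(sum(v.size for v in self.starts.values()))

    def chromosomes(self) -> list[str]:
        return list(self.starts)

    def count_overlapping(self, chrom: str, start: int, end: int) -> int:
        """Number of reads with >=1 bp overlap of [start, end)."""
        if chrom not in self.starts:
            return 0
        s = self.starts[chrom]
        e = self.ends[chrom]
        # reads here have (nearly) uniform length: overlap iff
        # read.start < end and read.end > start
        idx = np.searchsorted(s, end, side="left")
        return int(np.count_nonzero(e[:idx] > start))

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.starts):
                s, e = self.starts[chrom], self.ends[chrom]
                for i in range(s.size):
                    fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{self.sample}.{i}\t0\t.\n")

    @classmethod
    def from_bed(cls, path: str, sample: str) -> "ReadSet":
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                         names=["chrom", "start", "end"],
                         dtype={"chrom": str, "start": np.int64, "end": np.int64})
        starts, ends = {}, {}
        for chrom, sub in df.groupby("chrom", sort=True):
            starts[str(chrom)] = sub["start"].to_numpy()
            ends[str(chrom)] = sub["end"].to_numpy()
        return cls(sample=sample, starts=starts, ends=ends)


SAMPLES = ("1N", "2N", "3N")
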