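"""Ground-truth simulator for the 1N/2N/3N ploidy-series design.

Three genetically identical samples share one methylation landscape and
differ only in sequencing depth (1:2:3 after length normalisation), except
for a small planted set of differentially methylated genes. MeDIP read
starts are drawn from a piecewise-constant per-base methylation propensity;
digital-expression tag counts are coupled to that landscape (positively to
methylation upstream of the TSS, negatively to gene-body methylation); and
miRNA counts plus 5'-RACE cleavage clones carry planted directions with a
canonical cleavage site between duplex positions 10 and 11.

Everything is deterministic given ``SimulationConfig.seed``: each stage and
sample draws from its own numbered substream of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import substream
from .genome import SAMPLES, GeneModel, GenomeAnnotation, ReadSet

# substream ids, one per stochastic stage
_S_GENOME, _S_METH, _S_READS, _S_DGE, _S_SRNA = 1, 2, 3, 4, 5

#: minimum intergenic gap; keeps one gene's 1.5 kb flanking windows off the
#: next gene's body so planted per-gene signals stay attributable
MIN_GENE_GAP = 1600


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic ploidy series.

    Defaults give a desk-scale genome (two 2.4 Mb chromosomes, 1000 genes)
    with MeDIP depths in the 1:2:3 ratio of the ploidy series.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 2_400_000
    n_genes: int = 1000
    gene_length_range: tuple[int, int] = (800, 1200)
    fraction_methylated: float = 0.5
    n_diff_genes: int = 50
    diff_fold: float = 2.5
    depth_per_ploidy: dict[str, int] = field(
        default_factory=lambda: {"1N": 400_000, "2N": 800_000, "3N": 1_200_000}
    )
    read_length: int = 50
    expression_coupling: tuple[float, float] = (0.8, -0.8)
    # landscape shape (background propensity is 1.0 per base)
    flank_bp: int = 1500
    upstream_enrichment: float = 10.0
    downstream_enrichment: float = 8.0  # promoter methylation dominates
    body_enrichment: float = 5.0
    # expression model
    expression_base_median: float = 60.0
    expression_log_sd: float = 1.2
    dispersion: float | None = None  # None -> Poisson; else NB with this alpha
    n_expression_diff: int = 30
    expression_diff_fold: float = 3.0
    # small RNA
    n_mirnas: int = 20
    n_mirna_up_1n: int = 13  # all differential miRNAs are up in 1N vs 2N
    n_mirna_up_3n: int = 4   # of those, this many are also up in 3N vs 2N
    mirna_base_mean: float = 400.0
    mirna_fold: float = 2.5
    clone_plan: dict[str, dict[str, tuple[int, int]]] = field(
        default_factory=lambda: {
            "mir-A": {"1N": (11, 0), "2N": (8, 0), "3N": (4, 1)},
            "mir-B": {"1N": (6, 0), "2N": (5, 0), "3N": (1, 2)},
        }
    )
    site_length: int = 21

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0 or self.chromosome_length <= 0:
            raise ValueError("chromosome counts/lengths must be positive")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        lo, hi = self.gene_length_range
        if not 0 < lo <= hi:
            raise ValueError("bad gene_length_range")
        if not 0.0 <= self.fraction_methylated <= 1.0:
            raise ValueError("fraction_methylated must be in [0,1]")
        if self.n_diff_genes < 0:
            raise ValueError("n_diff_genes must be >= 0")
        if self.diff_fold <= 1.0:
            raise ValueError("diff_fold must exceed 1")
        if set(self.depth_per_ploidy) != set(SAMPLES):
            raise ValueError("depth_per_ploidy must have exactly the keys 1N, 2N, 3N")
        if any(d < 0 for d in self.depth_per_ploidy.values()):
            raise ValueError("depths must be >= 0")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")


@dataclass
class TruthTable:
    """Planted ground truth: one row per gene, one per miRNA."""

    genes: pd.DataFrame   # gene_id, methylated, diff (bool), diff_direction
    mirnas: pd.DataFrame  # mirna_id, direction_1n_vs_2n, direction_3n_vs_2n

    def __post_init__(self) -> None:
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("duplicate gene in truth table")


@dataclass
class PropensityMap:
    """Per-sample per-base methylation propensity (relative read rate)."""

    per_sample: dict[str, dict[str, np.ndarray]]

    def sample(self, sample: str) -> dict[str, np.ndarray]:
        return self.per_sample[sample]


# ----------------------------------------------------------------- genome
def make_genome(config: SimulationConfig) -> GenomeAnnotation:
    """Place non-overlapping stranded gene models on the toy chromosomes."""
    rng = substream(config.seed, _S_GENOME)
    lo, hi = config.gene_length_range
    per_chrom = _split_counts(config.n_genes, config.n_chromosomes)
    chrom_lengths = {
        f"chr{i + 1}": config.chromosome_length for i in range(config.n_chromosomes)
    }
    genes: list[GeneModel] = []
    gid = 0
    for ci, (chrom, n_here) in enumerate(zip(chrom_lengths, per_chrom)):
        lengths = rng.integers(lo, hi + 1, size=n_here)
        need = int(lengths.sum()) + MIN_GENE_GAP * (n_here + 1)
        slack = config.chromosome_length - need
        if slack < 0:
            raise ValueError(
                f"{n_here} genes (plus {MIN_GENE_GAP} bp gaps) do not fit in a "
                f"{config.chromosome_length} bp chromosome"
            )
        extra = rng.multinomial(slack, np.full(n_here + 1, 1.0 / (n_here + 1)))
        pos = 0
        for j in range(n_here):
            pos += MIN_GENE_GAP + int(extra[j])
            start, end = pos, pos + int(lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(_build_gene(f"g{gid:05d}", chrom, strand, start, end, rng))
            gid += 1
            pos = end
    return GenomeAnnotation(chrom_lengths=chrom_lengths, genes=genes)


def _split_counts(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _build_gene(gene_id: str, chrom: str, strand: str, start: int, end: int,
                rng: np.random.Generator) -> GeneModel:
    length = end - start
    n_exons = int(rng.integers(1, 5))
    # cut the span into alternating exons/introns; exons take >=60% of length
    if n_exons == 1:
        exons = [(start, end)]
    else:
        cuts = np.sort(rng.choice(
            np.arange(start + 50, end - 50), size=2 * n_exons - 2, replace=False))
        bounds = [start, *cuts.tolist(), end]
        exons = [(bounds[2 * i], bounds[2 * i + 1]) for i in range(n_exons)]
        exons = [(s, e) for s, e in exons if e > s]
    u5_len = min(int(rng.integers(30, 120)), exons[0][1] - exons[0][0])
    u3_len = min(int(rng.integers(30, 150)), exons[-1][1] - exons[-1][0])
    first, last = exons[0], exons[-1]
    if strand == "+":
        utr5 = ((first[0], first[0] + u5_len),)
        utr3 = ((last[1] - u3_len, last[1]),)
    else:
        utr5 = ((last[1] - u5_len, last[1]),)
        utr3 = ((first[0], first[0] + u3_len),)
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, start=start,
                     end=end, exons=tuple(exons), utr5=utr5, utr3=utr3)


# -------------------------------------------------------------- methylome
def simulate_methylome(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> tuple[PropensityMap, TruthTable]:
    """Plant the shared landscape and the differentially methylated genes.

    Methylated genes get elevated propensity over their 1.5 kb upstream
    window, gene body, and 1.5 kb downstream-of-TES window. Upstream and
    body multipliers are drawn independently per gene so expression coupling
    to the two compartments can carry opposite signs. Planted differential
    genes scale their whole footprint monotonically across 1N/2N/3N with a
    total span of ``diff_fold``.
    """
    if len(annotation) == 0:
        raise ValueError("annotation is empty")
    if config.n_diff_genes > len(annotation):
        raise ValueError("n_diff_genes exceeds number of genes")
    rng = substream(config.seed, _S_METH)
    genes = sorted(annotation.genes, key=lambda g: g.gene_id)
    n = len(genes)
    n_meth = int(round(config.fraction_methylated * n))
    meth_idx = rng.choice(n, size=n_meth, replace=False)
    methylated = np.zeros(n, dtype=bool)
    methylated[meth_idx] = True
    # differential genes are drawn from the methylated set
    diff = np.zeros(n, dtype=bool)
    if config.n_diff_genes > 0:
        if config.n_diff_genes > n_meth:
            raise ValueError("n_diff_genes exceeds number of methylated genes")
        diff_idx = rng.choice(meth_idx, size=config.n_diff_genes, replace=False)
        diff[diff_idx] = True
    direction = np.where(diff, "", "none").astype(object)
    up = rng.random(n) < 0.5
    direction[diff & up] = "increasing"
    direction[diff & ~up] = "decreasing"

    # per-gene multipliers: upstream/downstream vs body drawn independently
    up_mult = np.where(
        methylated,
        config.upstream_enrichment * np.exp(rng.normal(0.0, 0.35, n)),
        1.0,
    )
    down_mult = np.where(
        methylated,
        config.downstream_enrichment * np.exp(rng.normal(0.0, 0.35, n)),
        1.0,
    )
    body_mult = np.where(
        methylated,
        config.body_enrichment * np.exp(rng.normal(0.0, 0.35, n)),
        1.0,
    )

    f = config.diff_fold
    ploidy_scale = {"1N": {}, "2N": {}, "3N": {}}
    for i, g in enumerate(genes):
        if direction[i] == "increasing":
            s1, s2, s3 = 1.0, np.sqrt(f), f
        elif direction[i] == "decreasing":
            s1, s2, s3 = f, np.sqrt(f), 1.0
        else:
            s1 = s2 = s3 = 1.0
        ploidy_scale["1N"][g.gene_id] = s1
        ploidy_scale["2N"][g.gene_id] = s2
        ploidy_scale["3N"][g.gene_id] = s3

    per_sample: dict[str, dict[str, np.ndarray]] = {}
    for sample in SAMPLES:
        arrs = {
            chrom: np.ones(L, dtype=np.float32)
            for chrom, L in annotation.chrom_lengths.items()
        }
        for i, g in enumerate(genes):
            if not methylated[i]:
                continue
            scale = ploidy_scale[sample][g.gene_id]
            arr = arrs[g.chrom]
            L = arr.size
            if g.strand == "+":
                up_iv = (max(0, g.start - config.flank_bp), g.start)
                down_iv = (g.end, min(L, g.end + config.flank_bp))
            else:
                up_iv = (g.end, min(L, g.end + config.flank_bp))
                down_iv = (max(0, g.start - config.flank_bp), g.start)
            arr[up_iv[0]:up_iv[1]] = up_mult[i] * scale
            arr[down_iv[0]:down_iv[1]] = down_mult[i] * scale
            arr[g.start:g.end] = body_mult[i] * scale
        per_sample[sample] = arrs

    # planted differential *expression*: overlaps the methylation-diff set
    # first (the joint genes of the cross-tabulation), then other genes
    expr_diff = np.zeros(n, dtype=bool)
    n_ediff = min(config.n_expression_diff, n)
    diff_first = np.concatenate([
        np.flatnonzero(diff), rng.permutation(np.flatnonzero(~diff))])
    e_idx = diff_first[:n_ediff]
    expr_diff[e_idx] = True
    expr_direction = np.full(n, "none", dtype=object)
    e_up = rng.random(n) < 0.5
    expr_direction[expr_diff & e_up] = "increasing"
    expr_direction[expr_diff & ~e_up] = "decreasing"

    truth_genes = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "methylated": methylated,
        "diff": diff,
        "diff_direction": direction.astype(str),
        "expr_diff": expr_diff,
        "expr_direction": expr_direction.astype(str),
        "upstream_multiplier": up_mult,
        "body_multiplier": body_mult,
    })
    truth = TruthTable(genes=truth_genes, mirnas=_mirna_truth(config))
    return PropensityMap(per_sample=per_sample), truth


def _mirna_truth(config: SimulationConfig) -> pd.DataFrame:
    ids = [f"mir{i:03d}" for i in range(config.n_mirnas)]
    d12 = ["unchanged"] * config.n_mirnas
    d32 = ["unchanged"] * config.n_mirnas
    k = min(config.n_mirna_up_1n, config.n_mirnas)
    for i in range(k):
        d12[i] = "up"  # up in 1N relative to 2N
        d32[i] = "up" if i < config.n_mirna_up_3n else "down"
    return pd.DataFrame({
        "mirna_id": ids,
        "direction_1n_vs_2n": d12,
        "direction_3n_vs_2n": d32,
    })


# ------------------------------------------------------------ MeDIP reads
def simulate_medip_reads(
    propensity: PropensityMap, sample: str, config: SimulationConfig,
    annotation: GenomeAnnotation | None = None,
) -> ReadSet:
    """Draw fixed-length read intervals with starts ~ propensity."""
    if sample not in config.depth_per_ploidy:
        raise ValueError(f"no configured depth for sample {sample!r}")
    rng = substream(config.seed, _S_READS, SAMPLES.index(sample))
    depth = config.depth_per_ploidy[sample]
    n_reads = int(rng.poisson(depth)) if depth > 0 else 0
    arrs = propensity.sample(sample)
    rl = config.read_length
    weights = np.array(
        [float(arr[: max(arr.size - rl + 1, 0)].sum()) for arr in arrs.values()]
    )
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    if n_reads > 0 and weights.sum() > 0:
        per_chrom = rng.multinomial(n_reads, weights / weights.sum())
        for (chrom, arr), k in zip(arrs.items(), per_chrom):
            if k == 0:
                starts[chrom] = np.empty(0, dtype=np.int64)
                ends[chrom] = np.empty(0, dtype=np.int64)
                continue
            w = arr[: arr.size - rl + 1].astype(np.float64)
            cdf = np.cumsum(w)
            cdf /= cdf[-1]
            pos = np.searchsorted(cdf, rng.random(k), side="right").astype(np.int64)
            pos.sort()
            starts[chrom] = pos
            ends[chrom] = pos + rl
    else:
        for chrom in arrs:
            starts[chrom] = np.empty(0, dtype=np.int64)
            ends[chrom] = np.empty(0, dtype=np.int64)
    return ReadSet(sample=sample, starts=starts, ends=ends)


# ------------------------------------------------------------- DGE counts
def simulate_dge_counts(
    annotation: GenomeAnnotation, propensity: PropensityMap,
    config: SimulationConfig, truth: TruthTable | None = None,
) -> pd.DataFrame:
    """Tag counts per gene and sample, coupled to the methylation landscape.

    log(mean) = log(base) + c_up * z(upstream methylation)
                          + c_body * z(gene-body methylation),
    where z() standardises the per-sample mean propensity over genes and
    (c_up, c_body) = ``expression_coupling``. When a truth table is given,
    its planted expression-differential genes additionally scale their mean
    monotonically across 1N/2N/3N with a total span of
    ``expression_diff_fold``. Counts are Poisson (or negative binomial when
    ``dispersion`` is set). Expression library sizes are roughly equal
    across ploidies, as in tag-based DGE sequencing.
    """
    rng = substream(config.seed, _S_DGE)
    genes = sorted(annotation.genes, key=lambda g: g.gene_id)
    n = len(genes)
    base = config.expression_base_median * np.exp(
        rng.normal(0.0, config.expression_log_sd, n))
    c_up, c_body = config.expression_coupling
    sample_fold = {s: np.ones(n) for s in SAMPLES}
    if truth is not None:
        tg = truth.genes.set_index("gene_id")
        f = config.expression_diff_fold
        for i, g in enumerate(genes):
            d = tg.at[g.gene_id, "expr_direction"]
            if d == "increasing":
                sample_fold["2N"][i] = np.sqrt(f)
                sample_fold["3N"][i] = f
            elif d == "decreasing":
                sample_fold["1N"][i] = f
                sample_fold["2N"][i] = np.sqrt(f)
    out = pd.DataFrame({"gene_id": [g.gene_id for g in genes]})
    for sample in SAMPLES:
        arrs = propensity.sample(sample)
        m_up = np.empty(n)
        m_body = np.empty(n)
        for i, g in enumerate(genes):
            arr = arrs[g.chrom]
            if g.strand == "+":
                a, b = max(0, g.start - config.flank_bp), g.start
            else:
                a, b = g.end, min(arr.size, g.end + config.flank_bp)
            m_up[i] = np.log(arr[a:b].mean()) if b > a else 0.0
            m_body[i] = np.log(arr[g.start:g.end].mean())
        z_up = _zscore(m_up)
        z_body = _zscore(m_body)
        mean = base * sample_fold[sample] * np.exp(c_up * z_up + c_body * z_body)
        if config.dispersion is None:
            counts = rng.poisson(mean)
        else:
            shape = 1.0 / config.dispersion
            counts = rng.poisson(rng.gamma(shape, mean / shape))
        out[f"count_{sample}"] = counts.astype(np.int64)
    return out


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


# -------------------------------------------------------------- small RNA
_ALPHABET = np.array(list("ACGU"))


@dataclass
class SmallRnaSim:
    """Synthetic small-RNA bundle: counts, clones, reference, library sizes."""

    counts: pd.DataFrame          # mirna_id, count_1N, count_2N, count_3N
    clones: pd.DataFrame          # mirna_id, target_gene, sample, position
    reference: dict[str, str]     # mirna_id -> 21-nt sequence
    library_totals: dict[str, int]  # total small-RNA reads per sample


def simulate_small_rna(config: SimulationConfig) -> SmallRnaSim:
    """miRNA counts per sample, 5'-RACE clone records, and reference seqs.

    Counts carry the planted directions of the truth table
    (``mirna_fold``-fold between the affected samples). Normalisation totals
    are whole small-RNA library sizes (miRNAs are a small fraction of the
    library), so the planted folds survive per-million normalisation. Clone
    records follow ``clone_plan``: per miRNA and sample, (canonical, other)
    clone numbers, canonical clones cleaved between positions 10 and 11 of
    the 21-nt site.
    """
    rng = substream(config.seed, _S_SRNA)
    truth = _mirna_truth(config)
    seqs = {
        mid: "".join(rng.choice(_ALPHABET, size=21))
        for mid in truth["mirna_id"]
    }
    rows = []
    for _, row in truth.iterrows():
        base = config.mirna_base_mean * np.exp(rng.normal(0.0, 0.3))
        mean = {"1N": base, "2N": base, "3N": base}
        if row["direction_1n_vs_2n"] == "up":
            mean["1N"] = base * config.mirna_fold
        if row["direction_3n_vs_2n"] == "up":
            mean["3N"] = base * config.mirna_fold
        elif row["direction_3n_vs_2n"] == "down":
            mean["3N"] = base / config.mirna_fold
        rows.append({
            "mirna_id": row["mirna_id"],
            **{f"count_{s}": int(rng.poisson(mean[s])) for s in SAMPLES},
        })
    counts = pd.DataFrame(rows)

    clone_rows = []
    for mirna, per_sample in config.clone_plan.items():
        target = f"target_of_{mirna}"
        for sample, (n_canon, n_other) in per_sample.items():
            for _ in range(int(n_canon)):
                clone_rows.append((mirna, target, sample, 10))
            for _ in range(int(n_other)):
                pos = 10
                while pos == 10:
                    pos = int(rng.integers(1, config.site_length))
                clone_rows.append((mirna, target, sample, pos))
    clones = pd.DataFrame(
        clone_rows, columns=["mirna_id", "target_gene", "sample", "position"]
    )
    totals = {
        s: int(rng.poisson(1_500_000)) for s in SAMPLES
    }
    return SmallRnaSim(counts=counts, clones=clones, reference=seqs,
                       library_totals=totals)


# ------------------------------------------------------------------ I/O
def write_outputs(outdir: str, annotation: GenomeAnnotation,
                  readsets: dict[str, ReadSet], expression: pd.DataFrame,
                  truth: TruthTable, clones: pd.DataFrame,
                  mirna_reference: dict[str, str] | None = None) -> None:
    """Write annotation (GFF3 + BED12), reads (BED), tables (TSV), and the
    miRNA reference (FASTA) when given."""
    import os

    os.makedirs(outdir, exist_ok=True)
    if mirna_reference:
        with open(os.path.join(outdir, "mirna_reference.fasta"), "w") as fh:
            for mid, seq in mirna_reference.items():
                fh.write(f">{mid}\n{seq}\n")
    annotation.to_gff3(os.path.join(outdir, "genome.gff3"))
    annotation.to_bed12(os.path.join(outdir, "genome.bed12"))
    for sample, rs in readsets.items():
        rs.to_bed(os.path.join(outdir, f"reads_{sample}.bed"))
    expression.to_csv(os.path.join(outdir, "expression.tsv"), sep="\t", index=False)
    truth.genes.to_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t", index=False)
    truth.mirnas.to_csv(os.path.join(outdir, "truth_mirnas.tsv"), sep="\t", index=False)
    clones.to_csv(os.path.join(outdir, "clones.tsv"), sep="\t", index=False)
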