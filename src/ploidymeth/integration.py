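"""Joining methylation and expression.

Inter-sample concordance of gene-body methylation (Pearson r of per-gene
RPM vectors), metagene methylation profiles stratified by expression level,
the differential-methylation x differential-expression cross-tabulation,
and the joint screen of monotone ploidy trends in both dimensions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeAnnotation, ReadSet
from .gene_methylation import flank_profile


def sample_correlation(levels_a, levels_b) -> float:
    """Pearson correlation between two per-gene level vectors."""
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(stats.pearsonr(a, b).statistic)


def stratified_metagene(
    reads: ReadSet,
    annotation: GenomeAnnotation,
    strata: pd.Series,
    flank: int = 4000,
    bins: int = 80,
    anchor: str = "TSS",
) -> dict[str, pd.DataFrame]:
    """One flanking profile per expression stratum, RPM-normalised.

    ``strata`` maps gene_id -> label and must cover every gene. Empty strata
    are omitted with a warning. Densities are per bp per million mapped reads.
    """
    missing = [g.gene_id for g in annotation.genes if g.gene_id not in strata.index]
    if missing:
        raise ValueError(f"genes without stratum, e.g. {missing[0]!r}")
    total = reads.total
    scale = 1e6 / total if total > 0 else 0.0
    out: dict[str, pd.DataFrame] = {}
    for label in strata.unique():
        ids = set(strata.index[strata == label])
        sub = GenomeAnnotation(
            chrom_lengths=annotation.chrom_lengths,
            genes=[g for g in annotation.genes if g.gene_id in ids],
        )
        if len(sub) == 0:
            warnings.warn(f"stratum {label!r} is empty; profile omitted")
            continue
        prof = flank_profile(reads, sub, flank=flank, bins=bins, anchor=anchor)
        prof["density"] *= scale
        out[str(label)] = prof
    return out


def meth_expr_crosstab(
    diff_meth: pd.DataFrame, de: pd.DataFrame, pair: tuple[str, str]
) -> pd.DataFrame:
    """2x2 table {meth high, meth low} x {expr up, expr down} for one pair.

    Methylation direction is re-expressed relative to the higher-ploidy
    sample of the pair ('high' = more methylated in the later sample), to
    match the expression calls' up/down convention. Genes called in only one
    dimension are excluded.
    """
    sa, sb = pair
    dm = diff_meth[diff_meth["pair"] == f"{sa}_vs_{sb}"]
    dd = de[de["pair"] == f"{sa}_vs_{sb}"]
    meth_dir = dm.set_index("gene_id")["direction"].map(
        lambda s: "high" if s == sb else "low")
    expr_dir = dd.set_index("gene_id")["direction"]
    joined = pd.concat([meth_dir.rename("meth"), expr_dir.rename("expr")],
                       axis=1, join="inner")
    tab = pd.DataFrame(0, index=["high", "low"], columns=["up", "down"])
    for (m, e), k in joined.value_counts().items():
        tab.loc[m, e] = int(k)
    tab.index.name = "methylation"
    tab.columns.name = "expression"
    return tab


def monotone_joint_screen(
    meth_trend: pd.DataFrame, expr_trend: pd.DataFrame
) -> pd.DataFrame:
    """Genes with monotone ploidy trends in both methylation and expression,
    labelled by the four direction combinations."""
    m = meth_trend.set_index("gene_id")["direction"].rename("meth_trend")
    e = expr_trend.set_index("gene_id")["direction"].rename("expr_trend")
    joined = pd.concat([m, e], axis=1, join="inner").reset_index()
    joined["class"] = joined["meth_trend"] + "_meth__" + joined["expr_trend"] + "_expr"
    return joined


def expression_trend(
    table: pd.DataFrame, threshold: float = 2.0, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Monotone expression trend across 1N/2N/3N on normalised counts,
    mirroring the methylation trend rule."""
    gene_ids = (table["gene_id"] if "gene_id" in table.columns
                else table.index.to_series()).to_numpy()
    norm = {}
    for s in ("1N", "2N", "3N"):
        c = table[f"count_{s}"].to_numpy(dtype=float)
        norm[s] = c * 1e6 / c.sum() + pseudocount
    inc = (norm["1N"] <= norm["2N"]) & (norm["2N"] <= norm["3N"]) \
        & (norm["3N"] / norm["1N"] >= threshold)
    dec = (norm["1N"] >= norm["2N"]) & (norm["2N"] >= norm["3N"]) \
        & (norm["1N"] / norm["3N"] >= threshold)
    out = pd.DataFrame({
        "gene_id": gene_ids,
        "direction": np.where(inc, "increasing", np.where(dec, "decreasing", "none")),
    })
    return out[out["direction"] != "none"].reset_index(drop=True)
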