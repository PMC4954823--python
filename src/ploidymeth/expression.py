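"""Digital gene expression: strata, and a two-library exact test.

Tag counts are absolute transcript abundances from a single library per
ploidy, so differential expression between two libraries is screened with a
two-sided exact binomial test (Audic-Claverie style): conditional on the
total count of a gene across both libraries, under the null its split
follows Binomial(n, total_a / (total_a + total_b)). P-values are adjusted
with Benjamini-Hochberg; fold changes use per-million-normalised counts
with a pseudocount. Expression strata follow raw tag counts: high > 200,
moderate 30-200 inclusive, weak < 30.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import SAMPLES

STRATA = ("weak", "moderate", "high")
DEFAULT_PSEUDOCOUNT = 0.5  # tags per million


@dataclass(frozen=True)
class DECall:
    gene_id: str
    pair: tuple[str, str]
    fold: float
    pvalue: float
    direction: str  # sample with the higher normalized count


def stratify(counts) -> pd.Series:
    """Stratum labels from raw tag counts: >200 high, 30-200 moderate, <30 weak."""
    c = pd.Series(counts)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    labels = pd.Series("moderate", index=c.index)
    labels[c > 200] = "high"
    labels[c < 30] = "weak"
    return labels


def de_exact_test(
    count_a: int, count_b: int, total_a: int, total_b: int,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> DECall:
    """Two-sided exact binomial test of one gene between two libraries."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    n = count_a + count_b
    p0 = total_a / (total_a + total_b)
    pval = 1.0 if n == 0 else float(
        stats.binomtest(count_a, n, p0, alternative="two-sided").pvalue)
    na = count_a * 1e6 / total_a + pseudocount
    nb = count_b * 1e6 / total_b + pseudocount
    fold = max(na, nb) / min(na, nb)
    direction = "a" if na > nb else ("b" if nb > na else "tie")
    return DECall(gene_id="", pair=("a", "b"), fold=fold, pvalue=min(pval, 1.0),
                  direction=direction)


def de_pvalues(
    counts_a: np.ndarray, counts_b: np.ndarray, total_a: int, total_b: int
) -> np.ndarray:
    """Vector of two-sided exact binomial p-values, one per gene."""
    out = np.ones(len(counts_a))
    p0 = total_a / (total_a + total_b)
    for i, (ca, cb) in enumerate(zip(counts_a, counts_b)):
        n = int(ca) + int(cb)
        if n > 0:
            out[i] = stats.binomtest(int(ca), n, p0, alternative="two-sided").pvalue
    return np.minimum(out, 1.0)


def call_de(
    table: pd.DataFrame,
    pair: tuple[str, str],
    alpha: float = 0.05,
    min_fold: float = 2.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    totals: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Differentially expressed genes between one sample pair.

    ``table`` needs ``count_<sample>`` columns and a gene_id column or index.
    Calls genes with BH-adjusted p <= alpha and normalized fold >= min_fold;
    direction is recorded relative to the higher-ploidy sample of the pair
    ('up' = higher in the later sample).
    """
    sa, sb = pair
    for s in pair:
        if f"count_{s}" not in table.columns:
            raise ValueError(f"sample {s!r} not in expression table")
    gene_ids = (table["gene_id"] if "gene_id" in table.columns
                else table.index.to_series()).to_numpy()
    ca = table[f"count_{sa}"].to_numpy()
    cb = table[f"count_{sb}"].to_numpy()
    ta = int(totals[sa]) if totals else int(ca.sum())
    tb = int(totals[sb]) if totals else int(cb.sum())
    pvals = de_pvalues(ca, cb, ta, tb)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    na = ca * 1e6 / ta + pseudocount
    nb = cb * 1e6 / tb + pseudocount
    fold = np.maximum(na, nb) / np.minimum(na, nb)
    # direction relative to the higher-ploidy (second) sample of the pair
    later = sb if SAMPLES.index(sb) > SAMPLES.index(sa) else sa
    hi_in_later = (nb > na) if later == sb else (na > nb)
    called = (qvals <= alpha) & (fold >= min_fold)
    return pd.DataFrame({
        "gene_id": gene_ids[called],
        "pair": f"{sa}_vs_{sb}",
        "fold": fold[called],
        "pvalue": pvals[called],
        "qvalue": qvals[called],
        "direction": np.where(hi_in_later[called], "up", "down"),
    })
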