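"""Differential methylation between ploidy levels.

Pure fold-change semantics on depth-normalised (RPM) gene levels: a gene is
differentially methylated between two samples when the ratio of its
pseudocount-regularised levels reaches the threshold (default 2-fold), and
shows a ploidy trend when its levels are monotone across 1N/2N/3N with a
1N-to-3N span of at least the trend threshold (default 1.5-fold). No
significance test is attached to these calls.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from ._utils import pct
from .genome import SAMPLES

PAIRS = tuple(itertools.combinations(SAMPLES, 2))  # (1N,2N), (1N,3N), (2N,3N)

DEFAULT_PSEUDOCOUNT = 0.5  # RPM


def fold_change(
    level_a: float, level_b: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> tuple[float, str]:
    """Ratio max/min of pseudocount-shifted levels, with the higher side.

    Returns (ratio >= 1, direction), direction one of 'first'/'second'/'tie'.
    """
    if level_a < 0 or level_b < 0:
        raise ValueError("levels must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    a = level_a + pseudocount
    b = level_b + pseudocount
    if a == b:
        return 1.0, "tie"
    if a > b:
        return a / b, "first"
    return b / a, "second"


def call_differential(
    table: pd.DataFrame,
    pair: tuple[str, str],
    threshold: float = 2.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Genes whose RPM fold change between the pair reaches ``threshold``.

    ``table`` must carry ``level_<sample>`` columns indexed by gene id.
    Returns columns gene_id / pair / fold / direction, direction naming the
    sample with the higher level.
    """
    sa, sb = pair
    for s in pair:
        if f"level_{s}" not in table.columns:
            raise ValueError(f"sample {s!r} not in table")
    a = table[f"level_{sa}"] + pseudocount
    b = table[f"level_{sb}"] + pseudocount
    hi = a.where(a >= b, b)
    lo = a.where(a < b, b)
    fold = hi / lo
    called = fold >= threshold
    direction = np.where(a[called] > b[called], sa,
                         np.where(a[called] < b[called], sb, "tie"))
    return pd.DataFrame({
        "gene_id": table.index[called].to_numpy(),
        "pair": f"{sa}_vs_{sb}",
        "fold": fold[called].to_numpy(),
        "direction": direction,
    })


def exclusive_pairwise_summary(
    calls: dict[tuple[str, str], pd.DataFrame]
) -> pd.DataFrame:
    """Per-pair exclusive counts as a share of the union of all called genes."""
    sets = {pair: set(df["gene_id"]) for pair, df in calls.items()}
    union: set[str] = set().union(*sets.values()) if sets else set()
    rows = []
    for pair, s in sets.items():
        others: set[str] = set().union(
            *(o for p, o in sets.items() if p != pair)) if len(sets) > 1 else set()
        excl = len(s - others)
        rows.append({
            "pair": f"{pair[0]}_vs_{pair[1]}",
            "called": len(s),
            "exclusive": excl,
            "exclusive_pct_of_union": pct(excl, len(union)) if union else 0.0,
        })
    out = pd.DataFrame(rows)
    out.attrs["union_size"] = len(union)
    return out


def call_trend(
    table: pd.DataFrame,
    threshold: float = 1.5,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Genes monotone across 1N<=2N<=3N (or >=) with span fold >= threshold.

    Returns columns gene_id / direction ('increasing'/'decreasing') / span_fold.
    """
    l1 = table["level_1N"] + pseudocount
    l2 = table["level_2N"] + pseudocount
    l3 = table["level_3N"] + pseudocount
    inc = (l1 <= l2) & (l2 <= l3) & (l3 / l1 >= threshold)
    dec = (l1 >= l2) & (l2 >= l3) & (l1 / l3 >= threshold)
    span = pd.concat([l3 / l1, l1 / l3], axis=1).max(axis=1)
    out = pd.DataFrame({
        "gene_id": table.index,
        "direction": pd.Series("none", index=table.index),
        "span_fold": span,
    })
    out.loc[inc.to_numpy(), "direction"] = "increasing"
    out.loc[dec.to_numpy(), "direction"] = "decreasing"
    return out[out["direction"] != "none"].reset_index(drop=True)
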