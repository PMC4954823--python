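"""Small-RNA quantification and 5'-RACE cleavage tallies.

Collapsed small-RNA reads are matched to a user-supplied miRNA reference
(fewest mismatches wins, ties discarded), filtered at an abundance
threshold (> 50 reads in at least one sample), compared across the ploidy
series on per-million-normalised counts, and 5'-RACE clone records are
tallied per cleavage position within the target site. The canonical
miRNA-guided cleavage site lies between duplex positions 10 and 11,
recorded here as position 10 (1-based; position p means cleavage between
p and p+1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import SAMPLES

CANONICAL_POSITION = 10


def load_reference(path: str) -> dict[str, str]:
    """Read a miRNA reference FASTA into an id -> sequence mapping."""
    from Bio import SeqIO

    ref = {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
    if not ref:
        raise ValueError(f"no sequences in miRNA reference {path!r}")
    return ref


def _distance(read: str, ref: str) -> int:
    if len(read) == len(ref):
        return sum(1 for x, y in zip(read, ref) if x != y)
    import edlib

    return int(edlib.align(read, ref, task="distance")["editDistance"])


def match_reads(
    reads: pd.DataFrame, reference: dict[str, str], max_mismatch: int = 2
) -> pd.DataFrame:
    """Assign collapsed reads (columns seq/count/sample) to reference miRNAs.

    Each read goes to the unique reference with the fewest mismatches
    <= max_mismatch; reads tied between references are discarded. Returns
    one row per reference miRNA with count_1N/count_2N/count_3N.
    """
    if not reference:
        raise ValueError("empty miRNA reference")
    ref_items = sorted(reference.items())
    counts = {mid: {s: 0 for s in SAMPLES} for mid, _ in ref_items}
    for row in reads.itertuples(index=False):
        seq = str(row.seq).upper().replace("T", "U")
        best, best_d, tied = None, max_mismatch + 1, False
        for mid, ref in ref_items:
            d = _distance(seq, ref.upper().replace("T", "U"))
            if d < best_d:
                best, best_d, tied = mid, d, False
            elif d == best_d:
                tied = True
        if best is not None and not tied and best_d <= max_mismatch:
            counts[best][str(row.sample)] += int(row.count)
    return pd.DataFrame([
        {"mirna_id": mid, **{f"count_{s}": counts[mid][s] for s in SAMPLES}}
        for mid, _ in ref_items
    ])


def filter_expressed(counts: pd.DataFrame, min_reads: int = 50) -> pd.DataFrame:
    """Keep miRNAs with > min_reads in at least one sample (strict)."""
    cols = [f"count_{s}" for s in SAMPLES]
    keep = (counts[cols] > min_reads).any(axis=1)
    return counts[keep].reset_index(drop=True)


def compare_across_ploidy(
    counts: pd.DataFrame,
    min_fold: float = 1.5,
    pseudocount: float = 0.5,
    totals: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Direction labels for 1N-vs-2N and 3N-vs-2N on normalised counts."""
    norm = {}
    for s in SAMPLES:
        c = counts[f"count_{s}"].to_numpy(dtype=float)
        t = totals[s] if totals else c.sum()
        norm[s] = c * 1e6 / t + pseudocount if t > 0 else c + pseudocount

    def label(num, den):
        up = num / den >= min_fold
        down = den / num >= min_fold
        return np.where(up, "up", np.where(down, "down", "unchanged"))

    return pd.DataFrame({
        "mirna_id": counts["mirna_id"],
        "direction_1n_vs_2n": label(norm["1N"], norm["2N"]),
        "direction_3n_vs_2n": label(norm["3N"], norm["2N"]),
    })


def tally_cleavage(clones: pd.DataFrame, site_length: int = 21) -> pd.DataFrame:
    """Per (miRNA, target, sample): clone counts and frequencies by position.

    ``clones`` columns: mirna_id, target_gene, sample, position (1-based,
    cleavage between position p and p+1, so valid p is 1..site_length-1).
    Adds per-position frequency, a canonical flag (p == 10), and the group's
    canonical fraction.
    """
    cols = ["mirna_id", "target_gene", "sample", "position", "count",
            "frequency", "canonical", "canonical_fraction"]
    if len(clones) == 0:
        return pd.DataFrame(columns=cols)
    bad = clones[(clones["position"] < 1) | (clones["position"] >= site_length)]
    if len(bad):
        r = bad.iloc[0]
        raise ValueError(
            f"clone position {r['position']} out of range for "
            f"{r['mirna_id']}/{r['target_gene']}/{r['sample']}"
        )
    grouped = (
        clones.groupby(["mirna_id", "target_gene", "sample", "position"])
        .size().rename("count").reset_index()
    )
    out_rows = []
    for (mid, tgt, sample), sub in grouped.groupby(
            ["mirna_id", "target_gene", "sample"]):
        total = int(sub["count"].sum())
        canon = int(sub.loc[sub["position"] == CANONICAL_POSITION, "count"].sum())
        for row in sub.itertuples(index=False):
            out_rows.append({
                "mirna_id": mid, "target_gene": tgt, "sample": sample,
                "position": int(row.position), "count": int(row.count),
                "frequency": row.count / total,
                "canonical": int(row.position) == CANONICAL_POSITION,
                "canonical_fraction": canon / total,
            })
    return pd.DataFrame(out_rows, columns=cols)
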