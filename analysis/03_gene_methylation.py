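"""Gene-level methylation calls, feature-class densities and TSS profile.

Applies the methylated-gene rule (>=1 peak overlapping TSS-1.5kb..TES),
summarises the three-sample Venn overlap, the per-feature-class peak
density, and the read density around the TSS. Writes the per-gene
methylation table used by the differential analysis.
"""

import importlib

import pandas as pd

common = importlib.import_module("00_common")

from ploidymeth import gene_methylation as GM
from ploidymeth.genome import SAMPLES


def main() -> None:
    ann = common.load_annotation()
    readsets = common.load_reads()
    peaksets = {s: common.load_tsv(f"../peaks_{s}.tsv") for s in SAMPLES}

    meth_sets = {s: GM.call_methylated_genes(peaksets[s], ann) for s in SAMPLES}
    venn = GM.venn_summary(meth_sets)
    print("methylated genes per sample:", venn.totals)
    print("exclusive:", venn.exclusive, "->", venn.exclusive_pct, "%")
    print("methylated in all three:", venn.shared_all,
          "of union", venn.union_size)

    table = GM.build_methylation_table(ann, readsets, peaksets)
    common.write_out(table, "gene_methylation.tsv", index=True)

    dens = GM.feature_density(peaksets["2N"], ann)
    common.write_out(dens, "feature_density_2N.tsv")
    top = dens.sort_values("density", ascending=False).iloc[0]
    print(f"\nhighest peak density in the {top['feature']} class "
          f"({top['density']:.3f}), matching promoter/downstream "
          "hypermethylation of the planted landscape")

    prof = GM.flank_profile(readsets["2N"], ann, flank=4000, bins=80)
    common.write_out(prof, "tss_profile_2N.tsv")

    def window_mean(lo, hi):
        m = (prof["rel_start"] >= lo) & (prof["rel_end"] <= hi)
        return prof.loc[m, "density"].mean()

    up, body, distal = (window_mean(-1500, 0), window_mean(0, 800),
                        window_mean(-4000, -2500))
    print(f"TSS profile: upstream-1.5kb density {up:.3f} vs gene body "
          f"{body:.3f} vs distal {distal:.3f} — enrichment sits in the "
          "1.5 kb window upstream of the TSS (distal bins also pick up "
          "neighbouring genes' flanks at this toy genome's gene density)")


if __name__ == "__main__":
    main()
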