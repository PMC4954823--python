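"""miRNA abundance across the ploidy series and 5'-RACE cleavage tallies.

Filters miRNAs at > 50 reads, labels cross-ploidy expression directions on
library-normalised counts, and tallies cleavage clone positions per target
(canonical site between positions 10 and 11).
"""

import importlib

common = importlib.import_module("00_common")

from ploidymeth import small_rna as S


def main() -> None:
    counts = common.load_tsv("mirna_counts.tsv")
    totals = common.load_tsv("mirna_totals.tsv").set_index("sample")["total"]
    clones = common.load_tsv("clones.tsv")

    expressed = S.filter_expressed(counts, min_reads=50)
    print(f"{len(expressed)} of {len(counts)} miRNAs exceed 50 reads")
    directions = S.compare_across_ploidy(expressed, min_fold=1.5,
                                         totals=totals.to_dict())
    common.write_out(directions, "mirna_directions.tsv")
    up1 = int((directions["direction_1n_vs_2n"] == "up").sum())
    up3 = int((directions["direction_3n_vs_2n"] == "up").sum())
    dn3 = int((directions["direction_3n_vs_2n"] == "down").sum())
    print(f"up in 1N vs 2N: {up1}; in 3N vs 2N: {up3} up, {dn3} down "
          "(the planted monoploid-elevated pattern)")

    tally = S.tally_cleavage(clones)
    common.write_out(tally, "cleavage_tally.tsv")
    canon = (tally[tally["canonical"]]
             .set_index(["mirna_id", "sample"])["canonical_fraction"])
    for (mid, sample), frac in canon.items():
        print(f"{mid} {sample}: canonical 10-11 cleavage fraction {frac:.2f}")


if __name__ == "__main__":
    main()
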