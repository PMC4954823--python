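"""Expression strata, DE screen, and methylation-expression integration.

Computes inter-sample gene-body concordance, the exact-test DE calls, the
stratified metagene profiles (the upstream-positive / body-negative
coupling pattern), the differential-methylation x differential-expression
cross-tab, and the joint monotone screen.
"""

import importlib

import pandas as pd

common = importlib.import_module("00_common")

from ploidymeth import differential as D
from ploidymeth import expression as E
from ploidymeth import integration as I


def main() -> None:
    ann = common.load_annotation()
    readsets = common.load_reads()
    expr = common.load_tsv("expression.tsv")
    meth_table = common.load_tsv("../gene_methylation.tsv", index_col="gene_id")
    diff_meth = common.load_tsv("../diff_methylation.tsv")

    for a, b in D.PAIRS:
        r = I.sample_correlation(meth_table[f"level_{a}"],
                                 meth_table[f"level_{b}"])
        print(f"gene-body methylation concordance {a} vs {b}: r = {r:.4f}")

    strata = E.stratify(expr.set_index("gene_id")["count_2N"])
    print("expression strata (2N):", strata.value_counts().to_dict())

    de = {p: E.call_de(expr, p) for p in D.PAIRS}
    de_all = pd.concat(de.values(), ignore_index=True)
    common.write_out(de_all, "diff_expression.tsv")
    print("DE calls per pair:",
          {f"{a}_vs_{b}": len(v) for (a, b), v in de.items()})

    profs = I.stratified_metagene(readsets["2N"], ann, strata,
                                  flank=4000, bins=80)
    for label, prof in profs.items():
        common.write_out(prof, f"metagene_TSS_{label}.tsv")

    def mean_density(label, lo, hi):
        p = profs[label]
        m = (p["rel_start"] >= lo) & (p["rel_end"] <= hi)
        return p.loc[m, "density"].mean()

    up_ratio = mean_density("high", -1500, 0) / mean_density("weak", -1500, 0)
    body_ratio = mean_density("high", 0, 800) / mean_density("weak", 0, 800)
    print(f"upstream-of-TSS density, high/weak stratum: {up_ratio:.2f} (>1: "
          "upstream methylation tracks expression positively)")
    print(f"gene-body density, high/weak stratum: {body_ratio:.2f} (<1: "
          "body methylation tracks expression negatively)")

    for pair in D.PAIRS:
        tab = I.meth_expr_crosstab(diff_meth, de_all, pair)
        common.write_out(tab, f"crosstab_{pair[0]}_vs_{pair[1]}.tsv",
                         index=True)
    trend = common.load_tsv("../meth_trend.tsv")
    etrend = I.expression_trend(expr)
    joint = I.monotone_joint_screen(trend, etrend)
    common.write_out(joint, "joint_trend.tsv")
    print("joint monotone methylation/expression classes:",
          joint["class"].value_counts().to_dict())


if __name__ == "__main__":
    main()
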