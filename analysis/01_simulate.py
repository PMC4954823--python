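"""Generate the synthetic 1N/2N/3N ploidy series that drives the analysis.

Three genetically identical samples share one methylation landscape, differ
in sequencing depth 1:2:3, and carry 50 planted 2.5-fold differentially
methylated genes plus coupled expression and small-RNA signals. Writes the
annotation (GFF3), per-sample reads (BED), expression counts, clone records
and the ground-truth tables under results/analysis/data/.
"""

import importlib
import os

common = importlib.import_module("00_common")

from ploidymeth.genome import SAMPLES
from ploidymeth.simulate import (
    SimulationConfig,
    make_genome,
    simulate_dge_counts,
    simulate_medip_reads,
    simulate_methylome,
    simulate_small_rna,
    write_outputs,
)


def main() -> None:
    common.ensure_dirs()
    cfg = SimulationConfig(seed=common.SEED)
    annotation = make_genome(cfg)
    pmap, truth = simulate_methylome(annotation, cfg)
    readsets = {s: simulate_medip_reads(pmap, s, cfg) for s in SAMPLES}
    expr = simulate_dge_counts(annotation, pmap, cfg, truth)
    srna = simulate_small_rna(cfg)
    write_outputs(common.DATA, annotation, readsets, expr, truth, srna.clones,
                  mirna_reference=srna.reference)
    srna.counts.to_csv(os.path.join(common.DATA, "mirna_counts.tsv"),
                       sep="\t", index=False)
    with open(os.path.join(common.DATA, "mirna_totals.tsv"), "w") as fh:
        fh.write("sample\ttotal\n")
        for s in SAMPLES:
            fh.write(f"{s}\t{srna.library_totals[s]}\n")
    print(f"genome: {annotation.genome_length/1e6:.1f} Mb, "
          f"{len(annotation)} genes")
    print("reads:", {s: r.total for s, r in readsets.items()},
          "(~1:2:3 as configured)")
    print(f"planted: {int(truth.genes['methylated'].sum())} methylated genes, "
          f"{int(truth.genes['diff'].sum())} differential, "
          f"{int(truth.genes['expr_diff'].sum())} expression-differential")


if __name__ == "__main__":
    main()
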