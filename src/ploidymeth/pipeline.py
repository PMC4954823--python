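"""End-to-end orchestration: simulate -> callpeaks -> annotate -> diff ->
expr -> integrate -> smallrna -> report, with deterministic outputs.

One YAML/JSON config drives every stage; identical config + seed gives
byte-identical TSV outputs. Logging goes to stderr; results only to files.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import differential, expression, gene_methylation, integration, peaks, small_rna
from .genome import SAMPLES, GenomeAnnotation, ReadSet
from .simulate import SimulationConfig, make_genome, simulate_dge_counts, \
    simulate_medip_reads, simulate_methylome, simulate_small_rna

log = logging.getLogger("ploidymeth")

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """All stage parameters plus paths, resolvable from one YAML file."""

    outdir: str = "ploidymeth_out"
    seed: int = 0
    simulate: bool = True
    reads_bed: dict[str, str] = field(default_factory=dict)  # sample -> path
    annotation_gff3: str | None = None
    expression_tsv: str | None = None
    clones_tsv: str | None = None
    sim: dict = field(default_factory=dict)  # SimulationConfig overrides
    # peak calling
    window: int = 200
    step: int = 50
    alpha: float = 1e-5
    min_length: int = 200
    merge_gap: int = 100
    # gene methylation
    upstream: int = 1500
    flank: int = 4000
    bins: int = 80
    # differential methylation
    diff_threshold: float = 2.0
    trend_threshold: float = 1.5
    pseudocount: float = 0.5
    # expression
    de_alpha: float = 0.05
    de_min_fold: float = 2.0
    # small RNA
    mirna_min_reads: int = 50
    mirna_min_fold: float = 1.5

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.de_alpha < 1:
            raise ValueError("significance thresholds must be in (0,1)")
        if self.diff_threshold < 1 or self.trend_threshold < 1:
            raise ValueError("fold thresholds must be >= 1")
        if not self.simulate:
            missing = [s for s in SAMPLES if s not in self.reads_bed]
            if missing or self.annotation_gff3 is None:
                raise ValueError(
                    "simulation disabled but input paths missing "
                    f"(reads for {missing or 'all samples'}, annotation)"
                )

    def simulation_config(self) -> SimulationConfig:
        params = dict(self.sim)
        if "depth_per_ploidy" in params:
            params["depth_per_ploidy"] = {
                k: int(v) for k, v in params["depth_per_ploidy"].items()}
        if "gene_length_range" in params:
            params["gene_length_range"] = tuple(params["gene_length_range"])
        if "expression_coupling" in params:
            params["expression_coupling"] = tuple(params["expression_coupling"])
        params.setdefault("seed", self.seed)
        return SimulationConfig(**params)


def _write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the report bundle (also written to disk)."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    bundle: dict = {}
    t_all = time.time()

    def stage(name):
        log.info("stage %s ...", name)
        return time.time()

    try:
        t = stage("simulate/load")
        if config.simulate:
            sim = config.simulation_config()
            annotation = make_genome(sim)
            pmap, truth = simulate_methylome(annotation, sim)
            readsets = {
                s: simulate_medip_reads(pmap, s, sim) for s in SAMPLES
            }
            expr_table = simulate_dge_counts(annotation, pmap, sim, truth)
            srna_sim = simulate_small_rna(sim)
            mirna_counts = srna_sim.counts
            mirna_totals = srna_sim.library_totals
            clones = srna_sim.clones
            annotation.to_gff3(os.path.join(config.outdir, "genome.gff3"))
            for s, rs in readsets.items():
                rs.to_bed(os.path.join(config.outdir, f"reads_{s}.bed"))
            _write_tsv(truth.genes, os.path.join(config.outdir, "truth_genes.tsv"))
            _write_tsv(clones, os.path.join(config.outdir, "clones.tsv"))
        else:
            annotation = GenomeAnnotation.from_gff3(config.annotation_gff3)
            readsets = {
                s: ReadSet.from_bed(p, s) for s, p in config.reads_bed.items()
            }
            expr_table = (pd.read_csv(config.expression_tsv, sep="\t")
                          if config.expression_tsv else None)
            clones = (pd.read_csv(config.clones_tsv, sep="\t")
                      if config.clones_tsv else pd.DataFrame(
                          columns=["mirna_id", "target_gene", "sample", "position"]))
            mirna_counts = None
            mirna_totals = None
        log.info("  %.1fs", time.time() - t)

        t = stage("callpeaks")
        genome_len = annotation.genome_length
        peaksets: dict[str, pd.DataFrame] = {}
        for s, rs in readsets.items():
            wc = peaks.compute_window_counts(rs, annotation, config.window, config.step)
            pk = peaks.call_peaks(wc, rs.total, genome_len, alpha=config.alpha,
                                  min_length=config.min_length,
                                  merge_gap=config.merge_gap)
            pk = peaks.annotate_peak_counts(pk, rs)
            peaksets[s] = pk
            peaks.peaks_to_bed(pk, os.path.join(config.outdir, f"peaks_{s}.bed"))
            _write_tsv(pk, os.path.join(config.outdir, f"peaks_{s}.tsv"))
        stats = {
            s: peaks.peak_stats(peaksets[s], genome_len, annotation,
                                upstream=config.upstream)
            for s in peaksets
        }
        bundle["peak_stats"] = {s: asdict(v) for s, v in stats.items()}
        log.info("  %.1fs", time.time() - t)

        t = stage("annotate")
        meth_sets = {
            s: gene_methylation.call_methylated_genes(
                peaksets[s], annotation, upstream=config.upstream)
            for s in peaksets
        }
        venn = gene_methylation.venn_summary(meth_sets)
        bundle["venn"] = {
            "totals": venn.totals, "exclusive": venn.exclusive,
            "pairwise_only": {f"{a}_{b}": v for (a, b), v in venn.pairwise_only.items()},
            "shared_all": venn.shared_all, "exclusive_pct": venn.exclusive_pct,
        }
        table = gene_methylation.build_methylation_table(
            annotation, readsets, peaksets, upstream=config.upstream)
        _write_tsv(table, os.path.join(config.outdir, "gene_methylation.tsv"),
                   index=True)
        fdens = {s: gene_methylation.feature_density(peaksets[s], annotation)
                 for s in peaksets}
        for s, df in fdens.items():
            _write_tsv(df, os.path.join(config.outdir, f"feature_density_{s}.tsv"))
        log.info("  %.1fs", time.time() - t)

        t = stage("diff")
        diff_calls = {
            pair: differential.call_differential(
                table, pair, threshold=config.diff_threshold,
                pseudocount=config.pseudocount)
            for pair in differential.PAIRS
        }
        excl = differential.exclusive_pairwise_summary(diff_calls)
        trend = differential.call_trend(table, threshold=config.trend_threshold,
                                        pseudocount=config.pseudocount)
        _write_tsv(pd.concat(diff_calls.values(), ignore_index=True),
                   os.path.join(config.outdir, "diff_methylation.tsv"))
        _write_tsv(excl, os.path.join(config.outdir, "diff_exclusive.tsv"))
        _write_tsv(trend, os.path.join(config.outdir, "meth_trend.tsv"))
        bundle["diff_exclusive"] = excl.to_dict(orient="records")
        bundle["diff_union"] = int(excl.attrs["union_size"])
        bundle["n_trend"] = {
            d: int((trend["direction"] == d).sum())
            for d in ("increasing", "decreasing")
        }
        log.info("  %.1fs", time.time() - t)

        de_calls = {}
        strata = None
        if expr_table is not None:
            t = stage("expr")
            strata = expression.stratify(
                expr_table.set_index("gene_id")["count_2N"])
            for pair in differential.PAIRS:
                de_calls[pair] = expression.call_de(
                    expr_table, pair, alpha=config.de_alpha,
                    min_fold=config.de_min_fold)
            _write_tsv(pd.concat(de_calls.values(), ignore_index=True),
                       os.path.join(config.outdir, "diff_expression.tsv"))
            bundle["n_de"] = {
                f"{a}_vs_{b}": len(df) for (a, b), df in de_calls.items()}
            log.info("  %.1fs", time.time() - t)

            t = stage("integrate")
            body = {s: table[f"level_{s}"] for s in SAMPLES}
            bundle["sample_correlation"] = {
                f"{a}_vs_{b}": integration.sample_correlation(body[a], body[b])
                for a, b in differential.PAIRS
            }
            profiles = integration.stratified_metagene(
                readsets["2N"], annotation, strata,
                flank=config.flank, bins=config.bins)
            for label, prof in profiles.items():
                _write_tsv(prof, os.path.join(
                    config.outdir, f"metagene_TSS_{label}.tsv"))
            crosstabs = {}
            for pair in differential.PAIRS:
                ct = integration.meth_expr_crosstab(
                    diff_calls[pair], de_calls[pair], pair)
                crosstabs[f"{pair[0]}_vs_{pair[1]}"] = ct
                _write_tsv(ct, os.path.join(
                    config.outdir, f"crosstab_{pair[0]}_vs_{pair[1]}.tsv"),
                    index=True)
            bundle["crosstab"] = {
                k: v.to_dict() for k, v in crosstabs.items()}
            etrend = integration.expression_trend(expr_table)
            joint = integration.monotone_joint_screen(trend, etrend)
            _write_tsv(joint, os.path.join(config.outdir, "joint_trend.tsv"))
            bundle["joint_trend_classes"] = (
                joint["class"].value_counts().to_dict())
            log.info("  %.1fs", time.time() - t)

        t = stage("smallrna")
        if mirna_counts is not None:
            expressed = small_rna.filter_expressed(
                mirna_counts, min_reads=config.mirna_min_reads)
            directions = small_rna.compare_across_ploidy(
                expressed, min_fold=config.mirna_min_fold, totals=mirna_totals)
            _write_tsv(expressed, os.path.join(config.outdir, "mirna_counts.tsv"))
            _write_tsv(directions, os.path.join(config.outdir, "mirna_directions.tsv"))
            bundle["mirna"] = {
                "expressed": len(expressed),
                "up_in_1n": int((directions["direction_1n_vs_2n"] == "up").sum()),
                "up_in_3n": int((directions["direction_3n_vs_2n"] == "up").sum()),
                "down_in_3n": int((directions["direction_3n_vs_2n"] == "down").sum()),
            }
        tally = small_rna.tally_cleavage(clones)
        _write_tsv(tally, os.path.join(config.outdir, "cleavage_tally.tsv"))
        if len(tally):
            bundle["cleavage"] = (
                tally[tally["canonical"]]
                .set_index(["mirna_id", "sample"])["canonical_fraction"]
                .to_dict()
            )
        log.info("  %.1fs", time.time() - t)

        report = write_report(bundle)
        with open(os.path.join(config.outdir, "report.md"), "w") as fh:
            fh.write(report)
        with open(os.path.join(config.outdir, "report.json"), "w") as fh:
            json.dump(_jsonable(bundle), fh, indent=2, sort_keys=True)
    except Exception as exc:  # annotate failures with the stage
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    log.info("pipeline done in %.1fs", time.time() - t_all)
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_report(bundle: dict) -> str:
    """Human-readable markdown summary of every stage's headline numbers."""
    lines = ["# Ploidy-series methylome pipeline report", ""]
    if "peak_stats" in bundle:
        lines += ["## Methylation peaks", "",
                  "| sample | peaks | mean length | total length | coverage % | genes |",
                  "|---|---|---|---|---|---|"]
        for s, st in bundle["peak_stats"].items():
            lines.append(
                f"| {s} | {st['n_peaks']} | {st['mean_length']:.1f} | "
                f"{st['total_length']} | {st['coverage_pct']:.2f} | "
                f"{st['genes_involved']} |")
        lines.append("")
    if "venn" in bundle:
        v = bundle["venn"]
        lines += ["## Methylated genes (Venn)", ""]
        for s in SAMPLES:
            lines.append(
                f"- {s}: total {v['totals'][s]}, exclusive {v['exclusive'][s]} "
                f"({v['exclusive_pct'][s]}%)")
        lines.append(f"- shared by all three: {v['shared_all']}")
        lines.append("")
    if "diff_exclusive" in bundle:
        lines += ["## Differential methylation (>= 2-fold)", "",
                  f"- union of called genes: {bundle['diff_union']}"]
        for rec in bundle["diff_exclusive"]:
            lines.append(
                f"- {rec['pair']}: {rec['called']} called, {rec['exclusive']} "
                f"exclusive ({rec['exclusive_pct_of_union']}% of union)")
        nt = bundle.get("n_trend", {})
        lines.append(
            f"- monotone 1.5-fold trend: {nt.get('increasing', 0)} increasing, "
            f"{nt.get('decreasing', 0)} decreasing")
        lines.append("")
    if "n_de" in bundle:
        lines += ["## Differential expression", ""]
        for pair, n in bundle["n_de"].items():
            lines.append(f"- {pair}: {n} genes")
        lines.append("")
    if "sample_correlation" in bundle:
        lines += ["## Gene-body methylation concordance", ""]
        for pair, r in bundle["sample_correlation"].items():
            lines.append(f"- Pearson r {pair}: {r:.4f}")
        lines.append("")
    if "crosstab" in bundle:
        lines += ["## Differential methylation x expression", ""]
        for pair, tab in bundle["crosstab"].items():
            lines.append(f"- {pair}: " + ", ".join(
                f"meth-{m}/expr-{e}={tab[e][m]}"
                for e in ("up", "down") for m in ("high", "low")))
        lines.append("")
    if "mirna" in bundle:
        m = bundle["mirna"]
        lines += ["## miRNAs", "",
                  f"- expressed (>50 reads): {m['expressed']}",
                  f"- up in 1N vs 2N: {m['up_in_1n']}",
                  f"- up in 3N vs 2N: {m['up_in_3n']}; down: {m['down_in_3n']}", ""]
    if "cleavage" in bundle:
        lines += ["## 5'-RACE cleavage (canonical 10-11 site)", ""]
        for (mid, sample), frac in sorted(bundle["cleavage"].items()):
            lines.append(f"- {mid} {sample}: canonical fraction {frac:.2f}")
        lines.append("")
    return "\n".join(lines) + "\n"
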