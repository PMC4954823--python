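"""The synthetic ploidy series: determinism, conservation, planted signal."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ploidymeth.genome import SAMPLES
from ploidymeth.simulate import (
    SimulationConfig,
    make_genome,
    simulate_dge_counts,
    simulate_medip_reads,
    simulate_methylome,
    simulate_small_rna,
)


class TestMakeGenome:
    def test_gene_count_conserved(self):
        cfg = SimulationConfig(seed=7, n_genes=50)
        assert len(make_genome(cfg)) == 50

    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=7, n_genes=50)
        paths = []
        for i in range(2):
            p = tmp_path / f"g{i}.gff3"
            make_genome(cfg).to_gff3(str(p))
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_degenerate_length_range(self):
        cfg = SimulationConfig(seed=1, n_genes=30,
                               gene_length_range=(1000, 1000))
        ann = make_genome(cfg)
        assert all(g.length == 1000 for g in ann.genes)

    def test_genes_do_not_overlap_and_fit(self):
        ann = make_genome(SimulationConfig(seed=3, n_genes=200))
        for chrom in ann.chrom_lengths:
            genes = ann.genes_by_chrom(chrom)
            for a, b in zip(genes, genes[1:]):
                assert a.end <= b.start
            assert genes[-1].end <= ann.chrom_lengths[chrom]

    def test_oversized_request_raises(self):
        with pytest.raises(ValueError, match="fit"):
            make_genome(SimulationConfig(
                seed=1, n_chromosomes=1, chromosome_length=10_000, n_genes=50))


class TestSimulateMethylome:
    def test_zero_fraction_gives_flat_landscape(self):
        cfg = SimulationConfig(seed=2, n_genes=30, fraction_methylated=0.0,
                               n_diff_genes=0)
        ann = make_genome(cfg)
        pmap, truth = simulate_methylome(ann, cfg)
        for sample in SAMPLES:
            for arr in pmap.sample(sample).values():
                assert np.all(arr == 1.0)
        assert not truth.genes["methylated"].any()

    def test_planted_diff_count(self):
        cfg = SimulationConfig(seed=2, n_genes=40, n_diff_genes=5,
                               diff_fold=2.5)
        ann = make_genome(cfg)
        _, truth = simulate_methylome(ann, cfg)
        assert int(truth.genes["diff"].sum()) == 5
        assert set(truth.genes.loc[truth.genes["diff"], "diff_direction"]) <= {
            "increasing", "decreasing"}

    def test_upstream_propensity_elevated_for_methylated_plus_gene(self):
        cfg = SimulationConfig(seed=5, n_genes=40, fraction_methylated=1.0,
                               n_diff_genes=0)
        ann = make_genome(cfg)
        pmap, truth = simulate_methylome(ann, cfg)
        arrs = pmap.sample("1N")
        gene = next(g for g in ann.genes if g.strand == "+")
        arr = arrs[gene.chrom]
        upstream_mean = arr[gene.start - 1500:gene.start].mean()
        background = 1.0
        assert upstream_mean > background

    def test_too_many_diff_genes_raises(self):
        cfg = SimulationConfig(seed=1, n_genes=10, n_diff_genes=11)
        ann = make_genome(SimulationConfig(seed=1, n_genes=10, n_diff_genes=0))
        with pytest.raises(ValueError):
            simulate_methylome(ann, cfg)

    def test_truth_covers_every_gene_once(self):
        cfg = SimulationConfig(seed=4, n_genes=25, n_diff_genes=3)
        ann = make_genome(cfg)
        _, truth = simulate_methylome(ann, cfg)
        assert sorted(truth.genes["gene_id"]) == sorted(ann.gene_ids())


class TestSimulateReads:
    def test_zero_depth_empty(self):
        cfg = SimulationConfig(
            seed=1, n_genes=20, n_diff_genes=2,
            depth_per_ploidy={"1N": 0, "2N": 1000, "3N": 1000})
        ann = make_genome(cfg)
        pmap, _ = simulate_methylome(ann, cfg)
        rs = simulate_medip_reads(pmap, "1N", cfg)
        assert rs.total == 0

    def test_depth_ratio_within_poisson_error(self):
        cfg = SimulationConfig(
            seed=9, n_genes=100,
            depth_per_ploidy={"1N": 100_000, "2N": 200_000, "3N": 300_000})
        ann = make_genome(cfg)
        pmap, _ = simulate_methylome(ann, cfg)
        for sample, depth in cfg.depth_per_ploidy.items():
            n = simulate_medip_reads(pmap, sample, cfg).total
            assert abs(n - depth) <= 3 * np.sqrt(depth)

    def test_reads_within_chromosome_bounds(self, small_config):
        ann = make_genome(small_config)
        pmap, _ = simulate_methylome(ann, small_config)
        rs = simulate_medip_reads(pmap, "2N", small_config)
        for chrom, s in rs.starts.items():
            e = rs.ends[chrom]
            assert np.all(s >= 0)
            assert np.all(s < e)
            assert np.all(e <= ann.chrom_lengths[chrom])

    def test_seed_determinism(self, small_config):
        ann = make_genome(small_config)
        pmap, _ = simulate_methylome(ann, small_config)
        a = simulate_medip_reads(pmap, "3N", small_config)
        b = simulate_medip_reads(pmap, "3N", small_config)
        for chrom in a.starts:
            np.testing.assert_array_equal(a.starts[chrom], b.starts[chrom])


class TestSimulateDge:
    def _sim(self, coupling, seed=13, n=600):
        cfg = SimulationConfig(
            seed=seed, n_chromosomes=2, chromosome_length=1_600_000,
            n_genes=n, n_diff_genes=0, n_expression_diff=0,
            expression_coupling=coupling)
        ann = make_genome(cfg)
        pmap, truth = simulate_methylome(ann, cfg)
        counts = simulate_dge_counts(ann, pmap, cfg, truth)
        upstream = truth.genes.set_index("gene_id")["upstream_multiplier"]
        return counts.set_index("gene_id"), upstream

    def test_zero_coupling_no_correlation(self):
        counts, upstream = self._sim((0.0, 0.0))
        r = stats.spearmanr(upstream, counts.loc[upstream.index, "count_2N"]).statistic
        assert abs(r) < 4 / np.sqrt(len(upstream))

    def test_positive_upstream_coupling_positive_correlation(self):
        counts, upstream = self._sim((0.8, 0.0))
        r = stats.spearmanr(upstream, counts.loc[upstream.index, "count_2N"]).statistic
        assert r > 0.2

    def test_seed_determinism(self, small_config):
        ann = make_genome(small_config)
        pmap, truth = simulate_methylome(ann, small_config)
        a = simulate_dge_counts(ann, pmap, small_config, truth)
        b = simulate_dge_counts(ann, pmap, small_config, truth)
        pd.testing.assert_frame_equal(a, b)

    def test_counts_non_negative_integers(self, small_config):
        ann = make_genome(small_config)
        pmap, truth = simulate_methylome(ann, small_config)
        counts = simulate_dge_counts(ann, pmap, small_config, truth)
        for s in SAMPLES:
            assert (counts[f"count_{s}"] >= 0).all()


class TestSimulateSmallRna:
    def test_no_clones_configured(self):
        cfg = SimulationConfig(seed=1, clone_plan={})
        assert len(simulate_small_rna(cfg).clones) == 0

    def test_canonical_only_plan_all_at_site_10(self):
        cfg = SimulationConfig(
            seed=1, clone_plan={"m": {"1N": (11, 0), "2N": (8, 0), "3N": (4, 1)}})
        clones = simulate_small_rna(cfg).clones
        mono = clones[clones["sample"] == "1N"]
        assert len(mono) == 11
        assert (mono["position"] == 10).all()

    def test_planted_directions_match_counts(self):
        cfg = SimulationConfig(seed=21)
        sim = simulate_small_rna(cfg)
        ann_cfg = SimulationConfig(seed=21, n_genes=20, n_diff_genes=2)
        _, truth = simulate_methylome(make_genome(ann_cfg), ann_cfg)
        merged = sim.counts.merge(truth.mirnas, on="mirna_id")
        t = sim.library_totals
        for _, row in merged.iterrows():
            n1 = row["count_1N"] / t["1N"]
            n2 = row["count_2N"] / t["2N"]
            if row["direction_1n_vs_2n"] == "up":
                assert n1 > n2
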