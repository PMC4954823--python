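"""The methylated-gene rule, per-gene levels, feature classes, flanking
profiles and the three-sample Venn decomposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_readset
from ploidymeth.genome import GeneModel, GenomeAnnotation
from ploidymeth.gene_methylation import (
    FEATURE_CLASSES,
    call_methylated_genes,
    feature_class_arrays,
    feature_density,
    flank_profile,
    gene_level,
    gene_levels,
    methylation_region,
    venn_summary,
)


def peaks_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count", "pvalue"])


class TestMethylationRegion:
    def test_plus_strand(self):
        g = GeneModel("g", "chr1", "+", 5000, 8000)
        assert methylation_region(g) == (3500, 8000)

    def test_minus_strand_orientation_flip(self):
        # TSS at 8000, TES at 5000 on the - strand: 1.5 kb upstream of the
        # TSS extends to higher coordinates -> [5000, 9500)
        g = GeneModel("g", "chr1", "-", 5000, 8000)
        assert methylation_region(g, chrom_length=20_000) == (5000, 9500)

    def test_clipped_at_chromosome_start(self):
        g = GeneModel("g", "chr1", "+", 1000, 2000)
        assert methylation_region(g, upstream=1500) == (0, 2000)


class TestCallMethylatedGenes:
    def test_peak_outside_window_not_called(self, tiny_annotation):
        # gA: + strand, TSS 5000; peak in [3000, 3400) is beyond -1.5 kb
        pk = peaks_df([("chr1", 3000, 3400, 5, 1e-9)])
        assert call_methylated_genes(pk, tiny_annotation) == set()

    def test_single_bp_overlap_calls(self, tiny_annotation):
        pk = peaks_df([("chr1", 3200, 3501, 5, 1e-9)])  # 1 bp into [3500, 8000)
        assert call_methylated_genes(pk, tiny_annotation) == {"gA"}

    def test_peak_spanning_two_regions_calls_both(self, tiny_annotation):
        # brute-force oracle: region gA = [3500, 8000), gB = [12000, 16500)
        pk = peaks_df([("chr1", 7000, 13000, 50, 1e-20)])
        called = call_methylated_genes(pk, tiny_annotation)
        from _oracles import overlap_1bp
        expected = set()
        for g in tiny_annotation.genes:
            region = methylation_region(g, chrom_length=20_000)
            if overlap_1bp(region, (7000, 13000)):
                expected.add(g.gene_id)
        assert called == expected == {"gA", "gB"}


class TestGeneLevel:
    def test_no_reads_zero(self, tiny_annotation):
        rs = make_readset("1N", "chr1", [])
        assert gene_level(rs, tiny_annotation.genes[0], 1_000_000) == 0.0

    def test_rpm_definition(self, tiny_annotation):
        rs = make_readset("1N", "chr1", np.arange(5000, 6000, 10))  # 100 reads
        assert gene_level(rs, tiny_annotation.genes[0], 1_000_000) == 100.0

    def test_scale_invariance(self, tiny_annotation):
        starts = np.arange(5000, 6000, 10)
        rs1 = make_readset("1N", "chr1", starts)
        rs2 = make_readset("1N", "chr1", np.concatenate([starts, starts]))
        l1 = gene_levels(rs1, tiny_annotation, library_total=1000)
        l2 = gene_levels(rs2, tiny_annotation, library_total=2000)
        pd.testing.assert_series_equal(l1, l2, check_names=False)

    def test_bad_library_total(self, tiny_annotation):
        rs = make_readset("1N", "chr1", [5100])
        with pytest.raises(ValueError):
            gene_level(rs, tiny_annotation.genes[0], 0)


class TestFeatureDensity:
    def test_classes_partition_genome(self, tiny_annotation):
        arrays = feature_class_arrays(tiny_annotation)
        total = sum(arr.size for arr in arrays.values())
        counts = np.zeros(len(FEATURE_CLASSES), dtype=np.int64)
        for arr in arrays.values():
            counts += np.bincount(arr, minlength=len(FEATURE_CLASSES))
        assert counts.sum() == total == tiny_annotation.genome_length

    def test_empty_peaks_zero_density(self, tiny_annotation):
        dens = feature_density(peaks_df([]), tiny_annotation)
        assert (dens["density"] == 0).all()

    def test_peak_inside_intron(self):
        g = GeneModel("g", "chr1", "+", 1000, 12_000,
                      exons=((1000, 1500), (11_500, 12_000)))
        ann = GenomeAnnotation({"chr1": 20_000}, [g])
        dens = feature_density(peaks_df([("chr1", 2000, 2100, 3, 1e-8)]), ann)
        intron = dens.set_index("feature").loc["intron"]
        assert intron["class_length"] == 10_000
        assert intron["overlap_length"] == 100
        assert intron["density"] == pytest.approx(0.01)

    def test_boundary_peak_split_sums_to_length(self):
        g = GeneModel("g", "chr1", "+", 2000, 3000, exons=((2000, 3000),))
        ann = GenomeAnnotation({"chr1": 10_000}, [g])
        dens = feature_density(peaks_df([("chr1", 1950, 2050, 4, 1e-8)]), ann)
        by = dens.set_index("feature")["overlap_length"]
        assert by["promoter"] == 50 and by["exon"] == 50
        assert by.sum() == 100


class TestFlankProfile:
    def test_no_reads_flat_zero(self, tiny_annotation):
        prof = flank_profile(make_readset("s", "chr1", []), tiny_annotation)
        assert (prof["density"] == 0).all()

    def test_single_read_bin_arithmetic(self):
        g = GeneModel("g", "chr1", "+", 10_000, 12_000)
        ann = GenomeAnnotation({"chr1": 30_000}, [g])
        prof = flank_profile(make_readset("s", "chr1", [10_100]), ann,
                             flank=4000, bins=80)
        nonzero = prof[prof["density"] > 0]
        assert len(nonzero) == 1
        assert nonzero.iloc[0]["rel_start"] == 100

    def test_minus_strand_read_reflected_upstream(self):
        # - strand gene: a read 100 bp downstream in genomic coordinates
        # (past the TSS edge) sits 100 bp upstream in gene orientation
        g = GeneModel("g", "chr1", "-", 10_000, 12_000)
        ann = GenomeAnnotation({"chr1": 30_000}, [g])
        prof = flank_profile(make_readset("s", "chr1", [12_100]), ann,
                             flank=4000, bins=80)
        nonzero = prof[prof["density"] > 0]
        assert len(nonzero) == 1
        assert nonzero.iloc[0]["rel_start"] == -100

    def test_profile_maximal_upstream_of_tss_on_sparse_landscape(self):
        # genes far enough apart that neighbouring flanks stay outside the
        # +/-4 kb window: the profile maximum falls in the 1.5 kb upstream bin
        from ploidymeth.simulate import (
            SimulationConfig, make_genome, simulate_medip_reads,
            simulate_methylome)
        cfg = SimulationConfig(seed=12, n_genes=200, n_diff_genes=0,
                               fraction_methylated=1.0)
        ann = make_genome(cfg)
        pmap, _ = simulate_methylome(ann, cfg)
        reads = simulate_medip_reads(pmap, "2N", cfg)
        prof = flank_profile(reads, ann, flank=4000, bins=80)
        best = prof.loc[prof["density"].idxmax()]
        assert -1500 <= best["rel_start"] < 0

    def test_bins_must_divide_span(self, tiny_annotation):
        with pytest.raises(ValueError):
            flank_profile(make_readset("s", "chr1", []), tiny_annotation,
                          flank=4000, bins=81)


class TestVennSummary:
    def test_diploid_exclusive_share_arithmetic(self):
        # 702 exclusive of a 25,103-gene sample -> 2.8%
        sets = {
            "1N": {f"a{i}" for i in range(100)},
            "2N": {f"b{i}" for i in range(100)},
            "3N": {f"c{i}" for i in range(100)},
        }
        v = venn_summary(sets)
        assert v.exclusive_pct["1N"] == 100.0
        from ploidymeth._utils import pct
        assert pct(702, 25_103) == 2.8
        assert pct(1167, 25_285) == 4.6

    def test_identical_sets(self):
        s = {"g1", "g2", "g3"}
        v = venn_summary({"1N": set(s), "2N": set(s), "3N": set(s)})
        assert v.shared_all == 3
        assert all(e == 0 for e in v.exclusive.values())

    def test_exhaustive_small_example(self):
        v = venn_summary({
            "1N": {"g1", "g2", "g3"},
            "2N": {"g2", "g3", "g4"},
            "3N": {"g3", "g4", "g5"},
        })
        assert v.shared_all == 1
        assert v.exclusive == {"1N": 1, "2N": 0, "3N": 1}
        assert v.pairwise_only == {
            ("1N", "2N"): 1, ("1N", "3N"): 0, ("2N", "3N"): 1}

    @given(st.lists(st.sets(st.integers(0, 30)), min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_regions_partition_union(self, raw):
        sets = {s: {str(x) for x in vals}
                for s, vals in zip(("1N", "2N", "3N"), raw)}
        v = venn_summary(sets)
        union = set().union(*sets.values())
        assert v.union_size == len(union)
        for s in sets:
            others = [("1N", "2N"), ("1N", "3N"), ("2N", "3N")]
            pair_sum = sum(v.pairwise_only[p] for p in others if s in p)
            assert v.totals[s] == v.exclusive[s] + pair_sum + v.shared_all
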