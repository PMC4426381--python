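"""Window grids, relative densities, gene-rich and gap windows."""

import numpy as np
import pytest

from tomindel.density_scan import (
    build_window_stats,
    chromosome_relative_density,
    gap_windows,
    gene_rich_windows,
    window_counts,
)
from tomindel.gene_models import GeneModel
from tomindel.variant_io import VariantRecord

MB = 1_000_000


def snp(chrom, pos0):
    return VariantRecord(chrom=chrom, pos0=pos0, ref="A", alt="T", genotype="hom_alt")


def indel(chrom, pos0):
    return VariantRecord(chrom=chrom, pos0=pos0, ref="A", alt="AT", genotype="hom_alt")


def gene(chrom, start, gid="g"):
    return GeneModel(
        gene_id=f"{gid}_{start}", chrom=chrom, strand="+",
        exons=((start, start + 300),), cds=((start, start + 300),),
    )


class TestWindowCounts:
    def test_half_open_boundary_assignment(self):
        variants = [snp("chr1", p) for p in (1, 999_999, 1_000_000, 1_500_000, 2_000_001)]
        stats = window_counts(variants, {"chr1": 3 * MB}, window_size=MB)
        assert [s.snp_count for s in stats] == [2, 2, 1]

    def test_empty_stream_all_zero(self):
        stats = window_counts([], {"chr1": 3 * MB}, window_size=MB)
        assert all(s.snp_count == 0 and s.indel_count == 0 for s in stats)

    def test_unknown_chromosome_is_error(self):
        with pytest.raises(ValueError, match="chrUn"):
            window_counts([snp("chrUn", 5)], {"chr1": MB})

    def test_het_exclusion_option(self):
        variants = [snp("chr1", 10), snp("chr1", 20)]
        het = VariantRecord(chrom="chr1", pos0=30, ref="A", alt="T", genotype="het")
        full = window_counts(variants + [het], {"chr1": MB}, include_het=True)
        no_het = window_counts(variants + [het], {"chr1": MB}, include_het=False)
        assert full[0].snp_count == 3 and no_het[0].snp_count == 2

    def test_conservation_and_refinement(self):
        rng = np.random.default_rng(7)
        variants = sorted(
            [snp("chr1", int(p)) for p in rng.integers(0, 3 * MB, 500)]
            + [indel("chr1", int(p)) for p in rng.integers(0, 3 * MB, 200)],
            key=lambda r: r.pos0,
        )
        for w in (MB, MB // 2):
            stats = window_counts(variants, {"chr1": 3 * MB}, window_size=w)
            assert sum(s.snp_count for s in stats) == 500
            assert sum(s.indel_count for s in stats) == 200
        coarse = window_counts(variants, {"chr1": 3 * MB}, window_size=MB)
        fine = window_counts(variants, {"chr1": 3 * MB}, window_size=MB // 2)
        for i, c in enumerate(coarse):
            halves = [f for f in fine if c.start <= f.start < c.end]
            assert c.snp_count == sum(f.snp_count for f in halves)


class TestRelativeDensity:
    def test_two_chromosomes(self):
        variants = [snp("chr1", i * 10) for i in range(100)] + [
            snp("chr2", i * 10) for i in range(50)
        ]
        out = chromosome_relative_density(variants, {"chr1": MB, "chr2": MB})
        by = {d.chrom: d for d in out}
        assert by["chr1"].relative_snp == 1.0
        assert by["chr2"].relative_snp == pytest.approx(0.5)

    def test_single_chromosome_is_unity(self):
        out = chromosome_relative_density([snp("chr1", 5)], {"chr1": MB})
        assert out[0].relative_snp == 1.0

    def test_zero_length_chromosome_error(self):
        with pytest.raises(ValueError):
            chromosome_relative_density([snp("chr1", 5)], {"chr1": 0})

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            chromosome_relative_density([], {"chr1": MB})

    def test_planted_three_two_one_ratio(self):
        rng = np.random.default_rng(11)
        variants = []
        for chrom, n in (("chr1", 3000), ("chr2", 2000), ("chr3", 1000)):
            variants += [snp(chrom, int(p)) for p in rng.integers(0, MB, n)]
        out = chromosome_relative_density(
            variants, {"chr1": MB, "chr2": MB, "chr3": MB}
        )
        by = {d.chrom: d for d in out}
        assert by["chr1"].relative_snp == 1.0
        assert by["chr2"].relative_snp == pytest.approx(2 / 3, abs=0.01)
        assert by["chr3"].relative_snp == pytest.approx(1 / 3, abs=0.01)


class TestGeneRichAndGaps:
    def test_strictly_more_than_threshold(self):
        half = 500_000
        rich = [gene("chr1", 1000 + i * 50, "a") for i in range(51)]
        edge = [gene("chr1", half + 1000 + i * 50, "b") for i in range(50)]
        out = gene_rich_windows(rich + edge, window_size=half, min_genes=50)
        assert ("chr1", 0) in out
        assert ("chr1", half) not in out

    def test_gap_fractions(self):
        genome = {"chr1": "N" * MB + "A" * MB}
        out = gap_windows(genome, {"chr1": 2 * MB}, window_size=MB)
        assert out[0][3] == 1.0 and out[0][4] is True
        assert out[1][3] == 0.0 and out[1][4] is False

    def test_partial_gap_run_arithmetic(self):
        # a 1.6-Mb N run overlapping three windows: 0.3 / 1.0 / 0.3
        seq = ["A"] * (5 * MB)
        seq[1_700_000:3_300_000] = ["N"] * 1_600_000
        genome = {"chr1": "".join(seq)}
        out = gap_windows(genome, {"chr1": 5 * MB}, window_size=MB)
        fracs = [round(o[3], 3) for o in out]
        assert fracs == [0.0, 0.3, 1.0, 0.3, 0.0]

    def test_build_window_stats_reports_max_half_window_gene_count(self):
        genes = [gene("chr1", i * 100, "x") for i in range(60)]  # all in first half-Mb
        stats = build_window_stats([], {"chr1": MB}, genes=genes, window_size=MB)
        assert stats[0].gene_count == 60


def test_indel_density_follows_gene_density(dataset):
    """The planted euchromatic InDel enrichment shows up as a positive
    correlation between per-window InDel and gene counts."""
    stats = build_window_stats(
        dataset.variants[dataset.config.line_b],
        dataset.chrom_lengths,
        genome=dataset.genome,
        genes=dataset.genes,
        window_size=500_000,
    )
    keep = [
        s for s in stats
        if not s.is_gap()
        and not any(
            seg["chrom"] == s.chrom and seg["start"] < s.end and seg["end"] > s.start
            for seg in dataset.manifest["segments"]
        )
    ]
    indels = np.array([s.indel_count for s in keep], dtype=float)
    genes_ = np.array([s.gene_count for s in keep], dtype=float)
    r = np.corrcoef(indels, genes_)[0, 1]
    assert r > 0.5
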