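"""Variant reading, classification, hard filtering and normalisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tomindel.variant_io import (
    FilterThresholds,
    VariantRecord,
    apply_edit,
    apply_hard_filters,
    classify_alleles,
    is_homozygous_alt,
    normalize_indel,
    read_variants,
    write_filtered_vcf,
)
from tomindel.synthetic_data import write_vcf


def rec(chrom="chr1", pos0=10, ref="A", alt="T", genotype="hom_alt", ann=None):
    return VariantRecord(
        chrom=chrom, pos0=pos0, ref=ref, alt=alt, genotype=genotype,
        site_annotations=ann or {},
    )


@pytest.mark.parametrize(
    "ref,alt,expected",
    [
        ("A", "T", "snp"),
        ("A", "AT", "insertion"),
        ("AT", "A", "deletion"),
        ("AT", "ATT", "insertion"),
        ("ATT", "AT", "deletion"),
        ("AT", "GC", "mnp_other"),
        ("CAA", "CA", "deletion"),
        ("A", "A", "mnp_other"),
        ("ACGT", "AGGT", "mnp_other"),
    ],
)
def test_allele_classification(ref, alt, expected):
    assert classify_alleles(ref, alt) == expected


class TestReadVariants:
    def _write(self, tmp_path, body):
        path = tmp_path / "toy.vcf"
        header = (
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=100000>\n"
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        )
        path.write_text(header + body)
        return str(path)

    def test_biallelic_hom_alt_snp(self, tmp_path):
        path = self._write(tmp_path, "chr1\t100\t.\tA\tT\t50\t.\tDP=30\tGT\t1/1\n")
        (r,) = list(read_variants(path))
        assert (r.chrom, r.pos, r.ref, r.alt) == ("chr1", 100, "A", "T")
        assert r.var_class == "snp" and r.genotype == "hom_alt"
        assert r.site_annotations["DP"] == 30

    def test_multiallelic_split(self, tmp_path):
        path = self._write(tmp_path, "chr1\t200\t.\tAT\tA,ATT\t50\t.\t.\tGT\t1/2\n")
        records = list(read_variants(path))
        assert [r.var_class for r in records] == ["deletion", "insertion"]
        assert all(r.genotype == "het" for r in records)
        # splitting conserves the alt-allele count
        assert len(records) == 2

    def test_missing_sample_names_available(self, tmp_path):
        path = self._write(tmp_path, "chr1\t100\t.\tA\tT\t50\t.\t.\tGT\t1/1\n")
        with pytest.raises(ValueError, match="S1"):
            list(read_variants(path, sample="nope"))

    def test_round_trip_against_writer(self, tmp_path):
        rng = np.random.default_rng(5)
        planted = []
        for i in range(10):
            p = 100 + 50 * i
            planted.append(rec(pos0=p, ref="ACGT"[rng.integers(0, 4)], alt="AACGT"[rng.integers(0, 5)] * 2))
        path = tmp_path / "w.vcf"
        write_vcf(str(path), planted, {"chr1": 100000}, sample="S1")
        back = list(read_variants(str(path)))
        assert [(r.chrom, r.pos, r.ref, r.alt) for r in back] == [
            (r.chrom, r.pos, r.ref, r.alt) for r in planted
        ]


class TestHardFilters:
    def test_depth_above_limit_fails(self):
        ok, failed = apply_hard_filters(rec(ann={"DP": 101.0}))
        assert not ok and failed == ["max_depth"]

    def test_qd_and_fs_fail_together(self):
        ok, failed = apply_hard_filters(rec(ann={"QD": 1.9, "FS": 61.0}))
        assert not ok and failed == ["min_qd", "max_fisher_strand"]

    def test_absent_annotations_pass(self):
        ok, failed = apply_hard_filters(rec(ann={}))
        assert ok and failed == []

    @given(
        dp=st.floats(1, 200),
        qd=st.floats(0, 40),
        fs=st.floats(0, 120),
        mq=st.floats(0, 70),
        slack=st.floats(0.1, 50),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_relaxing_thresholds_is_monotone(self, dp, qd, fs, mq, slack):
        """Relaxing any threshold never turns a pass into a fail."""
        r = rec(ann={"DP": dp, "QD": qd, "FS": fs, "MQ": mq})
        tight = FilterThresholds()
        loose = FilterThresholds(
            max_depth=int(tight.max_depth + slack),
            min_qd=tight.min_qd - slack,
            max_fisher_strand=tight.max_fisher_strand + slack,
            min_mq=tight.min_mq - slack,
            min_read_pos_rank_sum=tight.min_read_pos_rank_sum - slack,
            min_mq_rank_sum=tight.min_mq_rank_sum - slack,
        )
        if apply_hard_filters(r, tight)[0]:
            assert apply_hard_filters(r, loose)[0]

    def test_filter_column_written(self, tmp_path):
        records = [
            rec(pos0=9, ann={"DP": 101.0}),
            rec(pos0=19, ann={"DP": 50.0}),
        ]
        vin = tmp_path / "in.vcf"
        write_vcf(str(vin), records, {"chr1": 1000}, sample="S1")
        vout = tmp_path / "out.vcf"
        counts = write_filtered_vcf(str(vin), str(vout))
        assert counts == {"pass": 1, "fail": 1}
        text = vout.read_text()
        assert "max_depth" in text


class TestGenotypes:
    def test_hom_alt(self):
        assert is_homozygous_alt(rec(genotype="hom_alt"))

    def test_het_is_artifact_candidate(self):
        assert not is_homozygous_alt(rec(genotype="het"))

    def test_missing_warns(self, caplog):
        with caplog.at_level("WARNING"):
            assert not is_homozygous_alt(rec(genotype="missing"))
        assert "missing genotype" in caplog.text


class TestNormalize:
    GENOME = {"chr1": "GGGCAAATTTCGATCGGGCT" * 5}

    def test_homopolymer_deletion_left_aligns(self):
        # deleting the third A of the CAAAT run is the same edit as
        # deleting the first
        g = {"chr1": "GGGCAAATTT"}
        r = rec(pos0=5, ref="AA", alt="A")
        n = normalize_indel(r, g)
        assert (n.pos0, n.ref, n.alt) == (3, "CA", "C")
        assert apply_edit(g["chr1"], r) == apply_edit(g["chr1"], n)

    def test_idempotent(self):
        g = {"chr1": "GGGCAAATTT"}
        n = normalize_indel(rec(pos0=5, ref="AA", alt="A"), g)
        assert normalize_indel(n, g) == n

    def test_ref_mismatch_is_corrupt_input(self):
        with pytest.raises(ValueError, match="REF mismatch"):
            normalize_indel(rec(pos0=0, ref="TT", alt="T"), self.GENOME)

    def test_snp_passthrough(self):
        r = rec(pos0=0, ref="G", alt="A")
        assert normalize_indel(r, self.GENOME) is r

    @given(data=st.data())
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_sequence_equivalence_random_indels(self, data):
        """apply(raw) == apply(normalized) and normalisation is
        idempotent for random indels on random sequences."""
        rng_seq = data.draw(st.text(alphabet="ACGT", min_size=20, max_size=60))
        genome = {"chr1": rng_seq}
        p = data.draw(st.integers(1, len(rng_seq) - 6))
        if data.draw(st.booleans()):  # deletion
            k = data.draw(st.integers(1, min(4, len(rng_seq) - p - 1)))
            ref, alt = rng_seq[p : p + k + 1], rng_seq[p]
        else:  # insertion
            ins = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=4))
            ref, alt = rng_seq[p], rng_seq[p] + ins
        r = rec(pos0=p, ref=ref, alt=alt)
        if not r.is_indel:
            return
        n = normalize_indel(r, genome)
        assert apply_edit(rng_seq, r) == apply_edit(rng_seq, n)
        assert normalize_indel(n, genome) == n
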