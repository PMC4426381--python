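"""Edit-and-translate auditing of frameshift candidates.

The oracle used here is coded separately from the library path: it
materialises the whole edited chromosome, shifts every coordinate with
its own arithmetic and translates with its own codon loop.
"""

import pytest

from tomindel.expression import ExpressionTrack, expression_filter
from tomindel.fs_audit import (
    CascadeConfig,
    classify_protein_impact,
    detect_pseudo_fs,
    fs_candidates,
    mutant_protein,
    run_cascade,
)
from tomindel.gene_models import GeneModel
from tomindel.variant_io import VariantRecord

# -- independent oracle ------------------------------------------------

_CODONS = {}
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_a, _b, _c) in enumerate(
    (a, b, c) for a in _BASES for b in _BASES for c in _BASES
):
    _CODONS[_a + _b + _c] = _AA[_i]

_COMP = str.maketrans("ACGTN", "TGCAN")


def oracle_translate(seq):
    prot = []
    for i in range(0, len(seq) - 2, 3):
        aa = _CODONS.get(seq[i : i + 3], "X")
        if aa == "*":
            break
        prot.append(aa)
    return "".join(prot)


def oracle_proteins(variant, gene, chrom_seq):
    """Brute force: edit the full chromosome, shift coordinates, splice,
    translate."""
    p, ref, alt = variant.pos0, variant.ref, variant.alt
    assert chrom_seq[p : p + len(ref)] == ref
    edited = chrom_seq[:p] + alt + chrom_seq[p + len(ref) :]
    delta = len(alt) - len(ref)

    def shift(c):
        if c <= p:
            return c
        if c >= p + len(ref):
            return c + delta
        return p + min(c - p, len(alt))

    ref_cds = "".join(chrom_seq[s:e] for s, e in gene.cds)
    mut_cds = "".join(edited[shift(s) : shift(e)] for s, e in gene.cds)
    if gene.strand == "-":
        ref_cds = ref_cds.translate(_COMP)[::-1]
        mut_cds = mut_cds.translate(_COMP)[::-1]
    return oracle_translate(ref_cds), oracle_translate(mut_cds)


# -- hand-made gene on a toy chromosome --------------------------------


def toy_gene(strand="+"):
    """chr: 30 bp lead-in, exon1 (ATG + 4 codons), intron 20 bp, exon2
    (20 codons + stop), 30 bp tail.  Plus-strand layout; for '-' the
    gene is written reverse-complemented at the same coordinates."""
    lead = "GCTAGCTAGCATCGATCGATCCGATCGATC"
    cds1 = "ATG" + "GCT" * 4  # 15 bp
    intron = "GTAAGTTTTTTTTTTTTCAG"
    cds2 = "GAA" * 10 + "CCT" * 9 + "TGC" + "TAA"  # wait adjusted below
    cds2 = "GAACATCGGTGGACTGACCGGATTCAATGTCCGGATCAATCGCTCAGGCATCATCCAATTTAA"
    tail = "ACGTACGTACGTACGTACGTACGTACGTAC"
    s1 = len(lead)
    e1 = s1 + len(cds1)
    s2 = e1 + len(intron)
    e2 = s2 + len(cds2)
    seq = lead + cds1 + intron + cds2 + tail
    if strand == "-":
        seq = seq.translate(_COMP)[::-1]
        L = len(seq)
        s1, e1, s2, e2 = L - e2, L - s2, L - e1, L - s1
    gene = GeneModel(
        gene_id="toy", chrom="chr1", strand=strand,
        exons=((s1, e1), (s2, e2)), cds=((s1, e1), (s2, e2)),
    )
    return gene, {"chr1": seq}


def test_toy_gene_is_complete():
    for strand in "+-":
        gene, genome = toy_gene(strand)
        assert gene.is_complete(genome), strand


@pytest.mark.parametrize("strand", ["+", "-"])
def test_variant_outside_exons_is_identity(strand):
    gene, genome = toy_gene(strand)
    v = VariantRecord(chrom="chr1", pos0=2, ref=genome["chr1"][2], alt="T" if genome["chr1"][2] != "T" else "A", genotype="hom_alt")
    ref, mut, spl = mutant_protein(v, gene, genome)
    assert mut == ref and not spl


@pytest.mark.parametrize("strand", ["+", "-"])
def test_two_bp_cds_deletion_matches_oracle(strand):
    gene, genome = toy_gene(strand)
    s2 = gene.cds[0][0] if strand == "-" else gene.cds[1][0]
    # delete 2 bp mid second exon (genomic), anchored one base before
    p = gene.cds[1][0] + 6 if strand == "+" else gene.cds[0][0] + 6
    seq = genome["chr1"]
    v = VariantRecord(chrom="chr1", pos0=p, ref=seq[p : p + 3], alt=seq[p], genotype="hom_alt")
    ref, mut, _ = mutant_protein(v, gene, genome)
    oref, omut = oracle_proteins(v, gene, seq)
    assert (ref, mut) == (oref, omut)
    assert mut != ref  # canonical frameshift
    chk = detect_pseudo_fs(v, gene, genome)
    assert chk.verdict == "genuine_fs"


def test_border_homopolymer_insertion_is_pseudo():
    """A 1-bp insertion duplicating its neighbour at an exon border,
    left-normalising into the intron, leaves the protein unchanged."""
    gene, genome = toy_gene("+")
    seq = list(genome["chr1"])
    s2 = gene.cds[1][0]
    x = seq[s2]
    seq[s2 - 3 : s2] = [x, x, x]  # intron tail mirrors the exon start
    assert seq[s2 - 4] != x
    genome = {"chr1": "".join(seq)}
    v = VariantRecord(
        chrom="chr1", pos0=s2, ref=x, alt=x + x, genotype="hom_alt",
        effects=(("frameshift_variant", "toy"),),
    )
    ref, mut, _ = mutant_protein(v, gene, genome)
    assert mut == ref
    chk = detect_pseudo_fs(v, gene, genome)
    assert chk.verdict == "pseudo_fs"
    assert chk.pseudo_reason == "outside_cds_after_normalization"


def test_inframe_deletion_is_not_a_candidate():
    gene, genome = toy_gene("+")
    p = gene.cds[1][0] + 5
    seq = genome["chr1"]
    v = VariantRecord(chrom="chr1", pos0=p, ref=seq[p : p + 4], alt=seq[p], genotype="hom_alt")
    assert fs_candidates([v], [gene]) == []
    v1 = VariantRecord(chrom="chr1", pos0=p, ref=seq[p : p + 2], alt=seq[p], genotype="hom_alt")
    assert len(fs_candidates([v1], [gene])) == 1


def test_ann_route_pairs_tagged_gene():
    gene, genome = toy_gene("+")
    # a 3-bp insertion right at the stop anchor: frame rule misses it,
    # the annotation route keeps it
    p = gene.cds[1][1] - 1
    seq = genome["chr1"]
    v = VariantRecord(
        chrom="chr1", pos0=p, ref=seq[p], alt=seq[p] + "CGT", genotype="hom_alt",
        effects=(("frameshift_variant", "toy"),),
    )
    pairs = fs_candidates([v], [gene])
    assert len(pairs) == 1 and pairs[0][1].gene_id == "toy"
    chk = detect_pseudo_fs(v, gene, genome)
    assert chk.verdict == "pseudo_fs"
    assert chk.pseudo_reason == "inframe_after_normalization"


def test_splice_site_destruction_is_flagged_not_interpreted():
    gene, genome = toy_gene("+")
    e1 = gene.exons[0][1]  # donor dinucleotide at [e1, e1+2)
    seq = genome["chr1"]
    v = VariantRecord(
        chrom="chr1", pos0=e1 - 1, ref=seq[e1 - 1 : e1 + 2], alt=seq[e1 - 1],
        genotype="hom_alt",
    )
    ref, mut, spl = mutant_protein(v, gene, genome)
    assert spl is True


class TestImpactClassification:
    def test_truncation_below_half(self):
        ref = "M" + "A" * 399
        mut = ref[:120]
        assert classify_protein_impact(ref, mut) == "truncated_major"

    def test_altered_c_terminal(self):
        ref = "M" + "A" * 399
        mut = ref[:390] + "W" * 5
        assert classify_protein_impact(ref, mut) == "altered_C_terminal"

    def test_extended_c_terminal(self):
        ref = "M" + "A" * 399
        mut = ref[:395] + "W" * 30
        assert classify_protein_impact(ref, mut) == "extended_C_terminal"

    def test_altered_n_terminal(self):
        ref = "M" + "A" * 399
        mut = "MWWW" + ref[4:]
        assert classify_protein_impact(ref, mut) == "altered_N_terminal"

    def test_identical_proteins_are_minimal(self):
        assert classify_protein_impact("MAAA", "MAAA") == "minimal"

    def test_empty_protein_is_error(self):
        with pytest.raises(ValueError):
            classify_protein_impact("MA", "")


class TestExpressionFilter:
    def _track(self, value):
        return ExpressionTrack({"chr1": ([100], [400], [value])})

    def _gene(self):
        return GeneModel(
            gene_id="g1", chrom="chr1", strand="+",
            exons=((100, 400),), cds=((100, 400),),
        )

    @pytest.mark.parametrize(
        "value,kept", [(250.0, True), (200.0, True), (199.0, False), (0.0, False)]
    )
    def test_nondetectable_threshold_edge(self, value, kept):
        genes = {"g1": self._gene()}
        out = expression_filter(["g1"], genes, self._track(value))
        assert ("g1" in out) == kept

    def test_missing_gene_warns_and_drops(self, caplog):
        with caplog.at_level("WARNING"):
            out = expression_filter(["absent"], {}, self._track(500.0))
        assert out == set() and "absent" in caplog.text


def test_empty_vcf_gives_zero_cascade(tmp_path, dataset):
    empty = tmp_path / "empty.vcf"
    empty.write_text(
        "##fileformat=VCFv4.2\n##contig=<ID=chr1,length=5000000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
    )
    _, table = run_cascade(
        str(empty), dataset.paths["gff"], dataset.paths["fasta"],
        dataset.paths["bedgraph"],
    )
    assert list(table["survivors"]) == [0, 0, 0, 0]


def test_planted_verdicts_and_reasons_match_manifest(dataset):
    """Every planted frameshift candidate audits to its manifest verdict,
    reason and (for genuine survivors) impact class."""
    genes = {g.gene_id: g for g in dataset.genes}
    for e in dataset.manifest["fs_candidates"]:
        rec = VariantRecord(
            chrom=e["chrom"], pos0=e["pos"] - 1, ref=e["ref"], alt=e["alt"],
            genotype=e["genotype"],
        )
        chk = detect_pseudo_fs(rec, genes[e["gene_id"]], dataset.genome)
        assert chk.verdict == e["expected_verdict"], e
        if "expected_reason" in e:
            assert chk.pseudo_reason == e["expected_reason"], e
        if e.get("expected_impact") and e["category"] == "genuine":
            assert (
                classify_protein_impact(chk.ref_protein, chk.mut_protein)
                == e["expected_impact"]
            ), e
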