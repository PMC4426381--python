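"""Synthetic genome, gene models, expression track and parental VCFs
with a machine-readable truth manifest.

The generator emulates the statistical structure of two inbred parental
lines mapped to a common reference: a low-divergence parent at about
one sequence change per 1,100 bp and a high-divergence (wild) parent at
about one change per 111 bp, with InDels a fixed fraction of changes
and enriched in gene-rich euchromatic arms; localized high-density
segments covering the four cross-line introgression signatures;
assembly-gap (N) runs that silence windows; a small fraction of
heterozygous artifact calls; planted genuine and pseudo frameshift
InDels; and marker-grade InDels in a reserved intergenic region.

Everything planted is recorded in the manifest, which alone suffices to
predict the expected output of every pipeline stage.  Generation is
fully deterministic per master seed (sequence construction uses only
the integer state of the generator).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .expression import ExpressionTrack
from .gene_models import GeneModel, write_gff3
from .variant_io import VariantRecord, normalize_indel

BASES = "ACGT"
_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)
_N_CODE = ord("N")

STOPS = ("TAA", "TAG", "TGA")
NON_STOP_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOPS
)

HALF_MB = 500_000

# default gap runs and introgression segments as fractions of the
# chromosome length; at the default 5-Mb scale these are window-aligned
_DEFAULT_GAP_FRACTIONS = {0: [(0.72, 0.80)], 1: [(0.86, 0.90)], 2: [(0.34, 0.66)]}
_SNP_PER_MB = 1e-6  # change rate per bp for 1 SNP/Mb at snp_fraction 1


@dataclass(frozen=True)
class SegmentSpec:
    """A planted high-density segment: per-line change rates (per bp)
    override the background inside [start, end)."""

    chrom: str
    start: int
    end: int
    pattern_class: str
    rates: dict  # line -> change rate per bp


DEFAULT_FS_PLAN = {
    "genuine": {"truncated_major": 2, "altered_C_terminal": 2, "extended_C_terminal": 1},
    "pseudo_outside": 1,
    "pseudo_border": 1,
    "pseudo_inframe": 1,
    "pseudo_internal_stop": 1,
    "het": 6,
    "silent": 5,
}

DEFAULT_MARKER_PLAN = (
    [(s, "hom_alt") for s in (10, 12, 15, 20, 25, 30, 32)]
    + [(9, "hom_alt")] * 8
    + [(15, "het")] * 5
    + [(4, "hom_alt")] * 5
    + [(360, "hom_alt")] * 5
)


@dataclass(frozen=True)
class SyntheticConfig:
    n_chrom: int = 3
    chrom_length: int = 5_000_000
    arm_length: int = 1_500_000
    line_a: str = "lineA"
    line_b: str = "lineB"
    line_c: str = "lineC"
    lineA_rate: float = 1.0 / 1100.0
    lineB_rate: float = 1.0 / 111.0
    lineC_rate: float = 1.0 / 1100.0
    indel_fraction: float = 1.0 / 6.0
    het_fraction: float = 0.02
    generich_indel_enrichment: float = 3.0
    arm_gene_density: int = 120  # genes per 0.5-Mb tile
    peri_gene_density: int = 5
    expressed_fraction: float = 0.7
    indel_geometric_p: float = 0.35
    max_indel_length: int = 326
    with_genes: bool = True
    with_fs: bool = True
    with_markers: bool = True
    with_expression: bool = True
    third_line: bool = True
    n_accessions: int = 3
    gaps: dict | None = None  # chrom -> [(start, end)]; None -> scaled defaults
    segments: tuple | None = None  # None -> default four classes
    fs_plan: dict | None = None  # None -> DEFAULT_FS_PLAN (per parental line)
    marker_plan: tuple | None = None

    @property
    def snp_fraction(self) -> float:
        return 1.0 - self.indel_fraction

    def chrom_names(self):
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def resolved_gaps(self) -> dict:
        if self.gaps is not None:
            return self.gaps
        out = {}
        for i, chrom in enumerate(self.chrom_names()):
            runs = _DEFAULT_GAP_FRACTIONS.get(i, [])
            out[chrom] = [
                (int(a * self.chrom_length), int(b * self.chrom_length)) for a, b in runs
            ]
        return out

    def resolved_segments(self) -> tuple:
        if self.segments is not None:
            return tuple(self.segments)
        names = self.chrom_names()
        if len(names) < 3:
            return ()
        L = self.chrom_length
        sf = self.snp_fraction

        def rate(snp_per_mb):
            return snp_per_mb * _SNP_PER_MB / sf

        return (
            SegmentSpec(names[0], int(0.2 * L), int(0.6 * L), "lineB_divergent",
                        {self.line_b: rate(25000)}),
            SegmentSpec(names[1], 0, int(0.4 * L), "lineA_specific",
                        {self.line_a: rate(6000)}),
            SegmentSpec(names[2], 0, int(0.2 * L), "reference_divergent",
                        {self.line_a: rate(12000), self.line_b: rate(25000),
                         self.line_c: rate(6000)}),
            SegmentSpec(names[2], int(0.8 * L), L, "reference_from_wild",
                        {self.line_a: rate(6000), self.line_b: rate(300),
                         self.line_c: rate(6000)}),
        )

    def marker_region(self) -> tuple:
        L = self.chrom_length
        return (self.chrom_names()[0], int(0.60 * L), int(0.70 * L))

    def lines(self):
        out = [self.line_a, self.line_b]
        if self.third_line:
            out.append(self.line_c)
        return out

    def line_rate(self, line: str) -> float:
        return {self.line_a: self.lineA_rate, self.line_b: self.lineB_rate,
                self.line_c: self.lineC_rate}[line]


class _ChromArray:
    """String-slicing view over a mutable uint8 chromosome array, so the
    package's fetch/normalise helpers work during construction."""

    def __init__(self, arr: np.ndarray):
        self.arr = arr

    def __getitem__(self, sl):
        return self.arr[sl].tobytes().decode()

    def __len__(self):
        return len(self.arr)


def _view(genome_arrays: dict) -> dict:
    return {chrom: _ChromArray(arr) for chrom, arr in genome_arrays.items()}


def _translate(seq: str) -> str:
    seq = seq[: len(seq) // 3 * 3]
    return str(Seq(seq).translate(to_stop=True))


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------
# genome and gene models


def generate_genome(seed, n_chrom: int = 3, length: int = 5_000_000, gap_spec: dict | None = None):
    """Uniform-random reference chromosomes with planted N runs.

    Returns ``(genome_arrays, gaps)`` where genome_arrays maps chromosome
    name to a mutable uint8 array.  Deterministic per seed.
    """
    if length < 1_000_000:
        raise ValueError("chromosome length must be >= 1 Mb")
    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    if gap_spec is None:
        gap_spec = {
            chrom: [(int(a * length), int(b * length)) for a, b in _DEFAULT_GAP_FRACTIONS.get(i, [])]
            for i, chrom in enumerate(names)
        }
    genome = {}
    for chrom in names:
        arr = _BASE_CODES[rng.integers(0, 4, size=length)]
        for s, e in gap_spec.get(chrom, []):
            if e - s > length:
                raise ValueError(f"gap {s}-{e} longer than chromosome {chrom}")
            arr[s:e] = _N_CODE
        genome[chrom] = arr
    return genome, gap_spec


def _tiles(length: int):
    for start in range(0, length, HALF_MB):
        yield start, min(start + HALF_MB, length)


def _tile_is_arm(start: int, end: int, length: int, arm_length: int) -> bool:
    mid = (start + end) // 2
    return mid < arm_length or mid >= length - arm_length


def generate_gene_models(
    seed,
    genome_arrays: dict,
    gaps: dict,
    arm_density: int = 120,
    peri_density: int = 5,
    arm_length: int = 1_500_000,
):
    """Plant multi-exon protein-coding genes and write their CDS codons
    into the genome (valid start/stop, no internal stop, both strands,
    non-overlapping).  Euchromatic arms are dense, the pericentromeric
    middle sparse.  Returns the list of GeneModels and the spliced-CDS
    string of each gene (transcript orientation, including the stop)."""
    rng = np.random.default_rng(seed)
    genes, cds_strings = [], {}
    max_span = 50 + 903 + 2 * 150 + 50 + 20
    for chrom, arr in genome_arrays.items():
        length = len(arr)
        gap_runs = gaps.get(chrom, [])
        idx = 0
        for t0, t1 in _tiles(length):
            density = arm_density if _tile_is_arm(t0, t1, length, arm_length) else peri_density
            if density <= 0:
                continue
            slot = (t1 - t0) // density
            if slot < max_span + 50:
                raise ValueError(
                    f"gene density {density}/tile infeasible for tile size {t1 - t0}"
                )
            for j in range(density):
                s0 = t0 + j * slot
                s1 = s0 + slot
                if any(gs < s1 + 10 and ge > s0 - 10 for gs, ge in gap_runs):
                    continue
                gstart = s0 + int(rng.integers(0, 40))
                built = _build_gene(
                    rng, arr, chrom, f"g_{chrom}_{idx:04d}", gstart,
                    limit=min(s1 - 10, length - 10),
                )
                if built is None:
                    continue
                model, cds_str = built
                genes.append(model)
                cds_strings[model.gene_id] = cds_str
                idx += 1
    return genes, cds_strings


def _build_gene(rng, arr, chrom, gene_id, gstart, limit=None):
    n_aa = int(rng.integers(80, 301))
    cds_len = 3 * (n_aa + 1)
    n_ex = int(rng.integers(2, 4))
    # split the CDS into n_ex parts of >= 30 bp
    rem = cds_len - 30 * n_ex
    cuts = np.sort(rng.integers(0, rem + 1, size=n_ex - 1))
    parts = np.diff(np.concatenate([[0], cuts, [rem]])) + 30
    introns = rng.integers(60, 151, size=n_ex - 1)
    strand = "+" if rng.integers(0, 2) == 0 else "-"
    utr = 50

    cds_ivs, exon_ivs = [], []
    pos = gstart + utr
    for i, part in enumerate(parts):
        cds_ivs.append((pos, pos + int(part)))
        pos += int(part)
        if i < n_ex - 1:
            pos += int(introns[i])
    exon_ivs = [list(iv) for iv in cds_ivs]
    exon_ivs[0][0] -= utr
    exon_ivs[-1][1] += utr
    if limit is not None and exon_ivs[-1][1] > limit:
        return None

    codon_idx = rng.integers(0, len(NON_STOP_CODONS), size=n_aa - 1)
    cds_str = "ATG" + "".join(NON_STOP_CODONS[i] for i in codon_idx)
    cds_str += STOPS[int(rng.integers(0, 3))]

    genomic = cds_str if strand == "+" else _revcomp(cds_str)
    off = 0
    for s, e in cds_ivs:
        arr[s:e] = np.frombuffer(genomic[off : off + (e - s)].encode(), dtype=np.uint8)
        off += e - s
    # decorate splice dinucleotides (cosmetic; not interpreted downstream)
    for (s1, e1), (s2, e2) in zip(cds_ivs, cds_ivs[1:]):
        arr[e1 : e1 + 2] = np.frombuffer(b"GT", dtype=np.uint8)
        arr[s2 - 2 : s2] = np.frombuffer(b"AG", dtype=np.uint8)

    model = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=tuple((int(s), int(e)) for s, e in exon_ivs),
        cds=tuple(cds_ivs),
    )
    return model, cds_str


# ---------------------------------------------------------------------
# frameshift-candidate planting


def _exon_transcript_ranges(gene: GeneModel):
    """Transcript-offset range of each CDS interval (genomic order)."""
    L = gene.cds_length
    out, acc = [], 0
    for s, e in gene.cds:
        fwd = (acc, acc + (e - s))
        acc += e - s
        if gene.strand == "+":
            out.append(fwd)
        else:
            out.append((L - fwd[1], L - fwd[0]))
    return out


def _pick_offset(rng, gene, lo, hi, k, margin=8):
    """A transcript offset so [off, off+k) lies in one exon, inside
    [lo, hi), at least ``margin`` from the exon's transcript edges."""
    choices = []
    for (a, b) in _exon_transcript_ranges(gene):
        a2, b2 = max(a + margin, lo), min(b - margin - k, hi)
        if b2 > a2:
            choices.append((a2, b2))
    if not choices:
        return None
    a2, b2 = choices[int(rng.integers(0, len(choices)))]
    return int(rng.integers(a2, b2))


def _deletion_record(gene, seqview, off, k, genotype):
    if gene.strand == "+":
        gleft = gene.genomic_of(off)
    else:
        gleft = gene.genomic_of(off + k - 1)
    ref = seqview[gene.chrom][gleft - 1 : gleft + k]
    return VariantRecord(
        chrom=gene.chrom, pos0=gleft - 1, ref=ref, alt=ref[0], genotype=genotype,
        effects=(("frameshift_variant", gene.gene_id),),
    )


def _insertion_record(gene, seqview, anchor_off, ins, genotype):
    g = gene.genomic_of(anchor_off)
    if gene.strand == "+":
        pos0, inserted = g, ins
    else:
        pos0, inserted = g - 1, _revcomp(ins)
    ref = seqview[gene.chrom][pos0]
    return VariantRecord(
        chrom=gene.chrom, pos0=pos0, ref=ref, alt=ref + inserted, genotype=genotype,
        effects=(("frameshift_variant", gene.gene_id),),
    )


def _sim_deletion(cds: str, off: int, k: int) -> str:
    return cds[:off] + cds[off + k :]


def _sim_insertion(cds: str, anchor_off: int, ins: str) -> str:
    return cds[: anchor_off + 1] + ins + cds[anchor_off + 1 :]


def _normalized_in_exon(rec, seqview, gene):
    """Whether the left-aligned edit footprint stays inside one CDS
    interval of the gene (keeps planted genuine edits unambiguous)."""
    nrec = normalize_indel(rec, seqview)
    fs, fe = nrec.footprint()
    return any(s <= fs and fe <= e for s, e in gene.cds)


def _classify_impact(ref_prot, mut_prot, terminus_fraction=0.25):
    # local re-statement of the impact rule, used only to steer planting
    from .fs_audit import classify_protein_impact

    return classify_protein_impact(ref_prot, mut_prot, terminus_fraction)


class _FsPlanter:
    """Plants frameshift candidates of each category into host genes,
    computing the truth (reference and mutant proteins) by direct
    transcript-level simulation rather than through the audit path."""

    def __init__(self, rng, genome_arrays, genes, cds_strings):
        self.rng = rng
        self.arrays = genome_arrays
        self.view = _view(genome_arrays)
        self.genes = genes
        self.cds = cds_strings
        order = rng.permutation(len(genes))
        self._pool = [genes[i] for i in order]
        self._used = set()

    def _next_gene(self, strand=None, min_exons=2):
        for g in self._pool:
            if g.gene_id in self._used:
                continue
            if strand and g.strand != strand:
                continue
            if len(g.exons) < min_exons:
                continue
            return g
        raise RuntimeError("ran out of host genes for the frameshift plan")

    def _take(self, gene):
        self._used.add(gene.gene_id)

    # -- categories ---------------------------------------------------

    def plant_genuine(self, target_impact, genotype="hom_alt"):
        rng = self.rng
        windows = {
            "truncated_major": (0.10, 0.30),
            "altered_C_terminal": (0.80, 0.92),
            "extended_C_terminal": (0.80, 0.95),
        }
        lo_f, hi_f = windows.get(target_impact, (0.10, 0.30))
        for _ in range(80):
            gene = self._next_gene()
            cds = self.cds[gene.gene_id]
            L = len(cds)
            ref_prot = _translate(cds)
            ok = None
            for _ in range(40):
                lo, hi = int(lo_f * L), int(hi_f * L)
                if target_impact == "extended_C_terminal":
                    off = _pick_offset(rng, gene, lo, hi, 1)
                    if off is None:
                        break
                    ins = BASES[int(rng.integers(0, 4))]
                    mut_cds = _sim_insertion(cds, off, ins)
                    rec = _insertion_record(gene, self.view, off, ins, genotype)
                else:
                    k = int(rng.integers(1, 3))
                    if k == 2 and target_impact == "altered_C_terminal":
                        k = 1
                    off = _pick_offset(rng, gene, lo, hi, k)
                    if off is None:
                        break
                    mut_cds = _sim_deletion(cds, off, k)
                    rec = _deletion_record(gene, self.view, off, k, genotype)
                mut_prot = _translate(mut_cds)
                if not mut_prot or mut_prot == ref_prot:
                    continue
                if target_impact and _classify_impact(ref_prot, mut_prot) != target_impact:
                    continue
                if not _normalized_in_exon(rec, self.view, gene):
                    continue
                ok = (rec, ref_prot, mut_prot)
                break
            if ok:
                self._take(gene)
                rec, ref_prot, mut_prot = ok
                return gene, rec, {
                    "expected_verdict": "genuine_fs",
                    "expected_impact": _classify_impact(ref_prot, mut_prot),
                    "ref_prot_len": len(ref_prot),
                    "mut_prot_len": len(mut_prot),
                }
            self._take(gene)  # burn unlucky gene, move on
        raise RuntimeError(f"could not plant a {target_impact} frameshift")

    def plant_pseudo_outside(self):
        rng = self.rng
        for _ in range(40):
            gene = self._next_gene(min_exons=2)
            exon_i = int(rng.integers(1, len(gene.cds)))
            s = gene.cds[exon_i][0]
            arr = self.arrays[gene.chrom]
            x = chr(arr[s])
            arr[s - 3 : s] = ord(x)
            others = [b for b in BASES if b != x]
            arr[s - 4] = ord(others[int(rng.integers(0, 3))])
            rec = VariantRecord(
                chrom=gene.chrom, pos0=s, ref=x, alt=x + x, genotype="hom_alt",
                effects=(("frameshift_variant", gene.gene_id),),
            )
            nrec = normalize_indel(rec, self.view)
            fs, fe = nrec.footprint()
            if any(cs < fe and ce > fs for cs, ce in gene.cds):
                self._take(gene)
                continue
            self._take(gene)
            prot = _translate(self.cds[gene.gene_id])
            return gene, rec, {
                "expected_verdict": "pseudo_fs",
                "expected_reason": "outside_cds_after_normalization",
                "ref_prot_len": len(prot),
                "mut_prot_len": len(prot),
            }
        raise RuntimeError("could not plant an outside-CDS pseudo frameshift")

    def _stop_anchor(self, gene):
        """Genomic position of the transcript-last CDS base ('+' genes)."""
        return gene.genomic_of(gene.cds_length - 1)

    def plant_pseudo_border(self):
        rng = self.rng
        gene = self._next_gene(strand="+")
        g = self._stop_anchor(gene)
        arr = self.arrays[gene.chrom]
        x, nxt = chr(arr[g]), chr(arr[g + 1])
        b = next(base for base in BASES if base not in (x, nxt))
        rec = VariantRecord(
            chrom=gene.chrom, pos0=g, ref=x, alt=x + b, genotype="hom_alt",
            effects=(("frameshift_variant", gene.gene_id),),
        )
        self._take(gene)
        prot = _translate(self.cds[gene.gene_id])
        return gene, rec, {
            "expected_verdict": "pseudo_fs",
            "expected_reason": "border_artifact",
            "ref_prot_len": len(prot),
            "mut_prot_len": len(prot),
        }

    def plant_pseudo_inframe(self):
        rng = self.rng
        gene = self._next_gene(strand="+")
        g = self._stop_anchor(gene)
        arr = self.arrays[gene.chrom]
        x = chr(arr[g])
        last = next(base for base in BASES if base != x)
        ins = BASES[int(rng.integers(0, 4))] + BASES[int(rng.integers(0, 4))] + last
        rec = VariantRecord(
            chrom=gene.chrom, pos0=g, ref=x, alt=x + ins, genotype="hom_alt",
            effects=(("frameshift_variant", gene.gene_id),),
        )
        self._take(gene)
        prot = _translate(self.cds[gene.gene_id])
        return gene, rec, {
            "expected_verdict": "pseudo_fs",
            "expected_reason": "inframe_after_normalization",
            "ref_prot_len": len(prot),
            "mut_prot_len": len(prot),
        }

    def plant_pseudo_internal_stop(self):
        """A gene whose annotated CDS carries an internal stop (a
        partial / mis-predicted model, as real annotations contain); a
        frameshift downstream of that stop leaves the product unchanged."""
        rng = self.rng
        for _ in range(40):
            gene = self._next_gene()
            cds = self.cds[gene.gene_id]
            L = len(cds)
            ci = int(0.4 * (L // 3))  # codon index for the internal stop
            arr = self.arrays[gene.chrom]
            for kk in range(3):
                off = 3 * ci + kk
                g = gene.genomic_of(off)
                base = "TAA"[kk]
                if gene.strand == "-":
                    base = _revcomp(base)
                arr[g] = ord(base)
            cds = cds[: 3 * ci] + "TAA" + cds[3 * ci + 3 :]
            self.cds[gene.gene_id] = cds
            off = _pick_offset(rng, gene, 3 * ci + 9, L - 9, 1)
            if off is None:
                self._take(gene)
                continue
            rec = _deletion_record(gene, self.view, off, 1, "hom_alt")
            if not _normalized_in_exon(rec, self.view, gene):
                self._take(gene)
                continue
            nfs, nfe = normalize_indel(rec, self.view).footprint()
            near_border = any(
                abs(nfs - b) <= 2 or abs(nfe - b) <= 2
                for s, e in gene.exons
                for b in (s, e)
            )
            if near_border:
                self._take(gene)
                continue
            self._take(gene)
            prot = _translate(cds)
            mut = _translate(_sim_deletion(cds, off, 1))
            if mut != prot:  # deletion upstream of the planted stop; retry
                continue
            return gene, rec, {
                "expected_verdict": "pseudo_fs",
                "expected_reason": "protein_unchanged",
                "ref_prot_len": len(prot),
                "mut_prot_len": len(mut),
            }
        raise RuntimeError("could not plant an internal-stop pseudo frameshift")


# ---------------------------------------------------------------------
# the orchestrator


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    seed: int
    genome: dict  # chrom -> str (reference, frozen)
    genes: list
    cds_strings: dict
    variants: dict  # line -> sorted list[VariantRecord]
    accessions: dict  # accession -> list[VariantRecord]
    expression_max: dict  # gene_id -> float
    manifest: dict
    paths: dict = field(default_factory=dict)

    @property
    def chrom_lengths(self) -> dict:
        return {c: len(s) for c, s in self.genome.items()}

    def expression_track(self) -> ExpressionTrack:
        intervals: dict = {}
        for g in self.genes:
            val = self.expression_max.get(g.gene_id, 0.0)
            if val <= 0:
                continue
            for s, e in g.exons:
                intervals.setdefault(g.chrom, []).append((s, e, val))
        grouped = {}
        for chrom, rows in intervals.items():
            rows.sort()
            grouped[chrom] = (
                [r[0] for r in rows],
                [r[1] for r in rows],
                [r[2] for r in rows],
            )
        return ExpressionTrack(grouped)

    def write(self, out_dir) -> dict:
        """Write FASTA, GFF3, per-line VCFs, bedGraph, gap BED and the
        manifest; returns the path map."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        fasta = os.path.join(out_dir, "reference.fa")
        with open(fasta, "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        paths["fasta"] = fasta

        gff = os.path.join(out_dir, "genes.gff3")
        write_gff3(self.genes, gff)
        paths["gff"] = gff

        for line, records in self.variants.items():
            p = os.path.join(out_dir, f"{line}.vcf")
            write_vcf(p, records, self.chrom_lengths, sample=line)
            paths[f"vcf_{line}"] = p

        bedgraph = os.path.join(out_dir, "expression.bedgraph")
        with open(bedgraph, "w") as fh:
            rows = []
            for g in self.genes:
                val = self.expression_max.get(g.gene_id, 0.0)
                if val > 0:
                    for s, e in g.exons:
                        rows.append((g.chrom, s, e, val))
            for chrom, s, e, val in sorted(rows):
                fh.write(f"{chrom}\t{s}\t{e}\t{val:g}\n")
        paths["bedgraph"] = bedgraph

        gap_bed = os.path.join(out_dir, "gaps.bed")
        with open(gap_bed, "w") as fh:
            for chrom, runs in self.manifest["gaps"].items():
                for s, e in runs:
                    fh.write(f"{chrom}\t{s}\t{e}\tgap\n")
        paths["gaps"] = gap_bed

        acc_dir = os.path.join(out_dir, "accessions")
        if self.accessions:
            os.makedirs(acc_dir, exist_ok=True)
            for name, records in self.accessions.items():
                p = os.path.join(acc_dir, f"{name}.vcf")
                write_vcf(p, records, self.chrom_lengths, sample=name)
                paths[f"vcf_{name}"] = p

        manifest_path = os.path.join(out_dir, "manifest.json")
        with open(manifest_path, "w") as fh:
            json.dump(_jsonable(self.manifest), fh, indent=1)
        paths["manifest"] = manifest_path
        return paths


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


def write_vcf(path, records, chrom_lengths: dict, sample: str) -> None:
    """Emit a minimal single-sample VCF 4.2 with the GATK-style site
    annotations and an ANN field for planted effect tags."""
    gt_map = {"hom_alt": "1/1", "het": "0/1", "hom_ref": "0/0", "missing": "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        for key, typ in [
            ("DP", "Integer"), ("QD", "Float"), ("FS", "Float"), ("MQ", "Float"),
            ("ReadPosRankSum", "Float"), ("MQRankSum", "Float"),
        ]:
            fh.write(
                f'##INFO=<ID={key},Number=1,Type={typ},Description="{key}">\n'
            )
        fh.write('##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for rec in records:
            parts = []
            for key in ("DP", "QD", "FS", "MQ", "ReadPosRankSum", "MQRankSum"):
                if key in rec.site_annotations:
                    val = rec.site_annotations[key]
                    parts.append(
                        f"{key}={int(val)}" if key == "DP" else f"{key}={val:g}"
                    )
            for effect, gene_id in rec.effects:
                parts.append(f"ANN={rec.alt}|{effect}|HIGH|{gene_id}")
            info = ";".join(parts) if parts else "."
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t50\tPASS\t{info}"
                f"\tGT\t{gt_map[rec.genotype]}\n"
            )


def _merged_intervals(ivs):
    out = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    starts = np.array([x[0] for x in out], dtype=np.int64)
    ends = np.array([x[1] for x in out], dtype=np.int64)
    return starts, ends


def _overlaps(starts, ends, fs, fe) -> bool:
    if len(starts) == 0:
        return False
    i = np.searchsorted(starts, fe, side="left") - 1
    return i >= 0 and ends[i] > fs


def _drop_in_intervals(positions, starts, ends):
    if len(starts) == 0 or len(positions) == 0:
        return positions
    idx = np.searchsorted(starts, positions, side="right") - 1
    inside = (idx >= 0) & (positions < ends[np.clip(idx, 0, len(ends) - 1)])
    return positions[~inside]


def generate_dataset(seed: int, config: SyntheticConfig | None = None, out_dir=None) -> SyntheticDataset:
    """Build the complete synthetic study: reference, genes, expression,
    parental (and optional third-line) VCF record sets, marker InDels,
    frameshift plan and accession panel, plus the truth manifest.

    When ``out_dir`` is given all external files are written there.
    """
    cfg = config or SyntheticConfig()
    root = np.random.SeedSequence(seed)
    s_genome, s_genes, s_fs, s_markers, s_background, s_expr, s_acc = [
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(7)
    ]

    gaps_spec = cfg.resolved_gaps()
    genome_arrays, gaps = generate_genome(
        s_genome, cfg.n_chrom, cfg.chrom_length, gaps_spec
    )

    genes, cds_strings = ([], {})
    if cfg.with_genes:
        genes, cds_strings = generate_gene_models(
            s_genes, genome_arrays, gaps,
            arm_density=cfg.arm_gene_density,
            peri_density=cfg.peri_gene_density,
            arm_length=cfg.arm_length,
        )
    genes_by_chrom: dict = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    segments = cfg.resolved_segments()
    manifest: dict = {
        "seed": int(seed),
        "chrom_lengths": {c: cfg.chrom_length for c in cfg.chrom_names()},
        "gaps": {c: [list(map(int, r)) for r in gaps.get(c, [])] for c in cfg.chrom_names()},
        "segments": [
            {
                "chrom": s.chrom, "start": int(s.start), "end": int(s.end),
                "pattern_class": s.pattern_class,
                "rates": {k: float(v) for k, v in s.rates.items()},
            }
            for s in segments
        ],
        "rates": {line: cfg.line_rate(line) for line in cfg.lines()},
        "indel_fraction": cfg.indel_fraction,
        "het_fraction": cfg.het_fraction,
        "lines": cfg.lines(),
        "line_a": cfg.line_a,
        "line_b": cfg.line_b,
    }

    # -- frameshift plan ----------------------------------------------
    rng_fs = np.random.default_rng(s_fs)
    fs_entries: list = []
    expression_forced: dict = {}
    expected_cascade: dict = {}
    if cfg.with_fs and genes:
        plan = cfg.fs_plan or DEFAULT_FS_PLAN
        planter = _FsPlanter(rng_fs, genome_arrays, genes, cds_strings)
        first_expressed_forced = False
        silent_cycle = [199.0, 0.0, 150.0, 50.0]
        silent_i = 0
        for line in (cfg.line_a, cfg.line_b):
            n_het = n_silent = n_genuine = n_total = 0
            def add(gene, rec, truth, category, expressed):
                nonlocal first_expressed_forced
                entry = {
                    "line": line, "gene_id": gene.gene_id, "chrom": rec.chrom,
                    "pos": rec.pos, "ref": rec.ref, "alt": rec.alt,
                    "genotype": rec.genotype, "category": category,
                    "expressed": expressed,
                }
                entry.update(truth)
                fs_entries.append((rec, entry))
                if expressed:
                    if not first_expressed_forced:
                        expression_forced[gene.gene_id] = 200.0
                        first_expressed_forced = True
                    else:
                        expression_forced[gene.gene_id] = float(
                            rng_fs.integers(300, 8001)
                        )
                else:
                    nonlocal_silent = silent_cycle[silent_i % len(silent_cycle)]
                    expression_forced[gene.gene_id] = nonlocal_silent
            for impact, n in (plan.get("genuine") or {}).items():
                for _ in range(n):
                    gene, rec, truth = planter.plant_genuine(impact)
                    add(gene, rec, truth, "genuine", True)
                    n_genuine += 1
                    n_total += 1
            for category, fn in (
                ("pseudo_outside", planter.plant_pseudo_outside),
                ("pseudo_border", planter.plant_pseudo_border),
                ("pseudo_inframe", planter.plant_pseudo_inframe),
                ("pseudo_internal_stop", planter.plant_pseudo_internal_stop),
            ):
                for _ in range(plan.get(category, 0)):
                    gene, rec, truth = fn()
                    add(gene, rec, truth, category, True)
                    n_total += 1
            for _ in range(plan.get("het", 0)):
                gene, rec, truth = planter.plant_genuine("truncated_major", genotype="het")
                add(gene, rec, truth, "het", True)
                n_het += 1
                n_total += 1
            for _ in range(plan.get("silent", 0)):
                gene, rec, truth = planter.plant_genuine("truncated_major")
                add(gene, rec, truth, "silent", False)
                silent_i += 1
                n_silent += 1
                n_total += 1
            expected_cascade[line] = {
                "fs_candidates": n_total,
                "homozygous": n_total - n_het,
                "expressed": n_total - n_het - n_silent,
                "genuine_fs": n_genuine,
            }
    manifest["fs_candidates"] = [e for _, e in fs_entries]
    manifest["expected_cascade"] = expected_cascade

    # -- expression maxima --------------------------------------------
    rng_expr = np.random.default_rng(s_expr)
    expression_max: dict = {}
    if cfg.with_expression:
        for g in genes:
            if g.gene_id in expression_forced:
                expression_max[g.gene_id] = expression_forced[g.gene_id]
            elif rng_expr.random() < cfg.expressed_fraction:
                expression_max[g.gene_id] = float(rng_expr.integers(250, 8001))
            else:
                expression_max[g.gene_id] = float(
                    [0.0, 50.0, 150.0, 199.0][int(rng_expr.integers(0, 4))]
                )
    manifest["expression_max"] = dict(expression_max)

    # -- markers ------------------------------------------------------
    rng_mark = np.random.default_rng(s_markers)
    marker_records: list = []
    marker_entries: list = []
    marker_region = cfg.marker_region()
    if cfg.with_markers:
        plan = list(cfg.marker_plan or DEFAULT_MARKER_PLAN)
        chrom, r0, r1 = marker_region
        arr = genome_arrays[chrom]
        spans = [(g.start, g.end) for g in genes_by_chrom.get(chrom, [])]
        n = len(plan)
        step = (r1 - r0 - 10000) // max(1, n)
        for i, (size, genotype) in enumerate(plan):
            p0 = r0 + 5000 + i * step + int(rng_mark.integers(0, 1000))
            for _ in range(60):
                footprint_end = p0 + size + 1
                clash = any(gs < footprint_end + 20 and ge > p0 - 20 for gs, ge in spans)
                has_n = bool(np.any(arr[p0 : footprint_end] == _N_CODE))
                if not clash and not has_n:
                    break
                p0 += 97
            is_deletion = bool(rng_mark.integers(0, 2))
            if is_deletion:
                ref = arr[p0 : p0 + size + 1].tobytes().decode()
                alt = ref[0]
            else:
                ref = chr(arr[p0])
                alt = ref + "".join(
                    BASES[j] for j in rng_mark.integers(0, 4, size=size)
                )
            rec = VariantRecord(
                chrom=chrom, pos0=p0, ref=ref, alt=alt, genotype=genotype
            )
            marker_records.append(rec)
            marker_entries.append(
                {
                    "chrom": chrom, "pos": rec.pos, "ref": ref, "alt": alt,
                    "size": int(size), "genotype": genotype,
                    "qualifies": bool(10 <= size <= 350 and genotype == "hom_alt"),
                }
            )
    manifest["markers"] = marker_entries
    manifest["marker_region"] = list(marker_region)

    # -- background variants ------------------------------------------
    rng_bg = np.random.default_rng(s_background)
    planted_by_line: dict = {line: [] for line in cfg.lines()}
    for rec, entry in fs_entries:
        planted_by_line[entry["line"]].append(rec)
    planted_by_line[cfg.line_a].extend(marker_records)

    cds_index = {}
    for chrom in cfg.chrom_names():
        ivs = [iv for g in genes_by_chrom.get(chrom, []) for iv in g.cds]
        cds_index[chrom] = _merged_intervals(ivs) if ivs else (np.array([]), np.array([]))

    # realized gene-rich tiles (by gene starts per 0.5-Mb tile)
    tile_counts: dict = {}
    for g in genes:
        key = (g.chrom, (g.start // HALF_MB) * HALF_MB)
        tile_counts[key] = tile_counts.get(key, 0) + 1
    manifest["gene_rich_tiles"] = sorted(
        [list(k) for k, v in tile_counts.items() if v > 50]
    )

    variants: dict = {}
    for line in cfg.lines():
        rate = cfg.line_rate(line)
        all_records: list = []
        planted = planted_by_line[line]
        planted_foot: dict = {}
        for rec in planted:
            fs_, fe_ = rec.footprint()
            planted_foot.setdefault(rec.chrom, []).append((fs_ - 5, fe_ + 5))
        for chrom in cfg.chrom_names():
            arr = genome_arrays[chrom]
            L = len(arr)
            seg_ivs = [
                (s.start, s.end) for s in segments if s.chrom == chrom
            ]
            gap_ivs = gaps.get(chrom, [])
            n_bg = L - int(sum(e - s for s, e in seg_ivs) + sum(e - s for s, e in gap_ivs))

            snp_rate = np.full(L, rate * cfg.snp_fraction)
            w = np.ones(L)
            if genes and cfg.generich_indel_enrichment != 1.0:
                for (tc, ts), cnt in tile_counts.items():
                    if tc == chrom and cnt > 50:
                        w[ts : ts + HALF_MB] = cfg.generich_indel_enrichment
            cs, ce = cds_index[chrom]
            for s, e in zip(cs, ce):
                w[s:e] = 0.0
            if cfg.with_markers and line == cfg.line_a and chrom == marker_region[0]:
                w[marker_region[1] : marker_region[2]] = 0.0
            wbg = w.copy()
            for s, e in seg_ivs + gap_ivs:
                wbg[s:e] = 0.0
            total_w = float(wbg.sum())
            indel_rate = (
                w * (rate * cfg.indel_fraction * n_bg / total_w)
                if total_w > 0
                else np.zeros(L)
            )
            for seg in segments:
                if seg.chrom != chrom or line not in seg.rates:
                    continue
                snp_rate[seg.start : seg.end] = seg.rates[line] * cfg.snp_fraction
                indel_rate[seg.start : seg.end] = seg.rates[line] * cfg.indel_fraction

            pf = _merged_intervals(planted_foot.get(chrom, [])) if planted_foot.get(chrom) else (np.array([]), np.array([]))

            snp_pos = np.nonzero(rng_bg.random(L) < snp_rate)[0]
            snp_pos = snp_pos[arr[snp_pos] != _N_CODE]
            snp_pos = _drop_in_intervals(snp_pos, pf[0], pf[1])
            ref_codes = arr[snp_pos]
            shift = rng_bg.integers(1, 4, size=len(snp_pos))
            base_idx = np.searchsorted(_BASE_CODES, ref_codes)
            alt_codes = _BASE_CODES[(base_idx + shift) % 4]
            het_flags = rng_bg.random(len(snp_pos)) < cfg.het_fraction
            for p, rc, ac, het in zip(snp_pos, ref_codes, alt_codes, het_flags):
                all_records.append(
                    VariantRecord(
                        chrom=chrom, pos0=int(p), ref=chr(rc), alt=chr(ac),
                        genotype="het" if het else "hom_alt",
                    )
                )

            ind_pos = np.nonzero(rng_bg.random(L) < indel_rate)[0]
            ind_pos = ind_pos[arr[ind_pos] != _N_CODE]
            lengths = np.minimum(
                rng_bg.geometric(cfg.indel_geometric_p, size=len(ind_pos)),
                cfg.max_indel_length,
            )
            is_del = rng_bg.integers(0, 2, size=len(ind_pos)).astype(bool)
            het_flags = rng_bg.random(len(ind_pos)) < cfg.het_fraction
            chrom_view = {chrom: _ChromArray(arr)}
            in_marker = (
                cfg.with_markers
                and line == cfg.line_a
                and chrom == marker_region[0]
            )
            for p, k, deln, het in zip(ind_pos, lengths, is_del, het_flags):
                p, k = int(p), int(k)
                fe_ = p + k + 1 if deln else p + 1
                if fe_ >= L or p == 0:
                    continue
                if deln:
                    sl = arr[p : p + k + 1]
                    if np.any(sl == _N_CODE):
                        continue
                    ref = sl.tobytes().decode()
                    alt = ref[0]
                else:
                    ref = chr(arr[p])
                    alt = ref + "".join(
                        BASES[j] for j in rng_bg.integers(0, 4, size=k)
                    )
                rec = VariantRecord(
                    chrom=chrom, pos0=p, ref=ref, alt=alt,
                    genotype="het" if het else "hom_alt",
                )
                # keep the audit/marker truth exact: exclude indels whose
                # raw OR left-aligned footprint touches a CDS, a planted
                # variant, or the reserved marker region
                nfs, nfe = normalize_indel(rec, chrom_view).footprint()
                lo, hi = min(p, nfs), max(fe_, nfe)
                if _overlaps(cds_index[chrom][0], cds_index[chrom][1], lo, hi):
                    continue
                if _overlaps(pf[0], pf[1], lo, hi):
                    continue
                if in_marker and lo < marker_region[2] and hi > marker_region[1]:
                    continue
                all_records.append(rec)
        all_records.extend(planted)
        chrom_order = {c: i for i, c in enumerate(cfg.chrom_names())}
        all_records.sort(key=lambda r: (chrom_order[r.chrom], r.pos0, r.ref, r.alt))
        # attach plausible site annotations (all passing the hard filters)
        n = len(all_records)
        dp = rng_bg.integers(25, 61, size=n)
        qd = np.round(rng_bg.uniform(10, 30, size=n), 2)
        fsb = np.round(rng_bg.uniform(0, 8, size=n), 2)
        rprs = np.clip(np.round(rng_bg.normal(0, 1, size=n), 2), -4, 4)
        mqrs = np.clip(np.round(rng_bg.normal(0, 1, size=n), 2), -4, 4)
        annotated = []
        for i, rec in enumerate(all_records):
            ann = {
                "DP": float(dp[i]), "QD": float(qd[i]), "FS": float(fsb[i]),
                "MQ": 60.0, "ReadPosRankSum": float(rprs[i]),
                "MQRankSum": float(mqrs[i]),
            }
            annotated.append(
                VariantRecord(
                    chrom=rec.chrom, pos0=rec.pos0, ref=rec.ref, alt=rec.alt,
                    genotype=rec.genotype, site_annotations=ann, effects=rec.effects,
                )
            )
        variants[line] = annotated

    # -- accession panel ----------------------------------------------
    rng_acc = np.random.default_rng(s_acc)
    accessions: dict = {}
    accession_truth: dict = {}
    if cfg.n_accessions > 0 and fs_entries:
        genuine = [
            (rec, entry) for rec, entry in fs_entries if entry["category"] == "genuine"
        ]
        names = [f"accession{i + 1}" for i in range(cfg.n_accessions)]
        for name in names:
            accessions[name] = []
        for rec, entry in genuine:
            row = {}
            for name in names:
                present = bool(rng_acc.random() < 0.55)
                row[name] = present
                if present:
                    accessions[name].append(
                        VariantRecord(
                            chrom=rec.chrom, pos0=rec.pos0, ref=rec.ref,
                            alt=rec.alt, genotype="hom_alt",
                        )
                    )
            accession_truth[entry["gene_id"]] = row
        chrom_order = {c: i for i, c in enumerate(cfg.chrom_names())}
        for name in names:
            accessions[name].sort(key=lambda r: (chrom_order[r.chrom], r.pos0))
    manifest["accessions"] = accession_truth

    genome_str = {c: a.tobytes().decode() for c, a in genome_arrays.items()}
    manifest["genes"] = {
        g.gene_id: {
            "chrom": g.chrom, "start": g.start, "end": g.end, "strand": g.strand,
            "n_exons": len(g.exons),
            "expression_max": expression_max.get(g.gene_id, 0.0),
        }
        for g in genes
    }

    dataset = SyntheticDataset(
        config=cfg,
        seed=int(seed),
        genome=genome_str,
        genes=genes,
        cds_strings=cds_strings,
        variants=variants,
        accessions=accessions,
        expression_max=expression_max,
        manifest=manifest,
    )
    if out_dir is not None:
        dataset.paths = dataset.write(out_dir)
    return dataset


def generate_expression_track(genes, expression_max: dict) -> ExpressionTrack:
    """Plateau coverage at each gene's planted maximum over its exons,
    zero elsewhere (deterministic given the maxima)."""
    grouped: dict = {}
    for g in genes:
        val = expression_max.get(g.gene_id, 0.0)
        if val <= 0:
            continue
        for s, e in g.exons:
            grouped.setdefault(g.chrom, []).append((s, e, val))
    out = {}
    for chrom, rows in grouped.items():
        rows.sort()
        out[chrom] = ([r[0] for r in rows], [r[1] for r in rows], [r[2] for r in rows])
    return ExpressionTrack(out)
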