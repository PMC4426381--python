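"""The frameshift-InDel audit cascade.

Effect-prediction software flags every coding indel whose length is not
a multiple of three as a frameshift, but a sizeable fraction of those
calls are *pseudo* frameshifts: after left-alignment the edit no longer
touches the coding sequence (typically a single-base insertion or
deletion of a base identical to its neighbour at an exon border), or it
sits at a start/stop codon or border where it leaves the translated
protein untouched.  The audit therefore decides each candidate by the
one fact that matters — whether the translated mutant protein differs
from the reference protein — and uses the edit context only to explain
*why* a pseudo call arose.

The cascade mirrors the audit flowchart: frameshift candidates are
screened for homozygosity (heterozygous calls in inbred lines are
artifact candidates), then for detectable expression, then for pseudo
frameshifts, and the survivors are classified by protein impact.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field

import pandas as pd
import pyfaidx
from Bio.Seq import Seq

from .expression import ExpressionTrack
from .gene_models import GeneModel, load_gene_models
from .variant_io import (
    FilterThresholds,
    VariantRecord,
    apply_hard_filters,
    fetch_sequence,
    is_homozygous_alt,
    normalize_indel,
    read_variants,
)

logger = logging.getLogger(__name__)

PSEUDO_REASONS = (
    "inframe_after_normalization",
    "outside_cds_after_normalization",
    "border_artifact",
    "protein_unchanged",
)

IMPACT_CLASSES = (
    "truncated_major",
    "altered_C_terminal",
    "altered_N_terminal",
    "extended_C_terminal",
    "minimal",
)

CASCADE_STAGES = ("fs_candidates", "homozygous", "expressed", "genuine_fs")


@dataclass
class FSAuditRecord:
    """One candidate frameshift InDel with its cascade outcome."""

    variant: VariantRecord
    gene_id: str
    stage_flags: dict = field(default_factory=dict)
    verdict: str | None = None  # genuine_fs | pseudo_fs | None (not reached / withheld)
    pseudo_reason: str | None = None
    impact_class: str | None = None
    splice_disrupted: bool = False
    withheld: bool = False  # incomplete gene model
    curation_note: str = ""  # free-text column for homology-based curation

    @property
    def terminal_stage(self) -> str:
        if not self.stage_flags.get("is_homozygous", False):
            return "heterozygous"
        if not self.stage_flags.get("is_expressed", False):
            return "not_expressed"
        if self.withheld:
            return "withheld"
        return "pseudo_fs" if self.verdict == "pseudo_fs" else "genuine_fs"


@dataclass(frozen=True)
class PseudoCheck:
    verdict: str | None
    pseudo_reason: str | None
    ref_protein: str
    mut_protein: str
    splice_disrupted: bool
    withheld: bool = False


def _translate(seq: str) -> str:
    seq = seq[: len(seq) // 3 * 3]
    return str(Seq(seq).translate(to_stop=True))


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------
# candidate selection


def fs_candidates(variants, genes) -> list:
    """Pairs of (indel, gene) that are frameshift candidates.

    Two routes are supported and their union is taken: the frame rule
    (the normalised footprint intersects a CDS interval and the length
    change is not a multiple of 3) and an upstream effect-prediction
    "frameshift" tag from an annotated VCF.  The caller supplies
    normalised variants.
    """
    by_chrom: dict = {}
    genes_by_id = {}
    for g in genes:
        genes_by_id[g.gene_id] = g
        for s, e in g.cds:
            by_chrom.setdefault(g.chrom, []).append((s, e, g))
    index = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda t: t[0])
        starts = [t[0] for t in ivs]
        max_len = max(t[1] - t[0] for t in ivs)
        index[chrom] = (starts, ivs, max_len)

    def overlapping_genes(chrom, fs, fe):
        found = {}
        if chrom not in index:
            return found
        starts, ivs, max_len = index[chrom]
        lo = bisect_left(starts, fs - max_len)
        hi = bisect_left(starts, fe)
        for s, e, g in ivs[lo:hi]:
            if s < fe and e > fs:
                found[g.gene_id] = g
        return found

    pairs = {}
    for rec in variants:
        if not rec.is_indel:
            continue
        fs, fe = rec.footprint()
        if rec.indel_length % 3 != 0:
            for g in overlapping_genes(rec.chrom, fs, fe).values():
                pairs[(rec.key(), g.gene_id)] = (rec, g)
        for effect, gene_id in rec.effects:
            if "frameshift" not in effect.lower():
                continue
            g = genes_by_id.get(gene_id)
            if g is None:
                for g2 in overlapping_genes(rec.chrom, fs, fe).values():
                    pairs[(rec.key(), g2.gene_id)] = (rec, g2)
                continue
            if g.chrom != rec.chrom:
                logger.warning(
                    "annotation pairs %s with gene %s on a different chromosome; skipped",
                    rec.key(), gene_id,
                )
                continue
            pairs[(rec.key(), g.gene_id)] = (rec, g)
    return sorted(pairs.values(), key=lambda p: (p[0].chrom, p[0].pos0, p[1].gene_id))


# ---------------------------------------------------------------------
# edit-and-translate machinery


def _project_through_edit(c: int, p: int, lr: int, la: int) -> int:
    """Map a reference coordinate through an edit replacing
    ``[p, p+lr)`` with ``la`` bases.  Coordinates inside a deleted
    footprint clamp onto the replacement."""
    if c <= p:
        return c
    if c >= p + lr:
        return c + (la - lr)
    return p + min(c - p, la)


def mutant_protein(variant: VariantRecord, gene: GeneModel, genome):
    """Reference and mutant proteins for one edit on one gene model.

    The edit is applied to the chromosome, the spliced CDS is
    re-extracted with the exon boundaries projected through the edit,
    and both sequences are translated to the first stop (strand-aware).
    If the edit changes a splice donor/acceptor dinucleotide the mutant
    protein is still computed on the naively projected CDS and a
    ``splice_disrupted`` flag is returned alongside.

    Returns ``(ref_protein, mut_protein, splice_disrupted)``.
    """
    if variant.is_indel:
        variant = normalize_indel(variant, genome)
    region_start = max(0, min(gene.start, variant.pos0) - 25)
    region_end = max(gene.end, variant.pos0 + len(variant.ref)) + 25
    seq = fetch_sequence(genome, gene.chrom, region_start, region_end)

    rel_cds = [(s - region_start, e - region_start) for s, e in gene.cds]
    ref_cds = "".join(seq[s:e] for s, e in rel_cds)

    if variant.chrom != gene.chrom:
        prot = _translate(ref_cds if gene.strand == "+" else _revcomp(ref_cds))
        return prot, prot, False

    p = variant.pos0 - region_start
    lr, la = len(variant.ref), len(variant.alt)
    if seq[p : p + lr] != variant.ref:
        raise ValueError(
            f"REF allele disagrees with genome at {variant.chrom}:{variant.pos}"
        )
    edited = seq[:p] + variant.alt + seq[p + lr :]

    def proj(c):
        return max(0, min(len(edited), _project_through_edit(c, p, lr, la)))

    mut_ivs = []
    for s, e in rel_cds:
        ps, pe = proj(s), proj(e)
        if pe > ps:
            mut_ivs.append((ps, pe))
    mut_cds = "".join(edited[s:e] for s, e in mut_ivs)

    splice_disrupted = False
    rel_exons = [(s - region_start, e - region_start) for s, e in gene.exons]
    for (s1, e1), (s2, e2) in zip(rel_exons, rel_exons[1:]):
        donor_ref = seq[e1 : e1 + 2]
        acceptor_ref = seq[s2 - 2 : s2]
        donor_mut = edited[proj(e1) : proj(e1) + 2]
        acceptor_mut = edited[max(0, proj(s2) - 2) : proj(s2)]
        if donor_mut != donor_ref or acceptor_mut != acceptor_ref:
            splice_disrupted = True

    if gene.strand == "-":
        ref_cds, mut_cds = _revcomp(ref_cds), _revcomp(mut_cds)
    return _translate(ref_cds), _translate(mut_cds), splice_disrupted


def _footprint_cds_overlap(variant: VariantRecord, gene: GeneModel) -> bool:
    fs, fe = variant.footprint()
    return any(s < fe and e > fs for s, e in gene.cds)


def _net_cds_length_change(variant: VariantRecord, gene: GeneModel) -> int:
    p, lr, la = variant.pos0, len(variant.ref), len(variant.alt)
    net = 0
    for s, e in gene.cds:
        ps = _project_through_edit(s, p, lr, la)
        pe = _project_through_edit(e, p, lr, la)
        net += (pe - ps) - (e - s)
    return net


def _at_border(variant: VariantRecord, gene: GeneModel, pad: int = 1) -> bool:
    """Whether the edit footprint sits at the start codon, the stop
    codon or an exon-intron border (within ``pad`` bases)."""
    fs, fe = variant.footprint()
    fs, fe = fs - pad, fe + pad
    for s, e in gene.exons:
        if fs <= s <= fe or fs <= e <= fe:
            return True
    # terminal codons in genomic coordinates (approximated by the ends
    # of the terminal CDS segments; codons spanning a splice are rare)
    first_s, first_e = gene.cds[0]
    last_s, last_e = gene.cds[-1]
    left_codon = (first_s, min(first_s + 3, first_e))
    right_codon = (max(last_e - 3, last_s), last_e)
    for s, e in (left_codon, right_codon):
        if s < fe and e > fs:
            return True
    return False


def detect_pseudo_fs(variant: VariantRecord, gene: GeneModel, genome) -> PseudoCheck:
    """Audit one frameshift candidate.

    The verdict is decided by translate-and-compare: the call is a
    pseudo frameshift iff the mutant protein equals the reference
    protein.  A context tag explains pseudo calls; tags are assigned by
    priority (outside CDS after normalisation, then in-frame net CDS
    change, then border artifact, then the protein-unchanged catch-all).
    For incomplete gene models the verdict is withheld.
    """
    if variant.is_indel:
        variant = normalize_indel(variant, genome)
    if not gene.is_complete(genome):
        ref, mut, spl = mutant_protein(variant, gene, genome)
        return PseudoCheck(None, None, ref, mut, spl, withheld=True)
    ref, mut, spl = mutant_protein(variant, gene, genome)
    if mut != ref:
        return PseudoCheck("genuine_fs", None, ref, mut, spl)
    if not _footprint_cds_overlap(variant, gene):
        reason = "outside_cds_after_normalization"
    elif _net_cds_length_change(variant, gene) % 3 == 0:
        reason = "inframe_after_normalization"
    elif _at_border(variant, gene):
        reason = "border_artifact"
    else:
        reason = "protein_unchanged"
    return PseudoCheck("pseudo_fs", reason, ref, mut, spl)


def classify_protein_impact(
    ref_prot: str, mut_prot: str, terminus_fraction: float = 0.25
) -> str:
    """Classify a genuine frameshift by its effect on the protein.

    With ``d`` the first differing position, ``L`` and ``M`` the
    reference and mutant lengths: a mutant shorter than half the
    reference misses most of the protein; changes confined to the last
    (first) ``terminus_fraction`` of the protein are altered C- (N-)
    terminal; a longer mutant whose divergence starts in the C-terminal
    window carries a new, longer C-terminal sequence.
    """
    if not ref_prot or not mut_prot:
        raise ValueError("proteins must be non-empty")
    if ref_prot == mut_prot:
        return "minimal"
    L, M = len(ref_prot), len(mut_prot)
    d = next(
        (i for i, (a, b) in enumerate(zip(ref_prot, mut_prot)) if a != b),
        min(L, M),
    )
    c_window = (1.0 - terminus_fraction) * L
    if M < 0.5 * L:
        return "truncated_major"
    if M > L and d >= c_window:
        return "extended_C_terminal"
    if d >= c_window:
        return "altered_C_terminal"
    # N-terminal: a long common suffix with differences confined to the
    # first terminus_fraction of the protein
    suffix = 0
    while (
        suffix < min(L, M)
        and ref_prot[L - 1 - suffix] == mut_prot[M - 1 - suffix]
    ):
        suffix += 1
    if suffix >= c_window and max(L - suffix, M - suffix) <= terminus_fraction * L:
        return "altered_N_terminal"
    return "truncated_major"


# ---------------------------------------------------------------------
# the cascade


@dataclass(frozen=True)
class CascadeConfig:
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    apply_filters: bool = True
    expression_threshold: float = 200.0
    terminus_fraction: float = 0.25


def audit_candidates(pairs, genome, track: ExpressionTrack | None, config: CascadeConfig):
    """Run the staged audit over candidate (variant, gene) pairs."""
    records = []
    gene_max_cache: dict = {}
    gene_candidates: dict = {}
    for _, gene in pairs:
        gene_candidates[gene.gene_id] = gene_candidates.get(gene.gene_id, 0) + 1
    for variant, gene in pairs:
        rec = FSAuditRecord(variant=variant, gene_id=gene.gene_id)
        rec.stage_flags["is_fs_candidate"] = True
        if gene_candidates[gene.gene_id] > 1:
            rec.curation_note = "gene has multiple frameshift candidates"
        hom = is_homozygous_alt(variant)
        rec.stage_flags["is_homozygous"] = hom
        if not hom:
            records.append(rec)
            continue
        if gene.gene_id not in gene_max_cache:
            gene_max_cache[gene.gene_id] = track.gene_max(gene) if track else 0.0
        expressed = gene_max_cache[gene.gene_id] >= config.expression_threshold
        rec.stage_flags["is_expressed"] = expressed
        if not expressed:
            records.append(rec)
            continue
        check = detect_pseudo_fs(variant, gene, genome)
        rec.splice_disrupted = check.splice_disrupted
        rec.withheld = check.withheld
        rec.verdict = check.verdict
        rec.pseudo_reason = check.pseudo_reason
        rec.stage_flags["is_pseudo"] = check.verdict == "pseudo_fs"
        if check.verdict == "genuine_fs":
            rec.impact_class = classify_protein_impact(
                check.ref_protein, check.mut_protein, config.terminus_fraction
            )
        records.append(rec)
    return records


def cascade_table(records) -> pd.DataFrame:
    """Survivor counts per stage plus terminal-stage buckets."""
    n0 = len(records)
    n1 = sum(1 for r in records if r.stage_flags.get("is_homozygous"))
    n2 = sum(1 for r in records if r.stage_flags.get("is_expressed"))
    n3 = sum(1 for r in records if r.verdict == "genuine_fs")
    buckets: dict = {}
    for r in records:
        buckets[r.terminal_stage] = buckets.get(r.terminal_stage, 0) + 1
    df = pd.DataFrame(
        {"stage": list(CASCADE_STAGES), "survivors": [n0, n1, n2, n3]}
    )
    df.attrs["terminal_buckets"] = buckets
    return df


def run_cascade(
    vcf_path,
    gff_path,
    fasta_path,
    track_path=None,
    config: CascadeConfig | None = None,
    sample: str | None = None,
):
    """End-to-end audit from files.

    Reads and hard-filters the VCF, normalises indels, selects
    frameshift candidates against the gene models, and applies the
    cascade.  Returns ``(records, table)`` where the table carries the
    per-stage survivor counts.
    """
    config = config or CascadeConfig()
    genome = pyfaidx.Fasta(str(fasta_path))
    genes = load_gene_models(gff_path)
    track = (
        track_path
        if isinstance(track_path, ExpressionTrack)
        else ExpressionTrack.from_bedgraph(track_path)
        if track_path is not None
        else None
    )
    variants = []
    for rec in read_variants(vcf_path, sample):
        if config.apply_filters and not apply_hard_filters(rec, config.thresholds)[0]:
            continue
        variants.append(normalize_indel(rec, genome) if rec.is_indel else rec)
    pairs = fs_candidates(variants, genes)
    records = audit_candidates(pairs, genome, track, config)
    return records, cascade_table(records)


def records_to_dataframe(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "chrom": r.variant.chrom,
                "pos": r.variant.pos,
                "ref": r.variant.ref,
                "alt": r.variant.alt,
                "gene_id": r.gene_id,
                "genotype": r.variant.genotype,
                "is_homozygous": r.stage_flags.get("is_homozygous"),
                "is_expressed": r.stage_flags.get("is_expressed"),
                "verdict": r.verdict,
                "pseudo_reason": r.pseudo_reason,
                "impact_class": r.impact_class,
                "splice_disrupted": r.splice_disrupted,
                "terminal_stage": r.terminal_stage,
                "curation_note": r.curation_note,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# cross-accession sharing


def accession_matrix(audited, accession_vcfs: dict, genome) -> pd.DataFrame:
    """Presence/absence of the audited indels across other accessions.

    A cell is True iff the accession carries a normalised indel
    identical in (chrom, pos, ref, alt) to the audited variant —
    identity matching, not gene-level matching.  All VCFs must be
    against the same reference; a contig mismatch is an error.
    """
    from cyvcf2 import VCF

    audited = list(audited)
    needed_chroms = {r.variant.chrom for r in audited}
    columns = {}
    for accession, path in accession_vcfs.items():
        header_chroms = set(VCF(str(path)).seqnames)
        missing = needed_chroms - header_chroms
        if missing:
            raise ValueError(
                f"accession {accession!r} VCF lacks contigs {sorted(missing)}"
            )
        keys = set()
        for rec in read_variants(path):
            if rec.is_indel and rec.genotype != "hom_ref":
                keys.add(normalize_indel(rec, genome).key())
        columns[accession] = keys
    data = {
        accession: [r.variant.key() in keys for r in audited]
        for accession, keys in columns.items()
    }
    df = pd.DataFrame(data, index=[r.gene_id for r in audited])
    df.index.name = "gene_id"
    return df
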