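"""Reading, normalising, filtering and classifying VCF variant calls.

This module is the single source of truth for coordinate and genotype
semantics in the package.  Internally every record carries a 0-based
half-open start (``pos0``); the 1-based VCF position is exposed as the
``pos`` property and conversion happens only at the file boundary.

Hard filtering follows the usual GATK-style site-annotation thresholds
(depth, quality-by-depth, Fisher strand bias, mapping quality and the
two rank-sum statistics).  An annotation that is absent from a record
passes its filter, which is the conventional treatment of the rank-sum
fields (they are undefined for sites without both ref and alt reads).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

from cyvcf2 import VCF, Writer

logger = logging.getLogger(__name__)

ANNOTATION_KEYS = ("DP", "QD", "FS", "MQ", "ReadPosRankSum", "MQRankSum")

#: names of the hard filters, in the order they are evaluated
FILTER_NAMES = (
    "max_depth",
    "min_qd",
    "max_fisher_strand",
    "min_mq",
    "min_read_pos_rank_sum",
    "min_mq_rank_sum",
)


def classify_alleles(ref: str, alt: str) -> str:
    """Classify a ref/alt pair as ``snp``, ``insertion``, ``deletion`` or
    ``mnp_other``.

    Classification is done on the parsimony-trimmed pair: a shared suffix
    and then a shared prefix are removed, and the pair is an insertion
    (deletion) iff the trimmed ref (alt) is empty.
    """
    if len(ref) == 1 and len(alt) == 1:
        return "snp" if ref != alt else "mnp_other"
    r, a = ref, alt
    while len(r) > 0 and len(a) > 0 and r[-1] == a[-1] and (len(r) > 1 or len(a) > 1):
        r, a = r[:-1], a[:-1]
    while len(r) > 1 and len(a) > 1 and r[0] == a[0]:
        r, a = r[1:], a[1:]
    if len(r) < len(a) and (len(r) == 0 or (len(r) == 1 and a.startswith(r))):
        return "insertion"
    if len(a) < len(r) and (len(a) == 0 or (len(a) == 1 and r.startswith(a))):
        return "deletion"
    return "mnp_other"


@dataclass(frozen=True)
class VariantRecord:
    """One normalised variant call with site annotations and genotype.

    ``effects`` holds upstream effect-prediction tags as
    ``(effect, gene_id)`` pairs parsed from an ``ANN`` INFO field when an
    annotated VCF is read; the package emulates then audits those calls,
    it never generates them.
    """

    chrom: str
    pos0: int  # 0-based start of the REF allele
    ref: str
    alt: str
    genotype: str  # hom_ref | het | hom_alt | missing
    site_annotations: Mapping[str, float] = field(default_factory=dict)
    effects: tuple = ()

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.pos0 < 0:
            raise ValueError("pos0 must be >= 0")

    @property
    def pos(self) -> int:
        """1-based VCF position."""
        return self.pos0 + 1

    @property
    def var_class(self) -> str:
        return classify_alleles(self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return self.var_class in ("insertion", "deletion")

    @property
    def indel_length(self) -> int:
        """Signed length change (positive for insertions)."""
        return len(self.alt) - len(self.ref)

    def footprint(self) -> tuple:
        """0-based half-open interval covered by the REF allele."""
        return (self.pos0, self.pos0 + len(self.ref))

    def key(self) -> tuple:
        return (self.chrom, self.pos0, self.ref, self.alt)


@dataclass(frozen=True)
class FilterThresholds:
    """GATK-style hard-filter thresholds.

    The depth bound removes sites covered above ``max_depth`` (repeat
    collapse / mapping pile-ups); the remaining bounds are the canonical
    lower/upper limits on the site annotations.
    """

    max_depth: int = 100
    min_qd: float = 2.0
    max_fisher_strand: float = 60.0
    min_mq: float = 40.0
    min_read_pos_rank_sum: float = -8.0
    min_mq_rank_sum: float = -12.5

    def __post_init__(self):
        if self.max_depth <= 0:
            raise ValueError("max_depth must be positive")


def _genotype_for_alt(gt_indices, alt_index: int) -> str:
    alleles = [a for a in gt_indices if a is not None]
    if not alleles or all(a < 0 for a in alleles):
        return "missing"
    if any(a < 0 for a in alleles):
        # half-missing: treat by the called allele alone
        called = [a for a in alleles if a >= 0]
        return "hom_alt" if all(a == alt_index for a in called) else (
            "het" if alt_index in called else "hom_ref"
        )
    if all(a == alt_index for a in alleles):
        return "hom_alt"
    if alt_index in alleles:
        return "het"
    return "hom_ref"


def _parse_ann(info_ann: str, alt: str):
    """Parse a SnpEff-style ANN INFO string into (effect, gene_id) pairs
    for one alt allele.  Only the first four pipe-delimited fields are
    interpreted (allele | effect | impact | gene)."""
    out = []
    for entry in info_ann.split(","):
        fields = entry.split("|")
        if len(fields) < 4:
            continue
        if fields[0] and fields[0] != alt:
            continue
        out.append((fields[1], fields[3]))
    return tuple(out)


def read_variants(vcf_path, sample: str | None = None) -> Iterator[VariantRecord]:
    """Stream :class:`VariantRecord` objects from a VCF file.

    Multi-allelic sites are split into one record per alt allele, each
    inheriting the site annotations; records come out in file (chrom,
    pos) order.  ``sample`` defaults to the only sample in the file.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if sample is None:
        if len(samples) != 1:
            raise ValueError(
                f"sample must be given for multi-sample VCF; available: {samples}"
            )
        sample_index = 0
    else:
        if sample not in samples:
            raise ValueError(
                f"sample {sample!r} not found in {vcf_path}; available: {samples}"
            )
        sample_index = samples.index(sample)

    for i, v in enumerate(vcf):
        try:
            gt = v.genotypes[sample_index][:2] if v.genotypes else [-1, -1]
            annotations = {}
            for key in ANNOTATION_KEYS:
                val = v.INFO.get(key)
                if val is not None:
                    annotations[key] = float(val)
            ann = v.INFO.get("ANN")
            for alt_index, alt in enumerate(v.ALT, start=1):
                effects = _parse_ann(ann, alt) if ann else ()
                yield VariantRecord(
                    chrom=v.CHROM,
                    pos0=v.POS - 1,
                    ref=v.REF,
                    alt=alt,
                    genotype=_genotype_for_alt(gt, alt_index),
                    site_annotations=annotations,
                    effects=effects,
                )
        except ValueError:
            raise
        except Exception as exc:  # malformed record
            raise ValueError(f"malformed VCF record #{i + 1} in {vcf_path}: {exc}")


def apply_hard_filters(rec: VariantRecord, th: FilterThresholds | None = None):
    """Evaluate the hard filters on one record.

    Returns ``(passed, failed_names)``.  Absent annotations pass their
    filter.
    """
    th = th or FilterThresholds()
    ann = rec.site_annotations
    failed = []
    if "DP" in ann and ann["DP"] > th.max_depth:
        failed.append("max_depth")
    if "QD" in ann and ann["QD"] < th.min_qd:
        failed.append("min_qd")
    if "FS" in ann and ann["FS"] > th.max_fisher_strand:
        failed.append("max_fisher_strand")
    if "MQ" in ann and ann["MQ"] < th.min_mq:
        failed.append("min_mq")
    if "ReadPosRankSum" in ann and ann["ReadPosRankSum"] < th.min_read_pos_rank_sum:
        failed.append("min_read_pos_rank_sum")
    if "MQRankSum" in ann and ann["MQRankSum"] < th.min_mq_rank_sum:
        failed.append("min_mq_rank_sum")
    return (not failed, failed)


def is_homozygous_alt(rec: VariantRecord) -> bool:
    """True iff the genotype is hom-alt.

    Heterozygous calls in inbred parental lines are artifact candidates
    (sequencing / read-mapping errors) and are screened out of the
    frameshift audit; a ``missing`` genotype is logged and returns False.
    """
    if rec.genotype == "missing":
        logger.warning(
            "missing genotype at %s:%d treated as not homozygous", rec.chrom, rec.pos
        )
        return False
    return rec.genotype == "hom_alt"


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch ``genome[chrom][start:end]`` (0-based half-open) from either a
    ``pyfaidx.Fasta`` or a plain mapping of chromosome -> string."""
    start = max(0, start)
    seq = genome[chrom]
    if isinstance(seq, str):
        return seq[start:end]
    return str(seq[start:end]).upper()


def chromosome_length(genome, chrom: str) -> int:
    seq = genome[chrom]
    return len(seq) if isinstance(seq, str) else len(seq)


def normalize_indel(rec: VariantRecord, genome) -> VariantRecord:
    """Left-align and parsimony-trim an indel record.

    The allele pair is right-trimmed, left-extended through homopolymer /
    repeat context while the edit stays sequence-equivalent, and finally
    prefix-trimmed, following the standard variant-normalisation
    algorithm.  The returned record applies to the chromosome the exact
    same edit as the input.  Non-indels are returned unchanged.
    """
    if not rec.is_indel:
        return rec
    chrom, p, ref, alt = rec.chrom, rec.pos0, rec.ref, rec.alt
    observed = fetch_sequence(genome, chrom, p, p + len(ref))
    if observed != ref:
        raise ValueError(
            f"REF mismatch at {chrom}:{p + 1}: VCF says {ref!r}, genome has {observed!r}"
        )
    while True:
        if ref and alt and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if p == 0:  # cannot extend past the chromosome start
                    base = fetch_sequence(genome, chrom, 0, 1)
                    ref, alt = base + ref, base + alt
                    break
                p -= 1
                base = fetch_sequence(genome, chrom, p, p + 1)
                ref, alt = base + ref, base + alt
            continue
        break
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        p += 1
    if (p, ref, alt) == (rec.pos0, rec.ref, rec.alt):
        return rec
    return replace(rec, pos0=p, ref=ref, alt=alt)


def apply_edit(sequence: str, rec: VariantRecord) -> str:
    """Apply a variant to a chromosome string and return the edited
    sequence.  Used for sequence-equivalence checks."""
    p = rec.pos0
    if sequence[p : p + len(rec.ref)] != rec.ref:
        raise ValueError("REF allele disagrees with the sequence")
    return sequence[:p] + rec.alt + sequence[p + len(rec.ref) :]


def write_filtered_vcf(
    in_path,
    out_path,
    thresholds: FilterThresholds | None = None,
    sample: str | None = None,
) -> dict:
    """Annotate a VCF's FILTER column with the hard-filter outcome.

    Failing records get a semicolon-joined list of failed filter names;
    passing records get PASS.  Returns counts of passing/failing records.
    Filtering is site-level, so the per-alt genotype is irrelevant here.
    """
    th = thresholds or FilterThresholds()
    vcf = VCF(str(in_path))
    for name, desc in [
        ("max_depth", f"DP > {th.max_depth}"),
        ("min_qd", f"QD < {th.min_qd}"),
        ("max_fisher_strand", f"FS > {th.max_fisher_strand}"),
        ("min_mq", f"MQ < {th.min_mq}"),
        ("min_read_pos_rank_sum", f"ReadPosRankSum < {th.min_read_pos_rank_sum}"),
        ("min_mq_rank_sum", f"MQRankSum < {th.min_mq_rank_sum}"),
    ]:
        vcf.add_filter_to_header({"ID": name, "Description": desc})
    writer = Writer(str(out_path), vcf)
    n_pass = n_fail = 0
    for v in vcf:
        annotations = {}
        for key in ANNOTATION_KEYS:
            val = v.INFO.get(key)
            if val is not None:
                annotations[key] = float(val)
        probe = VariantRecord(
            chrom=v.CHROM, pos0=v.POS - 1, ref=v.REF, alt=v.ALT[0] if v.ALT else v.REF,
            genotype="hom_alt", site_annotations=annotations,
        )
        ok, failed = apply_hard_filters(probe, th)
        v.FILTER = "PASS" if ok else ";".join(failed)
        if ok:
            n_pass += 1
        else:
            n_fail += 1
        writer.write_record(v)
    writer.close()
    vcf.close()
    return {"pass": n_pass, "fail": n_fail}


def normalize_stream(
    variants: Iterable[VariantRecord], genome
) -> Iterator[VariantRecord]:
    """Normalise every indel in a stream, passing other records through."""
    for rec in variants:
        yield normalize_indel(rec, genome) if rec.is_indel else rec
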