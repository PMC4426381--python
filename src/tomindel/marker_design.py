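"""InDel-based PCR size markers for fine mapping.

Homozygous InDels of 10 bp and up can be scored as simple size
polymorphisms on a high-percentage agarose gel; this module selects
qualifying InDels, places an amplicon window around each, reports the
expected allele sizes, and flags flanks that would make primer design
awkward (low complexity or assembly gaps).  No thermodynamic primer
design is attempted — the flank sequences are exported verbatim for
external primer tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .variant_io import VariantRecord, chromosome_length, fetch_sequence


@dataclass(frozen=True)
class MarkerCandidate:
    variant: VariantRecord
    chrom: str
    amplicon_start: int  # 0-based half-open, on the reference
    amplicon_end: int
    expected_size_ref: int
    expected_size_alt: int
    flank_quality: str  # ok | low_complexity | near_gap

    @property
    def size_difference(self) -> int:
        return abs(self.expected_size_ref - self.expected_size_alt)

    @property
    def resolvable(self) -> bool:
        return gel_resolvable(self.expected_size_ref, self.expected_size_alt)


def select_marker_indels(
    variants,
    region: tuple | None = None,
    min_size: int = 10,
    max_size: int = 350,
    require_hom: bool = True,
) -> list:
    """Keep indels with ``min_size <= |length change| <= max_size``,
    homozygous when required, inside ``region`` (chrom, start, end)
    when given; sorted by position."""
    out = []
    for rec in variants:
        if not rec.is_indel:
            continue
        size = abs(rec.indel_length)
        if not (min_size <= size <= max_size):
            continue
        if require_hom and rec.genotype != "hom_alt":
            continue
        if region is not None:
            chrom, start, end = region
            if rec.chrom != chrom or not (start <= rec.pos0 < end):
                continue
        out.append(rec)
    return sorted(out, key=lambda r: (r.chrom, r.pos0))


def _flank_quality(left: str, right: str) -> str:
    for flank in (left, right):
        if "N" in flank:
            return "near_gap"
    for flank in (left, right):
        if flank and max(flank.count(b) for b in "ACGT") > 0.8 * len(flank):
            return "low_complexity"
    return "ok"


def design_amplicon(
    variant: VariantRecord,
    genome,
    target_amplicon: int = 150,
    flank_min: int = 30,
) -> MarkerCandidate:
    """Centre an amplicon of roughly ``target_amplicon`` bp on the indel.

    The reference allele size is the amplicon length on the reference;
    the alt allele size differs by the signed indel length.  Errors if
    the indel sits within ``flank_min`` of a contig end.
    """
    fs, fe = variant.footprint()
    chrom_len = chromosome_length(genome, variant.chrom)
    foot_len = fe - fs
    total = max(target_amplicon, foot_len + 2 * flank_min)
    pad = (total - foot_len) // 2
    start = fs - pad
    end = fe + (total - foot_len - pad)
    if start < 0 or end > chrom_len:
        raise ValueError(
            f"indel at {variant.chrom}:{variant.pos} is within {flank_min} bp "
            "of a contig end; no amplicon possible"
        )
    left = fetch_sequence(genome, variant.chrom, start, fs)
    right = fetch_sequence(genome, variant.chrom, fe, end)
    size_ref = end - start
    return MarkerCandidate(
        variant=variant,
        chrom=variant.chrom,
        amplicon_start=start,
        amplicon_end=end,
        expected_size_ref=size_ref,
        expected_size_alt=size_ref + variant.indel_length,
        flank_quality=_flank_quality(left, right),
    )


def gel_resolvable(
    size_a: int, size_b: int, min_diff: int = 10, max_product: int = 500
) -> bool:
    """Whether two allele products separate on a high-percentage agarose
    gel: at least ``min_diff`` bp apart and both under ``max_product``."""
    if size_a <= 0 or size_b <= 0:
        raise ValueError("sizes must be positive")
    return abs(size_a - size_b) >= min_diff and max(size_a, size_b) <= max_product


def design_markers(
    variants,
    genome,
    region: tuple | None = None,
    min_size: int = 10,
    max_size: int = 350,
    require_hom: bool = True,
    target_amplicon: int = 150,
    flank_min: int = 30,
    min_diff: int = 10,
    max_product: int = 500,
) -> list:
    """Select qualifying indels and emit gel-resolvable marker
    candidates; every emitted candidate satisfies ``gel_resolvable``
    under the active configuration."""
    markers = []
    for rec in select_marker_indels(variants, region, min_size, max_size, require_hom):
        try:
            cand = design_amplicon(rec, genome, target_amplicon, flank_min)
        except ValueError:
            continue
        if gel_resolvable(
            cand.expected_size_ref, cand.expected_size_alt, min_diff, max_product
        ):
            markers.append(cand)
    return markers


def markers_to_dataframe(markers) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [m.chrom for m in markers],
            "pos": [m.variant.pos for m in markers],
            "ref": [m.variant.ref for m in markers],
            "alt": [m.variant.alt for m in markers],
            "amplicon_start": [m.amplicon_start for m in markers],
            "amplicon_end": [m.amplicon_end for m in markers],
            "expected_size_ref": [m.expected_size_ref for m in markers],
            "expected_size_alt": [m.expected_size_alt for m in markers],
            "size_difference": [m.size_difference for m in markers],
            "flank_quality": [m.flank_quality for m in markers],
        }
    )


def write_amplicon_bed(markers, path) -> None:
    with open(path, "w") as fh:
        for m in markers:
            fh.write(
                f"{m.chrom}\t{m.amplicon_start}\t{m.amplicon_end}\t"
                f"marker_{m.chrom}_{m.variant.pos}\n"
            )


def write_flank_fasta(markers, genome, path) -> None:
    """Flank sequences, verbatim, for external primer design tools."""
    with open(path, "w") as fh:
        for m in markers:
            fs, fe = m.variant.footprint()
            left = fetch_sequence(genome, m.chrom, m.amplicon_start, fs)
            right = fetch_sequence(genome, m.chrom, fe, m.amplicon_end)
            name = f"marker_{m.chrom}_{m.variant.pos}"
            fh.write(f">{name}_left\n{left}\n>{name}_right\n{right}\n")
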