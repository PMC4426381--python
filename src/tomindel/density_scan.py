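"""Windowed polymorphism densities on a fixed genomic grid.

Windows are fixed, non-overlapping, anchored at coordinate 0 (the last
window of a chromosome may be short).  A variant belongs to exactly one
window, by its (normalised) start position, so window counts sum
exactly to the input counts at every grid size and a 1-Mb window count
equals the sum of its two 0.5-Mb halves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .variant_io import chromosome_length, fetch_sequence

MB = 1_000_000


@dataclass(frozen=True)
class WindowStat:
    """Per-window counts on the fixed grid.

    ``gene_count`` is computed on the 0.5-Mb subgrid and reported per
    window as the max over the halves it contains; ``gap_fraction`` is
    the fraction of window bases that are N in the reference assembly.
    """

    chrom: str
    start: int
    end: int
    snp_count: int = 0
    indel_count: int = 0
    gene_count: int = 0
    gap_fraction: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start

    def snp_per_mb(self) -> float:
        return self.snp_count / (self.length / MB)

    def indel_per_mb(self) -> float:
        return self.indel_count / (self.length / MB)

    def is_gap(self, threshold: float = 0.5) -> bool:
        return self.gap_fraction > threshold


@dataclass(frozen=True)
class ChromDensity:
    chrom: str
    snp_per_bp: float
    indel_per_bp: float
    relative_snp: float = 1.0
    relative_indel: float = 1.0


def _grid(chrom_lengths: dict, window_size: int):
    for chrom, length in chrom_lengths.items():
        for start in range(0, length, window_size):
            yield chrom, start, min(start + window_size, length)


def window_counts(
    variants,
    chrom_lengths: dict,
    window_size: int = MB,
    include_het: bool = True,
) -> list:
    """Count SNPs and InDels per fixed window.

    ``include_het`` keeps heterozygous calls in the tallies (density
    scans usually want them; the frameshift audit does not).  Missing
    genotypes are never counted.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    n_windows = {c: (l + window_size - 1) // window_size for c, l in chrom_lengths.items()}
    snp = {c: np.zeros(n, dtype=np.int64) for c, n in n_windows.items()}
    indel = {c: np.zeros(n, dtype=np.int64) for c, n in n_windows.items()}
    for rec in variants:
        if rec.chrom not in chrom_lengths:
            raise ValueError(
                f"variant on unknown chromosome {rec.chrom!r}; "
                f"known: {sorted(chrom_lengths)}"
            )
        if rec.genotype == "missing":
            continue
        if not include_het and rec.genotype == "het":
            continue
        w = rec.pos0 // window_size
        cls = rec.var_class
        if cls == "snp":
            snp[rec.chrom][w] += 1
        elif cls in ("insertion", "deletion"):
            indel[rec.chrom][w] += 1
    stats = []
    for chrom, start, end in _grid(chrom_lengths, window_size):
        w = start // window_size
        stats.append(
            WindowStat(chrom, start, end, int(snp[chrom][w]), int(indel[chrom][w]))
        )
    return stats


def chromosome_relative_density(variants, chrom_lengths: dict) -> list:
    """Per-chromosome linear densities, expressed relative to the
    chromosome with the maximum density (ties broken by chromosome
    order, so exactly one chromosome carries 1.0)."""
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"zero-length chromosome {chrom!r}")
    snp = {c: 0 for c in chrom_lengths}
    indel = {c: 0 for c in chrom_lengths}
    n = 0
    for rec in variants:
        if rec.chrom not in chrom_lengths:
            raise ValueError(f"variant on unknown chromosome {rec.chrom!r}")
        n += 1
        cls = rec.var_class
        if cls == "snp":
            snp[rec.chrom] += 1
        elif cls in ("insertion", "deletion"):
            indel[rec.chrom] += 1
    if n == 0:
        raise ValueError("at least one variant is required")
    out = []
    snp_density = {c: snp[c] / chrom_lengths[c] for c in chrom_lengths}
    indel_density = {c: indel[c] / chrom_lengths[c] for c in chrom_lengths}
    max_snp = max(snp_density.values()) or 1.0
    max_indel = max(indel_density.values()) or 1.0
    for chrom in chrom_lengths:
        out.append(
            ChromDensity(
                chrom=chrom,
                snp_per_bp=snp_density[chrom],
                indel_per_bp=indel_density[chrom],
                relative_snp=snp_density[chrom] / max_snp,
                relative_indel=indel_density[chrom] / max_indel,
            )
        )
    return out


def gene_rich_windows(genes, window_size: int = 500_000, min_genes: int = 50):
    """Windows with strictly more than ``min_genes`` gene starts.

    Membership is by gene start so no gene is counted twice.  Returns a
    set of (chrom, window_start) pairs.
    """
    counts = {}
    for g in genes:
        key = (g.chrom, (g.start // window_size) * window_size)
        counts[key] = counts.get(key, 0) + 1
    return {key for key, n in counts.items() if n > min_genes}


def gap_windows(genome, chrom_lengths: dict, window_size: int = MB, flag_threshold: float = 0.5):
    """Per-window N-base fraction, flagging windows above the threshold
    so zero-count windows over assembly gaps are explained rather than
    read as conserved sequence.

    Returns a list of (chrom, start, end, gap_fraction, flagged).
    """
    out = []
    for chrom, start, end in _grid(chrom_lengths, window_size):
        seq = fetch_sequence(genome, chrom, start, end)
        frac = seq.count("N") / (end - start)
        out.append((chrom, start, end, frac, frac > flag_threshold))
    return out


def build_window_stats(
    variants,
    chrom_lengths: dict,
    genome=None,
    genes=None,
    window_size: int = MB,
    include_het: bool = True,
) -> list:
    """Full per-window table: variant counts plus gene counts (max of
    the 0.5-Mb halves) and gap fractions when a genome is supplied."""
    stats = window_counts(variants, chrom_lengths, window_size, include_het)
    half = max(1, window_size // 2)
    gene_half = {}
    if genes:
        for g in genes:
            key = (g.chrom, (g.start // half) * half)
            gene_half[key] = gene_half.get(key, 0) + 1
    out = []
    for st in stats:
        gene_count = max(
            gene_half.get((st.chrom, h), 0) for h in range(st.start, st.end, half)
        ) if genes else 0
        gap_fraction = 0.0
        if genome is not None:
            seq = fetch_sequence(genome, st.chrom, st.start, st.end)
            gap_fraction = seq.count("N") / st.length
        out.append(replace(st, gene_count=gene_count, gap_fraction=gap_fraction))
    return out


def chrom_lengths_from_genome(genome) -> dict:
    return {chrom: chromosome_length(genome, chrom) for chrom in list(genome.keys())}


# -- tabular / file output ---------------------------------------------


def stats_to_dataframe(stats) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in stats],
            "start": [s.start for s in stats],
            "end": [s.end for s in stats],
            "snp_count": [s.snp_count for s in stats],
            "indel_count": [s.indel_count for s in stats],
            "gene_count": [s.gene_count for s in stats],
            "gap_fraction": [s.gap_fraction for s in stats],
        }
    )


def densities_to_dataframe(densities) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [d.chrom for d in densities],
            "snp_per_bp": [d.snp_per_bp for d in densities],
            "indel_per_bp": [d.indel_per_bp for d in densities],
            "relative_snp": [d.relative_snp for d in densities],
            "relative_indel": [d.relative_indel for d in densities],
        }
    )


def write_window_bed(stats, path) -> None:
    """BED4 with the SNP count in the name column."""
    with open(path, "w") as fh:
        for s in stats:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.snp_count}\n")


def plot_density(stats, path, value: str = "snp_count") -> None:
    """One panel per chromosome of windowed counts (quick-look plot)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = stats_to_dataframe(stats)
    chroms = list(dict.fromkeys(df["chrom"]))
    fig, axes = plt.subplots(len(chroms), 1, figsize=(8, 2 * len(chroms)), squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = df[df["chrom"] == chrom]
        ax.plot(sub["start"] / MB, sub[value], drawstyle="steps-post")
        ax.set_ylabel(chrom)
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
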