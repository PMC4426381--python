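"""High-density segment calling and cross-line introgression classes.

Two parental lines mapped to a common reference leave four window-level
signatures over a candidate region:

* ``lineB_divergent``   — only the high-divergence line (wild parent) is
  elevated above its own background: an ancestral introgression whose
  donor is divergent from that line, or locally deeper divergence.
* ``lineA_specific``    — only the low-divergence line is elevated: an
  introgression specific to that parent.
* ``reference_divergent`` — both lines are far above background, i.e. the
  reference assembly itself carries a divergent introgression there.
* ``reference_from_wild`` — the low-divergence line is elevated while the
  high-divergence line is at (or below) its genome-wide floor: the
  reference carries an introgression from the wild species, so the wild
  parent matches it almost perfectly.

Classification is window-count based; per-line background medians set
the "elevated" and "floor" levels.  A third line, when available, is
recorded as concordant or not but never changes the class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .density_scan import WindowStat

PATTERN_CLASSES = (
    "lineB_divergent",
    "lineA_specific",
    "reference_divergent",
    "reference_from_wild",
)


@dataclass(frozen=True)
class RawSegment:
    """A maximal merged run of qualifying windows from one line."""

    chrom: str
    start: int
    end: int
    windows: tuple  # member WindowStat objects (qualifying seeds)

    def mean_snp_per_mb(self) -> float:
        return float(np.mean([w.snp_per_mb() for w in self.windows]))


@dataclass(frozen=True)
class IntrogressionSegment:
    chrom: str
    start: int
    end: int
    mean_density_per_line: dict
    pattern_class: str
    support: tuple = ()
    third_line_concordant: bool | None = None
    position_jaccard: float | None = None
    note: str = ""


def call_dense_segments(
    stats,
    high_threshold: float,
    merge_gap: int = 1,
    gap_fraction_threshold: float = 0.5,
) -> list:
    """Seed on windows with SNP density >= ``high_threshold`` (SNPs/Mb)
    and merge seed runs separated by at most ``merge_gap`` intervening
    windows.  Gap-flagged windows never seed, and any intervening run of
    them longer than ``merge_gap`` breaks a segment."""
    by_chrom = {}
    for w in stats:
        by_chrom.setdefault(w.chrom, []).append(w)
    segments = []
    for chrom, windows in by_chrom.items():
        windows = sorted(windows, key=lambda w: w.start)
        seeds = [
            i
            for i, w in enumerate(windows)
            if not w.is_gap(gap_fraction_threshold) and w.snp_per_mb() >= high_threshold
        ]
        if not seeds:
            continue
        run = [seeds[0]]
        runs = []
        for i in seeds[1:]:
            if i - run[-1] - 1 <= merge_gap:
                run.append(i)
            else:
                runs.append(run)
                run = [i]
        runs.append(run)
        for run in runs:
            members = tuple(windows[i] for i in range(run[0], run[-1] + 1))
            segments.append(
                RawSegment(
                    chrom=chrom,
                    start=windows[run[0]].start,
                    end=windows[run[-1]].end,
                    windows=tuple(windows[i] for i in run),
                )
            )
    return segments


def _check_same_grid(stats_by_line: dict) -> None:
    grids = {
        line: tuple((w.chrom, w.start, w.end) for w in sorted(s, key=lambda w: (w.chrom, w.start)))
        for line, s in stats_by_line.items()
    }
    first = None
    for line, grid in grids.items():
        if first is None:
            first = grid
        elif grid != first:
            raise ValueError(f"window grid of line {line!r} does not match")


def _line_median(stats, gap_fraction_threshold: float = 0.5) -> float:
    dens = [w.snp_per_mb() for w in stats if not w.is_gap(gap_fraction_threshold)]
    return float(np.median(dens)) if dens else 0.0


def _merge_footprints(segments) -> list:
    by_chrom = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append((seg.start, seg.end))
    merged = []
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return sorted(merged)


def classify_segments(
    segments_by_line: dict,
    stats_by_line: dict,
    line_a: str,
    line_b: str,
    high_threshold_a: float = 5000.0,
    high_factor_b: float = 2.0,
    low_factor: float = 0.1,
    gap_fraction_threshold: float = 0.5,
    variants_by_line: dict | None = None,
) -> list:
    """Classify the union of per-line segment footprints.

    ``line_a`` is the low-divergence parent (its elevation threshold is
    an absolute SNPs/Mb anchor), ``line_b`` the high-divergence parent
    (elevated means >= ``high_factor_b`` x its genome-wide median;
    "floor" means <= ``low_factor`` x median).
    """
    _check_same_grid(stats_by_line)
    med_b = _line_median(stats_by_line[line_b], gap_fraction_threshold)
    windows_by_line = {
        line: sorted(s, key=lambda w: (w.chrom, w.start))
        for line, s in stats_by_line.items()
    }
    out = []
    all_segments = [s for segs in segments_by_line.values() for s in segs]
    for chrom, start, end in _merge_footprints(all_segments):
        means = {}
        support = ()
        for line, windows in windows_by_line.items():
            members = [
                w
                for w in windows
                if w.chrom == chrom
                and w.start < end
                and w.end > start
                and not w.is_gap(gap_fraction_threshold)
            ]
            means[line] = (
                float(np.mean([w.snp_per_mb() for w in members])) if members else 0.0
            )
            if line == line_a:
                support = tuple(members)
        a_high = means[line_a] >= high_threshold_a
        b_high = med_b > 0 and means[line_b] >= high_factor_b * med_b
        b_floor = means[line_b] <= low_factor * med_b
        note = ""
        if a_high and b_floor:
            cls = "reference_from_wild"
        elif a_high and b_high:
            cls = "reference_divergent"
            note = (
                "both lines elevated: reference carries a divergent segment, or an "
                "introgression arose in one line and moved to the other"
            )
        elif a_high:
            cls = "lineA_specific"
        else:
            cls = "lineB_divergent"
        jaccard = None
        if variants_by_line is not None:
            sets = []
            for line in (line_a, line_b):
                sets.append(
                    {
                        v.pos0
                        for v in variants_by_line.get(line, ())
                        if v.chrom == chrom and start <= v.pos0 < end
                    }
                )
            union = sets[0] | sets[1]
            jaccard = len(sets[0] & sets[1]) / len(union) if union else 0.0
        out.append(
            IntrogressionSegment(
                chrom=chrom,
                start=start,
                end=end,
                mean_density_per_line=means,
                pattern_class=cls,
                support=support,
                position_jaccard=jaccard,
                note=note,
            )
        )
    return out


def third_line_concordance(
    segment: IntrogressionSegment,
    third_stats,
    high_threshold: float = 5000.0,
    gap_fraction_threshold: float = 0.5,
) -> bool:
    """True iff the third line is elevated over at least half of the
    segment's windows.  Recorded as supporting evidence only."""
    members = [
        w
        for w in third_stats
        if w.chrom == segment.chrom and w.start < segment.end and w.end > segment.start
    ]
    if not members:
        return False
    elevated = sum(
        1
        for w in members
        if not w.is_gap(gap_fraction_threshold) and w.snp_per_mb() >= high_threshold
    )
    return elevated >= len(members) / 2


def segments_to_dataframe(segments) -> pd.DataFrame:
    rows = []
    for s in segments:
        row = {
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "pattern_class": s.pattern_class,
            "third_line_concordant": s.third_line_concordant,
            "position_jaccard": s.position_jaccard,
            "note": s.note,
        }
        for line, dens in s.mean_density_per_line.items():
            row[f"density_{line}"] = dens
        rows.append(row)
    return pd.DataFrame(rows)


def write_segments_bed(segments, path, line_for_score: str | None = None) -> None:
    """BED6: name = pattern class, score = mean density of one line
    (clamped to the BED 0-1000 range)."""
    with open(path, "w") as fh:
        for s in segments:
            dens = 0.0
            if line_for_score and line_for_score in s.mean_density_per_line:
                dens = s.mean_density_per_line[line_for_score]
            elif s.mean_density_per_line:
                dens = max(s.mean_density_per_line.values())
            score = int(min(1000, dens / 10))
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.pattern_class}\t{score}\t.\n"
            )
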