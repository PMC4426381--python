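"""RNA-seq coverage tracks and the expression screen.

The paper-style rule is a relative-maximum threshold: a gene whose
maximum coverage over its exons stays below the threshold (default 200)
is classified as having nondetectable expression and is dropped from
the frameshift audit.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ExpressionTrack:
    """Per-interval coverage values by chromosome (bedGraph dialect).

    Intervals are 0-based half-open and assumed non-overlapping per
    chromosome, as bedGraph guarantees.
    """

    def __init__(self, intervals: dict):
        # intervals: chrom -> (starts, ends, values) numpy arrays sorted by start
        self._ivs = {}
        for chrom, (starts, ends, values) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            if np.any(values < 0):
                raise ValueError("coverage values must be non-negative")
            order = np.argsort(starts, kind="stable")
            self._ivs[chrom] = (starts[order], ends[order], values[order])

    @classmethod
    def from_bedgraph(cls, path) -> "ExpressionTrack":
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        grouped = {
            chrom: (sub["start"].to_numpy(), sub["end"].to_numpy(), sub["value"].to_numpy())
            for chrom, sub in df.groupby("chrom", sort=False)
        }
        return cls(grouped)

    def max_over(self, chrom: str, intervals) -> float:
        """Maximum coverage over a set of 0-based half-open intervals
        (0.0 where the track has no data)."""
        if chrom not in self._ivs:
            return 0.0
        starts, ends, values = self._ivs[chrom]
        best = 0.0
        for qs, qe in intervals:
            i0 = np.searchsorted(ends, qs, side="right")
            i1 = np.searchsorted(starts, qe, side="left")
            if i1 > i0:
                best = max(best, float(values[i0:i1].max()))
        return best

    def gene_max(self, gene) -> float:
        return self.max_over(gene.chrom, gene.exons)


def expression_filter(gene_ids, genes_by_id, track: ExpressionTrack, threshold: float = 200.0):
    """Return the subset of ``gene_ids`` with detectable expression.

    A gene is kept iff its maximum exon coverage is >= ``threshold``
    (the "<threshold -> nondetectable" reading, so the threshold value
    itself passes).  Genes missing from the track are treated as zero
    coverage with a warning.
    """
    kept = set()
    for gid in gene_ids:
        gene = genes_by_id.get(gid)
        if gene is None:
            logger.warning("gene %s has no model; treated as unexpressed", gid)
            continue
        if track.gene_max(gene) >= threshold:
            kept.add(gid)
    return kept
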