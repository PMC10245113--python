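"""Interval algebra: buffer, merge, combine and summarize mask candidates.

Candidate intervals come from four detection methods (RepeatMasker rRNA
annotations, whole-reference BLAT hits, the fragment scan, and satellite
"rDNA" annotations). Each source is extended by a buffer flank — 100 nt
for annotation-derived sources, 500 nt for fragment-scan runs — and the
pooled set is merged into a final nonredundant list of mask intervals.
Book-ended intervals merge (distance-0 semantics, as bedtools/Galaxy
Merge default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .seqio import GenomicInterval, Source

__all__ = [
    "MaskReport",
    "extend_intervals",
    "merge_intervals",
    "combine_sources",
    "summarize",
]

#: Buffer flank (nt) per detection source.
DEFAULT_FLANKS = {
    Source.ANNOT_RMSK: 100,
    Source.BLAT: 100,
    Source.SATELLITE: 100,
    Source.USER: 100,
    Source.FRAGSCAN: 500,
}


@dataclass
class MaskReport:
    """Summary statistics of a final merged mask set."""

    n_intervals: int
    min_len: int
    max_len: int
    mean_len: int
    median_len: int
    total_masked: int
    n_over_reflen: int
    ref_len: int
    per_chrom_masked: dict = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = [
            "metric\tvalue",
            f"n_intervals\t{self.n_intervals}",
            f"min_len\t{self.min_len}",
            f"max_len\t{self.max_len}",
            f"mean_len\t{self.mean_len}",
            f"median_len\t{self.median_len}",
            f"total_masked\t{self.total_masked}",
            f"n_over_reflen\t{self.n_over_reflen}",
            f"ref_len\t{self.ref_len}",
        ]
        for chrom, nt in self.per_chrom_masked.items():
            lines.append(f"masked:{chrom}\t{nt}")
        return "\n".join(lines) + "\n"

    def format_log(self) -> str:
        return (
            f"{self.n_intervals} intervals ranging from {self.min_len} nt to "
            f"{self.max_len} nt in length, with mean and median lengths of "
            f"{self.mean_len} nt and {self.median_len} nt; total masked "
            f"{self.total_masked} nt; {self.n_over_reflen} interval(s) longer "
            f"than the reference rDNA length ({self.ref_len} nt)"
        )


def extend_intervals(
    intervals: list[GenomicInterval],
    flank: int,
    chrom_sizes: dict[str, int],
) -> list[GenomicInterval]:
    """Add a buffer of ``flank`` nt on both sides, clipped to the chromosome."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out = []
    for iv in intervals:
        if iv.chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {iv.chrom!r} (not in chrom.sizes)")
        out.append(
            GenomicInterval(
                iv.chrom,
                max(0, iv.start - flank),
                min(chrom_sizes[iv.chrom], iv.end + flank),
                iv.sources,
                iv.name,
            )
        )
    return out


def merge_intervals(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Coalesce overlapping and book-ended intervals into a nonredundant set.

    Output is sorted by (chrom, start), pairwise disjoint with positive
    gaps; a merged interval carries the union of its members' source tags.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        cur_sources = set(ivs[0].sources)
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or book-ended
                cur_end = max(cur_end, iv.end)
                cur_sources |= iv.sources
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end, frozenset(cur_sources)))
                cur_start, cur_end, cur_sources = iv.start, iv.end, set(iv.sources)
        merged.append(GenomicInterval(chrom, cur_start, cur_end, frozenset(cur_sources)))
    return merged


def combine_sources(
    annot: list[GenomicInterval],
    blat: list[GenomicInterval],
    fragscan: list[GenomicInterval],
    satellite: list[GenomicInterval],
    chrom_sizes: dict[str, int],
    flank_annot: int = 100,
    flank_scan: int = 500,
) -> list[GenomicInterval]:
    """Buffer each source with its flank, pool, and merge.

    Annotation-derived sources (RepeatMasker rRNA, BLAT, satellite) get
    ``flank_annot`` nt; fragment-scan runs get ``flank_scan`` nt — scan run
    envelopes underestimate divergent copy boundaries, hence the wider
    buffer. Buffering happens before the cross-source merge.
    """
    pooled: list[GenomicInterval] = []
    for group, flank in (
        (annot, flank_annot),
        (blat, flank_annot),
        (satellite, flank_annot),
        (fragscan, flank_scan),
    ):
        if group:
            pooled.extend(extend_intervals(group, flank, chrom_sizes))
    if not pooled:
        return []
    return merge_intervals(pooled)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def summarize(intervals: list[GenomicInterval], ref_len: int) -> MaskReport:
    """Length statistics of a merged mask set.

    The median of an even-count set is the mean of the two middle values;
    mean and median are rounded half-up to integer nt. ``n_over_reflen``
    counts intervals longer than the rDNA reference — such intervals
    typically contain more than one rDNA copy.
    """
    if not intervals:
        return MaskReport(0, 0, 0, 0, 0, 0, 0, ref_len, {})
    lengths = sorted(iv.length for iv in intervals)
    n = len(lengths)
    if n % 2:
        median = float(lengths[n // 2])
    else:
        median = (lengths[n // 2 - 1] + lengths[n // 2]) / 2
    per_chrom: dict[str, int] = {}
    for iv in intervals:
        per_chrom[iv.chrom] = per_chrom.get(iv.chrom, 0) + iv.length
    return MaskReport(
        n_intervals=n,
        min_len=lengths[0],
        max_len=lengths[-1],
        mean_len=_round_half_up(sum(lengths) / n),
        median_len=_round_half_up(median),
        total_masked=sum(lengths),
        n_over_reflen=sum(1 for L in lengths if L > ref_len),
        ref_len=ref_len,
        per_chrom_masked=per_chrom,
    )
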