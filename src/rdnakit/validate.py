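"""Masking-adequacy verification and minimal coverage tracks.

After masking, the fragment scan is re-run on the masked assembly
(without chrR): adequate masking means no genomic stretch still supports
a run of consecutively mapping reference tiles. Two thresholds are
reported: the strict one used for pass/fail (a run of >= min_fragments
placements fails) and the looser "more than min_fragments" count, since
both phrasings circulate; the strict reading keeps verification
consistent with detection.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .homology_scan import RunCluster, ScanParams, detect_runs, find_tile_hits, tile_reference
from .seqio import Genome, GenomeSequence, GenomicInterval, Source

__all__ = ["VerificationReport", "verify_masking", "coverage_from_sam"]


@dataclass
class VerificationReport:
    """Outcome of re-scanning a masked assembly."""

    max_run: int  # largest number of adjacent placements observed anywhere
    n_failing_strict: int  # clusters with n_hits >= min_fragments
    n_failing_paper: int  # clusters with n_hits > min_fragments
    min_fragments: int
    passed: bool  # strict criterion
    failing_clusters: list = field(default_factory=list)

    @property
    def passed_paper_threshold(self) -> bool:
        return self.n_failing_paper == 0

    def failing_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval.of(c.chrom, c.start, c.end, Source.FRAGSCAN, f"residual_run_{i}")
            for i, c in enumerate(self.failing_clusters)
        ]

    def to_tsv(self) -> str:
        return (
            "metric\tvalue\n"
            f"max_run\t{self.max_run}\n"
            f"min_fragments\t{self.min_fragments}\n"
            f"n_failing_strict\t{self.n_failing_strict}\n"
            f"n_failing_paper\t{self.n_failing_paper}\n"
            f"pass_strict\t{self.passed}\n"
            f"pass_over_threshold\t{self.passed_paper_threshold}\n"
        )


def verify_masking(
    masked_genome: Genome,
    ref: GenomeSequence,
    params: ScanParams | None = None,
    chrR_name: str = "chrR",
) -> VerificationReport:
    """Re-scan a masked assembly and report residual rDNA-like runs.

    The genome must not contain chrR (it holds a verbatim reference copy
    and would trivially fail); drop it first with ``genome.drop("chrR")``.
    """
    params = params or ScanParams()
    if chrR_name in masked_genome:
        raise ValueError(
            f"{chrR_name!r} must be excluded before verification (genome.drop({chrR_name!r}))"
        )
    tiles = tile_reference(ref, params.tile_len, params.step)
    hits = find_tile_hits(masked_genome, tiles, params.max_hits_per_tile)
    # min_fragments=1 enumerates every run so the maximum is observable
    all_runs = detect_runs(hits, 1, params.join_gap)
    max_run = max((c.n_hits for c in all_runs), default=0)
    failing = [c for c in all_runs if c.n_hits >= params.min_fragments]
    over = [c for c in all_runs if c.n_hits > params.min_fragments]
    return VerificationReport(
        max_run=max_run,
        n_failing_strict=len(failing),
        n_failing_paper=len(over),
        min_fragments=params.min_fragments,
        passed=not failing,
        failing_clusters=failing,
    )


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("MDN=X")


def _aligned_ref_length(cigar: str, seq: str) -> int:
    if cigar == "*":
        return len(seq) if seq != "*" else 0
    return sum(int(n) for n, op in _CIGAR_RE.findall(cigar) if op in _REF_CONSUMING)


def coverage_from_sam(
    sam_path: str | Path, chrom_sizes: dict[str, int], bin: int = 1
) -> dict[str, np.ndarray]:
    """Per-base read depth per chromosome from a SAM file.

    Mapped primary and secondary records contribute their
    reference-consuming aligned span. ``bin > 1`` averages depth within
    consecutive bins (the vector then has ceil(len/bin) entries).
    """
    cov = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    with open(sam_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("@") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 11:
                raise ValueError(f"{sam_path}:{lineno}: SAM record has < 11 mandatory fields")
            flag = int(f[1])
            if flag & 0x4 or flag & 0x800:
                continue
            chrom, pos = f[2], int(f[3]) - 1
            if chrom not in cov:
                raise ValueError(f"{sam_path}:{lineno}: unknown chromosome {chrom!r}")
            span = _aligned_ref_length(f[5], f[9])
            if pos + span > chrom_sizes[chrom]:
                raise ValueError(
                    f"{sam_path}:{lineno}: alignment {chrom}:{pos}-{pos + span} "
                    f"beyond chromosome length {chrom_sizes[chrom]}"
                )
            cov[chrom][pos : pos + span] += 1
    if bin > 1:
        binned = {}
        for chrom, vec in cov.items():
            n_bins = -(-vec.size // bin)
            padded = np.pad(vec, (0, n_bins * bin - vec.size))
            binned[chrom] = padded.reshape(n_bins, bin).mean(axis=1)
        return binned
    return cov
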