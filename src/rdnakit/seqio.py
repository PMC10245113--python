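"""Readers, writers and the core coordinate model.

Formats handled: FASTA (read/write), BED3/6/9 (read/write), chrom.sizes
(read/write), SAM (import only, mandatory fields), PSL (import only),
bedGraph (export only).

All internal coordinates are 0-based half-open (BED convention). SAM's
1-based POS is converted on import; 1-based positions from Genbank-style
annotations (e.g. rDNA cut sites) are converted at the API boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class Source(Enum):
    """Which detection method produced an interval.

    ANNOT_RMSK: RepeatMasker rRNA annotations (LSU-rRNA / SSU-rRNA records).
    BLAT: whole-reference alignment hits imported from PSL.
    FRAGSCAN: 50-nt fragment tiling scan (run detection).
    SATELLITE: centromeric-satellite annotations titled "rDNA".
    USER: anything supplied directly by the user.
    """

    ANNOT_RMSK = "annot_rmsk"
    BLAT = "blat"
    FRAGSCAN = "fragscan"
    SATELLITE = "satellite"
    USER = "user"


_COMPLEMENT = str.maketrans("ACGTacgtNnRYKMBVDHrykmbvdh", "TGCAtgcaNnYRMKVBHDyrmkvbhd")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC aware, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """One named DNA sequence of an assembly or reference."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("sequence name must be non-empty")

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


class Genome:
    """An ordered collection of named sequences (a genome assembly).

    Order is preserved on round-trip; names are unique. ``chrom_sizes``
    always agrees with the stored sequences.
    """

    def __init__(self, sequences: Iterable[GenomeSequence] = ()) -> None:
        self._seqs: dict[str, GenomeSequence] = {}
        for s in sequences:
            self.add(s)

    def add(self, seq: GenomeSequence) -> None:
        if seq.name in self._seqs:
            raise ValueError(f"duplicate sequence name: {seq.name!r}")
        self._seqs[seq.name] = seq

    @property
    def sequences(self) -> list[GenomeSequence]:
        return list(self._seqs.values())

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(s) for name, s in self._seqs.items()}

    def __getitem__(self, name: str) -> GenomeSequence:
        return self._seqs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return [(s.name, s.seq) for s in self.sequences] == [
            (s.name, s.seq) for s in other.sequences
        ]

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences)

    def drop(self, name: str) -> "Genome":
        """A new Genome without the named sequence (original untouched)."""
        return Genome(s for s in self.sequences if s.name != name)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span tagged with the detection method(s) behind it."""

    chrom: str
    start: int
    end: int
    sources: frozenset = frozenset()
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @classmethod
    def of(
        cls,
        chrom: str,
        start: int,
        end: int,
        source: Source = Source.USER,
        name: str | None = None,
    ) -> "GenomicInterval":
        return cls(chrom, start, end, frozenset([source]), name)

    @property
    def source(self) -> Source | None:
        """The sole source tag, or None when several methods contributed."""
        if len(self.sources) == 1:
            return next(iter(self.sources))
        return None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class BedRecord:
    """BED9 superset of BED4/6 for annotation tracks."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: int = 0
    strand: str = "."
    thick_start: int | None = None
    thick_end: int | None = None
    item_rgb: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"BED record {self.chrom}:{self.start}-{self.end} has start >= end")
        if self.item_rgb is not None:
            parts = self.item_rgb.split(",")
            if len(parts) != 3 or not all(p.isdigit() and 0 <= int(p) <= 255 for p in parts):
                raise ValueError(f"itemRgb must be 'R,G,B' with 0-255 components: {self.item_rgb!r}")

    def to_line(self) -> str:
        fields = [self.chrom, str(self.start), str(self.end)]
        if self.item_rgb is not None:
            ts = self.thick_start if self.thick_start is not None else self.start
            te = self.thick_end if self.thick_end is not None else self.end
            fields += [self.name, str(self.score), self.strand, str(ts), str(te), self.item_rgb]
        elif self.strand != "." or self.score or self.name != ".":
            fields += [self.name, str(self.score), self.strand]
        return "\t".join(fields)


@dataclass(frozen=True)
class FragmentHit:
    """One genomic placement of a reference fragment tile."""

    tile_index: int
    chrom: str
    pos: int  # 0-based start
    strand: str  # '+' or '-'
    length: int = 50

    @property
    def end(self) -> int:
        return self.pos + self.length


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Genome:
    """Read a multi-record FASTA into a Genome.

    The name is the header token up to the first whitespace (aligner
    behaviour); case is preserved. Duplicate names or an empty file are
    errors.
    """
    genome = Genome()
    for rec in SeqIO.parse(str(path), "fasta"):
        genome.add(GenomeSequence(rec.id, str(rec.seq)))
    if len(genome) == 0:
        raise ValueError(f"no FASTA records found in {path}")
    return genome


def write_fasta(genome: Genome, path: str | Path, wrap: int = 60) -> None:
    """Write a Genome as FASTA with lines wrapped at ``wrap`` characters."""
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    records = [
        SeqRecord(Seq(s.seq), id=s.name, description="") for s in genome.sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# chrom.sizes
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{i}: expected 2 tab-separated columns")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def _parse_bed_line(line: str, lineno: int, path: str) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ValueError(f"{path}:{lineno}: BED needs >= 3 tab-separated columns")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
    if start >= end:
        raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
    return fields


def read_bed(
    path: str | Path,
    name_filter: Sequence[str] | None = None,
    source: Source = Source.USER,
) -> list[GenomicInterval]:
    """Read BED records as intervals, optionally keeping only records whose
    name column contains any of the ``name_filter`` substrings.

    This is how RepeatMasker-derived tracks are reduced to the rRNA records
    of interest (e.g. ``["LSU-rRNA", "SSU-rRNA"]``) and satellite tracks to
    the records titled "rDNA".
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _parse_bed_line(line, i, str(path))
            name = fields[3] if len(fields) > 3 else None
            if name_filter:
                if name is None or not any(term in name for term in name_filter):
                    continue
            intervals.append(
                GenomicInterval.of(fields[0], int(fields[1]), int(fields[2]), source, name)
            )
    return intervals


def read_bed_records(path: str | Path) -> list[BedRecord]:
    """Read BED as full records (annotation tracks, RefGene BEDs)."""
    records: list[BedRecord] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _parse_bed_line(line, i, str(path))
            records.append(
                BedRecord(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    name=f[3] if len(f) > 3 else ".",
                    score=int(float(f[4])) if len(f) > 4 and f[4] != "." else 0,
                    strand=f[5] if len(f) > 5 else ".",
                    thick_start=int(f[6]) if len(f) > 6 else None,
                    thick_end=int(f[7]) if len(f) > 7 else None,
                    item_rgb=f[8] if len(f) > 8 else None,
                )
            )
    return records


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED (4 columns; name column carries the source tags
    when the interval has no explicit name)."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name or "|".join(sorted(s.value for s in iv.sources)) or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def write_bed_records(records: Iterable[BedRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_line() + "\n")


# ---------------------------------------------------------------------------
# PSL (BLAT output)
# ---------------------------------------------------------------------------

def read_psl(path: str | Path, min_block_span: int = 0) -> list[GenomicInterval]:
    """Import BLAT alignments from PSL as target-span intervals.

    One interval per alignment (tStart..tEnd on the target sequence),
    tagged BLAT. Block-level structure is ignored: the whole matched span
    is a masking candidate. Alignments whose target span is shorter than
    ``min_block_span`` are dropped (default: keep everything).
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            # header lines: "psLayout ...", column titles, dashes
            if not fields[0].strip().isdigit():
                continue
            if len(fields) < 17:
                raise ValueError(f"{path}:{i}: malformed PSL line ({len(fields)} columns)")
            t_name, t_start, t_end = fields[13], int(fields[15]), int(fields[16])
            if t_end - t_start < min_block_span:
                continue
            intervals.append(GenomicInterval.of(t_name, t_start, t_end, Source.BLAT))
    return intervals


# ---------------------------------------------------------------------------
# SAM import (mandatory fields only)
# ---------------------------------------------------------------------------

_TILE_NAME_RE = re.compile(r"^tile_(\d+)$")

# SAM flag bits
FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


def default_tile_name_parser(name: str) -> int:
    """Parse the fixed read-name dialect ``tile_<k>`` (k = 0-based index)."""
    m = _TILE_NAME_RE.match(name)
    if not m:
        raise ValueError(f"cannot parse tile index from read name {name!r} (expected 'tile_<k>')")
    return int(m.group(1))


def read_sam_hits(
    path: str | Path,
    tile_name_parser: Callable[[str], int] = default_tile_name_parser,
) -> list[FragmentHit]:
    """Import fragment placements from an externally produced SAM file.

    Only the 11 mandatory text fields are consulted, so minimal and
    headerless SAM is accepted. Unmapped (0x4) and supplementary (0x800)
    records are dropped; secondary alignments (0x100) are kept, matching a
    multi-hit-reporting mapping run (bowtie2 -k style). POS is converted to
    0-based; strand comes from flag bit 0x10.
    """
    hits: list[FragmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("@") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: SAM record has < 11 mandatory fields")
            qname, flag_s, rname, pos_s = fields[0], fields[1], fields[2], fields[3]
            flag = int(flag_s)
            if flag & FLAG_UNMAPPED or flag & FLAG_SUPPLEMENTARY:
                continue
            tile_index = tile_name_parser(qname)
            seq = fields[9]
            length = len(seq) if seq != "*" else 50
            hits.append(
                FragmentHit(
                    tile_index=tile_index,
                    chrom=rname,
                    pos=int(pos_s) - 1,
                    strand="-" if flag & FLAG_REVERSE else "+",
                    length=length,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# bedGraph export
# ---------------------------------------------------------------------------

def write_bedgraph(coverage: dict, path: str | Path) -> None:
    """Run-length-encode per-base coverage vectors into 4-column bedGraph.

    Zero-coverage runs are omitted (an all-zero genome yields an empty
    file). Coordinates are 0-based half-open.
    """
    import numpy as np

    with open(path, "w") as fh:
        for chrom, vec in coverage.items():
            arr = np.asarray(vec)
            if arr.size == 0:
                continue
            if np.any(arr < 0):
                raise ValueError(f"negative coverage on {chrom}")
            # breakpoints where the value changes
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    val = int(v) if float(v).is_integer() else float(v)
                    fh.write(f"{chrom}\t{s}\t{e}\t{val}\n")


def read_bedgraph(path: str | Path, chrom_sizes: dict[str, int]) -> dict:
    """Expand a bedGraph back into per-base vectors (round-trip checking)."""
    import numpy as np

    cov = {c: np.zeros(n) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")
            cov[chrom][int(s):int(e)] = float(v)
    return cov
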