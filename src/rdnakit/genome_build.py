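"""Build the customized genome: mask, rotate, append chrR, annotate.

The rDNA reference sequences used in the field start at the rRNA
transcription start site and end with the Pol I promoter. Because the
unit is tandemly repeated in nucleolar organizer regions, its 3' end is
continuous with its 5' end, so the reference can be rotated: cutting
inside the intergenic spacer and transposing the downstream sequence
upstream of the TSS places the promoters ahead of the transcribed region,
which is the orientation wanted for browser tracks. The rotated sequence
is appended to the hard-masked assembly as chromosome R ("chrR").

Default cut positions (1-based, cut after the position): 35,500 for the
human KY962518.1 reference (44,838 nt) and 36,000 for the mouse
BK000964.3 reference (45,306 nt), placing ~10 kb (9,338 / 9,306 nt) of
IGS ahead of the promoters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .seqio import BedRecord, Genome, GenomeSequence, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureClass",
    "RdnaFeature",
    "RdnaReference",
    "CustomGenome",
    "CLASS_COLORS",
    "HUMAN_CUT_POS",
    "MOUSE_CUT_POS",
    "mask_fasta",
    "rotate_reference",
    "rotate_features",
    "append_chrR",
    "swap_refgene_ids",
    "emit_annotation_bed",
    "read_feature_table",
    "write_feature_table",
]

HUMAN_CUT_POS = 35_500  # KY962518.1
MOUSE_CUT_POS = 36_000  # BK000964.3


class FeatureClass(Enum):
    PROMOTER = "promoter"
    ETS = "ets"
    ITS = "its"
    MATURE_RRNA = "mature_rrna"
    IGS = "igs"
    TTF1_SITE = "ttf1_site"


#: Browser track colors: mature rRNAs yellow, transcribed spacers blue,
#: IGS gray, promoters cyan; TTF1 sites red (configurable per feature).
CLASS_COLORS = {
    FeatureClass.MATURE_RRNA: "255,255,0",
    FeatureClass.ETS: "0,0,255",
    FeatureClass.ITS: "0,0,255",
    FeatureClass.IGS: "128,128,128",
    FeatureClass.PROMOTER: "0,255,255",
    FeatureClass.TTF1_SITE: "255,0,0",
}


@dataclass(frozen=True)
class RdnaFeature:
    """One annotated segment of the rDNA repeat (0-based half-open)."""

    name: str
    feature_class: FeatureClass
    start: int
    end: int
    color: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"feature {self.name!r}: need 0 <= start < end")

    @property
    def rgb(self) -> str:
        return self.color or CLASS_COLORS[self.feature_class]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RdnaReference:
    """A full-length rDNA reference with its cut position and feature table.

    ``cut_pos`` is 1-based (Genbank style): the sequence is cut after that
    position and the suffix transposed to the front.
    """

    accession: str
    seq: str
    cut_pos: int
    features: list[RdnaFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= self.cut_pos <= len(self.seq):
            raise ValueError(
                f"cut_pos {self.cut_pos} outside reference [1, {len(self.seq)}]"
            )
        for f in self.features:
            if f.end > len(self.seq):
                raise ValueError(f"feature {f.name!r} extends past reference end")

    @property
    def length(self) -> int:
        return len(self.seq)

    def as_sequence(self) -> GenomeSequence:
        return GenomeSequence(self.accession, self.seq)

    def rotated_seq(self) -> str:
        return rotate_reference(self.seq, self.cut_pos)

    def rotated_features(self) -> list[RdnaFeature]:
        return rotate_features(self.features, self.cut_pos, len(self.seq))


class CustomGenome(Genome):
    """A masked assembly with chrR appended, carrying a build tag."""

    def __init__(self, sequences=(), build_tag: str = "") -> None:
        super().__init__(sequences)
        self.build_tag = build_tag


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

def mask_fasta(
    genome: Genome, intervals: list[GenomicInterval], mode: str = "hard"
) -> Genome:
    """Mask interval spans in the assembly (bedtools-maskfasta semantics).

    ``hard`` replaces bases with N; ``soft`` lowercases them. Bases outside
    the intervals are untouched and sequence lengths are unchanged.
    """
    if mode not in ("hard", "soft"):
        raise ValueError(f"mode must be 'hard' or 'soft', got {mode!r}")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        if iv.chrom not in genome:
            raise ValueError(f"interval on unknown chromosome {iv.chrom!r}")
        if iv.end > len(genome[iv.chrom]):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} extends past "
                f"chromosome end ({len(genome[iv.chrom])})"
            )
        by_chrom.setdefault(iv.chrom, []).append(iv)

    out = Genome()
    for cs in genome.sequences:
        if cs.name not in by_chrom:
            out.add(GenomeSequence(cs.name, cs.seq))
            continue
        buf = list(cs.seq)
        for iv in by_chrom[cs.name]:
            span = cs.seq[iv.start : iv.end]
            buf[iv.start : iv.end] = (
                "N" * iv.length if mode == "hard" else span.lower()
            )
        out.add(GenomeSequence(cs.name, "".join(buf)))
    return out


# ---------------------------------------------------------------------------
# Rotation
# ---------------------------------------------------------------------------

def rotate_reference(seq: str, cut_pos: int) -> str:
    """Cut after 1-based ``cut_pos`` and move the suffix to the front.

    rotate("ABCDEFGHIJ", 7) == "HIJABCDEFG"; cut_pos == len(seq) is the
    identity rotation. Length and base composition are preserved.
    """
    if not 1 <= cut_pos <= len(seq):
        raise ValueError(f"cut_pos {cut_pos} outside [1, {len(seq)}]")
    return seq[cut_pos:] + seq[:cut_pos]


def rotate_features(
    features: list[RdnaFeature], cut_pos: int, ref_len: int
) -> list[RdnaFeature]:
    """Remap feature coordinates through the rotation.

    0-based coordinates shift by (ref_len - cut_pos) modulo ref_len. A
    feature straddling the cut is split into two records suffixed
    "_p1"/"_p2" (in original 5'->3' order); their lengths sum to the
    original.
    """
    shift = ref_len - cut_pos
    out: list[RdnaFeature] = []
    for f in features:
        if f.end > ref_len:
            raise ValueError(f"feature {f.name!r} extends past reference ({ref_len} nt)")
        if f.start < cut_pos < f.end:
            # part before the cut lands at the end of chrR, part after at the front
            out.append(
                RdnaFeature(f.name + "_p1", f.feature_class, f.start + shift, ref_len, f.color)
            )
            out.append(
                RdnaFeature(f.name + "_p2", f.feature_class, 0, f.end - cut_pos, f.color)
            )
        else:
            ns = (f.start + shift) % ref_len
            out.append(RdnaFeature(f.name, f.feature_class, ns, ns + f.length, f.color))
    return out


def append_chrR(
    masked_genome: Genome,
    rotated_ref: str,
    name: str = "chrR",
    build_tag: str = "",
) -> CustomGenome:
    """Append the rotated rDNA reference as the last record of the genome."""
    if name in masked_genome:
        raise ValueError(f"genome already contains a sequence named {name!r}")
    custom = CustomGenome(
        (GenomeSequence(s.name, s.seq) for s in masked_genome.sequences),
        build_tag=build_tag,
    )
    custom.add(GenomeSequence(name, rotated_ref))
    return custom


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def swap_refgene_ids(
    bed: list[BedRecord], id_to_name: dict[str, str]
) -> list[BedRecord]:
    """Replace RefSeq NM_/NR_ IDs in the name column with gene names.

    IDs absent from the map are kept verbatim and logged.
    """
    out = []
    unmapped = []
    for rec in bed:
        name = id_to_name.get(rec.name)
        if name is None:
            if rec.name != "." and id_to_name:
                unmapped.append(rec.name)
            name = rec.name
        out.append(
            BedRecord(
                rec.chrom, rec.start, rec.end, name, rec.score, rec.strand,
                rec.thick_start, rec.thick_end, rec.item_rgb,
            )
        )
    if unmapped:
        logger.warning(
            "%d RefSeq ID(s) not in the ID->name map, kept verbatim: %s",
            len(unmapped),
            ", ".join(unmapped[:10]) + ("..." if len(unmapped) > 10 else ""),
        )
    return out


def emit_annotation_bed(
    custom_genome: Genome,
    rotated_features: list[RdnaFeature],
    refgene_bed: list[BedRecord] | None = None,
    chrR_name: str = "chrR",
) -> list[BedRecord]:
    """Combine RefGene records with chrR feature annotations as BED9.

    chrR features get itemRgb from the class color scheme (mature rRNAs
    yellow, transcribed spacers blue, IGS gray, promoters cyan).
    """
    if chrR_name not in custom_genome:
        raise ValueError(f"{chrR_name!r} not present in the custom genome")
    chrR_len = len(custom_genome[chrR_name])
    records: list[BedRecord] = list(refgene_bed or [])
    for f in rotated_features:
        if f.end > chrR_len:
            raise ValueError(
                f"feature {f.name!r} ({f.start}-{f.end}) beyond {chrR_name} length {chrR_len}"
            )
        records.append(
            BedRecord(
                chrom=chrR_name,
                start=f.start,
                end=f.end,
                name=f.name,
                score=0,
                strand="+",
                thick_start=f.start,
                thick_end=f.end,
                item_rgb=f.rgb,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Feature-table config (TSV: name, class, start, end [, color])
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path) -> list[RdnaFeature]:
    """Read an rDNA feature table (TSV, original reference coordinates,
    0-based half-open; columns name, class, start, end, optional R,G,B)."""
    features = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{i}: feature table needs >= 4 columns")
            try:
                fclass = FeatureClass(f[1].strip().lower())
            except ValueError as exc:
                valid = ", ".join(c.value for c in FeatureClass)
                raise ValueError(f"{path}:{i}: unknown feature class {f[1]!r} (one of {valid})") from exc
            features.append(
                RdnaFeature(
                    name=f[0],
                    feature_class=fclass,
                    start=int(f[2]),
                    end=int(f[3]),
                    color=f[4] if len(f) > 4 and f[4].strip() else None,
                )
            )
    return features


def write_feature_table(features: list[RdnaFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#name\tclass\tstart\tend\tcolor\n")
        for f in features:
            fh.write(f"{f.name}\t{f.feature_class.value}\t{f.start}\t{f.end}\t{f.color or ''}\n")


def read_id_map(path: str | Path) -> dict[str, str]:
    """2-column TSV: RefSeq ID -> gene name."""
    mapping = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 2:
                raise ValueError(f"{path}:{i}: ID map needs 2 tab-separated columns")
            mapping[f[0]] = f[1]
    return mapping
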