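"""Fragment-tiling homology scan.

The rDNA reference is decomposed into fixed-length tiles (50 nt by
default, non-overlapping), the tiles are placed on the genome — either by
the built-in exact matcher or by importing an externally produced SAM —
and genomic stretches supported by many adjacently mapping tiles are
reported as candidate rDNA-like loci.

The built-in matcher is exact (both strands, N never matches); it is
meant for assemblies whose rDNA-like copies are close to the reference
and for fully reproducible desk-scale runs. Divergent copies are better
placed by a mismatch-tolerant external aligner; import those placements
with :func:`rdnakit.seqio.read_sam_hits` and pass them to
:func:`scan_genome` via ``hits=``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqio import (
    FragmentHit,
    Genome,
    GenomeSequence,
    GenomicInterval,
    Source,
    reverse_complement,
)

__all__ = [
    "FragmentTile",
    "FragmentHit",
    "RunCluster",
    "ScanParams",
    "tile_reference",
    "find_tile_hits",
    "detect_runs",
    "scan_genome",
]


@dataclass(frozen=True)
class FragmentTile:
    """A fixed-length fragment of the rDNA reference."""

    index: int
    offset: int
    length: int
    seq: str


@dataclass
class RunCluster:
    """A genomic stretch supported by adjacently mapping tiles.

    ``n_hits`` counts distinct placements (deduplicated on tile, position
    and strand); the envelope [start, end) spans from the first hit start
    to the last hit end.
    """

    chrom: str
    start: int
    end: int
    n_hits: int
    max_internal_gap: int
    hits: list = field(default_factory=list, repr=False)


@dataclass
class ScanParams:
    """Tunable parameters of the fragment scan.

    tile_len/step: fragment length and tiling stride in nt (50/50:
        non-overlapping 50-mers).
    max_hits_per_tile: placement cap per tile, mirroring multi-hit
        reporting caps of short-read aligners (-k 10 style).
    min_fragments: minimum number of adjacent placements for a stretch to
        be reported (at least eight).
    join_gap: maximum gap in nt between consecutive placements for them to
        belong to the same stretch (strictly less than 200).
    """

    tile_len: int = 50
    step: int = 50
    max_hits_per_tile: int = 10
    min_fragments: int = 8
    join_gap: int = 200


def tile_reference(
    ref: GenomeSequence, tile_len: int = 50, step: int = 50
) -> list[FragmentTile]:
    """Fragment a reference sequence into tiles of ``tile_len`` nt.

    Tiles start at offsets 0, step, 2*step, ...; a trailing remainder
    shorter than ``tile_len`` is discarded, so the tile count is
    floor((len - tile_len) / step) + 1.
    """
    if tile_len < 1 or step < 1:
        raise ValueError("tile_len and step must be >= 1")
    if len(ref) < tile_len:
        raise ValueError(
            f"reference {ref.name!r} ({len(ref)} nt) shorter than tile_len {tile_len}"
        )
    tiles = []
    for i, off in enumerate(range(0, len(ref) - tile_len + 1, step)):
        tiles.append(FragmentTile(i, off, tile_len, ref.seq[off : off + tile_len]))
    return tiles


def find_tile_hits(
    genome: Genome, tiles: list[FragmentTile], max_hits_per_tile: int = 10
) -> list[FragmentHit]:
    """Place tiles on the genome by exact matching, both strands.

    At most ``max_hits_per_tile`` placements are reported per tile, chosen
    deterministically: smallest (chromosome order, position), '+' before
    '-' at the same position. Genomic N (or any non-ACGT base) never
    matches, since tiles containing non-ACGT are skipped and matching is
    exact on the uppercased sequence.
    """
    if not tiles:
        return []
    lengths = {t.length for t in tiles}
    if len(lengths) > 1:
        raise ValueError("tiles must have uniform length")
    upper = [(cs.name, cs.seq.upper()) for cs in genome.sequences]

    hits: list[FragmentHit] = []
    for tile in tiles:
        query = tile.seq.upper()
        if any(b not in "ACGT" for b in query):
            continue
        rc = reverse_complement(query)
        palindromic = rc == query
        tile_hits: list[FragmentHit] = []
        for chrom, seq in upper:
            fwd = _find_all(seq, query)
            rev = [] if palindromic else _find_all(seq, rc)
            for pos, strand in _merge_positions(fwd, rev):
                tile_hits.append(FragmentHit(tile.index, chrom, pos, strand, tile.length))
                if len(tile_hits) >= max_hits_per_tile:
                    break
            if len(tile_hits) >= max_hits_per_tile:
                break
        hits.extend(tile_hits)
    return hits


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) occurrence positions, ascending."""
    positions = []
    i = haystack.find(needle)
    while i != -1:
        positions.append(i)
        i = haystack.find(needle, i + 1)
    return positions


def _merge_positions(fwd: list[int], rev: list[int]):
    """Merge two sorted position lists; '+' wins ties at equal position."""
    i = j = 0
    while i < len(fwd) or j < len(rev):
        if j >= len(rev) or (i < len(fwd) and fwd[i] <= rev[j]):
            yield fwd[i], "+"
            i += 1
        else:
            yield rev[j], "-"
            j += 1


def detect_runs(
    hits: list[FragmentHit], min_fragments: int = 8, join_gap: int = 200
) -> list[RunCluster]:
    """Group placements into genomic runs and keep the well-supported ones.

    Per chromosome, hits are deduplicated on (tile, position, strand) and
    sorted by position; consecutive hits whose gap (next start minus the
    running maximum end) is strictly less than ``join_gap`` chain into one
    cluster. Clusters with at least ``min_fragments`` distinct placements
    are returned. Any tile order and any strand mix counts: adjacency is
    purely genomic.
    """
    if min_fragments < 1:
        raise ValueError("min_fragments must be >= 1")
    if join_gap < 0:
        raise ValueError("join_gap must be >= 0")

    by_chrom: dict[str, list[FragmentHit]] = {}
    seen = set()
    for h in hits:
        key = (h.tile_index, h.chrom, h.pos, h.strand)
        if key in seen:
            continue
        seen.add(key)
        by_chrom.setdefault(h.chrom, []).append(h)

    clusters: list[RunCluster] = []
    for chrom in by_chrom:
        chrom_hits = sorted(by_chrom[chrom], key=lambda h: (h.pos, h.end, h.strand))
        chain: list[FragmentHit] = []
        chain_end = 0
        max_gap = 0
        for h in chrom_hits:
            if chain and h.pos - chain_end >= join_gap:
                _flush(clusters, chrom, chain, max_gap, min_fragments)
                chain, max_gap = [], 0
            if chain:
                max_gap = max(max_gap, h.pos - chain_end)
            chain.append(h)
            chain_end = max(chain_end, h.end)
        _flush(clusters, chrom, chain, max_gap, min_fragments)
    return clusters


def _flush(
    clusters: list[RunCluster],
    chrom: str,
    chain: list[FragmentHit],
    max_gap: int,
    min_fragments: int,
) -> None:
    if len(chain) >= min_fragments:
        clusters.append(
            RunCluster(
                chrom=chrom,
                start=chain[0].pos,
                end=max(h.end for h in chain),
                n_hits=len(chain),
                max_internal_gap=max(max_gap, 0),
                hits=chain,
            )
        )


def scan_genome(
    genome: Genome,
    ref: GenomeSequence,
    params: ScanParams | None = None,
    hits: list[FragmentHit] | None = None,
) -> list[GenomicInterval]:
    """End-to-end fragment scan: tile, place, detect runs.

    Pass ``hits`` (e.g. from :func:`rdnakit.seqio.read_sam_hits`) to use
    externally produced placements instead of the built-in exact matcher.
    Returns run envelopes as intervals tagged FRAGSCAN.
    """
    params = params or ScanParams()
    if hits is None:
        tiles = tile_reference(ref, params.tile_len, params.step)
        hits = find_tile_hits(genome, tiles, params.max_hits_per_tile)
    clusters = detect_runs(hits, params.min_fragments, params.join_gap)
    return [
        GenomicInterval.of(
            c.chrom, c.start, c.end, Source.FRAGSCAN, name=f"fragscan_run_{i}"
        )
        for i, c in enumerate(
            sorted(clusters, key=lambda c: (genome.names.index(c.chrom) if c.chrom in genome else 0, c.start))
        )
    ]
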