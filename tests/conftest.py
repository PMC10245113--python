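import numpy as np
import pytest

from rdnakit import Genome, GenomeSequence, make_rdna_reference
from rdnakit.fixtures import _random_dna


@pytest.fixture(scope="session")
def small_ref():
    """Miniature rDNA reference (1 kb, 20 tiles) for fast scans."""
    return make_rdna_reference(length=1000, seed=7)


@pytest.fixture(scope="session")
def toy_genome():
    return Genome([GenomeSequence("chr1", "ACGTACGT")])


def random_sequence(length, rng):
    return _random_dna(length, rng)


def naive_tile_search(genome, tiles, max_hits_per_tile=10):
    """All-positions string-search placement oracle, both strands.

    Independent of the indexed matcher: compares the slice at every
    genomic position against the tile and its reverse complement,
    then keeps the max_hits_per_tile smallest (chrom order, pos),
    '+' before '-' at equal position.
    """
    from rdnakit import FragmentHit, reverse_complement

    hits = []
    chrom_order = {name: i for i, name in enumerate(genome.names)}
    for tile in tiles:
        q = tile.seq.upper()
        if set(q) - set("ACGT"):
            continue
        rc = reverse_complement(q)
        found = []
        for cs in genome.sequences:
            seq = cs.seq.upper()
            for pos in range(len(seq) - tile.length + 1):
                window = seq[pos : pos + tile.length]
                if window == q:
                    found.append((chrom_order[cs.name], pos, 0, "+"))
                if rc != q and window == rc:
                    found.append((chrom_order[cs.name], pos, 1, "-"))
        found.sort()
        for ci, pos, _, strand in found[:max_hits_per_tile]:
            hits.append(FragmentHit(tile.index, genome.names[ci], pos, strand, tile.length))
    return hits


def paint_runs(hits, min_fragments, join_gap):
    """Per-base painting oracle for run detection.

    Paints [pos, end + join_gap - 1) per deduplicated hit — the -1 makes
    painted stretches touch exactly when the gap is strictly below
    join_gap; connected painted stretches group the hits, groups with
    >= min_fragments survive. Returns a set of (chrom, start, end,
    n_hits) envelopes from raw hits.
    """
    dedup = {}
    for h in hits:
        dedup[(h.tile_index, h.chrom, h.pos, h.strand)] = h
    by_chrom = {}
    for h in dedup.values():
        by_chrom.setdefault(h.chrom, []).append(h)
    out = set()
    for chrom, hs in by_chrom.items():
        size = max(h.end for h in hs) + join_gap + 1
        painted = np.zeros(size, dtype=bool)
        for h in hs:
            painted[h.pos : h.end + join_gap - 1] = True
        # label connected components
        labels = np.cumsum(np.concatenate(([painted[0]], ~painted[:-1] & painted[1:])))
        groups = {}
        for h in hs:
            groups.setdefault(labels[h.pos], []).append(h)
        for members in groups.values():
            if len(members) >= min_fragments:
                out.add(
                    (chrom, min(m.pos for m in members), max(m.end for m in members), len(members))
                )
    return out


def per_base_union(intervals, chrom_sizes):
    """Boolean per-base membership of an interval set."""
    cov = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
    for iv in intervals:
        cov[iv.chrom][iv.start : iv.end] = True
    return cov
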