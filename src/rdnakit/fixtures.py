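"""Deterministic synthetic genomes with embedded rDNA copies.

Real assemblies carry partial, fragmented, mutated and repeated rDNA
stretches; this module builds miniature versions of that situation with
known truth coordinates, so the whole pipeline (scan -> buffer/merge ->
mask -> verify) can be exercised without downloading anything. The
background is i.i.d. uniform ACGT — no repeat families, no GC structure —
so specificity results on these fixtures reflect random 50-mer collision
probabilities, not the harder repeat landscape of a real genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .genome_build import FeatureClass, RdnaFeature, RdnaReference
from .seqio import Genome, GenomeSequence, GenomicInterval, Source, reverse_complement

__all__ = [
    "EmbeddingKind",
    "EmbeddingSpec",
    "DEFAULT_SEED",
    "make_reference",
    "make_rdna_reference",
    "make_genome",
]

DEFAULT_SEED = 17

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class EmbeddingKind(Enum):
    FULL_COPY = "full_copy"
    FRAGMENT = "fragment"
    MUTATED_COPY = "mutated_copy"
    REVCOMP_COPY = "revcomp_copy"


@dataclass
class EmbeddingSpec:
    """One rDNA-derived insert written into a synthetic chromosome."""

    chrom: str
    position: int
    kind: EmbeddingKind
    fragment_span: tuple[int, int] | None = None  # reference coords, FRAGMENT only
    mutation_rate: float = 0.0  # per-base substitution prob, MUTATED_COPY only
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.kind is EmbeddingKind.FRAGMENT and self.fragment_span is None:
            raise ValueError("FRAGMENT embeddings need fragment_span")


def _random_dna(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def make_reference(length: int = 5000, seed: int = DEFAULT_SEED) -> GenomeSequence:
    """A uniform-random miniature rDNA reference, reproducible by seed."""
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    # distinct stream key per generator, so reference and background
    # sequences never coincide when built from the same top-level seed
    rng = np.random.default_rng([seed, 101])
    return GenomeSequence("rdna_ref_synthetic", _random_dna(length, rng))


def make_rdna_reference(length: int = 5000, seed: int = DEFAULT_SEED) -> RdnaReference:
    """A miniature rDNA reference with a proportionally scaled feature table.

    The layout mirrors the real repeat: two small promoters, a transcribed
    region of ~30% of the unit (13.4 kb of ~45 kb) split into external
    spacer / mature rRNA segments / internal spacers, and ~65% intergenic
    spacer. The cut position sits inside the IGS at ~79% of the unit,
    matching the 35,500 / 44,838 proportion of the human reference.
    """
    ref = make_reference(length, seed)
    L = length
    t_end = int(0.30 * L)  # transcribed region ~30%
    features = [
        RdnaFeature("5ETS", FeatureClass.ETS, 0, int(0.027 * L)),
        RdnaFeature("18S", FeatureClass.MATURE_RRNA, int(0.027 * L), int(0.123 * L)),
        RdnaFeature("ITS1", FeatureClass.ITS, int(0.123 * L), int(0.147 * L)),
        RdnaFeature("5.8S", FeatureClass.MATURE_RRNA, int(0.147 * L), int(0.151 * L)),
        RdnaFeature("ITS2", FeatureClass.ITS, int(0.151 * L), int(0.177 * L)),
        RdnaFeature("28S", FeatureClass.MATURE_RRNA, int(0.177 * L), int(0.290 * L)),
        RdnaFeature("3ETS", FeatureClass.ETS, int(0.290 * L), t_end),
        RdnaFeature("IGS", FeatureClass.IGS, t_end, int(0.985 * L)),
        RdnaFeature("spacer_promoter", FeatureClass.PROMOTER, int(0.985 * L), int(0.993 * L)),
        RdnaFeature("47S_promoter", FeatureClass.PROMOTER, int(0.993 * L), L),
    ]
    return RdnaReference(
        accession=ref.name,
        seq=ref.seq,
        cut_pos=int(round(L * 35_500 / 44_838)),
        features=features,
    )


def _embedded_seq(spec: EmbeddingSpec, ref: GenomeSequence) -> str:
    if spec.kind is EmbeddingKind.FULL_COPY:
        return ref.seq
    if spec.kind is EmbeddingKind.REVCOMP_COPY:
        return reverse_complement(ref.seq)
    if spec.kind is EmbeddingKind.FRAGMENT:
        s, e = spec.fragment_span
        if not 0 <= s < e <= len(ref):
            raise ValueError(f"fragment_span {spec.fragment_span} outside reference")
        return ref.seq[s:e]
    # MUTATED_COPY: per-base substitutions to a different base
    rng = np.random.default_rng([spec.seed, 303])
    arr = np.frombuffer(ref.seq.encode(), dtype="S1").copy()
    to_mutate = np.flatnonzero(rng.random(arr.size) < spec.mutation_rate)
    for i in to_mutate:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def make_genome(
    chrom_lens: dict[str, int],
    embeddings: list[EmbeddingSpec],
    ref: GenomeSequence,
    seed: int = DEFAULT_SEED,
) -> tuple[Genome, list[GenomicInterval]]:
    """Random background chromosomes with rDNA-derived inserts written in.

    Returns the genome and the truth intervals marking exactly where
    rDNA-derived sequence lies. Embeddings on the same chromosome must not
    overlap.
    """
    rng = np.random.default_rng([seed, 202])
    inserts: dict[str, list[tuple[int, str, EmbeddingSpec]]] = {}
    for spec in embeddings:
        if spec.chrom not in chrom_lens:
            raise ValueError(f"embedding on unknown chromosome {spec.chrom!r}")
        seq = _embedded_seq(spec, ref)
        if spec.position + len(seq) > chrom_lens[spec.chrom]:
            raise ValueError(
                f"embedding at {spec.chrom}:{spec.position} (+{len(seq)} nt) "
                f"exceeds chromosome length {chrom_lens[spec.chrom]}"
            )
        inserts.setdefault(spec.chrom, []).append((spec.position, seq, spec))

    for chrom, items in inserts.items():
        items.sort(key=lambda t: t[0])
        for (p1, s1, _), (p2, _, _) in zip(items, items[1:]):
            if p1 + len(s1) > p2:
                raise ValueError(f"overlapping embeddings on {chrom} at {p1} and {p2}")

    genome = Genome()
    truth: list[GenomicInterval] = []
    for chrom, length in chrom_lens.items():
        background = list(_random_dna(length, rng))
        for pos, seq, spec in inserts.get(chrom, []):
            background[pos : pos + len(seq)] = seq
            truth.append(
                GenomicInterval.of(chrom, pos, pos + len(seq), Source.USER, spec.kind.value)
            )
        genome.add(GenomeSequence(chrom, "".join(background)))
    return genome, truth
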