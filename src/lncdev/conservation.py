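"""Exon-level conservation from multi-species alignment blocks.

Each alignment block carries one similarity score and one genomic interval
per species. An exon's conservation contribution from a block is

    similarity * overlap(exon, block) / block_length

and a transcript's score is the sum over its exons and all blocks. A
lncRNA tuple (one transcript per species) is called conserved when every
element of some block overlaps an exon of the respective transcript in
every required species.

Significance comes from a structure-preserving genome shuffle: every
transcript is relocated uniformly at random among all placements whose span
avoids a set of exclusion regions (typically all coding and lncRNA loci),
mirroring shuffleBED with an exclusion file.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .core import (
    AlignmentBlock,
    GenomeInterval,
    GenomeSpec,
    TranscriptModel,
    merge_intervals,
    overlap_length,
)


@dataclass
class ConservationScore:
    transcript_id: str
    score: float
    per_exon: list[float]


def score_transcript(
    model: TranscriptModel, blocks: Sequence[AlignmentBlock], species: str
) -> ConservationScore:
    """Conservation score of one transcript against one species' block elements.

    Additive over exons and linear in block similarity; a block fully inside
    an exon contributes its whole similarity, and doubling a block's length
    at fixed overlap halves its contribution.
    """
    per_exon = []
    for exon in model.exons:
        contrib = 0.0
        for b in blocks:
            el = b.elements.get(species)
            if el is None:
                continue
            ov = overlap_length(exon, el)
            if ov:
                contrib += b.similarity * ov / el.length
        per_exon.append(contrib)
    return ConservationScore(model.transcript_id, float(sum(per_exon)), per_exon)


def _exon_index(models: Sequence[TranscriptModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for m in models:
        for e in m.exons:
            trees.setdefault(e.chrom, IntervalTree()).addi(e.start, e.end, m.transcript_id)
    return trees


def call_conserved(
    lnc_by_species: Mapping[str, Sequence[TranscriptModel]],
    blocks: Sequence[AlignmentBlock],
    required_species: Sequence[str],
    min_overlap: int = 1,
) -> set[tuple[tuple[str, str], ...]]:
    """Conserved lncRNA tuples across ``required_species``.

    For each block carrying elements in all required species, emits every
    combination of transcripts (one per species) whose exons the block's
    elements overlap by >= ``min_overlap`` bp. Two species give teleost-mode
    calls, four give vertebrate-mode calls. Each tuple is sorted by species
    name, so the result is order-invariant.
    """
    trees = {sp: _exon_index(lnc_by_species[sp]) for sp in required_species}
    calls: set[tuple[tuple[str, str], ...]] = set()
    for b in blocks:
        if not all(sp in b.elements for sp in required_species):
            continue
        hits_per_species = []
        for sp in required_species:
            el = b.elements[sp]
            tree = trees[sp].get(el.chrom)
            hits = set()
            if tree is not None:
                for iv in tree.overlap(el.start, el.end):
                    if min(iv.end, el.end) - max(iv.begin, el.start) >= min_overlap:
                        hits.add(iv.data)
            if not hits:
                break
            hits_per_species.append(sorted(hits))
        else:
            for combo in itertools.product(*hits_per_species):
                calls.add(tuple(sorted(zip(required_species, combo))))
    return calls


def conserved_ids(
    calls: Iterable[tuple[tuple[str, str], ...]], species: str
) -> set[str]:
    """Transcripts of one species appearing in >= 1 conserved tuple."""
    return {tid for call in calls for sp, tid in call if sp == species}


# ---------------------------------------------------------------------------
# structure-preserving shuffle
# ---------------------------------------------------------------------------

def _free_segments(
    genome: GenomeSpec, exclude: Sequence[GenomeInterval]
) -> list[tuple[str, int, int]]:
    merged = {c: [] for c in genome}
    for iv in merge_intervals(exclude):
        if iv.chrom in merged:
            merged[iv.chrom].append(iv)
    segments = []
    for chrom, length in genome.items():
        pos = 0
        for iv in sorted(merged[chrom], key=lambda i: i.start):
            if iv.start > pos:
                segments.append((chrom, pos, iv.start))
            pos = max(pos, iv.end)
        if pos < length:
            segments.append((chrom, pos, length))
    return segments


def shuffle_transcripts(
    models: Sequence[TranscriptModel],
    genome: GenomeSpec,
    exclude: Sequence[GenomeInterval],
    rng: np.random.Generator,
) -> list[TranscriptModel]:
    """Relocate each transcript uniformly at random outside the exclusion set.

    Exon-intron structure, length and strand are preserved; the placement is
    uniform over every genomic position where the whole transcript span fits
    inside one exclusion-free segment (an exact, rejection-free analogue of
    shuffleBED -excl). Raises if a transcript cannot be placed anywhere,
    naming its chromosome.
    """
    segments = _free_segments(genome, exclude)
    out = []
    for m in models:
        span = m.interval.length
        weights = np.array([max(0, e - s - span + 1) for _, s, e in segments], dtype=float)
        total = weights.sum()
        if total <= 0:
            raise ValueError(
                f"no placement for {m.transcript_id} (span {span} bp, from {m.chrom}): "
                "exclusion regions leave no room"
            )
        seg_i = rng.choice(len(segments), p=weights / total)
        chrom, s, e = segments[seg_i]
        new_start = int(rng.integers(s, e - span + 1))
        out.append(m.relocated(chrom, new_start))
    return out


def empirical_p(observed: float, null: np.ndarray) -> float:
    """Upper-tail empirical p with the +1 correction: (1 + #{null >= obs}) / (1 + n)."""
    null = np.asarray(null)
    return float((1 + (null >= observed).sum()) / (1 + null.size))


def shuffle_background(
    models: Sequence[TranscriptModel],
    genome: GenomeSpec,
    exclude: Sequence[GenomeInterval],
    statistic: Callable[[list[TranscriptModel]], float],
    n_reps: int,
    seed: int,
    observed: float | None = None,
) -> tuple[np.ndarray, float | None]:
    """Null distribution of ``statistic`` under genome-wide transcript shuffling.

    Returns (per-replicate statistics, empirical upper-tail p against
    ``observed`` or None). Fully reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    stats = np.array(
        [statistic(shuffle_transcripts(models, genome, exclude, rng)) for _ in range(n_reps)]
    )
    p = empirical_p(observed, stats) if observed is not None else None
    return stats, p


def mean_score_statistic(
    blocks: Sequence[AlignmentBlock], species: str
) -> Callable[[Sequence[TranscriptModel]], float]:
    """Statistic factory: mean conservation score over a transcript set."""

    def stat(models: Sequence[TranscriptModel]) -> float:
        return float(
            np.mean([score_transcript(m, blocks, species).score for m in models])
        )

    return stat
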