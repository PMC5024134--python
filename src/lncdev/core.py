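"""Core genomic domain types and interval arithmetic.

All coordinates are 0-based, half-open ``[start, end)`` (BED convention).
Format readers/writers (:mod:`lncdev.io`) convert at the boundary; nothing
else in the package ever sees 1-based closed coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

STRANDS = ("+", "-", ".")

#: Transcript biotype labels used throughout the pipeline.
BIOTYPES = ("coding", "lncRNA", "lincRNA", "unclassified")


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A stranded, half-open genomic interval.

    Strand "." is reserved for features that are inherently unstranded
    (repeats, shuffled placements); transcripts always carry "+" or "-".
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, chrom: str, offset: int) -> "GenomeInterval":
        """Return a copy relocated to ``chrom`` with coordinates shifted by ``offset``."""
        return GenomeInterval(chrom, self.start + offset, self.end + offset, self.strand)


def overlap_length(a: GenomeInterval, b: GenomeInterval) -> int:
    """Number of bases shared by two intervals (0 if on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def interval_gap(a: GenomeInterval, b: GenomeInterval) -> int:
    """Gap in bp between two intervals on the same chromosome; 0 if they overlap or abut.

    Raises ValueError for intervals on different chromosomes, where a gap is undefined.
    """
    if a.chrom != b.chrom:
        raise ValueError("gap undefined across chromosomes")
    if a.start >= b.end:
        return a.start - b.end
    if b.start >= a.end:
        return b.start - a.end
    return 0


def merge_intervals(
    intervals: Iterable[GenomeInterval], stranded: bool = False
) -> list[GenomeInterval]:
    """Collapse intervals to a minimal set of maximal non-overlapping ones.

    Abutting intervals ([10,20) + [20,30)) are merged. With ``stranded=True``
    merging happens only within a strand; merged intervals keep the common
    strand, otherwise they are emitted unstranded (".").

    Idempotent: ``merge_intervals(merge_intervals(x)) == merge_intervals(x)``.
    """
    groups: dict[tuple, list[GenomeInterval]] = {}
    for iv in intervals:
        key = (iv.chrom, iv.strand) if stranded else (iv.chrom,)
        groups.setdefault(key, []).append(iv)
    out: list[GenomeInterval] = []
    for key in sorted(groups):
        ivs = sorted(groups[key], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        strand = ivs[0].strand if stranded else "."
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomeInterval(ivs[0].chrom, cur_start, cur_end, strand))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomeInterval(ivs[0].chrom, cur_start, cur_end, strand))
    return out


def total_length(intervals: Iterable[GenomeInterval]) -> int:
    """Total bp covered by a set of intervals, counting shared bases once."""
    return sum(iv.length for iv in merge_intervals(intervals))


def intersect_lengths(
    a: Iterable[GenomeInterval], b: Iterable[GenomeInterval]
) -> int:
    """Total bp in the intersection of two interval sets (each merged first)."""
    am = merge_intervals(a)
    bm = {c: [] for c in {iv.chrom for iv in am}}
    for iv in merge_intervals(b):
        if iv.chrom in bm:
            bm[iv.chrom].append(iv)
    total = 0
    for iv in am:
        for other in bm.get(iv.chrom, ()):
            total += overlap_length(iv, other)
    return total


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded multi-exon gene model.

    ``exons`` are sorted, non-overlapping intervals on one chromosome and
    strand; introns are the gaps between consecutive exons. ``length`` is
    the mature (summed-exon) transcript length.
    """

    transcript_id: str
    locus_id: str
    exons: tuple[GenomeInterval, ...]
    biotype: str = "unclassified"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        chrom, strand = exons[0].chrom, exons[0].strand
        if strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: transcripts must be stranded")
        for prev, nxt in zip(exons, exons[1:]):
            if nxt.chrom != chrom or nxt.strand != strand:
                raise ValueError(f"{self.transcript_id}: exons on mixed chrom/strand")
            if nxt.start < prev.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.transcript_id}: unknown biotype {self.biotype!r}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def interval(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    @property
    def length(self) -> int:
        """Mature transcript length: sum of exon lengths."""
        return sum(e.length for e in self.exons)

    @property
    def introns(self) -> tuple[GenomeInterval, ...]:
        return tuple(
            GenomeInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        )

    @property
    def tss(self) -> int:
        """Coordinate of the 5' terminal base (start for +, end-1 for -)."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    def with_biotype(self, biotype: str) -> "TranscriptModel":
        return TranscriptModel(self.transcript_id, self.locus_id, self.exons, biotype)

    def relocated(self, chrom: str, new_start: int) -> "TranscriptModel":
        """Move the transcript, preserving its exon/intron structure and strand."""
        offset = new_start - self.interval.start
        return TranscriptModel(
            self.transcript_id,
            self.locus_id,
            tuple(e.shifted(chrom, offset) for e in self.exons),
            self.biotype,
        )


@dataclass(frozen=True)
class CageTag:
    """A CAGE tag: a width-1 genomic position with a tags-per-million value."""

    position: GenomeInterval
    tpm: float

    def __post_init__(self) -> None:
        if self.position.length != 1:
            raise ValueError("CAGE tag position must have width 1")
        if self.tpm < 0:
            raise ValueError("tpm must be >= 0")


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-transcript evidence consumed by the lncRNA classification cascade.

    Homology flags and the longest-ORF length come from sequence annotation;
    ``ncp`` is the non-coding potential score in [0, 1] (higher = more likely
    non-coding). These are inputs to the pipeline, never computed here.
    """

    transcript_id: str
    has_protein_hit: bool
    has_domain_hit: bool
    has_ncrna_hit: bool
    longest_orf_aa: int
    ncp: float
    has_swissprot_hit: bool
    go_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (0.0 <= self.ncp <= 1.0):
            raise ValueError(f"{self.transcript_id}: ncp must lie in [0,1]")
        if self.longest_orf_aa < 0:
            raise ValueError(f"{self.transcript_id}: negative ORF length")


@dataclass(frozen=True)
class RepeatElement:
    """A RepeatMasker-style repeat interval with class and family labels."""

    interval: GenomeInterval
    te_class: str
    te_family: str

    def __post_init__(self) -> None:
        if not self.te_class or not self.te_family:
            raise ValueError("repeat class/family must be non-empty")


@dataclass(frozen=True)
class AlignmentBlock:
    """One multi-species alignment unit: per-species interval + one similarity score."""

    block_id: str
    elements: Mapping[str, GenomeInterval]
    similarity: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "elements", dict(self.elements))
        if len(self.elements) < 2:
            raise ValueError(f"block {self.block_id}: needs >= 2 species elements")
        if not self.similarity > 0:
            raise ValueError(f"block {self.block_id}: similarity must be > 0")


class GenomeSpec(dict):
    """Chromosome name -> length (bp). A thin dict with validation helpers."""

    def __init__(self, lengths: Mapping[str, int]):
        for chrom, length in lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom}: non-positive length")
        super().__init__(lengths)

    @property
    def total_bp(self) -> int:
        return sum(self.values())

    def contains(self, iv: GenomeInterval) -> bool:
        return iv.chrom in self and 0 <= iv.start and iv.end <= self[iv.chrom]

    def validate_intervals(self, intervals: Iterable[GenomeInterval]) -> None:
        for iv in intervals:
            if not self.contains(iv):
                raise ValueError(f"interval {iv} outside genome bounds")


def window_neighbors(
    query: TranscriptModel,
    subjects: Sequence[TranscriptModel],
    window: int,
) -> list[TranscriptModel]:
    """Subjects whose span overlaps the query span extended by ``window`` bp each side.

    Strand-agnostic. With ``window=0`` this reduces to direct span overlap.
    Extension is on half-open coordinates, so a subject at a gap exactly equal
    to ``window`` is *not* a neighbor (bedtools-window semantics).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    q = query.interval
    ext = GenomeInterval(q.chrom, max(0, q.start - window), q.end + window)
    return [s for s in subjects if overlap_length(ext, s.interval) > 0]


def locus_spans(models: Iterable[TranscriptModel]) -> dict[str, GenomeInterval]:
    """Per-locus genomic span (min start to max end over the locus' transcripts)."""
    spans: dict[str, GenomeInterval] = {}
    for m in models:
        iv = m.interval
        if m.locus_id in spans:
            prev = spans[m.locus_id]
            if prev.chrom != iv.chrom:
                raise ValueError(f"locus {m.locus_id}: transcripts on multiple chromosomes")
            spans[m.locus_id] = GenomeInterval(
                prev.chrom, min(prev.start, iv.start), max(prev.end, iv.end), prev.strand
            )
        else:
            spans[m.locus_id] = iv
    return spans
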