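"""Microsynteny of lincRNAs across species (SynLinc-style).

A lincRNA pair from two species is microsyntenic when at least one of each
lincRNA's *immediate* flanking coding genes (nearest gene entirely to the
chromosomal left / right) are orthologous. Orientation conservation
additionally requires a shared orthologous flank on the same side with the
same lincRNA-vs-flank relative strand. A lincRNA is "vertebrate
microsyntenic" when it takes part in a call with every other species.

Significance: intergenic regions containing a lincRNA (lincIGs) give the
observed microsyntenic percentage; shuffling lincRNA coordinates per species
(outside coding and lncRNA loci) yields randIGs and a null percentage
distribution, summarized as a Z-score with an upper-tail normal p.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .core import GenomeInterval, GenomeSpec, TranscriptModel, locus_spans, overlap_length
from .conservation import empirical_p, shuffle_transcripts


@dataclass(frozen=True)
class Gene:
    """A coding gene as a locus-level span with a strand."""

    gene_id: str
    span: GenomeInterval


def coding_genes(models: Sequence[TranscriptModel]) -> list[Gene]:
    """Collapse coding transcripts into locus-level genes."""
    return [Gene(gid, span) for gid, span in sorted(locus_spans(models).items())]


def flanking_genes(
    linc: TranscriptModel, genes: Sequence[Gene]
) -> tuple[Gene | None, Gene | None]:
    """Nearest coding gene entirely left and entirely right of the lincRNA.

    Chromosome-coordinate based (not lincRNA-strand based); ties on the
    boundary coordinate break to the smaller gene id. Genes overlapping the
    lincRNA are ignored (the lincRNA is expected to be intergenic).
    """
    span = linc.interval
    left = right = None
    for g in genes:
        if g.span.chrom != span.chrom:
            continue
        if g.span.end <= span.start:
            if (
                left is None
                or g.span.end > left.span.end
                or (g.span.end == left.span.end and g.gene_id < left.gene_id)
            ):
                left = g
        elif g.span.start >= span.end:
            if (
                right is None
                or g.span.start < right.span.start
                or (g.span.start == right.span.start and g.gene_id < right.gene_id)
            ):
                right = g
    return left, right


@dataclass(frozen=True)
class SyntenyCall:
    linc_a: str
    linc_b: str
    species: tuple[str, str]
    shared_flank: frozenset[str]  # subset of {"upstream", "downstream"}, sides of linc_a
    orientation_conserved: bool


def _flank_info(
    lincs: Sequence[TranscriptModel], genes: Sequence[Gene]
) -> dict[str, dict[str, tuple[Gene, bool]]]:
    """Per lincRNA: side -> (flank gene, same-strand-as-linc flag).

    Uses sorted per-chromosome gene lists with bisection; equivalent to
    :func:`flanking_genes` per lincRNA but fast enough for the
    randomization loop.
    """
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.span.chrom, []).append(g)
    left_sorted = {
        c: sorted(gs, key=lambda g: (g.span.end, g.gene_id)) for c, gs in by_chrom.items()
    }
    left_ends = {c: [g.span.end for g in gs] for c, gs in left_sorted.items()}
    right_sorted = {
        c: sorted(gs, key=lambda g: (g.span.start, g.gene_id)) for c, gs in by_chrom.items()
    }
    right_starts = {c: [g.span.start for g in gs] for c, gs in right_sorted.items()}
    info: dict[str, dict[str, tuple[Gene, bool]]] = {}
    for m in lincs:
        span = m.interval
        left = right = None
        if span.chrom in by_chrom:
            i = bisect.bisect_right(left_ends[span.chrom], span.start)
            if i > 0:
                # ties on the boundary coordinate break to the smaller gene id
                gs = left_sorted[span.chrom]
                left = gs[i - 1]
                k = i - 1
                while k > 0 and gs[k - 1].span.end == left.span.end:
                    k -= 1
                left = gs[k]
            j = bisect.bisect_left(right_starts[span.chrom], span.end)
            if j < len(right_sorted[span.chrom]):
                right = right_sorted[span.chrom][j]
        d = {}
        if left is not None:
            d["upstream"] = (left, left.span.strand == m.strand)
        if right is not None:
            d["downstream"] = (right, right.span.strand == m.strand)
        info[m.transcript_id] = d
    return info


def pairwise_synteny(
    lincs1: Sequence[TranscriptModel],
    coding1: Sequence[TranscriptModel],
    lincs2: Sequence[TranscriptModel],
    coding2: Sequence[TranscriptModel],
    orthology: set[tuple[str, str]],
    species: tuple[str, str] = ("speciesA", "speciesB"),
) -> list[SyntenyCall]:
    """All microsyntenic lincRNA pairs between two species.

    ``orthology`` holds (species1 gene, species2 gene) pairs; it is treated
    symmetrically. A call is emitted when any immediate flank of the first
    lincRNA is orthologous to any immediate flank of the second.
    """
    genes1, genes2 = coding_genes(coding1), coding_genes(coding2)
    f1 = _flank_info(lincs1, genes1)
    f2 = _flank_info(lincs2, genes2)
    ortho: dict[str, set[str]] = {}
    for a, b in orthology:
        ortho.setdefault(a, set()).add(b)
        ortho.setdefault(b, set()).add(a)
    # index lincs2 by flank gene id
    by_gene: dict[str, list[tuple[str, str, bool]]] = {}
    for tid, d in f2.items():
        for side, (g, same) in d.items():
            by_gene.setdefault(g.gene_id, []).append((tid, side, same))
    calls: list[SyntenyCall] = []
    for tid1, d1 in f1.items():
        partners: dict[str, tuple[set[str], bool]] = {}
        for side1, (g1, same1) in d1.items():
            for g2_id in sorted(ortho.get(g1.gene_id, ())):
                for tid2, side2, same2 in by_gene.get(g2_id, ()):
                    shared, orient = partners.setdefault(tid2, (set(), False))
                    shared.add(side1)
                    if side1 == side2 and same1 == same2:
                        orient = True
                    partners[tid2] = (shared, orient)
        for tid2, (shared, orient) in sorted(partners.items()):
            calls.append(
                SyntenyCall(tid1, tid2, species, frozenset(shared), orient)
            )
    return calls


def multi_species_synteny(
    calls_by_pair: Mapping[tuple[str, str], Sequence[SyntenyCall]],
    species: Sequence[str],
) -> dict[str, set[str]]:
    """lincRNAs microsyntenic with a partner in *every* other species.

    Returns species -> set of lincRNA ids. Invariant to species ordering and
    to the orientation of each pairwise call set.
    """
    partners: dict[str, dict[str, set[str]]] = {
        sp: {other: set() for other in species if other != sp} for sp in species
    }
    for (s1, s2), calls in calls_by_pair.items():
        for c in calls:
            partners[s1][s2].add(c.linc_a)
            partners[s2][s1].add(c.linc_b)
    return {
        sp: set.intersection(*partners[sp].values()) if partners[sp] else set()
        for sp in species
    }


@dataclass
class RandomizationResult:
    observed_pct: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    null_pcts: np.ndarray


def _syntenic_pct(
    lincs_by_species: Mapping[str, Sequence[TranscriptModel]],
    coding_by_species: Mapping[str, Sequence[TranscriptModel]],
    orthology_maps: Mapping[tuple[str, str], set[tuple[str, str]]],
    focal: str,
) -> float:
    species = sorted(lincs_by_species)
    calls = {}
    for pair, omap in orthology_maps.items():
        s1, s2 = pair
        calls[pair] = pairwise_synteny(
            lincs_by_species[s1], coding_by_species[s1],
            lincs_by_species[s2], coding_by_species[s2], omap, pair,
        )
    multi = multi_species_synteny(calls, species)
    genes = coding_genes(coding_by_species[focal])
    denom = [
        m for m in lincs_by_species[focal]
        if any(flanking_genes(m, genes))
    ]
    if not denom:
        return 0.0
    return 100.0 * len(multi[focal] & {m.transcript_id for m in denom}) / len(denom)


def randomization_test(
    lincs_by_species: Mapping[str, Sequence[TranscriptModel]],
    coding_by_species: Mapping[str, Sequence[TranscriptModel]],
    orthology_maps: Mapping[tuple[str, str], set[tuple[str, str]]],
    genome_by_species: Mapping[str, GenomeSpec],
    exclude_by_species: Mapping[str, Sequence[GenomeInterval]],
    focal: str,
    n_reps: int = 1000,
    seed: int = 0,
) -> RandomizationResult:
    """lincIG/randIG randomization for multi-species microsynteny.

    Observed: % of the focal species' lincRNAs (those with at least one
    flank) microsyntenic across all species. Each replicate shuffles every
    species' lincRNA coordinates outside its exclusion regions and
    recomputes the percentage. Z = (obs - mean) / sd with an upper-tail
    normal p; if the null is degenerate (sd = 0) the empirical p is
    reported and Z is nan.
    """
    observed = _syntenic_pct(lincs_by_species, coding_by_species, orthology_maps, focal)
    rng = np.random.default_rng(seed)
    null = np.empty(n_reps)
    for i in range(n_reps):
        shuffled = {
            sp: shuffle_transcripts(
                lincs_by_species[sp], genome_by_species[sp], exclude_by_species[sp], rng
            )
            for sp in sorted(lincs_by_species)
        }
        null[i] = _syntenic_pct(shuffled, coding_by_species, orthology_maps, focal)
    mean, sd = float(null.mean()), float(null.std(ddof=1)) if n_reps > 1 else 0.0
    if sd > 0:
        z = (observed - mean) / sd
        p = float(sps.norm.sf(z))
    else:
        z = float("nan")
        p = empirical_p(observed, null)
    return RandomizationResult(observed, mean, sd, float(z), p, null)
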