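"""Transposable-element association of transcript sets.

All computations are strand-agnostic except TSS association, where the
relevant base is the transcript's 5' terminus (start coordinate on "+",
end coordinate on "-"). Exon spaces are merged to non-redundant sets before
coverage arithmetic, so shared bases count once; overlapping TE classes are
counted independently of one another.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    GenomeSpec,
    RepeatElement,
    TranscriptModel,
    intersect_lengths,
    merge_intervals,
    overlap_length,
    total_length,
)

#: Sentinel for a TE family present in the genome but absent from the
#: transcript set: depleted beyond what coverage arithmetic can quantify.
DEPLETED_BELOW_MEASUREMENT = float("-inf")


def exonic_te_loci(
    models: Sequence[TranscriptModel], repeats: Sequence[RepeatElement]
) -> pd.DataFrame:
    """Per biotype: number and % of loci with >= 1 bp of exonic TE overlap.

    Exons are merged per locus; a repeat anywhere in an intron does not
    count. Monotone in the repeat set: adding repeats never lowers counts.
    """
    by_bt: dict[str, dict[str, list]] = {}
    for m in models:
        by_bt.setdefault(m.biotype, {}).setdefault(m.locus_id, []).extend(m.exons)
    rep_by_chrom: dict[str, list[RepeatElement]] = {}
    for r in repeats:
        rep_by_chrom.setdefault(r.interval.chrom, []).append(r)
    rows = []
    for bt, loci in sorted(by_bt.items()):
        hit_loci = []
        for locus_id, exons in loci.items():
            merged = merge_intervals(exons)
            hit = any(
                overlap_length(e, r.interval) > 0
                for e in merged
                for r in rep_by_chrom.get(e.chrom, ())
            )
            if hit:
                hit_loci.append(locus_id)
        rows.append(
            {
                "biotype": bt,
                "n_loci": len(loci),
                "n_te_loci": len(hit_loci),
                "pct_te_loci": 100.0 * len(hit_loci) / len(loci) if loci else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _repeat_groups(
    repeats: Sequence[RepeatElement], by: str
) -> dict[str, list[RepeatElement]]:
    if by not in ("class", "family"):
        raise ValueError("by must be 'class' or 'family'")
    key = (lambda r: r.te_class) if by == "class" else (lambda r: r.te_family)
    groups: dict[str, list[RepeatElement]] = {}
    for r in repeats:
        groups.setdefault(key(r), []).append(r)
    return groups


def te_coverage(
    models: Sequence[TranscriptModel],
    repeats: Sequence[RepeatElement],
    by: str = "class",
) -> pd.DataFrame:
    """Fraction of merged exonic bp covered by each TE class (or family)."""
    exon_space = merge_intervals(e for m in models for e in m.exons)
    exonic_bp = sum(iv.length for iv in exon_space)
    rows = []
    for label, group in sorted(_repeat_groups(repeats, by).items()):
        covered = intersect_lengths(exon_space, [r.interval for r in group])
        rows.append(
            {
                by: label,
                "covered_bp": covered,
                "exonic_bp": exonic_bp,
                "fraction": covered / exonic_bp if exonic_bp else 0.0,
            }
        )
    return pd.DataFrame(rows)


def te_enrichment(
    models: Sequence[TranscriptModel],
    repeats: Sequence[RepeatElement],
    genome: GenomeSpec,
    by: str = "class",
) -> pd.DataFrame:
    """log2(transcript-set TE fraction / genomic TE fraction) per class/family.

    Positive values are enrichments, negative depletions. A set fraction of
    zero against a non-zero genomic fraction is reported as -inf ("depleted
    below measurement"); a zero genomic fraction makes the ratio undefined
    (nan) rather than infinite.
    """
    cov = te_coverage(models, repeats, by)
    groups = _repeat_groups(repeats, by)
    rows = []
    for row in cov.to_dict("records"):
        label = row[by]
        genomic_bp = total_length(r.interval for r in groups[label])
        genomic_fraction = genomic_bp / genome.total_bp
        set_fraction = row["fraction"]
        if genomic_fraction == 0:
            ratio = log2_ratio = float("nan")
        elif set_fraction == 0:
            ratio = 0.0
            log2_ratio = DEPLETED_BELOW_MEASUREMENT
        else:
            ratio = set_fraction / genomic_fraction
            log2_ratio = float(np.log2(ratio))
        rows.append(
            {
                by: label,
                "set_fraction": set_fraction,
                "genomic_fraction": genomic_fraction,
                "ratio": ratio,
                "log2_ratio": log2_ratio,
            }
        )
    return pd.DataFrame(rows)


def tss_associated(
    models: Sequence[TranscriptModel], repeats: Sequence[RepeatElement]
) -> dict[str, tuple[bool, str | None]]:
    """Per transcript: is a repeat sitting on the 5' terminal base, and its class.

    The 5' base is the start coordinate for plus-strand transcripts and the
    end coordinate (last base, end-1 internally) for minus-strand ones. A
    repeat merely abutting the base does not count. When several repeats
    cover the base the lexicographically first class is reported.
    """
    rep_by_chrom: dict[str, list[RepeatElement]] = {}
    for r in repeats:
        rep_by_chrom.setdefault(r.interval.chrom, []).append(r)
    out = {}
    for m in models:
        base = m.tss
        classes = sorted(
            r.te_class
            for r in rep_by_chrom.get(m.chrom, ())
            if r.interval.start <= base < r.interval.end
        )
        out[m.transcript_id] = (bool(classes), classes[0] if classes else None)
    return out
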