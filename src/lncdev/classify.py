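"""lncRNA classification cascade.

Transcripts are classified in an additive filtering cascade:

1. length filter — mature length must exceed 200 nt;
2. *candidate* lncRNAs — no protein / domain / structural-RNA homology and a
   longest ORF below 100 aa;
3. *potential* lncRNAs — non-coding potential (NCP) strictly greater than the
   mean NCP of all candidates (a data-driven cutoff; 0.76 on the original
   Tetraodon data);
4. positional filter — removes potential lncRNAs that likely are alternative
   polyadenylated read-through of coding genes (overlapping a coding gene or
   lying within 5 kb downstream of its 3' end; mono-exonic transcripts are
   removed regardless of orientation, multi-exonic ones only on the same
   strand);
5. *lincRNAs* — final lncRNAs with zero overlap with any coding locus span.

Everything failing the candidate/potential steps is treated as coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    AnnotationRecord,
    CageTag,
    GenomeInterval,
    GenomeSpec,
    TranscriptModel,
    locus_spans,
    overlap_length,
    total_length,
)

STAGES = ("discarded_short", "coding", "candidate", "potential", "lncRNA", "lincRNA")


@dataclass
class ClassificationResult:
    transcript_id: str
    stage_reached: str
    filter_reasons: list[str] = field(default_factory=list)
    cage_supported: bool = False


def filter_min_length(
    models: Iterable[TranscriptModel], min_length: int = 200, strict: bool = True
) -> list[TranscriptModel]:
    """Keep transcripts with mature length > ``min_length`` (>= if ``strict=False``).

    The default strict comparison discards a transcript of exactly 200 nt.
    """
    if strict:
        return [m for m in models if m.length > min_length]
    return [m for m in models if m.length >= min_length]


def call_candidates(records: Iterable[AnnotationRecord]) -> set[str]:
    """Candidate lncRNAs: no homology evidence of any kind and ORF < 100 aa."""
    seen: set[str] = set()
    out: set[str] = set()
    for r in records:
        if r.transcript_id in seen:
            raise ValueError(f"duplicate annotation record for {r.transcript_id}")
        seen.add(r.transcript_id)
        if (
            not r.has_protein_hit
            and not r.has_domain_hit
            and not r.has_ncrna_hit
            and r.longest_orf_aa < 100
        ):
            out.add(r.transcript_id)
    return out


def ncp_cutoff(candidates: Sequence[AnnotationRecord]) -> float:
    """Arithmetic mean NCP over candidate lncRNAs.

    Potential lncRNAs are the candidates with NCP *strictly greater* than
    this value; with a single candidate (or all-equal NCPs) nothing passes.
    """
    if not candidates:
        raise ValueError("NCP cutoff undefined with zero candidates")
    return float(np.mean([r.ncp for r in candidates]))


def _downstream_flank(gene: GenomeInterval, flank: int) -> GenomeInterval | None:
    """The ``flank``-bp region immediately 3' of a gene, in its strand orientation."""
    if gene.strand == "+":
        return GenomeInterval(gene.chrom, gene.end, gene.end + flank, gene.strand)
    if gene.start == 0:
        return None
    return GenomeInterval(gene.chrom, max(0, gene.start - flank), gene.start, gene.strand)


def positional_filter(
    potentials: Sequence[TranscriptModel],
    coding: Sequence[TranscriptModel],
    downstream_bp: int = 5000,
) -> tuple[list[TranscriptModel], dict[str, list[str]]]:
    """Remove potential lncRNAs that look like coding-gene 3' read-through.

    Mono-exonic potentials are removed when they overlap a coding gene span
    or intersect the 5-kb downstream (3'-oriented) flank of one, regardless
    of strand. Multi-exonic potentials are removed only when the offending
    coding gene is on the same strand. Returns (kept, removed reasons).
    """
    kept: list[TranscriptModel] = []
    removed: dict[str, list[str]] = {}
    coding_ivs = [c.interval for c in coding]
    flanks = [f for f in (_downstream_flank(iv, downstream_bp) for iv in coding_ivs) if f]
    for m in potentials:
        span = m.interval
        mono = len(m.exons) == 1
        reasons = []
        for iv in coding_ivs:
            if overlap_length(span, iv) > 0 and (mono or iv.strand == m.strand):
                reasons.append(f"overlaps_coding:{iv.chrom}:{iv.start}-{iv.end}")
                break
        if not reasons:
            for fl in flanks:
                if overlap_length(span, fl) > 0 and (mono or fl.strand == m.strand):
                    reasons.append(f"downstream_of_coding:{fl.chrom}:{fl.start}-{fl.end}")
                    break
        if reasons:
            removed[m.transcript_id] = reasons
        else:
            kept.append(m)
    return kept, removed


def call_lincRNAs(
    lncRNAs: Sequence[TranscriptModel], coding: Sequence[TranscriptModel]
) -> set[str]:
    """lncRNAs with zero overlap (exon or intron) with any coding locus span.

    Strand-agnostic; an antisense lncRNA inside a coding intron is a lncRNA
    but not a lincRNA.
    """
    spans = list(locus_spans(coding).values())
    out = set()
    for m in lncRNAs:
        if all(overlap_length(m.interval, s) == 0 for s in spans):
            out.add(m.transcript_id)
    return out


def cage_support(
    models: Sequence[TranscriptModel],
    tags: Iterable[CageTag],
    upstream: int = 1000,
    downstream: int = 400,
    min_tpm: float = 0.5,
) -> dict[str, bool]:
    """Flag transcripts with a CAGE tag of >= ``min_tpm`` near their TSS.

    The window is strand-oriented: [TSS - upstream, TSS + downstream] on the
    transcript's 5' side, inclusive at both ends. Invariant to tag order and
    duplicated tags.
    """
    by_chrom: dict[str, list[CageTag]] = {}
    for t in tags:
        if t.tpm >= min_tpm:
            by_chrom.setdefault(t.position.chrom, []).append(t)
    out = {}
    for m in models:
        tss = m.tss
        if m.strand == "+":
            lo, hi = tss - upstream, tss + downstream
        else:
            lo, hi = tss - downstream, tss + upstream
        out[m.transcript_id] = any(
            lo <= t.position.start <= hi for t in by_chrom.get(m.chrom, ())
        )
    return out


def map_to_reference(
    assembled: Sequence[TranscriptModel],
    reference: Sequence[TranscriptModel],
    ests: Sequence[GenomeInterval] = (),
) -> pd.DataFrame:
    """Label each assembled locus against reference gene models and ESTs.

    A locus is ``common`` when any of its transcripts shares >= 1 exonic bp
    with a reference transcript on the same strand; loci overlapping only an
    EST (strand-agnostic) are ``est_supported``; loci overlapping neither are
    ``novel``. For common loci the extension category compares the assembled
    locus span with the span of the matched reference gene, in the locus'
    strand orientation.
    """
    ref_by_locus = {}
    for r in reference:
        ref_by_locus.setdefault(r.locus_id, []).append(r)
    rows = []
    ass_by_locus: dict[str, list[TranscriptModel]] = {}
    for m in assembled:
        ass_by_locus.setdefault(m.locus_id, []).append(m)
    for locus_id, members in ass_by_locus.items():
        match_gene = None
        for m in members:
            for gid, refs in ref_by_locus.items():
                for r in refs:
                    if r.strand != m.strand or r.chrom != m.chrom:
                        continue
                    if any(
                        overlap_length(e, re_) > 0 for e in m.exons for re_ in r.exons
                    ):
                        match_gene = gid
                        break
                if match_gene:
                    break
            if match_gene:
                break
        span = locus_spans(members)[locus_id]
        if match_gene is not None:
            ref_span = locus_spans(ref_by_locus[match_gene])[match_gene]
            left = span.start < ref_span.start
            right = span.end > ref_span.end
            if span.strand == "-":
                left, right = right, left
            ext = {
                (True, True): "both_ends",
                (True, False): "5p_only",
                (False, True): "3p_only",
                (False, False): "none",
            }[(left, right)]
            rows.append({"locus_id": locus_id, "label": "common",
                         "reference_gene": match_gene, "extension": ext})
            continue
        est_hit = any(
            overlap_length(span, est) > 0 for est in ests
        )
        rows.append(
            {"locus_id": locus_id,
             "label": "est_supported" if est_hit else "novel",
             "reference_gene": None, "extension": "na"}
        )
    return pd.DataFrame(rows)


def anatomy_stats(
    models: Sequence[TranscriptModel], genome: GenomeSpec
) -> pd.DataFrame:
    """Transcript-anatomy summary per biotype.

    Reports exon/intron length distributions, exon counts, the mono-exonic
    fraction and the transcribed genomic fraction (merged exonic bp over
    genome bp, shared bases counted once).
    """
    rows = []
    by_bt: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_bt.setdefault(m.biotype, []).append(m)
    for bt, ms in sorted(by_bt.items()):
        exon_lens = [e.length for m in ms for e in m.exons]
        intron_lens = [i.length for m in ms for i in m.introns]
        exon_counts = [len(m.exons) for m in ms]
        merged_bp = total_length(e for m in ms for e in m.exons)
        rows.append(
            {
                "biotype": bt,
                "n_transcripts": len(ms),
                "n_loci": len({m.locus_id for m in ms}),
                "mean_exon_length": float(np.mean(exon_lens)),
                "median_exon_length": float(np.median(exon_lens)),
                "mean_intron_length": float(np.mean(intron_lens)) if intron_lens else 0.0,
                "median_intron_length": float(np.median(intron_lens)) if intron_lens else 0.0,
                "mean_exon_count": float(np.mean(exon_counts)),
                "monoexonic_fraction": float(np.mean([c == 1 for c in exon_counts])),
                "transcribed_fraction": merged_bp / genome.total_bp,
            }
        )
    return pd.DataFrame(rows)


def classify_transcripts(
    models: Sequence[TranscriptModel],
    records: Mapping[str, AnnotationRecord],
    cage: Iterable[CageTag] = (),
    min_length: int = 200,
    downstream_bp: int = 5000,
) -> tuple[dict[str, ClassificationResult], list[TranscriptModel]]:
    """Run the full cascade; returns (results by transcript, relabelled models).

    Relabelled models carry biotype coding / lncRNA / lincRNA according to the
    cascade outcome (short transcripts are dropped from the returned models).
    """
    results: dict[str, ClassificationResult] = {}
    kept = filter_min_length(models, min_length)
    kept_ids = {m.transcript_id for m in kept}
    for m in models:
        if m.transcript_id not in kept_ids:
            results[m.transcript_id] = ClassificationResult(
                m.transcript_id, "discarded_short", [f"length<={min_length}"]
            )
    recs = [records[m.transcript_id] for m in kept if m.transcript_id in records]
    missing = [m.transcript_id for m in kept if m.transcript_id not in records]
    if missing:
        raise ValueError(f"missing annotation records for {len(missing)} transcripts, e.g. {missing[0]}")
    candidates = call_candidates(recs)
    cand_recs = [r for r in recs if r.transcript_id in candidates]
    if cand_recs:
        cutoff = ncp_cutoff(cand_recs)
        potential_ids = {r.transcript_id for r in cand_recs if r.ncp > cutoff}
    else:
        cutoff = float("nan")
        potential_ids = set()
    coding_models = [m for m in kept if m.transcript_id not in potential_ids]
    potential_models = [m for m in kept if m.transcript_id in potential_ids]
    lnc_models, removed = positional_filter(potential_models, coding_models, downstream_bp)
    lnc_ids = {m.transcript_id for m in lnc_models}
    linc_ids = call_lincRNAs(lnc_models, coding_models)
    supported = cage_support(kept, cage) if cage else {}
    out_models: list[TranscriptModel] = []
    for m in kept:
        tid = m.transcript_id
        if tid in linc_ids:
            res = ClassificationResult(tid, "lincRNA")
            out_models.append(m.with_biotype("lincRNA"))
        elif tid in lnc_ids:
            res = ClassificationResult(tid, "lncRNA")
            out_models.append(m.with_biotype("lncRNA"))
        elif tid in removed:
            res = ClassificationResult(tid, "potential", removed[tid])
            out_models.append(m.with_biotype("coding"))
        elif tid in candidates:
            res = ClassificationResult(tid, "candidate", [f"ncp<=mean({cutoff:.4f})"])
            out_models.append(m.with_biotype("coding"))
        else:
            res = ClassificationResult(tid, "coding", ["homology_or_orf"])
            out_models.append(m.with_biotype("coding"))
        res.cage_supported = supported.get(tid, False)
        results[tid] = res
    return results, out_models
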