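"""Readers and writers for the standard formats the pipeline touches.

GTF (Ensembl dialect, 1-based closed) and refFlat are converted to the
internal 0-based half-open convention on read; BED is already half-open.
All tabular formats are TSV with a header row.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from gffutils.feature import feature_from_line

from .core import (
    AlignmentBlock,
    AnnotationRecord,
    CageTag,
    GenomeInterval,
    RepeatElement,
    TranscriptModel,
)


class FormatError(ValueError):
    """A malformed input file; the message names the offending file/line."""


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse a GTF file into transcript models.

    Only ``exon`` features are used; they must carry ``transcript_id`` and
    ``gene_id`` attributes. Exons arriving out of order are sorted. An
    optional ``transcript_biotype`` attribute is honoured when it matches an
    internal biotype label.
    """
    exons: dict[str, list[GenomeInterval]] = {}
    locus: dict[str, str] = {}
    biotype: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF fields")
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # gffutils raises assorted types
                raise FormatError(f"{path}:{lineno}: malformed GTF line ({exc})") from exc
            if feat.featuretype != "exon":
                continue
            attrs = feat.attributes
            if "transcript_id" not in attrs:
                raise FormatError(f"{path}:{lineno}: exon without transcript_id")
            tid = attrs["transcript_id"][0]
            gid = attrs["gene_id"][0] if "gene_id" in attrs else tid
            # GTF is 1-based closed: [start, end] -> [start-1, end)
            iv = GenomeInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            exons.setdefault(tid, []).append(iv)
            locus[tid] = gid
            if "transcript_biotype" in attrs:
                biotype[tid] = attrs["transcript_biotype"][0]
    models = []
    for tid, ivs in exons.items():
        bt = biotype.get(tid, "unclassified")
        if bt not in ("coding", "lncRNA", "lincRNA", "unclassified"):
            bt = "unclassified"
        models.append(TranscriptModel(tid, locus[tid], tuple(ivs), bt))
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str | Path, source: str = "lncdev") -> None:
    """Write transcript models as GTF exon lines (1-based closed coordinates).

    Round-trips with :func:`read_gtf`: reading a file produced here and
    writing it again is byte-identical.
    """
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.chrom, m.interval.start, m.transcript_id)):
            for e in m.exons:
                attrs = (
                    f'gene_id "{m.locus_id}"; transcript_id "{m.transcript_id}"; '
                    f'transcript_biotype "{m.biotype}";'
                )
                fh.write(
                    f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed12(models: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.chrom, m.interval.start, m.transcript_id)):
            iv = m.interval
            sizes = ",".join(str(e.length) for e in m.exons) + ","
            starts = ",".join(str(e.start - iv.start) for e in m.exons) + ","
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        m.transcript_id,
                        "0",
                        m.strand,
                        str(iv.start),
                        str(iv.end),
                        "0",
                        str(len(m.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def read_bed12(path: str | Path) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED columns, got {len(f)}")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                GenomeInterval(chrom, start + o, start + o + s, strand)
                for o, s in zip(offsets, sizes)
            )
            models.append(TranscriptModel(name, name, exons))
    return models


def write_bed6(intervals: Iterable[GenomeInterval], names: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, name in zip(intervals, names):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# refFlat (reader only)
# ---------------------------------------------------------------------------

def read_refflat(path: str | Path) -> list[TranscriptModel]:
    """Read UCSC refFlat gene models (0-based half-open exon coordinates)."""
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 11:
                raise FormatError(f"{path}:{lineno}: expected 11 refFlat columns")
            gene, name, chrom, strand = f[0], f[1], f[2], f[3]
            starts = [int(x) for x in f[9].rstrip(",").split(",")]
            ends = [int(x) for x in f[10].rstrip(",").split(",")]
            exons = tuple(GenomeInterval(chrom, s, e, strand) for s, e in zip(starts, ends))
            models.append(TranscriptModel(name, gene, exons))
    return models


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_annotation_table(path: str | Path) -> dict[str, AnnotationRecord]:
    """Annotation TSV -> records keyed by transcript id.

    Columns: transcript_id, has_protein_hit, has_domain_hit, has_ncrna_hit,
    longest_orf_aa, ncp, has_swissprot_hit, go_terms (semicolon-separated,
    may be empty).
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str}, float_precision="round_trip")
    records = {}
    for row in df.itertuples(index=False):
        go = getattr(row, "go_terms", "")
        go_set = frozenset(t for t in str(go).split(";") if t and t != "nan")
        rec = AnnotationRecord(
            transcript_id=row.transcript_id,
            has_protein_hit=bool(row.has_protein_hit),
            has_domain_hit=bool(row.has_domain_hit),
            has_ncrna_hit=bool(row.has_ncrna_hit),
            longest_orf_aa=int(row.longest_orf_aa),
            ncp=float(row.ncp),
            has_swissprot_hit=bool(row.has_swissprot_hit),
            go_terms=go_set,
        )
        if rec.transcript_id in records:
            raise FormatError(f"duplicate transcript_id {rec.transcript_id} in {path}")
        records[rec.transcript_id] = rec
    return records


def write_annotation_table(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    rows = [
        {
            "transcript_id": r.transcript_id,
            "has_protein_hit": int(r.has_protein_hit),
            "has_domain_hit": int(r.has_domain_hit),
            "has_ncrna_hit": int(r.has_ncrna_hit),
            "longest_orf_aa": r.longest_orf_aa,
            "ncp": r.ncp,
            "has_swissprot_hit": int(r.has_swissprot_hit),
            "go_terms": ";".join(sorted(r.go_terms)),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_cage_table(path: str | Path) -> list[CageTag]:
    """CAGE TSV with columns chrom, position, strand, tpm (position 0-based)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        CageTag(GenomeInterval(str(r.chrom), int(r.position), int(r.position) + 1, str(r.strand)), float(r.tpm))
        for r in df.itertuples(index=False)
    ]


def write_cage_table(tags: Iterable[CageTag], path: str | Path) -> None:
    rows = [
        {"chrom": t.position.chrom, "position": t.position.start, "strand": t.position.strand, "tpm": t.tpm}
        for t in tags
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_repeat_table(path: str | Path) -> list[RepeatElement]:
    """Repeats as BED6 plus te_class and te_family columns (8 columns, with header)."""
    reps = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            reps.append(
                RepeatElement(
                    GenomeInterval(row["chrom"], int(row["start"]), int(row["end"]), row["strand"]),
                    row["te_class"],
                    row["te_family"],
                )
            )
    return reps


def write_repeat_table(repeats: Iterable[RepeatElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tname\tscore\tstrand\tte_class\tte_family\n")
        for i, r in enumerate(repeats):
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\trep{i}\t0\t{iv.strand}\t{r.te_class}\t{r.te_family}\n"
            )


def read_block_table(path: str | Path) -> list[AlignmentBlock]:
    """Alignment blocks as TSV: block_id, species, chrom, start, end, score.

    One row per (block, species) element; a documented reduction of MAF.
    """
    df = pd.read_csv(path, sep="\t", dtype={"block_id": str, "species": str, "chrom": str}, float_precision="round_trip")
    blocks = []
    for bid, grp in df.groupby("block_id", sort=True):
        elements = {
            r.species: GenomeInterval(r.chrom, int(r.start), int(r.end))
            for r in grp.itertuples(index=False)
        }
        scores = set(float(s) for s in grp["score"])
        if len(scores) != 1:
            raise FormatError(f"block {bid}: inconsistent similarity scores in {path}")
        blocks.append(AlignmentBlock(bid, elements, scores.pop()))
    return blocks


def write_block_table(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    rows = []
    for b in blocks:
        for sp, iv in sorted(b.elements.items()):
            rows.append(
                {"block_id": b.block_id, "species": sp, "chrom": iv.chrom,
                 "start": iv.start, "end": iv.end, "score": b.similarity}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_orthology_table(path: str | Path) -> set[tuple[str, str]]:
    """Orthology TSV with two columns (geneA, geneB); returns a set of pairs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    a_col, b_col = df.columns[:2]
    return {(r1, r2) for r1, r2 in zip(df[a_col], df[b_col])}


def write_orthology_table(
    pairs: Iterable[tuple[str, str]], path: str | Path, species: tuple[str, str] = ("speciesA", "speciesB")
) -> None:
    rows = [{f"{species[0]}_gene": a, f"{species[1]}_gene": b} for a, b in sorted(pairs)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
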