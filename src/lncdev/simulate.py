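"""Synthetic multi-species datasets with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume, for a compact pufferfish-like genome:

* coding genes and lncRNAs with biotype-specific anatomy (lncRNAs shorter,
  with fewer but longer exons), placed without overlaps except for
  deliberately planted positional violators;
* per-transcript annotation evidence (homology flags, ORF length, NCP,
  SwissProt, GO terms) separating coding from non-coding transcripts;
* negative-binomial read counts over three stages (egg, 30% epiboly, 24 hpf)
  at a known common dispersion, with planted maternal / embryonic /
  housekeeping expression profiles;
* cross-species alignment blocks over planted conserved lncRNAs, planted
  microsyntenic lincRNA cassettes with orthologous flanking genes, TE
  insertions (exonic and TSS-associated), and CAGE tags at supported TSSs.

Only coordinates and feature tables are generated — never nucleotides.
Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import (
    AlignmentBlock,
    AnnotationRecord,
    CageTag,
    GenomeInterval,
    GenomeSpec,
    RepeatElement,
    TranscriptModel,
    locus_spans,
)

MARKER_GO_TERM = "GO:0009790"  # embryonic development — the planted marker class

TE_FAMILIES = {
    "LINE": ("L1", "L2"),
    "SINE": ("MIR", "V-SINE"),
    "DNA": ("hAT", "TcMar"),
    "LTR": ("ERVK", "Gypsy"),
}


def _default_genome() -> dict[str, int]:
    return {f"chr{i}": 1_500_000 for i in range(1, 13)}


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(default_factory=_default_genome)
    species: tuple[str, ...] = ("tetraodon", "zebrafish")
    n_coding: int = 500
    n_lncrna: int = 200
    stages: tuple[str, ...] = ("egg", "epi30", "hpf24")
    dispersion_true: float = 0.35
    frac_maternal: float = 0.08
    frac_embryonic: float = 0.12
    logfc_magnitude: float = 3.0
    n_housekeeping_true: int = 100
    n_planted_syntenic: int = 20
    n_embryonic_cassettes: int = 40
    n_planted_conserved_blocks: int = 8
    n_te_exonic: int = 20
    n_te_tss: int = 6
    frac_positional_violators: float = 0.15
    isoform_prob: float = 0.25
    frac_cage_supported: float = 0.6
    frac_background_orthologs: float = 0.5
    n_background_blocks: int = 100
    te_per_mb: float = 20.0
    # anatomy: log-normal parameters (log-scale mean, sigma)
    coding_exon_len: tuple[float, float] = (np.log(150), 0.5)
    coding_intron_len: tuple[float, float] = (np.log(400), 0.8)
    lnc_exon_len: tuple[float, float] = (np.log(350), 0.6)
    lnc_intron_len: tuple[float, float] = (np.log(800), 0.8)
    coding_exon_rate: float = 5.0  # exons ~ 1 + Poisson(rate)
    lnc_exon_rate: float = 1.2
    # expression: log-normal baseline means
    coding_mean: tuple[float, float] = (np.log(120), 1.0)
    lnc_mean: tuple[float, float] = (np.log(20), 1.0)

    def __post_init__(self) -> None:
        if not (0 <= self.frac_maternal <= 1 and 0 <= self.frac_embryonic <= 1):
            raise ValueError("proportions must lie in [0,1]")
        if self.frac_maternal + self.frac_embryonic > 1:
            raise ValueError("maternal + embryonic fractions exceed 1")
        if self.dispersion_true < 0:
            raise ValueError("dispersion must be >= 0")
        for name in ("n_coding", "n_lncrna", "n_planted_syntenic",
                     "n_planted_conserved_blocks", "n_te_exonic", "n_te_tss"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def genome(self) -> GenomeSpec:
        return GenomeSpec(self.chrom_lengths)


@dataclass
class PlantedTruth:
    """Ground-truth labels for everything the generator planted."""

    labels: dict[str, str] = field(default_factory=dict)  # tid -> maternal/embryonic/stable
    true_biotypes: dict[str, str] = field(default_factory=dict)  # tid -> coding/lncRNA
    housekeeping_genes: set[str] = field(default_factory=set)
    housekeeping_transcripts: set[str] = field(default_factory=set)
    syntenic_pairs: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    conserved: dict[str, set[str]] = field(default_factory=dict)  # species -> linc ids
    te_exonic_loci: set[str] = field(default_factory=set)
    te_tss_transcripts: set[str] = field(default_factory=set)
    positional_violators: dict[str, str] = field(default_factory=dict)  # tid -> reason
    cage_supported: set[str] = field(default_factory=set)
    marker_go_term: str = MARKER_GO_TERM
    marker_lincs: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        def enc(v):
            if isinstance(v, set):
                return sorted(list(x) if isinstance(x, tuple) else x for x in v)
            if isinstance(v, dict):
                return {"|".join(k) if isinstance(k, tuple) else k: enc(x) for k, x in v.items()}
            return v

        with open(path, "w") as fh:
            json.dump({k: enc(v) for k, v in asdict(self).items()}, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            labels=raw["labels"],
            true_biotypes=raw["true_biotypes"],
            housekeeping_genes=set(raw["housekeeping_genes"]),
            housekeeping_transcripts=set(raw["housekeeping_transcripts"]),
            syntenic_pairs={
                k: {tuple(p) for p in v} for k, v in raw["syntenic_pairs"].items()
            },
            conserved={k: set(v) for k, v in raw["conserved"].items()},
            te_exonic_loci=set(raw["te_exonic_loci"]),
            te_tss_transcripts=set(raw["te_tss_transcripts"]),
            positional_violators=raw["positional_violators"],
            cage_supported=set(raw["cage_supported"]),
            marker_go_term=raw["marker_go_term"],
            marker_lincs=set(raw["marker_lincs"]),
        )


# ---------------------------------------------------------------------------
# anatomy
# ---------------------------------------------------------------------------

def _lengths(rng, params, n, lo=30):
    mu, sigma = params
    return np.maximum(lo, np.rint(rng.lognormal(mu, sigma, n))).astype(int)


def _make_transcript(
    rng: np.random.Generator,
    tid: str,
    locus: str,
    chrom: str,
    start: int,
    strand: str,
    biotype_kind: str,
    cfg: SimulationConfig,
    min_mature: int = 0,
    n_exons: int | None = None,
) -> TranscriptModel:
    if biotype_kind == "coding":
        exon_p, intron_p, rate = cfg.coding_exon_len, cfg.coding_intron_len, cfg.coding_exon_rate
    else:
        exon_p, intron_p, rate = cfg.lnc_exon_len, cfg.lnc_intron_len, cfg.lnc_exon_rate
    if n_exons is None:
        n_exons = 1 + int(rng.poisson(rate))
    # redraw at fixed exon count until the mature-length floor is met (the
    # exon count is part of the planted design, e.g. mono-exonic violators)
    for _ in range(100):
        exon_lens = _lengths(rng, exon_p, n_exons)
        if exon_lens.sum() >= min_mature:
            break
    else:
        exon_lens = _lengths(rng, exon_p, n_exons, lo=-(-min_mature // n_exons))
    intron_lens = _lengths(rng, intron_p, max(0, n_exons - 1), lo=50)
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append(GenomeInterval(chrom, pos, pos + int(el), strand))
        pos += int(el)
        if i < len(intron_lens):
            pos += int(intron_lens[i])
    return TranscriptModel(tid, locus, tuple(exons), "unclassified")


def _isoform(rng: np.random.Generator, base: TranscriptModel, tid: str) -> TranscriptModel:
    """A second transcript of the same locus: drop one internal exon if possible."""
    exons = list(base.exons)
    if len(exons) > 2:
        drop = int(rng.integers(1, len(exons) - 1))
        exons.pop(drop)
    else:
        first = exons[0]
        trim = min(first.length - 30, 50)
        if trim > 0:
            exons[0] = GenomeInterval(first.chrom, first.start + trim, first.end, first.strand)
    return TranscriptModel(tid, base.locus_id, tuple(exons), "unclassified")


# ---------------------------------------------------------------------------
# per-species annotation
# ---------------------------------------------------------------------------

@dataclass
class SpeciesAnnotation:
    name: str
    genome: GenomeSpec
    models: list[TranscriptModel]
    records: list[AnnotationRecord]
    roles: dict[str, list]  # role name -> ordered ids (index-aligned across species)


def _place_units(
    rng: np.random.Generator, genome: GenomeSpec, units: list[list[TranscriptModel]]
) -> list[TranscriptModel]:
    """Distribute placement units over chromosomes with random inter-unit gaps.

    Units are internally laid out starting at 0; here each is shifted to a
    chromosome cursor. Raises when the genome cannot host all units.
    """
    order = rng.permutation(len(units))
    chroms = sorted(genome)
    cursors = {c: int(rng.integers(1_000, 5_000)) for c in chroms}
    placed: list[TranscriptModel] = []
    for idx in order:
        unit = units[idx]
        span = max(m.interval.end for m in unit)
        # inter-unit gaps stay above the 5-kb read-through flank so only the
        # deliberately planted violators trip the positional filter
        gap = int(rng.integers(5_500, 20_000))
        candidates = [c for c in chroms if cursors[c] + gap + span < genome[c]]
        if not candidates:
            raise ValueError(
                f"genome too small: cannot place a {span}-bp unit; "
                "increase chromosome lengths or reduce feature counts"
            )
        chrom = candidates[int(rng.integers(len(candidates)))]
        offset = cursors[chrom] + gap
        for m in unit:
            placed.append(m.relocated(chrom, m.interval.start + offset))
        cursors[chrom] = offset + span
    return placed


def _generate_species(
    config: SimulationConfig, species: str, rng: np.random.Generator
) -> tuple[SpeciesAnnotation, PlantedTruth]:
    """One species' transcript models, annotation records and local truth.

    Role lists (planted syntenic / conserved / ... feature ids) are
    index-aligned across species generated from the same config, which is
    how the orchestrator links features between species.
    """
    cfg = config
    P = f"{species[:3].upper()}"
    n_special = (
        cfg.n_planted_syntenic + cfg.n_embryonic_cassettes + cfg.n_planted_conserved_blocks
        + cfg.n_te_exonic + cfg.n_te_tss
    )
    n_violators = int(cfg.frac_positional_violators * cfg.n_lncrna)
    if n_special + n_violators > cfg.n_lncrna:
        raise ValueError("n_lncrna too small for the requested planted features")

    roles: dict[str, list] = {
        "syntenic": [], "syntenic_flanks": [], "embryonic_cassette": [],
        "marker_genes": [], "conserved": [], "te_exonic": [], "te_tss": [],
        "violator_overlap": [], "violator_downstream": [], "generic_lnc": [],
        "generic_coding": [],
    }
    units: list[list[TranscriptModel]] = []
    lnc_i = coding_i = 0

    def new_lnc(kind: str, start=0, strand=None, n_exons=None, min_mature=0):
        nonlocal lnc_i
        tid = f"{P}_LNC{lnc_i:04d}"
        lnc_i += 1
        strand = strand or ("+" if rng.random() < 0.5 else "-")
        return _make_transcript(
            rng, tid, f"{P}_LNCLOC{lnc_i - 1:04d}", "u", start, strand, "lnc", cfg,
            min_mature=min_mature, n_exons=n_exons,
        )

    def new_gene(start=0, strand=None):
        nonlocal coding_i
        tid = f"{P}_C{coding_i:04d}"
        coding_i += 1
        strand = strand or ("+" if rng.random() < 0.5 else "-")
        return _make_transcript(
            rng, tid, f"{P}_GENE{coding_i - 1:04d}", "u", start, strand, "coding", cfg
        )

    # planted microsyntenic cassettes: geneA -- linc -- geneB, contiguous unit
    for _ in range(cfg.n_planted_syntenic):
        a = new_gene()
        linc = new_lnc("syntenic", n_exons=2 + int(rng.poisson(1)), min_mature=400)
        b = new_gene()
        gap1, gap2 = rng.integers(6_000, 9_000, 2)
        linc = linc.relocated("u", a.interval.end + int(gap1))
        b = b.relocated("u", linc.interval.end + int(gap2))
        units.append([a, linc, b])
        roles["syntenic"].append(linc.transcript_id)
        roles["syntenic_flanks"].append((a.locus_id, b.locus_id))

    # embryonic lincRNAs next to marker-GO coding genes
    for _ in range(cfg.n_embryonic_cassettes):
        g = new_gene()
        linc = new_lnc("embryonic", n_exons=2 + int(rng.poisson(1)), min_mature=400)
        gap = int(rng.integers(6_000, 9_000))
        linc = linc.relocated("u", g.interval.end + gap)
        units.append([g, linc])
        roles["embryonic_cassette"].append(linc.transcript_id)
        roles["marker_genes"].append(g.locus_id)

    # conserved lincRNAs and TE-planted lncRNAs: ordinary intergenic units
    for role, n in (
        ("conserved", cfg.n_planted_conserved_blocks),
        ("te_exonic", cfg.n_te_exonic),
        ("te_tss", cfg.n_te_tss),
    ):
        for _ in range(n):
            linc = new_lnc(role, n_exons=2 + int(rng.poisson(1)), min_mature=400)
            units.append([linc])
            roles[role].append(linc.transcript_id)

    # positional violators: overlapping / downstream of a coding gene
    for v in range(n_violators):
        g = new_gene()
        if v % 2 == 0:
            # mono-exonic, any strand, overlapping the gene span
            off = int(rng.integers(0, max(1, g.interval.length // 2)))
            linc = new_lnc("viol", n_exons=1, min_mature=250)
            linc = linc.relocated("u", g.interval.start + off)
            roles["violator_overlap"].append(linc.transcript_id)
        else:
            # multi-exonic, same strand, < 5 kb downstream of the gene 3' end
            linc = new_lnc("viol", strand=g.strand, n_exons=2, min_mature=250)
            gap = int(rng.integers(100, 4_500))
            if g.strand == "+":
                linc = linc.relocated("u", g.interval.end + gap)
                units.append([g, linc])
            else:
                g = g.relocated("u", linc.interval.end + gap)
                units.append([linc, g])
            roles["violator_downstream"].append(linc.transcript_id)
            continue
        units.append([g, linc])

    # generic lncRNAs and the remaining coding genes
    for _ in range(cfg.n_lncrna - lnc_i):
        linc = new_lnc("generic")
        units.append([linc])
        roles["generic_lnc"].append(linc.transcript_id)
    for _ in range(cfg.n_coding - coding_i):
        g = new_gene()
        units.append([g])
        roles["generic_coding"].append(g.locus_id)

    genome = cfg.genome
    placed = _place_units(rng, genome, units)

    # coding isoforms
    models: list[TranscriptModel] = []
    iso_i = 0
    for m in placed:
        models.append(m)
        if m.transcript_id.startswith(f"{P}_C") and rng.random() < cfg.isoform_prob:
            models.append(_isoform(rng, m, f"{P}_C_ISO{iso_i:04d}"))
            iso_i += 1
    genome.validate_intervals(e for m in models for e in m.exons)

    # planted features (and violators, whose removal reason must be positional,
    # not an NCP failure) sit in the top NCP band so the data-driven mean
    # cutoff does not silently discard them
    special_lnc = set(
        roles["syntenic"] + roles["embryonic_cassette"] + roles["conserved"]
        + roles["te_exonic"] + roles["te_tss"]
        + roles["violator_overlap"] + roles["violator_downstream"]
    )
    records = []
    go_pool = [f"GO:{7000000 + i}" for i in range(30)]
    marker_gene_set = set(roles["marker_genes"])
    for m in models:
        is_coding = m.transcript_id.startswith(f"{P}_C")
        if is_coding:
            go = set(rng.choice(go_pool, size=int(rng.integers(0, 5)), replace=False))
            if m.locus_id in marker_gene_set and rng.random() < 0.9:
                go.add(MARKER_GO_TERM)
            elif rng.random() < 0.02:
                go.add(MARKER_GO_TERM)
            records.append(
                AnnotationRecord(
                    m.transcript_id,
                    has_protein_hit=rng.random() < 0.95,
                    has_domain_hit=rng.random() < 0.7,
                    has_ncrna_hit=False,
                    longest_orf_aa=max(100, int(rng.lognormal(np.log(300), 0.5))),
                    ncp=float(rng.beta(2, 5)),
                    has_swissprot_hit=rng.random() < 0.8,
                    go_terms=frozenset(go),
                )
            )
        else:
            if m.transcript_id in special_lnc:
                ncp = float(rng.uniform(0.95, 0.995))
            else:
                ncp = float(rng.beta(8, 2))
            records.append(
                AnnotationRecord(
                    m.transcript_id,
                    has_protein_hit=False,
                    has_domain_hit=False,
                    has_ncrna_hit=(m.transcript_id not in special_lnc) and rng.random() < 0.05,
                    longest_orf_aa=int(rng.integers(10, 100)),
                    ncp=ncp,
                    has_swissprot_hit=False,
                    go_terms=frozenset(),
                )
            )

    truth = PlantedTruth()
    for m in models:
        truth.true_biotypes[m.transcript_id] = (
            "coding" if m.transcript_id.startswith(f"{P}_C") else "lncRNA"
        )
    for tid in roles["violator_overlap"]:
        truth.positional_violators[tid] = "overlaps_coding"
    for tid in roles["violator_downstream"]:
        truth.positional_violators[tid] = "downstream_of_coding"
    truth.te_tss_transcripts = set(roles["te_tss"])
    truth.marker_lincs = set(roles["embryonic_cassette"])
    ann = SpeciesAnnotation(species, genome, models, records, roles)
    return ann, truth


def _species_key(config: SimulationConfig, species: str) -> int:
    return list(config.species).index(species) + 1


def _species_rng(config: SimulationConfig, species: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, _species_key(config, species)])
    )


def generate_annotation(
    config: SimulationConfig,
    species: str | None = None,
) -> tuple[list[TranscriptModel], list[AnnotationRecord], PlantedTruth]:
    """Models, annotation records and planted truth for one species."""
    species = species or config.species[0]
    ann, truth = _generate_species(config, species, _species_rng(config, species))
    return ann.models, ann.records, truth


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_draw(rng, mu, phi):
    mu = np.asarray(mu, dtype=float)
    if phi <= 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu))


def assign_expression_labels(
    models: Sequence[TranscriptModel],
    roles: Mapping[str, list],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, str], set[str]]:
    """Per-transcript maternal/embryonic/stable labels plus housekeeping genes.

    Embryonic-cassette lincRNAs are always embryonic; housekeeping genes are
    drawn from SwissProt-eligible coding loci and kept stable. Labels are
    assigned per locus so isoforms agree.
    """
    forced_emb = set(roles["embryonic_cassette"])
    forced_emb_loci = set(roles["marker_genes"])  # cassette genes co-vary with their lincRNA
    loci = sorted({m.locus_id for m in models})
    hk_candidates = [l for l in sorted(roles["generic_coding"])]
    rng.shuffle(hk_candidates)
    hk_genes = set(hk_candidates[: config.n_housekeeping_true])
    labels_by_locus: dict[str, str] = {}
    for locus in loci:
        u = rng.random()
        if u < config.frac_maternal:
            labels_by_locus[locus] = "maternal"
        elif u < config.frac_maternal + config.frac_embryonic:
            labels_by_locus[locus] = "embryonic"
        else:
            labels_by_locus[locus] = "stable"
    labels = {}
    for m in models:
        if m.transcript_id in forced_emb or m.locus_id in forced_emb_loci:
            labels[m.transcript_id] = "embryonic"
        elif m.locus_id in hk_genes:
            labels[m.transcript_id] = "stable"
        else:
            labels[m.transcript_id] = labels_by_locus[m.locus_id]
    return labels, hk_genes


def generate_counts(
    models: Sequence[TranscriptModel],
    labels: Mapping[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
    true_biotypes: Mapping[str, str] | None = None,
):
    """NB counts with stage structure: counts ~ NB(mu_ts, phi).

    Maternal transcripts have egg mean 2**logfc_magnitude times the later
    stages; embryonic the reverse; stable transcripts a constant mean.
    lncRNA baselines are drawn lower than coding ones. Library sizes are the
    column sums. Returns a :class:`lncdev.expression.CountMatrix`.
    """
    from .expression import CountMatrix

    stages = list(config.stages)
    fold = 2.0 ** config.logfc_magnitude
    mus = np.empty((len(models), len(stages)))
    for i, m in enumerate(models):
        bt = (true_biotypes or {}).get(m.transcript_id, "coding")
        params = config.coding_mean if bt == "coding" else config.lnc_mean
        mu0 = float(rng.lognormal(*params))
        lab = labels.get(m.transcript_id, "stable")
        if lab == "maternal":
            mus[i] = [mu0 * fold] + [mu0] * (len(stages) - 1)
        elif lab == "embryonic":
            mus[i] = [mu0] + [mu0 * fold] * (len(stages) - 1)
        else:
            mus[i] = mu0
    counts = _nb_draw(rng, mus, config.dispersion_true)
    return CountMatrix.from_counts([m.transcript_id for m in models], stages, counts)


def simulate_nb_counts(
    n_transcripts: int,
    n_stages: int,
    phi: float,
    rng: np.random.Generator,
    mean_log: tuple[float, float] = (np.log(120), 1.0),
):
    """Plain NB count matrix with a constant per-transcript mean across stages."""
    from .expression import CountMatrix

    mu = rng.lognormal(*mean_log, size=n_transcripts)
    counts = _nb_draw(rng, np.repeat(mu[:, None], n_stages, axis=1), phi)
    return CountMatrix.from_counts(
        [f"t{i}" for i in range(n_transcripts)],
        [f"s{j}" for j in range(n_stages)],
        counts,
    )


# ---------------------------------------------------------------------------
# cross-species features
# ---------------------------------------------------------------------------

def _random_subinterval(rng, iv: GenomeInterval, lo=50, hi=250) -> GenomeInterval:
    length = min(iv.length, int(rng.integers(lo, hi)))
    start = int(rng.integers(iv.start, iv.end - length + 1))
    return GenomeInterval(iv.chrom, start, start + length)


def _intergenic_interval(rng, genome: GenomeSpec, models, length: int) -> GenomeInterval:
    from .conservation import _free_segments

    spans = list(locus_spans(models).values())
    segs = [(c, s, e) for c, s, e in _free_segments(genome, spans) if e - s > length]
    c, s, e = segs[int(rng.integers(len(segs)))]
    start = int(rng.integers(s, e - length))
    return GenomeInterval(c, start, start + length)


def generate_alignment_blocks(
    species_annotations: Mapping[str, tuple[Sequence[TranscriptModel], Mapping[str, list]]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[AlignmentBlock]:
    """Blocks over planted conserved lncRNA exons plus uniform background.

    Planted blocks: two per conserved index, each element a random
    subinterval of an exon of the index-aligned conserved lncRNA of every
    species. Background blocks fall in intergenic space, so they can never
    touch a lncRNA exon.
    """
    species = list(species_annotations)
    if len(species) < 2:
        raise ValueError("alignment blocks need >= 2 species")
    by_id = {
        sp: {m.transcript_id: m for m in ann[0]} for sp, ann in species_annotations.items()
    }
    blocks: list[AlignmentBlock] = []
    bid = 0
    for j in range(config.n_planted_conserved_blocks):
        for _ in range(2):
            elements = {}
            for sp in species:
                roles = species_annotations[sp][1]
                linc = by_id[sp][roles["conserved"][j]]
                exon = linc.exons[int(rng.integers(len(linc.exons)))]
                elements[sp] = _random_subinterval(rng, exon)
            blocks.append(
                AlignmentBlock(f"pb{bid:04d}", elements, float(rng.uniform(0.4, 1.0)))
            )
            bid += 1
    for _ in range(config.n_background_blocks):
        elements = {}
        length = int(rng.integers(100, 300))
        for sp in species:
            models = species_annotations[sp][0]
            elements[sp] = _intergenic_interval(rng, config.genome, models, length)
        blocks.append(
            AlignmentBlock(f"bg{bid:04d}", elements, float(rng.uniform(0.2, 0.8)))
        )
        bid += 1
    return blocks


def generate_orthology(
    species_annotations: Mapping[str, tuple[Sequence[TranscriptModel], Mapping[str, list]]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[tuple[str, str], set[tuple[str, str]]]:
    """Orthology tables per species pair.

    Cassette flanking genes are orthologous by planted index; a configured
    fraction of generic coding genes is paired at random as background.
    """
    species = list(species_annotations)
    maps: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for i, s1 in enumerate(species):
        for s2 in species[i + 1:]:
            pairs: set[tuple[str, str]] = set()
            r1, r2 = species_annotations[s1][1], species_annotations[s2][1]
            for (a1, b1), (a2, b2) in zip(r1["syntenic_flanks"], r2["syntenic_flanks"]):
                pairs.add((a1, a2))
                pairs.add((b1, b2))
            g1 = sorted(r1["generic_coding"])
            g2 = sorted(r2["generic_coding"])
            rng.shuffle(g1)
            rng.shuffle(g2)
            n = int(config.frac_background_orthologs * min(len(g1), len(g2)))
            pairs.update(zip(g1[:n], g2[:n]))
            maps[(s1, s2)] = pairs
    return maps


def generate_repeats(
    models: Sequence[TranscriptModel],
    roles: Mapping[str, list],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[RepeatElement]:
    """Background TEs plus planted exonic and TSS-associated insertions.

    Planted exonic TEs sit inside an exon of each ``te_exonic`` lncRNA;
    planted TSS TEs are ERVK LTR fragments covering the 5' base of each
    ``te_tss`` lncRNA. Background elements are uniform over the genome.
    """
    genome = config.genome
    by_id = {m.transcript_id: m for m in models}
    repeats: list[RepeatElement] = []
    classes = sorted(TE_FAMILIES)
    n_background = int(config.te_per_mb * genome.total_bp / 1e6)
    chroms = sorted(genome)
    probs = np.array([genome[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    for _ in range(n_background):
        c = chroms[int(rng.choice(len(chroms), p=probs))]
        length = max(30, int(rng.lognormal(np.log(250), 0.6)))
        start = int(rng.integers(0, genome[c] - length))
        te_class = classes[int(rng.integers(len(classes)))]
        fam = TE_FAMILIES[te_class][int(rng.integers(len(TE_FAMILIES[te_class])))]
        repeats.append(RepeatElement(GenomeInterval(c, start, start + length), te_class, fam))
    for tid in roles["te_exonic"]:
        m = by_id[tid]
        exon = m.exons[int(rng.integers(len(m.exons)))]
        repeats.append(
            RepeatElement(
                _random_subinterval(rng, exon, 40, 150),
                classes[int(rng.integers(len(classes)))],
                "planted",
            )
        )
    for tid in roles["te_tss"]:
        m = by_id[tid]
        base = m.tss
        lead = int(rng.integers(10, 80))
        iv = GenomeInterval(m.chrom, max(0, base - lead), base + int(rng.integers(20, 120)))
        repeats.append(RepeatElement(iv, "LTR", "ERVK"))
    return repeats


def generate_cage(
    models: Sequence[TranscriptModel],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[CageTag], set[str]]:
    """CAGE tags supporting a configured fraction of transcripts.

    Supported transcripts get a tag with tpm >= 0.5 inside the -1000/+400
    strand-oriented TSS window; a further 20% get only a sub-threshold tag,
    exercising the tpm cut-off; 200 background tags land anywhere.
    """
    genome = config.genome
    tags: list[CageTag] = []
    supported: set[str] = set()
    for m in models:
        tss = m.tss
        u = rng.random()
        if u < config.frac_cage_supported or u < config.frac_cage_supported + 0.2:
            off = int(rng.integers(-1000, 401))
            pos = tss + off if m.strand == "+" else tss - off
            pos = min(max(pos, 0), genome[m.chrom] - 1)
            if u < config.frac_cage_supported:
                tpm = 0.5 + float(rng.exponential(2.0))
                supported.add(m.transcript_id)
            else:
                tpm = float(rng.uniform(0.05, 0.45))
            tags.append(CageTag(GenomeInterval(m.chrom, pos, pos + 1, m.strand), tpm))
    chroms = sorted(genome)
    for _ in range(200):
        c = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(0, genome[c] - 1))
        strand = "+" if rng.random() < 0.5 else "-"
        tags.append(CageTag(GenomeInterval(c, pos, pos + 1, strand), float(rng.exponential(1.0))))
    return tags, supported


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SimulationConfig
    annotations: dict[str, SpeciesAnnotation]
    counts: "object"  # CountMatrix of the focal species
    cage: list[CageTag]
    repeats: list[RepeatElement]
    blocks: list[AlignmentBlock]
    orthology: dict[tuple[str, str], set[tuple[str, str]]]
    truth: PlantedTruth

    @property
    def focal(self) -> SpeciesAnnotation:
        return self.annotations[self.config.species[0]]


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate every input the pipeline consumes, with planted truth."""
    anns: dict[str, SpeciesAnnotation] = {}
    truths: dict[str, PlantedTruth] = {}
    for sp in config.species:
        anns[sp], truths[sp] = _generate_species(config, sp, _species_rng(config, sp))
    focal = config.species[0]
    rng_expr = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    labels, hk_genes = assign_expression_labels(
        anns[focal].models, anns[focal].roles, config, rng_expr
    )
    counts = generate_counts(
        anns[focal].models, labels, config, rng_expr, truths[focal].true_biotypes
    )
    rng_feat = np.random.default_rng(np.random.SeedSequence([config.seed, 102]))
    pair_inputs = {sp: (a.models, a.roles) for sp, a in anns.items()}
    blocks = generate_alignment_blocks(pair_inputs, config, rng_feat)
    orthology = generate_orthology(pair_inputs, config, rng_feat)
    repeats = generate_repeats(anns[focal].models, anns[focal].roles, config, rng_feat)
    cage, cage_supported = generate_cage(anns[focal].models, config, rng_feat)

    truth = truths[focal]
    truth.labels = labels
    truth.housekeeping_genes = hk_genes
    truth.housekeeping_transcripts = {
        m.transcript_id for m in anns[focal].models if m.locus_id in hk_genes
    }
    truth.cage_supported = cage_supported
    truth.te_exonic_loci = {
        m.locus_id for m in anns[focal].models
        if m.transcript_id in set(anns[focal].roles["te_exonic"])
    }
    for sp in config.species[1:]:
        truth.syntenic_pairs[f"{focal}|{sp}"] = set(
            zip(anns[focal].roles["syntenic"], anns[sp].roles["syntenic"])
        )
    for sp in config.species:
        truth.conserved[sp] = set(anns[sp].roles["conserved"])
    return SyntheticDataset(config, anns, counts, cage, repeats, blocks, orthology, truth)
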