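"""End-to-end orchestration: classify -> DE -> conservation -> synteny -> TE -> GO.

Each stage consumes only upstream outputs and the immutable inputs; a single
global seed fans out to per-stage seeds by fixed offsets so re-running one
stage reproduces its outputs. The manifest summarizes category counts
(differential / maternal / embryonic x coding / lncRNA / lincRNA, at
transcript and locus level) plus each stage's headline statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np

from . import classify as _classify
from . import conservation as _cons
from . import enrichment as _enr
from . import expression as _expr
from . import repeats as _rep
from . import synteny as _syn
from .core import locus_spans
from .simulate import SyntheticDataset

# fixed per-stage seed offsets (stage-level reproducibility)
SEED_OFFSETS = {"classify": 11, "de": 12, "conservation": 13, "synteny": 14}


@dataclass
class PipelineConfig:
    """Every pipeline threshold, at its published default."""

    seed: int = 0
    min_length: int = 200
    downstream_bp: int = 5_000
    cage_upstream: int = 1_000
    cage_downstream: int = 400
    cage_min_tpm: float = 0.5
    hk_min_pooled_cpm: float = 1.0
    hk_n_genes: int = 100
    de_min_cpm: float = 0.5
    de_fdr_max: float = 0.01
    de_min_abs_logfc: float = 2.0
    proximal_window: int = 10_000
    shuffle_reps: int = 200
    synteny_reps: int = 100
    go_min_members: int = 5
    go_fdr_max: float = 0.05

    def validate(self) -> None:
        if not (0 < self.de_fdr_max <= 1 and 0 < self.go_fdr_max <= 1):
            raise ValueError("FDR thresholds must lie in (0, 1]")
        for name in ("min_length", "downstream_bp", "proximal_window",
                     "shuffle_reps", "synteny_reps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _category_counts(ids, models_by_id):
    loci = {models_by_id[t].locus_id for t in ids if t in models_by_id}
    return {"transcripts": len(ids), "loci": len(loci)}


def run_pipeline(
    dataset: SyntheticDataset, config: PipelineConfig, outdir: str | Path | None = None
) -> "PipelineState":
    """Run every stage on a dataset; returns all intermediate products."""
    config.validate()
    cfg = config
    focal = dataset.focal
    genome = focal.genome
    records = {r.transcript_id: r for r in focal.records}

    # --- classify -----------------------------------------------------------
    results, models = _classify.classify_transcripts(
        focal.models, records, dataset.cage,
        min_length=cfg.min_length, downstream_bp=cfg.downstream_bp,
    )
    by_id = {m.transcript_id: m for m in models}
    lnc = [m for m in models if m.biotype in ("lncRNA", "lincRNA")]
    linc = [m for m in models if m.biotype == "lincRNA"]
    coding = [m for m in models if m.biotype == "coding"]

    # --- differential expression -------------------------------------------
    matrix = dataset.counts
    locus_of = {m.transcript_id: m.locus_id for m in focal.models}
    swissprot = {r.transcript_id: r.has_swissprot_hit for r in focal.records}
    hk = _expr.select_housekeeping(
        matrix, locus_of, swissprot, n_genes=cfg.hk_n_genes,
        min_pooled_cpm=cfg.hk_min_pooled_cpm,
    )
    phi = _expr.estimate_dispersion(matrix.subset(hk.housekeeping_transcript_ids))
    hk.phi = phi
    de = _expr.run_de(
        matrix, phi, min_cpm=cfg.de_min_cpm, fdr_max=cfg.de_fdr_max,
        min_abs_logfc=cfg.de_min_abs_logfc,
    )
    maternal, embryonic = _expr.classify_stage_specific(de)
    lnc_ids = {m.transcript_id for m in lnc}
    linc_ids = {m.transcript_id for m in linc}
    coding_ids = {m.transcript_id for m in coding}
    de_called = {r.transcript_id for r in de if r.call != "ns"}
    comparison = (matrix.stages[0], matrix.stages[-1])
    lnc_res = [r for r in de if r.transcript_id in lnc_ids]
    cod_res = [r for r in de if r.transcript_id in coding_ids]
    try:
        rho, rho_p = _expr.neighbor_fc_correlation(
            lnc_res, cod_res, lnc, coding, comparison, window=cfg.proximal_window
        )
    except ValueError:
        rho, rho_p = float("nan"), float("nan")

    # --- conservation -------------------------------------------------------
    species = list(dataset.config.species)
    focal_name = species[0]
    lnc_by_species = {focal_name: linc}
    for sp in species[1:]:
        other = dataset.annotations[sp]
        other_lnc_ids = {
            tid for role in ("conserved", "syntenic", "embryonic_cassette",
                             "te_exonic", "te_tss", "generic_lnc")
            for tid in other.roles[role]
        }
        lnc_by_species[sp] = [m for m in other.models if m.transcript_id in other_lnc_ids]
    cons_calls = _cons.call_conserved(lnc_by_species, dataset.blocks, species)
    conserved_focal = _cons.conserved_ids(cons_calls, focal_name)
    exclude = list(locus_spans(models).values())
    if cfg.shuffle_reps > 0 and linc:
        stat = _cons.mean_score_statistic(dataset.blocks, focal_name)
        observed = stat(linc)
        null, shuffle_p = _cons.shuffle_background(
            linc, genome, exclude, stat, cfg.shuffle_reps,
            seed=cfg.seed + SEED_OFFSETS["conservation"], observed=observed,
        )
        cons_summary = {
            "observed_mean_score": observed,
            "null_mean_score": float(null.mean()),
            "empirical_p": shuffle_p,
        }
    else:
        cons_summary = {}

    # --- microsynteny -------------------------------------------------------
    coding_by_species = {focal_name: coding}
    lincs_by_species = {focal_name: linc}
    for sp in species[1:]:
        other = dataset.annotations[sp]
        other_lnc = {
            tid for role in ("conserved", "syntenic", "embryonic_cassette",
                             "te_exonic", "te_tss", "generic_lnc",
                             "violator_overlap", "violator_downstream")
            for tid in other.roles[role]
        }
        coding_by_species[sp] = [
            m for m in other.models if m.transcript_id not in other_lnc
        ]
        lincs_by_species[sp] = lnc_by_species[sp]
    pair_calls = {}
    for i, s1 in enumerate(species):
        for s2 in species[i + 1:]:
            omap = dataset.orthology[(s1, s2)]
            pair_calls[(s1, s2)] = _syn.pairwise_synteny(
                lincs_by_species[s1], coding_by_species[s1],
                lincs_by_species[s2], coding_by_species[s2], omap, (s1, s2),
            )
    multi = _syn.multi_species_synteny(pair_calls, species)
    if cfg.synteny_reps > 0:
        genome_by_species = {sp: dataset.annotations[sp].genome for sp in species}
        exclude_by_species = {
            sp: list(locus_spans(dataset.annotations[sp].models).values())
            for sp in species
        }
        rand = _syn.randomization_test(
            lincs_by_species, coding_by_species, dataset.orthology,
            genome_by_species, exclude_by_species, focal_name,
            n_reps=cfg.synteny_reps, seed=cfg.seed + SEED_OFFSETS["synteny"],
        )
        syn_summary = {
            "observed_pct": rand.observed_pct, "null_mean": rand.null_mean,
            "null_sd": rand.null_sd, "z": rand.z, "p": rand.p,
        }
    else:
        syn_summary = {}

    # --- transposable elements ---------------------------------------------
    te_loci = _rep.exonic_te_loci(models, dataset.repeats)
    te_enr = _rep.te_enrichment(lnc, dataset.repeats, genome, by="class")
    tss = _rep.tss_associated(models, dataset.repeats)

    # --- GO enrichment ------------------------------------------------------
    go_map = {r.transcript_id: r.go_terms for r in focal.records}
    background = {m.transcript_id for m in models}
    go_maternal = _enr.fisher_enrich(
        maternal & coding_ids, background, go_map,
        min_members=cfg.go_min_members, fdr_max=cfg.go_fdr_max,
    ) if maternal & coding_ids else None
    go_embryonic = _enr.fisher_enrich(
        embryonic & coding_ids, background, go_map,
        min_members=cfg.go_min_members, fdr_max=cfg.go_fdr_max,
    ) if embryonic & coding_ids else None
    emb_lincs = [m for m in linc if m.transcript_id in embryonic]
    go_proximal = _enr.proximal_enrichment(
        emb_lincs, linc, coding, go_map, window=cfg.proximal_window,
        min_members=cfg.go_min_members, fdr_max=cfg.go_fdr_max,
    ) if emb_lincs else None

    # --- manifest -----------------------------------------------------------
    def cat_table(id_set):
        return {
            "coding": _category_counts(sorted(id_set & coding_ids), by_id),
            "lncRNA": _category_counts(sorted(id_set & lnc_ids), by_id),
            "lincRNA": _category_counts(sorted(id_set & linc_ids), by_id),
        }

    stage_counts: dict[str, int] = {}
    for r in results.values():
        stage_counts[r.stage_reached] = stage_counts.get(r.stage_reached, 0) + 1
    manifest = {
        "seed": cfg.seed,
        "classification": {
            "stage_counts": dict(sorted(stage_counts.items())),
            "n_lncRNA": len(lnc),
            "n_lincRNA": len(linc),
            "cage_supported_fraction": float(
                np.mean([r.cage_supported for r in results.values()])
            ),
        },
        "dispersion": {
            "phi": phi,
            "n_housekeeping_genes": len(hk.housekeeping_gene_ids),
            "n_housekeeping_transcripts": len(hk.housekeeping_transcript_ids),
        },
        "differential": cat_table(de_called),
        "maternal": cat_table(maternal),
        "embryonic": cat_table(embryonic),
        "neighbor_correlation": {"rho": rho, "p": rho_p},
        "conservation": {
            "n_calls": len(cons_calls),
            "n_conserved_focal": len(conserved_focal),
            **cons_summary,
        },
        "synteny": {
            "n_pairwise_calls": sum(len(v) for v in pair_calls.values()),
            "n_multi_species_focal": len(multi[focal_name]),
            **syn_summary,
        },
        "te": {
            "loci": te_loci.to_dict("records"),
            "lnc_enrichment": te_enr.replace([np.inf, -np.inf], None).to_dict("records"),
            "n_tss_associated": sum(1 for f, _ in tss.values() if f),
        },
        "go": {
            "n_maternal_terms": int(go_maternal["significant"].sum()) if go_maternal is not None else 0,
            "n_embryonic_terms": int(go_embryonic["significant"].sum()) if go_embryonic is not None else 0,
            "n_proximal_terms": int(go_proximal["significant"].sum()) if go_proximal is not None else 0,
        },
    }
    state = PipelineState(
        manifest=manifest, classification=results, models=models, de=de,
        maternal=maternal, embryonic=embryonic, dispersion=hk,
        conserved_calls=cons_calls, conserved_focal=conserved_focal,
        synteny_calls=pair_calls, multi_syntenic=multi,
        synteny_summary=syn_summary, tss=tss,
        go_proximal=go_proximal, go_maternal=go_maternal, go_embryonic=go_embryonic,
    )
    if outdir is not None:
        _write_outputs(state, dataset, Path(outdir))
    return state


@dataclass
class PipelineState:
    """Full in-memory outputs of :func:`run_pipeline` for downstream inspection."""

    manifest: dict
    classification: dict
    models: list
    de: list
    maternal: set
    embryonic: set
    dispersion: object
    conserved_calls: set
    conserved_focal: set
    synteny_calls: dict
    multi_syntenic: dict
    synteny_summary: dict
    tss: dict
    go_proximal: object
    go_maternal: object
    go_embryonic: object


def run_all(
    dataset: SyntheticDataset, config: PipelineConfig, outdir: str | Path | None = None
) -> dict:
    """Run every stage end-to-end and return the output manifest."""
    return run_pipeline(dataset, config, outdir).manifest


def _write_outputs(state: PipelineState, dataset: SyntheticDataset, outdir: Path) -> None:
    from . import io as _io

    outdir.mkdir(parents=True, exist_ok=True)
    _io.write_gtf(state.models, outdir / "classified.gtf")
    _io.write_bed12(
        [m for m in state.models if m.biotype in ("lncRNA", "lincRNA")],
        outdir / "lncRNAs.bed",
    )
    _expr.results_table(state.de).to_csv(outdir / "de.tsv", sep="\t", index=False)
    rows = [
        {
            "transcript_id": r.transcript_id,
            "stage_reached": r.stage_reached,
            "filter_reasons": ";".join(r.filter_reasons),
            "cage_supported": int(r.cage_supported),
        }
        for r in state.classification.values()
    ]
    import pandas as pd

    pd.DataFrame(rows).to_csv(outdir / "classification.tsv", sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(state.manifest, fh, indent=1, sort_keys=True)
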