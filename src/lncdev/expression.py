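"""Replicate-free differential expression for a three-stage design.

One RNA-seq library per developmental stage (egg, 30% epiboly, 24 hpf) and no
replicates: the negative-binomial dispersion cannot be estimated from
within-condition variation. Instead, a common dispersion phi (var = mu +
phi*mu^2) is inferred from the between-stage fluctuations of a set of
putative housekeeping genes — SwissProt-annotated genes whose expression
varies least across stages — by conditional maximum likelihood, and pairwise
stage comparisons use an exact conditional test at that dispersion.

With library sizes equal, the null distribution of one count given the pair
total s is beta-binomial(s, r, r) with r = 1/phi (binomial(s, 1/2) in the
Poisson limit phi -> 0). The two-sided p-value sums the probabilities of all
splits no more likely than the observed one, as in edgeR's exactTest.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .core import TranscriptModel, window_neighbors

DEFAULT_STAGES = ("egg", "epi30", "hpf24")


@dataclass
class CountMatrix:
    """Raw integer read counts per transcript across named stages."""

    transcript_ids: list[str]
    stages: list[str]
    counts: np.ndarray  # shape (n_transcripts, n_stages)
    library_sizes: np.ndarray  # total mapped reads per stage

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes)
        n, k = self.counts.shape
        if n != len(self.transcript_ids) or k != len(self.stages):
            raise ValueError("count matrix dimensions inconsistent with labels")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @classmethod
    def from_counts(cls, transcript_ids, stages, counts) -> "CountMatrix":
        """Build with library sizes set to the column sums."""
        counts = np.asarray(counts)
        return cls(list(transcript_ids), list(stages), counts, counts.sum(axis=0))

    def subset(self, ids: Sequence[str]) -> "CountMatrix":
        idx = {t: i for i, t in enumerate(self.transcript_ids)}
        rows = [idx[t] for t in ids]
        return CountMatrix(list(ids), self.stages, self.counts[rows], self.library_sizes)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.counts, index=self.transcript_ids, columns=self.stages)
        df.index.name = "transcript_id"
        with open(path, "w") as fh:
            fh.write("# library_sizes\t" + "\t".join(str(int(x)) for x in self.library_sizes) + "\n")
            df.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        with open(path) as fh:
            first = fh.readline()
            libs = None
            if first.startswith("# library_sizes"):
                libs = np.array([int(x) for x in first.strip().split("\t")[1:]])
                df = pd.read_csv(fh, sep="\t", index_col=0)
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t", index_col=0)
        counts = df.to_numpy()
        if libs is None:
            libs = counts.sum(axis=0)
        return cls([str(i) for i in df.index], list(df.columns), counts, libs)


def cpm(matrix: CountMatrix) -> np.ndarray:
    """Counts per million mapped reads: counts / library_size * 1e6."""
    return matrix.counts / matrix.library_sizes * 1e6


def gene_level_fpkm(
    matrix: CountMatrix, models: Sequence[TranscriptModel]
) -> pd.DataFrame:
    """Mean FPKM of a gene's transcripts, per stage.

    FPKM = counts * 1e9 / (library size * mature transcript length in bp);
    the gene-level value is the mean over its transcripts. A helper for
    comparing gene expression across annotations, not a DE input.
    """
    length = {m.transcript_id: m.length for m in models}
    locus = {m.transcript_id: m.locus_id for m in models}
    rows: dict[str, list[np.ndarray]] = {}
    for i, tid in enumerate(matrix.transcript_ids):
        if tid not in length:
            continue
        fpkm = matrix.counts[i] * 1e9 / (matrix.library_sizes * length[tid])
        rows.setdefault(locus[tid], []).append(fpkm)
    return pd.DataFrame(
        {g: np.mean(v, axis=0) for g, v in sorted(rows.items())},
        index=list(matrix.stages),
    ).T


@dataclass
class DispersionEstimate:
    phi: float
    housekeeping_gene_ids: list[str] = field(default_factory=list)
    housekeeping_transcript_ids: list[str] = field(default_factory=list)


def select_housekeeping(
    matrix: CountMatrix,
    locus_of: Mapping[str, str],
    swissprot: Mapping[str, bool],
    n_genes: int = 100,
    min_pooled_cpm: float = 1.0,
) -> DispersionEstimate:
    """Select stable SwissProt genes to serve as housekeeping references.

    1. drop transcripts with pooled CPM < 1 (pooled counts over summed
       library sizes, per million);
    2. rank surviving transcripts by the standard deviation of their
       per-stage CPM (ascending — least variable first);
    3. drop transcripts of genes without a SwissProt match;
    4. walk the ranking until transcripts from ``n_genes`` distinct genes have
       been seen; the housekeeping set is *all* surviving transcripts of
       those genes.

    The returned estimate has ``phi`` unset (nan); pass the selected
    transcripts to :func:`estimate_dispersion`.
    """
    pooled_cpm = matrix.counts.sum(axis=1) / matrix.library_sizes.sum() * 1e6
    expr = cpm(matrix)
    sd = expr.std(axis=1, ddof=1)
    eligible = []
    for i, tid in enumerate(matrix.transcript_ids):
        if pooled_cpm[i] < min_pooled_cpm:
            continue
        gene = locus_of.get(tid)
        if gene is None or not swissprot.get(tid, False):
            continue
        eligible.append((sd[i], tid, gene))
    eligible.sort(key=lambda x: (x[0], x[1]))
    genes: list[str] = []
    for _, tid, gene in eligible:
        if gene not in genes:
            genes.append(gene)
        if len(genes) == n_genes:
            break
    if len(genes) < n_genes:
        raise ValueError(
            f"only {len(genes)} eligible genes for housekeeping selection, need {n_genes}"
        )
    gene_set = set(genes)
    transcripts = [tid for _, tid, gene in eligible if gene in gene_set]
    return DispersionEstimate(float("nan"), genes, transcripts)


def _equalize(counts: np.ndarray, library_sizes: np.ndarray) -> np.ndarray:
    """Scale counts to a common (geometric-mean) library size and round."""
    target = np.exp(np.mean(np.log(library_sizes)))
    return np.rint(counts * (target / library_sizes)).astype(np.int64)


def estimate_dispersion(
    matrix: CountMatrix,
    phi_bounds: tuple[float, float] = (1e-6, 10.0),
) -> float:
    """Common NB dispersion by conditional maximum likelihood.

    Stages are treated as replicates of each (housekeeping) transcript after
    library-size equalization. With equal sizes the per-transcript likelihood
    of the observed split conditional on its total is free of the mean, so a
    single 1-D bounded optimization over phi suffices. A Poisson-like matrix
    (variance ~ mean) drives the estimate to the lower bound (~0).
    """
    if len(matrix.stages) < 2:
        raise ValueError("dispersion estimation needs >= 2 stages")
    y = _equalize(matrix.counts, matrix.library_sizes)
    s = y.sum(axis=1)
    k = y.shape[1]
    keep = s > 0
    y, s = y[keep], s[keep]
    if y.size == 0:
        raise ValueError("no non-zero transcripts for dispersion estimation")

    def neg_cll(log_phi: float) -> float:
        r = 1.0 / np.exp(log_phi)
        ll = (
            gammaln(y + r).sum(axis=1)
            - k * gammaln(r)
            - (gammaln(s + k * r) - gammaln(k * r))
        )
        return -float(ll.sum())

    res = optimize.minimize_scalar(
        neg_cll,
        bounds=(np.log(phi_bounds[0]), np.log(phi_bounds[1])),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"dispersion optimization failed: {res.message}")
    return float(np.exp(res.x))


def _conditional_logpmf(s: int, lib1: float, lib2: float, phi: float) -> np.ndarray:
    """log P(K = k | K + K' = s) for k = 0..s under the no-replicate null.

    Equal libraries, phi > 0: beta-binomial(s, r, r), r = 1/phi — the exact
    conditional of two iid NB counts. phi = 0: binomial(s, lib1/(lib1+lib2)).
    Unequal libraries with phi > 0: plug-in conditional with a common
    concentration lambda-hat = s/(lib1+lib2), i.e. NB(k; r, mu=lambda*lib1) *
    NB(s-k; r, mu=lambda*lib2), renormalized.
    """
    ks = np.arange(s + 1)
    if phi <= 0:
        p1 = lib1 / (lib1 + lib2)
        logp = (
            gammaln(s + 1) - gammaln(ks + 1) - gammaln(s - ks + 1)
            + ks * np.log(p1) + (s - ks) * np.log1p(-p1)
        )
        return logp
    r = 1.0 / phi
    if lib1 == lib2:
        logp = (
            gammaln(ks + r) - gammaln(ks + 1)
            + gammaln(s - ks + r) - gammaln(s - ks + 1)
        )
    else:
        lam = s / (lib1 + lib2)
        logit1 = np.log(lam * lib1) - np.log(r + lam * lib1)
        logit2 = np.log(lam * lib2) - np.log(r + lam * lib2)
        logp = (
            gammaln(ks + r) - gammaln(ks + 1) + ks * logit1
            + gammaln(s - ks + r) - gammaln(s - ks + 1) + (s - ks) * logit2
        )
    logp -= logp.max()
    return logp - np.log(np.exp(logp).sum())


def nb_exact_test(
    y1: int,
    y2: int,
    lib1: float = 1.0,
    lib2: float = 1.0,
    phi: float = 0.0,
    rel_tol: float = 0.1,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided conditional exact test of equal expression for one pair.

    Conditions on s = y1 + y2 and sums P(k) over every split k whose null
    probability does not exceed P(y1). Libraries differing by less than
    ``rel_tol`` (relative) use the analytic conditional; larger imbalances
    are handled by binomial thinning of the larger library's count down to
    the smaller (seeded via ``rng``), after which the equal-library
    conditional applies.
    """
    if y1 < 0 or y2 < 0:
        raise ValueError("counts must be non-negative")
    big, small = max(lib1, lib2), min(lib1, lib2)
    if phi > 0 and big > 0 and (big - small) / big >= rel_tol:
        rng = rng or np.random.default_rng(0)
        if lib1 > lib2:
            y1 = int(rng.binomial(y1, lib2 / lib1))
            lib1 = lib2
        else:
            y2 = int(rng.binomial(y2, lib1 / lib2))
            lib2 = lib1
    s = y1 + y2
    if s == 0:
        return 1.0
    logp = _conditional_logpmf(s, lib1, lib2, phi)
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return float(min(1.0, p[p <= p[y1] * (1 + 1e-12)].sum()))


@dataclass
class DEResult:
    transcript_id: str
    comparison: tuple[str, str]
    logfc: float  # log2(first stage / second stage)
    p_value: float
    fdr: float
    call: str  # up / down / ns, relative to the FIRST stage of the pair


def run_de(
    matrix: CountMatrix,
    phi: float,
    min_cpm: float = 0.5,
    fdr_max: float = 0.01,
    min_abs_logfc: float = 2.0,
    pseudo_cpm: float = 0.25,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> list[DEResult]:
    """Pairwise exact tests across all stage pairs with BH correction.

    Transcripts with CPM <= ``min_cpm`` in every stage are excluded. logFC is
    log2 of the first stage's CPM over the second's, each offset by a
    ``pseudo_cpm`` pseudo-count (0.25 per million) so zero counts give finite
    fold changes; ``call`` is up/down when fdr <= ``fdr_max`` AND |logFC| >=
    ``min_abs_logfc``, and refers to the first stage of the comparison.
    BH runs within each comparison.
    """
    expr = cpm(matrix)
    keep = (expr > min_cpm).any(axis=1)
    ids = [t for t, k in zip(matrix.transcript_ids, keep) if k]
    rows = np.flatnonzero(keep)
    if pairs is None:
        pairs = list(itertools.combinations(matrix.stages, 2))
    col = {s: j for j, s in enumerate(matrix.stages)}
    results: list[DEResult] = []
    for a, b in pairs:
        ja, jb = col[a], col[b]
        la, lb = float(matrix.library_sizes[ja]), float(matrix.library_sizes[jb])
        pvals = np.array(
            [
                nb_exact_test(int(matrix.counts[i, ja]), int(matrix.counts[i, jb]), la, lb, phi)
                for i in rows
            ]
        )
        if len(pvals):
            fdr = multipletests(pvals, method="fdr_bh")[1]
        else:
            fdr = pvals
        lfc = np.log2((expr[rows, ja] + pseudo_cpm) / (expr[rows, jb] + pseudo_cpm))
        for tid, p, q, f in zip(ids, pvals, fdr, lfc):
            if q <= fdr_max and abs(f) >= min_abs_logfc:
                call = "up" if f > 0 else "down"
            else:
                call = "ns"
            results.append(DEResult(tid, (a, b), float(f), float(p), float(q), call))
    return results


def classify_stage_specific(
    results: Iterable[DEResult], egg_stage: str = "egg"
) -> tuple[set[str], set[str]]:
    """(maternal, embryonic) transcript sets.

    Maternal transcripts are called *up* in the egg in every comparison whose
    first stage is the egg; embryonic transcripts are called *down* in all of
    them. The two sets are disjoint by construction.
    """
    per_tid: dict[str, list[str]] = {}
    for r in results:
        if r.comparison[0] == egg_stage:
            per_tid.setdefault(r.transcript_id, []).append(r.call)
    n_egg_comparisons = max((len(v) for v in per_tid.values()), default=0)
    maternal = {
        t for t, calls in per_tid.items()
        if len(calls) == n_egg_comparisons and all(c == "up" for c in calls)
    }
    embryonic = {
        t for t, calls in per_tid.items()
        if len(calls) == n_egg_comparisons and all(c == "down" for c in calls)
    }
    return maternal, embryonic


def results_table(results: Iterable[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "comparison": f"{r.comparison[0]}_vs_{r.comparison[1]}",
                "logFC": r.logfc,
                "p": r.p_value,
                "fdr": r.fdr,
                "call": r.call,
            }
            for r in results
        ]
    )


def neighbor_fc_correlation(
    lnc_results: Sequence[DEResult],
    coding_results: Sequence[DEResult],
    lnc_models: Sequence[TranscriptModel],
    coding_models: Sequence[TranscriptModel],
    comparison: tuple[str, str],
    window: int = 10_000,
) -> tuple[float, float]:
    """Spearman correlation of lncRNA logFC vs proximal coding-gene logFC.

    Pairs every lncRNA with each coding transcript within ``window`` bp of
    it (one pair per lncRNA-neighbor combination) for the given comparison;
    returns (rho, p) with p from the large-sample approximation.
    """
    lnc_fc = {r.transcript_id: r.logfc for r in lnc_results if r.comparison == comparison}
    cod_fc = {r.transcript_id: r.logfc for r in coding_results if r.comparison == comparison}
    xs, ys = [], []
    cands = [c for c in coding_models if c.transcript_id in cod_fc]
    for m in lnc_models:
        if m.transcript_id not in lnc_fc:
            continue
        for nb in window_neighbors(m, cands, window):
            xs.append(lnc_fc[m.transcript_id])
            ys.append(cod_fc[nb.transcript_id])
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} lncRNA-neighbor pairs; need >= 3")
    rho, p = stats.spearmanr(xs, ys)
    return float(rho), float(p)
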