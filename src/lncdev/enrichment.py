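"""Fisher-exact GO enrichment with Benjamini-Hochberg correction.

Terms are tested one-sided for over-representation of a transcript set
against a background (the set must be contained in the background), at
transcript level, with a minimum of 5 set representatives per term. No GO
DAG propagation is performed: terms are taken exactly as annotated.
"""

from __future__ import annotations

from typing import Mapping, Sequence, Set

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import TranscriptModel, window_neighbors


def fisher_enrich(
    set_ids: Set[str],
    background_ids: Set[str],
    go_map: Mapping[str, Set[str]],
    min_members: int = 5,
    fdr_max: float = 0.05,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Per-term enrichment of ``set_ids`` within ``background_ids``.

    For each GO term with >= ``min_members`` representatives in the set the
    2x2 table (in set & has term / in set & lacks / background-only pairs)
    is tested with Fisher's exact test (one-sided over-representation by
    default, i.e. the hypergeometric upper tail); BH correction runs across
    the tested terms. Returns all tested terms with a ``significant`` flag
    at ``fdr <= fdr_max``.
    """
    set_ids = set(set_ids)
    background_ids = set(background_ids)
    if not set_ids <= background_ids:
        raise ValueError("set must be a subset of the background")
    term_in_set: dict[str, int] = {}
    term_in_bg: dict[str, int] = {}
    for tid in background_ids:
        for term in go_map.get(tid, ()):
            term_in_bg[term] = term_in_bg.get(term, 0) + 1
            if tid in set_ids:
                term_in_set[term] = term_in_set.get(term, 0) + 1
    n, N = len(set_ids), len(background_ids)
    rows = []
    for term, k in sorted(term_in_set.items()):
        if k < min_members:
            continue
        K = term_in_bg[term]
        # P(X >= k) for X ~ Hypergeom(N, K, n) == one-sided Fisher p
        p_over = min(1.0, float(hypergeom.sf(k - 1, N, K, n)))
        if two_sided:
            p_under = float(hypergeom.cdf(k, N, K, n))
            p = min(1.0, 2.0 * min(p_over, p_under))
        else:
            p = p_over
        rows.append(
            {
                "go_term": term,
                "k_in_set": k,
                "n_set": n,
                "K_in_background": K,
                "N_background": N,
                "odds_direction": "over" if k / n >= K / N else "under",
                "percent_of_set": 100.0 * k / n,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["fdr"] <= fdr_max
        df = df.sort_values(["p", "go_term"]).reset_index(drop=True)
    else:
        df = pd.DataFrame(
            columns=[
                "go_term", "k_in_set", "n_set", "K_in_background", "N_background",
                "odds_direction", "percent_of_set", "p", "fdr", "significant",
            ]
        )
    return df


def proximal_enrichment(
    lincs_of_interest: Sequence[TranscriptModel],
    all_lincs: Sequence[TranscriptModel],
    coding_models: Sequence[TranscriptModel],
    go_map: Mapping[str, Set[str]],
    window: int = 10_000,
    min_members: int = 5,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """GO enrichment of coding genes proximal to a lincRNA subset.

    Set = coding transcripts within ``window`` bp of any lincRNA of
    interest; background = coding transcripts within the window of any
    lincRNA at all; then :func:`fisher_enrich`.
    """
    def proximal(lincs: Sequence[TranscriptModel]) -> set[str]:
        hits: set[str] = set()
        for m in lincs:
            hits.update(
                c.transcript_id for c in window_neighbors(m, coding_models, window)
            )
        return hits

    return fisher_enrich(
        proximal(lincs_of_interest),
        proximal(all_lincs),
        go_map,
        min_members=min_members,
        fdr_max=fdr_max,
    )
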