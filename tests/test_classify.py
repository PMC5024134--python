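"""Classification cascade: every printed threshold, exactly at its boundary."""

import numpy as np
import pytest

from lncdev.core import AnnotationRecord, CageTag, GenomeInterval, GenomeSpec, TranscriptModel
from lncdev.classify import (
    anatomy_stats,
    cage_support,
    call_candidates,
    call_lincRNAs,
    classify_transcripts,
    filter_min_length,
    map_to_reference,
    ncp_cutoff,
    positional_filter,
)


def tx(tid, exons, strand="+", chrom="chr1", locus=None, biotype="unclassified"):
    return TranscriptModel(
        tid, locus or tid,
        tuple(GenomeInterval(chrom, s, e, strand) for s, e in exons), biotype,
    )


def rec(tid, protein=False, domain=False, ncrna=False, orf=50, ncp=0.9, sp=False, go=()):
    return AnnotationRecord(tid, protein, domain, ncrna, orf, ncp, sp, frozenset(go))


class TestLengthFilter:
    def test_exactly_200_discarded(self):
        assert filter_min_length([tx("t", [(0, 200)])]) == []

    def test_201_retained(self):
        m = tx("t", [(0, 201)])
        assert filter_min_length([m]) == [m]

    def test_spliced_length_is_summed_exons(self):
        # genomic span 1000 but mature length 200 -> discarded
        m = tx("t", [(0, 100), (900, 1000)])
        assert filter_min_length([m]) == []

    def test_empty_input(self):
        assert filter_min_length([]) == []


class TestCandidates:
    def test_orf_99_is_candidate(self):
        assert call_candidates([rec("t", orf=99)]) == {"t"}

    def test_orf_100_is_not(self):
        assert call_candidates([rec("t", orf=100)]) == set()

    @pytest.mark.parametrize("flag", ["protein", "domain", "ncrna"])
    def test_any_homology_hit_disqualifies(self, flag):
        assert call_candidates([rec("t", **{flag: True}, orf=50)]) == set()

    def test_duplicate_record_errors(self):
        with pytest.raises(ValueError, match="duplicate"):
            call_candidates([rec("t"), rec("t")])


class TestNcpCutoff:
    def test_mean_and_strict_greater(self):
        cands = [rec("a", ncp=0.60), rec("b", ncp=0.80), rec("c", ncp=0.88)]
        cutoff = ncp_cutoff(cands)
        assert cutoff == pytest.approx(0.76)
        assert {r.transcript_id for r in cands if r.ncp > cutoff} == {"b", "c"}

    def test_all_equal_gives_zero_potentials(self):
        cands = [rec(t, ncp=0.8) for t in "abc"]
        cutoff = ncp_cutoff(cands)
        assert not [r for r in cands if r.ncp > cutoff]

    def test_single_candidate_excluded(self):
        (c,) = [rec("a", ncp=0.9)]
        assert not c.ncp > ncp_cutoff([c])

    def test_zero_candidates_error(self):
        with pytest.raises(ValueError):
            ncp_cutoff([])


class TestPositionalFilter:
    coding = [tx("c1", [(10_000, 12_000)], strand="+", biotype="coding")]

    def test_monoexonic_antisense_overlap_removed(self):
        m = tx("m", [(11_000, 11_500)], strand="-")
        kept, removed = positional_filter([m], self.coding)
        assert kept == [] and "m" in removed

    def test_multiexonic_antisense_overlap_kept(self):
        m = tx("m", [(10_500, 10_800), (11_200, 11_500)], strand="-")
        kept, removed = positional_filter([m], self.coding)
        assert kept == [m]

    def test_multiexonic_same_strand_4999_downstream_removed(self):
        m = tx("m", [(16_999, 17_300), (17_500, 17_800)], strand="+")
        kept, removed = positional_filter([m], self.coding)
        assert "m" in removed and removed["m"][0].startswith("downstream_of_coding")

    def test_multiexonic_same_strand_5001_downstream_kept(self):
        m = tx("m", [(17_001, 17_300), (17_500, 17_800)], strand="+")
        kept, _ = positional_filter([m], self.coding)
        assert kept == [m]

    def test_downstream_is_3prime_oriented_for_minus_genes(self):
        gene = [tx("c", [(50_000, 60_000)], strand="-", biotype="coding")]
        # 3' flank of a minus gene lies to its left
        m = tx("m", [(46_000, 46_300), (46_500, 46_800)], strand="-")
        kept, removed = positional_filter([m], gene)
        assert "m" in removed
        right = tx("r", [(61_000, 61_300), (61_500, 61_800)], strand="-")
        kept, _ = positional_filter([right], gene)
        assert kept == [right]


class TestLincRNAs:
    def test_antisense_in_intron_not_linc(self):
        coding = [tx("c", [(0, 100), (5_000, 6_000)], strand="+", biotype="coding")]
        lnc = tx("l", [(2_000, 2_400), (3_000, 3_400)], strand="-")
        assert call_lincRNAs([lnc], coding) == set()

    def test_one_bp_away_is_linc(self):
        coding = [tx("c", [(0, 1_000)], strand="+", biotype="coding")]
        lnc = tx("l", [(1_001, 1_400), (1_600, 1_900)], strand="-")
        assert call_lincRNAs([lnc], coding) == {"l"}

    def test_no_coding_genes_all_linc(self):
        lncs = [tx("a", [(0, 400), (600, 900)]), tx("b", [(5_000, 5_600)])]
        assert call_lincRNAs(lncs, []) == {"a", "b"}


class TestCageSupport:
    model = tx("t", [(10_000, 10_400), (10_600, 11_000)], strand="+")

    def tag(self, pos, tpm, strand="+"):
        return CageTag(GenomeInterval("chr1", pos, pos + 1, strand), tpm)

    def test_tag_500_upstream_supported(self):
        out = cage_support([self.model], [self.tag(9_500, 0.6)])
        assert out["t"]

    def test_low_tpm_unsupported(self):
        assert not cage_support([self.model], [self.tag(9_500, 0.4)])["t"]

    def test_tpm_exactly_half_supported(self):
        assert cage_support([self.model], [self.tag(9_500, 0.5)])["t"]

    def test_beyond_plus_400_unsupported(self):
        assert not cage_support([self.model], [self.tag(10_500, 2.0)])["t"]

    def test_minus_strand_window_oriented_from_3prime_end(self):
        m = tx("m", [(10_000, 11_000)], strand="-")  # TSS at 10_999
        assert cage_support([m], [self.tag(11_500, 1.0)])["m"]  # 501 bp upstream
        assert not cage_support([m], [self.tag(10_500, 1.0)])["m"]  # 499 downstream... within 400? no: 10_999-10_500=499 > 400
        assert cage_support([m], [self.tag(10_700, 1.0)])["m"]  # 299 downstream

    def test_invariant_to_order_and_duplicates(self):
        tags = [self.tag(9_500, 0.6), self.tag(9_000, 0.1)]
        a = cage_support([self.model], tags)
        b = cage_support([self.model], tags[::-1] + tags)
        assert a == b


class TestMapToReference:
    def test_common_both_ends(self):
        ref = [tx("r", [(100, 300)], locus="R", biotype="coding")]
        ass = [tx("a", [(90, 310)], locus="A")]
        (row,) = map_to_reference(ass, ref).to_dict("records")
        assert row["label"] == "common" and row["extension"] == "both_ends"

    def test_est_supported_is_neither_common_nor_novel(self):
        ass = [tx("a", [(90, 310)], locus="A")]
        est = [GenomeInterval("chr1", 200, 400)]
        (row,) = map_to_reference(ass, [], est).to_dict("records")
        assert row["label"] == "est_supported"

    def test_no_overlap_is_novel(self):
        ass = [tx("a", [(90, 310)], locus="A")]
        (row,) = map_to_reference(ass, [], []).to_dict("records")
        assert row["label"] == "novel"

    def test_antisense_reference_not_common(self):
        ref = [tx("r", [(100, 300)], strand="-", locus="R", biotype="coding")]
        ass = [tx("a", [(90, 310)], locus="A")]
        (row,) = map_to_reference(ass, ref).to_dict("records")
        assert row["label"] == "novel"

    def test_extension_strand_aware(self):
        ref = [tx("r", [(100, 300)], strand="-", locus="R", biotype="coding")]
        ass = [tx("a", [(90, 300)], strand="-", locus="A")]
        (row,) = map_to_reference(ass, ref).to_dict("records")
        # minus strand: extending the left edge extends the 3' end
        assert row["extension"] == "3p_only"


class TestAnatomyStats:
    genome = GenomeSpec({"chr1": 100_000})

    def test_single_intron_between_exons(self):
        m = tx("t", [(0, 100), (200, 300)], biotype="lncRNA")
        row = anatomy_stats([m], self.genome).iloc[0]
        assert row["mean_intron_length"] == 100

    def test_shared_exon_counted_once_in_transcribed_fraction(self):
        a = tx("a", [(0, 100)], locus="g", biotype="coding")
        b = tx("b", [(0, 100), (200, 300)], locus="g", biotype="coding")
        row = anatomy_stats([a, b], self.genome).iloc[0]
        # per-base oracle: bases 0..100 and 200..300 -> 200 bp
        assert row["transcribed_fraction"] == pytest.approx(200 / 100_000)

    def test_monoexonic_contributes_no_introns(self):
        m = tx("t", [(0, 500)], biotype="lincRNA")
        row = anatomy_stats([m], self.genome).iloc[0]
        assert row["mean_intron_length"] == 0 and row["monoexonic_fraction"] == 1.0

    def test_generated_lncRNAs_have_fewer_exons_than_coding(self, dataset, classified):
        _, models = classified
        counts = {"coding": [], "lnc": []}
        truth = dataset.truth.true_biotypes
        for m in dataset.focal.models:
            counts["coding" if truth[m.transcript_id] == "coding" else "lnc"].append(
                len(m.exons)
            )
        assert np.mean(counts["lnc"]) < np.mean(counts["coding"])


class TestCascade:
    def test_monotone_and_reasons_on_planted_data(self, dataset, classified):
        results, models = classified
        truth = dataset.truth
        stages = {r.transcript_id: r.stage_reached for r in results.values()}
        lnc_ids = {m.transcript_id for m in models if m.biotype in ("lncRNA", "lincRNA")}
        linc_ids = {m.transcript_id for m in models if m.biotype == "lincRNA"}
        assert linc_ids <= lnc_ids
        # every non-lncRNA outcome carries a reason
        for r in results.values():
            if r.stage_reached not in ("lncRNA", "lincRNA"):
                assert r.filter_reasons
        # planted positional violators removed with the planted reason
        for tid, reason in truth.positional_violators.items():
            assert stages[tid] == "potential"
            assert results[tid].filter_reasons[0].startswith(reason)

    def test_cage_supported_fraction_close_to_configured(self, dataset, classified):
        results, _ = classified
        frac = np.mean([r.cage_supported for r in results.values()])
        assert frac == pytest.approx(dataset.config.frac_cage_supported, abs=0.08)

    def test_recall_of_true_lncRNAs_reported_against_truth(self, dataset, classified):
        results, models = classified
        truth = dataset.truth.true_biotypes
        called = {m.transcript_id for m in models if m.biotype in ("lncRNA", "lincRNA")}
        true_lnc = {t for t, b in truth.items() if b == "lncRNA"}
        precision = len(called & true_lnc) / len(called)
        assert precision == 1.0  # homology filters make false positives impossible here
        recall = len(called & true_lnc) / len(true_lnc)
        assert 0.3 < recall < 1.0  # the NCP mean cutoff is deliberately conservative
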