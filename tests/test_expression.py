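"""Replicate-free DE: exact test vs brute-force oracle, dispersion recovery, filters."""

import numpy as np
import pytest
from scipy import stats as sps

from lncdev.core import GenomeInterval, TranscriptModel
from lncdev.expression import (
    CountMatrix,
    DEResult,
    classify_stage_specific,
    cpm,
    estimate_dispersion,
    gene_level_fpkm,
    nb_exact_test,
    neighbor_fc_correlation,
    run_de,
    select_housekeeping,
)
from lncdev.simulate import simulate_nb_counts


def exact_test_oracle(y1, y2, phi, lib1=1.0, lib2=1.0):
    """Brute-force conditional p: enumerate all splits of s with scipy pmfs."""
    s = y1 + y2
    if s == 0:
        return 1.0
    ks = np.arange(s + 1)
    if phi == 0:
        lam = s / (lib1 + lib2)
        probs = sps.poisson.pmf(ks, lam * lib1) * sps.poisson.pmf(s - ks, lam * lib2)
    else:
        r = 1.0 / phi
        lam = s / (lib1 + lib2)
        p1, p2 = r / (r + lam * lib1), r / (r + lam * lib2)
        probs = sps.nbinom.pmf(ks, r, p1) * sps.nbinom.pmf(s - ks, r, p2)
    probs = probs / probs.sum()
    return min(1.0, probs[probs <= probs[y1] * (1 + 1e-12)].sum())


class TestCpm:
    def test_count_5_in_a_million(self):
        m = CountMatrix(["t"], ["a"], np.array([[5]]), np.array([10**6]))
        assert cpm(m)[0, 0] == 5.0

    def test_scale_invariance(self):
        m1 = CountMatrix(["t"], ["a", "b"], np.array([[5, 8]]), np.array([100, 200]))
        m2 = CountMatrix(["t"], ["a", "b"], np.array([[10, 16]]), np.array([200, 400]))
        assert np.allclose(cpm(m1), cpm(m2))

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            CountMatrix(["t"], ["a"], np.array([[0]]), np.array([0]))

    def test_gene_level_fpkm_is_mean_over_transcripts(self):
        # two 1-kb transcripts of one gene, 1 M reads: FPKM == count
        models = [
            TranscriptModel("t1", "g", (GenomeInterval("chr1", 0, 1000, "+"),)),
            TranscriptModel("t2", "g", (GenomeInterval("chr1", 0, 1000, "+"),)),
        ]
        m = CountMatrix(["t1", "t2"], ["a"], np.array([[10], [30]]), np.array([10**6]))
        df = gene_level_fpkm(m, models)
        assert df.loc["g", "a"] == pytest.approx(20.0)


class TestExactTest:
    def test_both_zero_gives_p_one(self):
        assert nb_exact_test(0, 0, 1e6, 1e6, 0.35) == 1.0

    def test_ten_vs_zero_poisson_matches_binomial(self):
        # all 10 reads in one library under a fair split: p = 2 * (1/2)^10
        assert nb_exact_test(10, 0, 1e6, 1e6, 0.0) == pytest.approx(2 * 0.5**10)

    @pytest.mark.parametrize("phi", [0.0, 0.35, 1.0])
    def test_matches_brute_force_enumeration(self, phi, rng):
        for _ in range(150):
            y1, y2 = int(rng.integers(0, 120)), int(rng.integers(0, 120))
            if y1 + y2 > 200:
                continue
            got = nb_exact_test(y1, y2, 1e6, 1e6, phi)
            want = exact_test_oracle(y1, y2, phi)
            assert got == pytest.approx(want, rel=1e-9), (y1, y2, phi)

    def test_matches_edger_reference_values(self):
        # frozen from Bioconductor edgeR 4.0.16 exactTest, equal library sizes
        cases = {
            (10, 0, 0.35): 0.04706076516,
            (30, 5, 0.35): 0.0986355943,
            (100, 10, 0.35): 0.02334877734,
            (7, 3, 0.35): 0.5799667443,
            (10, 0, 0.0): 0.001953125039,
            (30, 5, 0.0): 2.236152405e-05,
        }
        for (y1, y2, phi), want in cases.items():
            assert nb_exact_test(y1, y2, 1e6, 1e6, phi) == pytest.approx(want, rel=1e-6)

    def test_symmetric_in_swap(self, rng):
        for _ in range(50):
            y1, y2 = int(rng.integers(0, 80)), int(rng.integers(0, 80))
            assert nb_exact_test(y1, y2, 1e6, 1e6, 0.35) == pytest.approx(
                nb_exact_test(y2, y1, 1e6, 1e6, 0.35)
            )

    def test_unequal_libraries_analytic_path_matches_oracle(self):
        # libraries differ by < 10%: analytic plug-in conditional
        for y1, y2 in [(10, 3), (40, 60), (0, 12)]:
            got = nb_exact_test(y1, y2, 1.00e6, 1.05e6, 0.35)
            want = exact_test_oracle(y1, y2, 0.35, 1.00e6, 1.05e6)
            assert got == pytest.approx(want, rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test(-1, 5, 1e6, 1e6, 0.35)

    def test_type_one_error_calibrated(self, rng):
        # under H0 with phi fixed, the rejection rate at alpha=0.05 is near nominal
        phi, r = 0.35, 1 / 0.35
        mu = rng.lognormal(np.log(100), 1.0, 4000)
        y1 = rng.negative_binomial(r, r / (r + mu))
        y2 = rng.negative_binomial(r, r / (r + mu))
        ps = [nb_exact_test(int(a), int(b), 1e6, 1e6, phi) for a, b in zip(y1, y2)]
        assert 0.02 <= np.mean(np.asarray(ps) <= 0.05) <= 0.08


class TestDispersion:
    def test_poisson_counts_drive_phi_to_zero(self, rng):
        m = simulate_nb_counts(300, 3, 0.0, rng)
        assert estimate_dispersion(m) < 1e-3

    def test_recovers_planted_dispersion(self, rng):
        est = [estimate_dispersion(simulate_nb_counts(305, 3, 0.35, rng)) for _ in range(30)]
        assert np.mean(est) == pytest.approx(0.35, abs=0.05)

    def test_single_transcript_equal_counts(self):
        m = CountMatrix(["t"], ["a", "b", "c"], np.array([[50, 50, 50]]), np.array([100, 100, 100]))
        assert estimate_dispersion(m) < 1e-3

    def test_median_bias_small_across_phis(self, rng):
        for phi in (0.1, 0.35, 1.0):
            est = [
                estimate_dispersion(simulate_nb_counts(305, 3, phi, rng))
                for _ in range(20)
            ]
            assert abs(np.median(est) - phi) / phi < 0.2


class TestHousekeeping:
    def _matrix(self):
        ids = ["flat", "noisy", "low", "nosp"]
        counts = np.array([[100, 100, 100], [10, 300, 80], [0, 1, 0], [90, 90, 90]])
        return CountMatrix(ids, ["egg", "epi30", "hpf24"], counts, np.array([10**6] * 3))

    def test_zero_sd_swissprot_selected_first(self):
        m = self._matrix()
        sel = select_housekeeping(
            m, {t: t for t in m.transcript_ids},
            {"flat": True, "noisy": True, "low": True, "nosp": False}, n_genes=1,
        )
        assert sel.housekeeping_gene_ids == ["flat"]

    def test_pooled_cpm_below_one_excluded(self):
        m = self._matrix()  # "low" has pooled CPM 1/3 < 1
        sel = select_housekeeping(
            m, {t: t for t in m.transcript_ids}, {t: True for t in m.transcript_ids},
            n_genes=2,
        )
        assert "low" not in sel.housekeeping_transcript_ids

    def test_all_transcripts_of_selected_genes_included(self, rng):
        # 100 genes x ~3 isoforms, structured like the published 305/100 split
        ids, genes = [], {}
        per_gene = [3] * 5 + [3, 3, 2, 4, 3] * 19  # 100 genes, 295 transcripts
        counts = []
        for g, k in enumerate(per_gene):
            for i in range(k):
                tid = f"g{g}_t{i}"
                ids.append(tid)
                genes[tid] = f"g{g}"
                counts.append(rng.poisson(200, 3))
        m = CountMatrix(ids, ["a", "b", "c"], np.array(counts), np.array([10**6] * 3))
        sel = select_housekeeping(m, genes, {t: True for t in ids}, n_genes=100)
        assert len(sel.housekeeping_gene_ids) == 100
        assert len(sel.housekeeping_transcript_ids) == len(ids)

    def test_shortfall_raises(self):
        m = self._matrix()
        with pytest.raises(ValueError, match="eligible genes"):
            select_housekeeping(
                m, {t: t for t in m.transcript_ids}, {t: False for t in m.transcript_ids},
                n_genes=2,
            )


class TestRunDe:
    def _matrix(self):
        ids = ["up", "flat", "lowexpr"]
        counts = np.array(
            [[4000, 100, 100], [500, 500, 500], [0, 0, 0]]
        )
        return CountMatrix(ids, ["egg", "epi30", "hpf24"], counts, np.array([10**6] * 3))

    def test_low_cpm_transcript_absent(self):
        res = run_de(self._matrix(), 0.1)
        assert "lowexpr" not in {r.transcript_id for r in res}

    def test_call_requires_both_fdr_and_logfc(self):
        res = {(r.transcript_id, r.comparison): r for r in run_de(self._matrix(), 0.05)}
        r = res[("up", ("egg", "epi30"))]
        assert r.call == "up" and r.logfc > 2
        assert res[("flat", ("egg", "epi30"))].call == "ns"

    def test_benjamini_hochberg_hand_example(self):
        from statsmodels.stats.multitest import multipletests

        fdr = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(fdr, [0.03, 0.03, 0.03])

    def test_swapping_stages_flips_logfc_and_keeps_p(self):
        m = self._matrix()
        fwd = {r.transcript_id: r for r in run_de(m, 0.1, pairs=[("egg", "epi30")])}
        rev = {r.transcript_id: r for r in run_de(m, 0.1, pairs=[("epi30", "egg")])}
        for t in fwd:
            assert fwd[t].logfc == pytest.approx(-rev[t].logfc)
            assert fwd[t].p_value == pytest.approx(rev[t].p_value)


class TestStageSpecific:
    def _res(self, tid, first, second, call):
        return DEResult(tid, (first, second), 0.0, 0.5, 0.5, call)

    def test_up_in_one_comparison_only_is_neither(self):
        res = [
            self._res("t", "egg", "epi30", "up"),
            self._res("t", "egg", "hpf24", "ns"),
        ]
        mat, emb = classify_stage_specific(res)
        assert mat == set() and emb == set()

    def test_down_in_both_egg_comparisons_is_embryonic(self):
        res = [
            self._res("t", "egg", "epi30", "down"),
            self._res("t", "egg", "hpf24", "down"),
        ]
        mat, emb = classify_stage_specific(res)
        assert emb == {"t"} and mat == set()

    def test_maternal_and_embryonic_disjoint_on_simulation(self, pipeline_state):
        assert not (pipeline_state.maternal & pipeline_state.embryonic)


class TestNeighborCorrelation:
    def _models(self, n):
        lnc, cod = [], []
        for i in range(n):
            base = i * 100_000
            lnc.append(TranscriptModel(
                f"l{i}", f"l{i}",
                (GenomeInterval("chr1", base, base + 500, "+"),), "lincRNA"))
            cod.append(TranscriptModel(
                f"c{i}", f"c{i}",
                (GenomeInterval("chr1", base + 2_000, base + 3_000, "+"),), "coding"))
        return lnc, cod

    def _results(self, vals, ids, comparison=("egg", "hpf24")):
        return [DEResult(t, comparison, v, 0.5, 0.5, "ns") for t, v in zip(ids, vals)]

    def test_perfectly_covarying_pairs(self):
        lnc, cod = self._models(5)
        vals = [1.0, 2.0, -1.0, 0.5, 3.0]
        rho, _ = neighbor_fc_correlation(
            self._results(vals, [m.transcript_id for m in lnc]),
            self._results(vals, [m.transcript_id for m in cod]),
            lnc, cod, ("egg", "hpf24"),
        )
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks(self):
        lnc, cod = self._models(3)
        rho, _ = neighbor_fc_correlation(
            self._results([1, 2, 3], [m.transcript_id for m in lnc]),
            self._results([3, 2, 1], [m.transcript_id for m in cod]),
            lnc, cod, ("egg", "hpf24"),
        )
        assert rho == pytest.approx(-1.0)

    def test_matches_hand_computed_spearman(self):
        lnc, cod = self._models(5)
        x = [0.1, 1.2, -0.4, 2.0, 0.9]
        y = [0.0, 0.8, 0.3, 2.5, -0.2]
        rho, p = neighbor_fc_correlation(
            self._results(x, [m.transcript_id for m in lnc]),
            self._results(y, [m.transcript_id for m in cod]),
            lnc, cod, ("egg", "hpf24"),
        )
        # rank formula: rho = 1 - 6*sum(d^2)/(n(n^2-1))
        rx = np.argsort(np.argsort(x))
        ry = np.argsort(np.argsort(y))
        want = 1 - 6 * np.sum((rx - ry) ** 2) / (5 * 24)
        assert rho == pytest.approx(want)

    def test_fewer_than_three_pairs_errors(self):
        lnc, cod = self._models(2)
        with pytest.raises(ValueError):
            neighbor_fc_correlation(
                self._results([1, 2], [m.transcript_id for m in lnc]),
                self._results([1, 2], [m.transcript_id for m in cod]),
                lnc, cod, ("egg", "hpf24"),
            )
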