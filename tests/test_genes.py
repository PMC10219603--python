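"""Gene-content overlap, gene numbers, and differential-KO procedures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossbiome.core import GenomeRecord, KOMatrix, LabeledTree
from crossbiome.genes import (
    censor_presence,
    gene_number_difference,
    gene_overlap,
    fit_overlap_vs_time,
    msg_presence,
    paired_differential_kos,
    unpaired_differential_kos,
    OverlapPoint,
    _sign_test_p,
)
from crossbiome.treeops import MSG, MSGPair, find_msg_pairs


class TestGeneOverlap:
    def test_identical_sets(self):
        assert gene_overlap({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert gene_overlap({"a"}, {"b"}) == 0.0

    def test_hand_arithmetic(self):
        # |A| = 4, |B| = 6, |A∩B| = 3 -> 3 / ((4+6)/2)
        a = set("abcd")
        b = set("bcdefg")
        assert gene_overlap(a, b) == pytest.approx(3 / 5)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            gene_overlap(set(), set())

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)))
    def test_symmetry_bounds_and_equality(self, a, b):
        if not a and not b:
            return
        o = gene_overlap(a, b)
        assert o == gene_overlap(b, a)
        assert 0.0 <= o <= 1.0
        assert (o == 1.0) == (a == b)


def _pairs_on_chain(n_pairs, ttype="BM"):
    low, high = {"FB": ("freshwater", "brackish"),
                 "BM": ("brackish", "marine"),
                 "FM": ("freshwater", "marine")}[ttype]
    newick = "(" + ",".join(f"(L{i}:1,H{i}:1):{i + 1}" for i in range(n_pairs)) + ");"
    tree = LabeledTree.from_newick(newick)
    biomes = {}
    for i in range(n_pairs):
        biomes[f"L{i}"] = low
        biomes[f"H{i}"] = high
    return tree, find_msg_pairs(tree, biomes), biomes


class TestGeneNumberDifference:
    def test_identical_counts_zero(self, make_record):
        tree, pairs, biomes = _pairs_on_chain(6)
        recs = [GenomeRecord(g, b, 90, 1, n_genes=2000) for g, b in biomes.items()]
        df = gene_number_difference(pairs, recs)
        assert (df["delta_genes"] == 0).all()

    def test_planted_brackish_excess_recovered(self):
        rng = np.random.default_rng(0)
        tree, pairs, biomes = _pairs_on_chain(30, "BM")
        recs = []
        for g, b in biomes.items():
            n = 2000 + (300 if b == "brackish" else 0) + int(rng.normal(0, 50))
            recs.append(GenomeRecord(g, b, 90, 1, n_genes=n))
        df = gene_number_difference(pairs, recs)
        # oriented saline (marine) minus fresher (brackish): excess is negative
        assert np.median(df["delta_genes"]) == pytest.approx(-300, abs=80)
        tests = df.attrs["type_tests"]
        assert tests.loc[tests["type"] == "BM", "p_bonf"].iloc[0] < 0.01


class TestSignTest:
    def test_exact_binomial_small_n(self):
        from scipy.stats import binomtest

        assert _sign_test_p(6, 0) == pytest.approx(binomtest(6, 6, 0.5).pvalue)
        assert _sign_test_p(3, 3) == pytest.approx(1.0)

    def test_no_informative_pairs(self):
        assert _sign_test_p(0, 0) == 1.0

    def test_normal_approximation_large_n(self):
        # moderate 32/18 split: the continuity-corrected normal
        # approximation tracks the exact two-sided binomial closely
        from scipy.stats import binomtest

        exact = binomtest(32, 50, 0.5).pvalue
        approx = _sign_test_p(32, 18)
        assert approx == pytest.approx(exact, rel=0.1)


class TestCensoring:
    def test_no_thinning_at_equal_completeness(self):
        rng = np.random.default_rng(0)
        row = np.ones(100, dtype=bool)
        out = censor_presence(row, 90.0, 90.0, rng)
        assert out.all()

    def test_expected_retention_matches_ratio(self):
        rng = np.random.default_rng(1)
        row = np.ones(20000, dtype=bool)
        out = censor_presence(row, 100.0, 80.0, rng)
        assert out.mean() == pytest.approx(0.8, abs=0.02)


def _ko_matrix_for_pairs(biomes, n_null=30, planted=None, seed=0,
                         p_high=0.9, p_low=0.1):
    """Presence matrix over the pair genomes: null KOs present everywhere,
    one optional planted KO differential between the two biomes."""
    rng = np.random.default_rng(seed)
    genomes = sorted(biomes)
    kos = [f"K{j:03d}" for j in range(n_null)]
    presence = np.ones((len(genomes), n_null), dtype=bool)
    if planted:
        high_biome = planted
        kos.append("K_planted")
        col = np.array([
            rng.random() < (p_high if biomes[g] == high_biome else p_low)
            for g in genomes])
        presence = np.column_stack([presence, col])
    return KOMatrix(genomes=genomes, kos=kos, presence=presence)


class TestPairedDifferentialKOs:
    def test_ubiquitous_ko_never_significant(self):
        tree, pairs, biomes = _pairs_on_chain(10)
        recs = [GenomeRecord(g, b, 90, 1) for g, b in biomes.items()]
        ko = _ko_matrix_for_pairs(biomes)
        res = paired_differential_kos(pairs, ko, recs, n_iter=10, seed=0)
        assert all(not r.significant for r in res)

    def test_planted_ko_detected_with_direction(self):
        tree, pairs, biomes = _pairs_on_chain(40, "BM")
        recs = [GenomeRecord(g, b, 95, 1) for g, b in biomes.items()]
        ko = _ko_matrix_for_pairs(biomes, planted="brackish", seed=3)
        res = paired_differential_kos(pairs, ko, recs, n_iter=20, seed=1)
        hit = next(r for r in res if r.ko_id == "K_planted")
        assert hit.significant
        assert hit.direction == "more_in_fresher"   # brackish side of BM
        # null KOs stay quiet
        false = [r for r in res if r.ko_id != "K_planted" and r.significant]
        assert len(false) <= max(1, len(res) // 10)

    def test_completeness_confound_needs_correction(self):
        # a KO present in every genome, but saline genomes assembled at 80%
        # completeness and fresher ones at 95%: without correction the
        # observed absence pattern fakes a biome effect
        tree, pairs, biomes = _pairs_on_chain(40, "BM")
        rng = np.random.default_rng(7)
        recs = []
        for g, b in biomes.items():
            comp = 80.0 if b == "marine" else 95.0
            recs.append(GenomeRecord(g, b, comp, 1))
        genomes = sorted(biomes)
        kos = [f"K{j:03d}" for j in range(40)]
        truth = np.ones((len(genomes), len(kos)), dtype=bool)
        observed = truth.copy()
        for i, g in enumerate(genomes):
            comp = 80.0 if biomes[g] == "marine" else 95.0
            observed[i] &= rng.random(len(kos)) < comp / 100.0
        ko = KOMatrix(genomes=genomes, kos=kos, presence=observed)
        corrected = paired_differential_kos(pairs, ko, recs, n_iter=20, seed=2,
                                            correct_completeness=True)
        uncorrected = paired_differential_kos(pairs, ko, recs, n_iter=20, seed=2,
                                              correct_completeness=False)
        n_sig_corr = sum(r.significant for r in corrected)
        n_sig_raw = sum(r.significant for r in uncorrected)
        assert n_sig_corr <= len(kos) * 0.1
        assert n_sig_raw > n_sig_corr

    def test_too_few_pairs_skipped_with_warning(self):
        tree, pairs, biomes = _pairs_on_chain(3)
        recs = [GenomeRecord(g, b, 90, 1) for g, b in biomes.items()]
        ko = _ko_matrix_for_pairs(biomes)
        with pytest.warns(UserWarning, match="skipped"):
            res = paired_differential_kos(pairs, ko, recs, n_iter=5, seed=0)
        assert res == []

    def test_seed_reproducibility(self):
        tree, pairs, biomes = _pairs_on_chain(8)
        recs = [GenomeRecord(g, b, 85, 1) for g, b in biomes.items()]
        ko = _ko_matrix_for_pairs(biomes, planted="marine", seed=5)
        r1 = paired_differential_kos(pairs, ko, recs, n_iter=10, seed=4)
        r2 = paired_differential_kos(pairs, ko, recs, n_iter=10, seed=4)
        assert [(r.ko_id, r.mean_q) for r in r1] == [(r.ko_id, r.mean_q) for r in r2]

    def test_null_fdr_calibration(self):
        # fully null data (equal completeness, no planted KOs, random
        # presence): the fraction of KOs called at mean q < 0.1 stays
        # within the nominal FDR
        rng = np.random.default_rng(11)
        n_called = 0
        n_total = 0
        for rep in range(5):
            tree, pairs, biomes = _pairs_on_chain(20, "FB")
            recs = [GenomeRecord(g, b, 90, 1) for g, b in biomes.items()]
            genomes = sorted(biomes)
            kos = [f"K{j:03d}" for j in range(60)]
            presence = rng.random((len(genomes), len(kos))) < 0.5
            ko = KOMatrix(genomes=genomes, kos=kos, presence=presence)
            res = paired_differential_kos(pairs, ko, recs, n_iter=10,
                                          seed=100 + rep)
            n_called += sum(r.significant for r in res)
            n_total += len(res)
        assert n_called <= 0.1 * n_total


class TestMsgPresence:
    def _matrix(self):
        return KOMatrix(genomes=["a", "b", "c"], kos=["K1"],
                        presence=np.array([[True], [True], [False]]))

    def test_majority_present(self):
        msg = MSG(tips=frozenset("abc"), biome="marine", node=None)
        assert msg_presence(msg, "K1", self._matrix()) is True

    def test_exact_half_is_absent(self):
        msg = MSG(tips=frozenset("bc"), biome="marine", node=None)
        # 1 of 2 = 0.5, not > 0.5
        assert msg_presence(msg, "K1", self._matrix()) is False

    def test_singleton(self):
        msg = MSG(tips=frozenset("a"), biome="marine", node=None)
        assert msg_presence(msg, "K1", self._matrix()) is True


class TestUnpairedDifferentialKOs:
    def test_planted_and_confounded_kos_both_flagged(self):
        # phylogeny-unaware testing flags the planted KO *and* a purely
        # clade-confounded KO; the paired analysis on the same data only
        # finds the planted one
        rng = np.random.default_rng(0)
        n = 60
        biomes = {}
        recs = []
        for i in range(n):
            b = "freshwater" if i < n // 2 else "brackish"
            g = f"g{i:03d}"
            biomes[g] = b
            recs.append(GenomeRecord(g, b, 90, 1))
        genomes = sorted(biomes)
        kos = ["K_planted", "K_clade"] + [f"K{j:02d}" for j in range(30)]
        cols = []
        cols.append(np.array([rng.random() < (0.8 if biomes[g] == "brackish" else 0.1)
                              for g in genomes]))
        # clade-confounded: fixed in one half of each biome? make it fixed in
        # a clade that happens to be all brackish
        cols.append(np.array([biomes[g] == "brackish" for g in genomes]))
        for _ in range(30):
            cols.append(rng.random(len(genomes)) < 0.5)
        ko = KOMatrix(genomes=genomes, kos=kos,
                      presence=np.column_stack(cols))
        res = unpaired_differential_kos(recs, ko, seed=1,
                                        biome_pair=("freshwater", "brackish"))
        by_id = {r.ko_id: r for r in res}
        assert by_id["K_planted"].mean_q < 0.1
        assert by_id["K_clade"].mean_q < 0.1
        assert by_id["K_planted"].direction == "more_in_saline"

    def test_retention_probability_boundary(self):
        # completeness exactly 75 -> retention probability 1
        recs = [GenomeRecord("a", "freshwater", 75.0, 1),
                GenomeRecord("b", "brackish", 75.0, 1)]
        ko = KOMatrix(genomes=["a", "b"], kos=["K1"],
                      presence=np.array([[True], [True]]))
        res = unpaired_differential_kos(recs, ko, seed=0)
        assert res[0].presence_fraction_fresher == 1.0
        assert res[0].presence_fraction_saline == 1.0


class TestOverlapVsTime:
    def test_common_curve_no_contrast(self):
        rng = np.random.default_rng(0)
        pts = []
        for g in ("FB", "none"):
            t = rng.uniform(10, 500, 40)
            y = np.exp(-0.002 * t) + rng.normal(0, 0.01, 40)
            pts += [OverlapPoint(f"{g}{i}", max(y[i], 1e-3), t[i], g)
                    for i in range(40)]
        res = fit_overlap_vs_time(pts)
        assert (res.contrasts["p"] > 0.01).all()

    def test_planted_offset_recovered(self):
        rng = np.random.default_rng(1)
        pts = []
        for g, off in (("FB", 0.0), ("BM", -0.2)):
            t = rng.uniform(10, 500, 50)
            y = 0.8 - 0.0005 * t + off + rng.normal(0, 0.01, 50)
            pts += [OverlapPoint(f"{g}{i}", y[i], t[i], g) for i in range(50)]
        res = fit_overlap_vs_time(pts)
        lin = res.contrasts[res.contrasts["model"] == "linear"].iloc[0]
        assert abs(abs(lin["estimate"]) - 0.2) < 0.02
        assert lin["p"] < 1e-6

    def test_single_group_no_contrasts(self):
        rng = np.random.default_rng(2)
        t = rng.uniform(10, 100, 10)
        pts = [OverlapPoint(f"p{i}", 0.5, t[i], "FB") for i in range(10)]
        res = fit_overlap_vs_time(pts)
        assert len(res.contrasts) == 0
        assert len(res.coefficients) == 2  # log + linear fits
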