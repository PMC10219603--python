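"""Isoelectric points, composition profiles, and transition comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossbiome.proteome import (
    AA_CATEGORIES,
    AMINO_ACIDS,
    DEFAULT_PK,
    N_BINS,
    aa_composition,
    compare_transitions,
    fit_difference_vs_time,
    fit_log_curve,
    msg_profile,
    net_charge,
    pi_distribution,
    posttransition_convergence,
    profile_proteome,
    protein_pi,
    proteome_pis,
    total_pi_difference,
)


class TestProteinPI:
    def test_glycine_dipeptide_closed_form(self):
        # only termini ionize: pI = (pK_N + pK_C) / 2 = (8.6 + 3.6) / 2;
        # the bisection stops on |charge| < 1e-4, which bounds the pH to
        # a few thousandths around the root
        assert protein_pi("GG") == pytest.approx(6.1, abs=5e-3)

    def test_acidic_residue_lowers_pi(self):
        assert protein_pi("GGDGG") < protein_pi("GGGGG")

    def test_polylysine_above_nterm_pk(self):
        # net charge at pH 8.6 is still positive (4 lysines), so the zero
        # crossing must lie above it
        assert net_charge("KKKK", 8.6) > 0
        assert protein_pi("KKKK") > 8.6

    def test_charge_strictly_decreasing_in_ph(self):
        rng = np.random.default_rng(0)
        aas = np.array(list(AMINO_ACIDS))
        for _ in range(200):
            seq = "".join(rng.choice(aas, size=rng.integers(5, 60)))
            phs = np.linspace(0.5, 13.5, 27)
            charges = [net_charge(seq, p) for p in phs]
            assert all(a > b for a, b in zip(charges, charges[1:]))

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(1)
        aas = np.array(list(AMINO_ACIDS))
        seqs = ["".join(rng.choice(aas, size=rng.integers(10, 80)))
                for _ in range(50)]
        vec = proteome_pis(seqs)
        ref = np.array([protein_pi(s) for s in seqs])
        assert vec == pytest.approx(ref, abs=2e-3)

    def test_charge_near_zero_at_pi(self):
        rng = np.random.default_rng(2)
        aas = np.array(list(AMINO_ACIDS))
        for _ in range(20):
            seq = "".join(rng.choice(aas, size=30))
            assert abs(net_charge(seq, protein_pi(seq))) < 1e-3


class TestDistribution:
    def test_identical_proteins_single_bin(self):
        bins, classes, ncl = pi_distribution([7.1] * 5)
        assert bins[int((7.0 - 3.0) / 0.5)] == 1.0
        assert classes["neutral"] == 1.0 and ncl == 0

    def test_boundary_5p5_is_neutral(self):
        _, classes, _ = pi_distribution([5.5])
        assert classes["neutral"] == 1.0 and classes["acidic"] == 0.0

    def test_mixed_classes(self):
        _, classes, _ = pi_distribution([4.0, 9.0])
        assert classes == {"acidic": 0.5, "neutral": 0.0, "basic": 0.5}

    def test_out_of_range_clamped_and_counted(self):
        bins, _, ncl = pi_distribution([2.0, 13.0, 7.0])
        assert ncl == 2
        assert bins.sum() == pytest.approx(1.0)
        assert bins[0] > 0 and bins[-1] > 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pi_distribution([])


class TestComposition:
    def test_pure_acidic(self):
        freq, cat, _ = aa_composition(["DDEE"])
        assert cat["acidic_aa"] == pytest.approx(1.0)
        assert cat["charged"] == pytest.approx(1.0)
        assert cat["polar"] == pytest.approx(1.0)

    def test_alanine_has_no_charge(self):
        _, cat, _ = aa_composition(["AAAA"])
        assert cat["charged"] == 0.0 and cat["polar"] == 0.0

    def test_category_identities(self):
        rng = np.random.default_rng(3)
        aas = np.array(list(AMINO_ACIDS))
        seqs = ["".join(rng.choice(aas, size=100)) for _ in range(5)]
        _, cat, _ = aa_composition(seqs)
        assert cat["charged"] == pytest.approx(cat["acidic_aa"] + cat["basic_aa"])
        assert cat["polar"] >= cat["charged"] - 1e-12
        assert set(AA_CATEGORIES["charged"]) <= set(AA_CATEGORIES["polar"])

    def test_ambiguous_residues_excluded(self):
        freq, _, skipped = aa_composition(["AAXX*"])
        assert skipped == 3
        assert freq[AMINO_ACIDS.index("A")] == pytest.approx(1.0)


class TestProfiles:
    def test_single_member_msg_identity(self):
        p = profile_proteome("g1", ["MKDEDE", "GGKKRR"])
        m = msg_profile("msg", [p])
        assert m.pi_bins == pytest.approx(p.pi_bins)
        assert m.class_fractions == p.class_fractions

    def test_two_member_average(self):
        p1 = profile_proteome("g1", ["DDDDEE"] * 4)
        p2 = profile_proteome("g2", ["KKKKRR"] * 4)
        m = msg_profile("msg", [p1, p2])
        assert m.class_fractions["acidic"] == pytest.approx(
            (p1.class_fractions["acidic"] + p2.class_fractions["acidic"]) / 2)
        assert m.pi_bins.sum() == pytest.approx(1.0)


class TestTotalPiDifference:
    def test_identical_zero(self):
        a = np.full(N_BINS, 1 / N_BINS)
        assert total_pi_difference(a, a) == 0.0

    def test_disjoint_is_two(self):
        a = np.zeros(N_BINS); a[0] = 1.0
        b = np.zeros(N_BINS); b[5] = 1.0
        assert total_pi_difference(a, b) == pytest.approx(2.0)

    def test_half_overlap(self):
        a = np.zeros(N_BINS); a[0] = a[1] = 0.5
        b = np.zeros(N_BINS); b[1] = b[2] = 0.5
        assert total_pi_difference(a, b) == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.dirichlet(np.ones(N_BINS), size=3)
        assert total_pi_difference(a, b) == pytest.approx(total_pi_difference(b, a))
        assert total_pi_difference(a, c) <= (
            total_pi_difference(a, b) + total_pi_difference(b, c) + 1e-12)
        assert 0.0 <= total_pi_difference(a, b) <= 2.0


def _fake_pairs_and_profiles(n_pairs, delta_acidic, seed=0, ttype="FB"):
    """MSG pairs with synthetic per-pair profiles; the saline member gets
    a +delta_acidic shift in the acidic pI class."""
    from crossbiome.core import LabeledTree
    from crossbiome.proteome import pair_profile_key
    from crossbiome.treeops import find_msg_pairs

    biome_low, biome_high = {"FB": ("freshwater", "brackish"),
                             "BM": ("brackish", "marine"),
                             "FM": ("freshwater", "marine")}[ttype]
    rng = np.random.default_rng(seed)
    newick = "(" + ",".join(
        f"(L{i}:1,H{i}:1):{i + 1}" for i in range(n_pairs)) + ");"
    tree = LabeledTree.from_newick(newick)
    biomes = {}
    for i in range(n_pairs):
        biomes[f"L{i}"] = biome_low
        biomes[f"H{i}"] = biome_high
    pairs = find_msg_pairs(tree, biomes)
    profiles = {}
    for p in pairs:
        for msg in (p.msg_a, p.msg_b):
            base = rng.dirichlet(np.ones(N_BINS) * 10)
            shift = delta_acidic if msg.biome == biome_high else 0.0
            bins = base.copy()
            bins[2] += shift          # an acidic bin [4.0, 4.5)
            bins[10] -= shift         # a neutral bin
            bins = np.clip(bins, 0, None); bins /= bins.sum()
            classes = {
                "acidic": float(bins[:5].sum()),
                "neutral": float(bins[5:11].sum()),
                "basic": float(bins[11:].sum()),
            }
            aa = rng.dirichlet(np.ones(20) * 20)
            cats = {k: float(sum(aa[AMINO_ACIDS.index(x)] for x in v))
                    for k, v in AA_CATEGORIES.items()}
            from crossbiome.proteome import ProteomeProfile

            profiles[pair_profile_key(p, msg.biome)] = ProteomeProfile(
                profile_id=f"{p.pair_id}:{msg.biome}", pi_bins=bins,
                class_fractions=classes, aa_freq=aa, category_freq=cats,
                n_proteins=100, n_residues=10000)
    return pairs, profiles


class TestCompareTransitions:
    def test_identical_profiles_give_no_signal(self):
        pairs, profiles = _fake_pairs_and_profiles(10, 0.0, seed=1)
        # make both sides literally identical
        for p in pairs:
            k_low = f"{p.pair_id}:freshwater"; k_high = f"{p.pair_id}:brackish"
            profiles[k_high] = profiles[k_low]
        res = compare_transitions(pairs, profiles)
        assert all(d.total_pi_difference == 0 for d in res.deltas)
        assert (res.tests["p_bonf"] == 1.0).all()

    def test_planted_acidic_shift_recovered(self):
        pairs, profiles = _fake_pairs_and_profiles(40, 0.03, seed=2)
        res = compare_transitions(pairs, profiles)
        row = res.tests[(res.tests["type"] == "FB")
                        & (res.tests["quantity"] == "class_acidic")]
        assert row["median_delta"].iloc[0] > 0
        assert row["p_bonf"].iloc[0] < 0.05

    def test_label_flip_negates_deltas(self):
        pairs, profiles = _fake_pairs_and_profiles(8, 0.02, seed=3)
        res = compare_transitions(pairs, profiles)
        flipped = {}
        for p in pairs:
            flipped[f"{p.pair_id}:freshwater"] = profiles[f"{p.pair_id}:brackish"]
            flipped[f"{p.pair_id}:brackish"] = profiles[f"{p.pair_id}:freshwater"]
        res2 = compare_transitions(pairs, flipped)
        for d1, d2 in zip(res.deltas, res2.deltas):
            assert d2.bin_deltas == pytest.approx(-d1.bin_deltas)

    def test_null_profiles_control_type_one_error(self):
        rejections = 0
        n_sims = 40
        for s in range(n_sims):
            pairs, profiles = _fake_pairs_and_profiles(12, 0.0, seed=100 + s)
            res = compare_transitions(pairs, profiles)
            rejections += int((res.tests["p_raw"] < 0.05).mean() > 0.05 * 2.5)
        # raw p-values should be roughly uniform; allow generous slack
        assert rejections <= n_sims * 0.25


class TestTimeFits:
    def test_beta_recovered_on_noiseless_log_curve(self):
        t = np.linspace(10, 500, 30)
        y = 1.0 + 0.2 * np.log(t)
        fit = fit_log_curve("FB", t, y)
        assert fit.beta == pytest.approx(0.2, abs=1e-9)
        assert fit.alpha == pytest.approx(1.0, abs=1e-9)

    def test_identical_groups_never_separate(self):
        rng = np.random.default_rng(0)
        t = np.linspace(10, 500, 40)
        y = 1.0 + 0.2 * np.log(t) + rng.normal(0, 0.05, t.size)
        fits, sep = fit_difference_vs_time({"FB": (t, y), "none": (t, y)})
        assert sep["FB"] is None

    def test_large_offset_separates_everywhere(self):
        rng = np.random.default_rng(1)
        t = np.linspace(10, 500, 60)
        base = 1.0 + 0.2 * np.log(t)
        noise = rng.normal(0, 0.01, t.size)
        fits, sep = fit_difference_vs_time(
            {"FB": (t, base + 1.0 + noise), "none": (t, base + noise)})
        assert sep["FB"] is not None
        assert sep["FB"] == pytest.approx(t.min(), rel=0.05)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            fit_log_curve("FB", np.array([0.0, 1.0, 2.0]), np.zeros(3))


class TestPosttransitionConvergence:
    def test_zero_excess_gives_max_threshold(self):
        dt = np.linspace(10, 400, 40)
        dy = np.zeros(40)
        thr, scan = posttransition_convergence(dy, np.zeros(40), dt, np.zeros(40))
        assert thr == pytest.approx(dt.max())

    def test_uniform_excess_significant_everywhere(self):
        dt = np.linspace(10, 400, 40)
        dy = np.full(40, 0.3)
        thr, _ = posttransition_convergence(dy, np.zeros(40), dt, np.zeros(40))
        assert thr == float("-inf")

    def test_planted_changepoint_recovered(self):
        rng = np.random.default_rng(4)
        dt = np.sort(rng.uniform(10, 300, 60))
        dy = np.where(dt >= 100, 0.3, 0.0) + rng.normal(0, 0.02, 60)
        thr, scan = posttransition_convergence(dy, np.zeros(60), dt, np.zeros(60))
        # the scan needs a handful of excess points before the signed-rank
        # test reaches significance, so allow a few grid steps of slack
        above = dt[dt >= 100]
        below = dt[dt < 100]
        assert below[-3] <= thr <= above[5]
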