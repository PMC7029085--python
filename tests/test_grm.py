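import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpkin.grm import (
    additive_codes,
    build_grms,
    classify_inbreeding,
    coancestry,
    dominance_codes,
    grm_inbreeding,
    het_inbreeding,
    sample_frequencies,
)
from snpkin.io_formats import MISSING
from snpkin.pedsim import SimConfig, gene_drop, make_pedigree

from conftest import make_gm
from oracles import grm_bruteforce


class TestCodes:
    def test_single_locus_forced_arithmetic(self):
        # p = 0.5, one ALT-hom and one REF-hom individual
        gm = make_gm([[2], [0]])
        rm = build_grms(gm, np.array([0.5]))
        assert rm.A_g[0, 0] == pytest.approx(2.0)  # F = 1
        assert rm.A_g[0, 1] == pytest.approx(-2.0)  # theta = -1
        assert coancestry(rm.A_g)[0, 1] == pytest.approx(-1.0)
        assert grm_inbreeding(rm.A_g)[0] == pytest.approx(1.0)

    def test_additive_code_zero_at_2p(self):
        assert additive_codes(np.array([1]), 0.5)[0] == 0.0

    @pytest.mark.parametrize("p", [0.1, 0.25, 0.5, 0.77])
    def test_codings_zero_mean_under_hwe(self, p):
        q = 1 - p
        gfreq = np.array([q * q, 2 * p * q, p * p])
        a = additive_codes(np.array([0, 1, 2]), p)
        d = dominance_codes(np.array([0, 1, 2]), p)
        assert gfreq @ a == pytest.approx(0.0, abs=1e-12)
        assert gfreq @ d == pytest.approx(0.0, abs=1e-12)

    def test_dominance_hets_at_half(self):
        gm = make_gm([[1], [1]])
        rm = build_grms(gm, np.array([0.5]))
        assert rm.D_g[0, 1] == pytest.approx(1.0)

    def test_monomorphic_frequency_rejected(self):
        with pytest.raises(ValueError):
            additive_codes(np.array([0, 1]), 0.0)
        gm = make_gm([[0], [0]])
        with pytest.raises(ValueError, match="monomorphic"):
            build_grms(gm, "sample")


@st.composite
def genotype_matrices(draw):
    n = draw(st.integers(2, 10))
    m = draw(st.integers(2, 50))
    codes = draw(
        st.lists(
            st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=m, max_size=m),
            min_size=n,
            max_size=n,
        )
    )
    p = draw(
        st.lists(
            st.floats(0.05, 0.95, allow_nan=False), min_size=m, max_size=m
        )
    )
    return np.array(codes, dtype=np.int8), np.array(p)


class TestGRMOracle:
    @given(genotype_matrices())
    @settings(max_examples=30, deadline=None)
    def test_matches_bruteforce_summation(self, data):
        calls, p = data
        # every pair must share at least one called locus
        called = calls != MISSING
        if not (called.astype(int) @ called.astype(int).T).all():
            return
        gm = make_gm(calls)
        rm = build_grms(gm, p)
        A, D = grm_bruteforce(calls, p)
        np.testing.assert_allclose(rm.A_g, A, atol=1e-12)
        np.testing.assert_allclose(rm.D_g, D, atol=1e-12)

    def test_symmetry_and_toy_example(self, tiny_gm):
        rm = build_grms(tiny_gm)
        np.testing.assert_allclose(rm.A_g, rm.A_g.T, atol=1e-12)
        np.testing.assert_allclose(rm.D_g, rm.D_g.T, atol=1e-12)
        A, D = grm_bruteforce(tiny_gm.calls, sample_frequencies(tiny_gm))
        np.testing.assert_allclose(rm.A_g, A, atol=1e-12)
        np.testing.assert_allclose(rm.D_g, D, atol=1e-12)

    def test_duplicated_individual_offdiag_equals_diag(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([0, 1, 2], size=(4, 40)).astype(np.int8)
        calls = np.vstack([calls, calls[0]])
        gm = make_gm(calls)
        rm = build_grms(gm, np.full(40, 0.5))
        assert rm.A_g[0, 4] == pytest.approx(rm.A_g[0, 0], abs=1e-12)


class TestPedigreeRecovery:
    """Small-scale recovery; the full-scale protocol runs in acceptance."""

    def test_parent_offspring_theta(self):
        ped = make_pedigree("parent_offspring", 60)
        gm, p = gene_drop(ped, SimConfig(n_loci=4000, seed=21))
        rm = build_grms(gm, p)
        idx = {s: i for i, s in enumerate(gm.samples)}
        th = [
            coancestry(rm.A_g)[idx[a], idx[b]] for a, b in ped.focal_pairs
        ]
        assert np.mean(th) == pytest.approx(0.25, abs=0.02)

    def test_sample_freqs_give_negative_mean_offdiag(self):
        ped = make_pedigree("unrelated", 25)
        gm, _ = gene_drop(ped, SimConfig(n_loci=3000, seed=22))
        rm = build_grms(gm, "sample")
        n = gm.n_samples
        off = rm.A_g[np.triu_indices(n, 1)]
        assert off.mean() < 0

    def test_loo_freqs_remove_negative_bias(self):
        # with full-sample frequencies the off-diagonal mean is pushed
        # negative (the focal pair is in the frequency estimate); with
        # leave-pair-out frequencies that downward pull disappears,
        # leaving a small positive finite-sample variance term instead
        ped = make_pedigree("unrelated", 25)
        gm, _ = gene_drop(ped, SimConfig(n_loci=3000, seed=23))
        n = gm.n_samples
        biased = build_grms(gm, "sample").A_g[np.triu_indices(n, 1)].mean()
        loo = build_grms(gm, loo=True).A_g[np.triu_indices(n, 1)].mean()
        assert biased < 0
        assert loo > biased
        assert abs(loo - 1.0 / (n - 2)) < abs(biased)  # matches theory


class TestHetInbreeding:
    def test_two_locus_hand_computation(self):
        # 3 individuals, 2 loci, no missing
        gm = make_gm([[0, 1], [1, 1], [2, 0]])
        p = sample_frequencies(gm)  # (0.5, 1/3)
        Na = 6.0
        e = (1 - 2 * p[0] * (1 - p[0]) * Na / (Na - 1)) + (
            1 - 2 * p[1] * (1 - p[1]) * Na / (Na - 1)
        )
        F = het_inbreeding(gm)
        want0 = (1 - e) / (2 - e)  # individual 0: one hom of two loci
        assert F[0] == pytest.approx(want0, abs=1e-12)

    def test_all_het_individual_negative(self):
        gm = make_gm([[1, 1, 1, 1], [0, 0, 2, 2], [0, 2, 0, 2]])
        F = het_inbreeding(gm)
        assert F[0] < 0

    def test_mean_near_zero_for_outbred_sample(self):
        ped = make_pedigree("unrelated", 60)
        gm, p = gene_drop(ped, SimConfig(n_loci=4000, seed=31))
        F = het_inbreeding(gm, p)
        assert np.nanmean(F) == pytest.approx(0.0, abs=0.01)


class TestClassification:
    @pytest.mark.parametrize(
        "F, label",
        [
            (0.0625, "first_cousin_mating"),
            (0.125, "half_sib_mating"),
            (0.01, "outbred"),
            (0.25, "full_sib_mating"),
            (-0.1, "outbred"),
        ],
    )
    def test_nearest_expectation(self, F, label):
        assert classify_inbreeding(np.array([F]))[0] == label
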