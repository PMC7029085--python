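import numpy as np
import pytest

from snpkin.io_formats import MISSING, write_vcf
from snpkin.pedsim import (
    TEMPLATES,
    Pedigree,
    SimConfig,
    duplicate_individual,
    expected_coefficients,
    gene_drop,
    kinship_matrix,
    make_pedigree,
    make_study_fixture,
    realized_ibd_fraction,
)
from snpkin.snp_filter import filter_loci

from oracles import pedigree_enumeration

# classical expectations: (kinship of focal pair, dominance of focal pair)
PAIR_EXPECTATIONS = {
    "unrelated": (0.0, 0.0),
    "parent_offspring": (0.25, 0.0),
    "full_sibs": (0.25, 0.25),
    "half_sibs": (0.125, 0.0),
    "first_cousins": (0.0625, 0.0),
    "double_first_cousins": (0.125, 0.0625),
}

# inbreeding of the focal offspring
F_EXPECTATIONS = {
    "first_cousin_mating": 0.0625,
    "half_sib_mating": 0.125,
}


class TestPedigreeStructure:
    def test_full_sibs_template(self):
        ped = make_pedigree("full_sibs")
        assert len(ped.founders) == 2
        assert ped.focal_pairs == [("r0_S1", "r0_S2")]

    def test_first_cousin_mating_template(self):
        ped = make_pedigree("first_cousin_mating")
        assert len(ped.founders) == 4
        assert ped.focal_individuals == ["r0_Z"]

    def test_half_sib_mating_template(self):
        ped = make_pedigree("half_sib_mating")
        assert len(ped.founders) == 3
        assert ped.focal_individuals == ["r0_Z"]

    def test_unknown_template(self):
        with pytest.raises(ValueError, match="unknown pedigree template"):
            make_pedigree("clones_of_dolly")

    def test_replicates_disjoint(self):
        ped = make_pedigree("full_sibs", 3)
        assert len(ped.focal_pairs) == 3
        assert len(set(ped.individuals)) == 3 * 4

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            Pedigree(["a", "b"], {"a": ("b", "b"), "b": ("a", "a")})

    def test_missing_parent_rejected(self):
        with pytest.raises(ValueError, match="parent"):
            Pedigree(["a"], {"a": ("x", "y")})


class TestExpectedCoefficients:
    @pytest.mark.parametrize("template", sorted(PAIR_EXPECTATIONS))
    def test_classical_pair_values(self, template):
        ped = make_pedigree(template)
        a, b = ped.focal_pairs[0]
        e = expected_coefficients(ped, a, b)
        kin, dom = PAIR_EXPECTATIONS[template]
        assert e.kinship == pytest.approx(kin)
        assert e.additive == pytest.approx(2 * kin)
        assert e.dominance == pytest.approx(dom)
        assert e.dominance_exact

    @pytest.mark.parametrize("template", sorted(F_EXPECTATIONS))
    def test_inbred_offspring_F(self, template):
        ped = make_pedigree(template)
        z = ped.focal_individuals[0]
        e = expected_coefficients(ped, z, z)
        assert e.inbreeding_i == pytest.approx(F_EXPECTATIONS[template])

    @pytest.mark.parametrize("template", TEMPLATES)
    def test_matches_transmission_enumeration(self, template):
        ped = make_pedigree(template)
        targets = list(ped.focal_pairs) + [
            (z, z) for z in ped.focal_individuals
        ]
        for a, b in targets:
            e = expected_coefficients(ped, a, b)
            kin, Fi, Fj, dom = pedigree_enumeration(ped, a, b)
            assert e.kinship == pytest.approx(kin, abs=1e-12)
            assert e.inbreeding_i == pytest.approx(Fi, abs=1e-12)
            assert e.inbreeding_j == pytest.approx(Fj, abs=1e-12)
            if e.dominance_exact:
                assert e.dominance == pytest.approx(dom, abs=1e-12)

    def test_kinship_matrix_symmetric_with_half_diagonal_base(self):
        ped = make_pedigree("full_sibs")
        f, ids = kinship_matrix(ped)
        np.testing.assert_allclose(f, f.T)
        for founder in ped.founders:
            assert f[ids.index(founder), ids.index(founder)] == 0.5

    def test_inbred_member_dominance_flagged(self):
        ped = make_pedigree("first_cousin_mating")
        e = expected_coefficients(ped, "r0_Z", "r0_C1")
        assert not e.dominance_exact


class TestGeneDrop:
    def test_deterministic_vcf_bytes(self, tmp_path):
        ped = make_pedigree("half_sibs", 2)
        cfg = SimConfig(n_loci=50, missing_rate=0.05, seed=17)
        out = []
        for name in ("a.vcf", "b.vcf"):
            gm, _ = gene_drop(ped, cfg)
            write_vcf(gm, tmp_path / name)
            out.append((tmp_path / name).read_bytes())
        assert out[0] == out[1]

    def test_founder_heterozygosity(self):
        ped = make_pedigree("unrelated", 1)
        p = np.full(20000, 0.3)
        gm, _ = gene_drop(ped, SimConfig(seed=4), freqs=p)
        het = (gm.calls == 1).mean(axis=1)
        assert het.mean() == pytest.approx(2 * 0.3 * 0.7, abs=0.01)

    def test_duplicate_individual_identical_rows(self):
        ped = make_pedigree("unrelated", 2)
        gm, _ = gene_drop(ped, SimConfig(n_loci=100, seed=5))
        gm2 = duplicate_individual(gm, gm.samples[1], "clone")
        np.testing.assert_array_equal(gm2.calls[1], gm2.calls[-1])

    def test_realized_ibd_matches_kinship(self):
        ped = make_pedigree("full_sibs", 30)
        _, _, org = gene_drop(
            ped, SimConfig(n_loci=2000, seed=6), return_origins=True
        )
        vals = [
            realized_ibd_fraction(org[a], org[b]) for a, b in ped.focal_pairs
        ]
        # E = kinship 1/4; SE of the mean over 30 pairs is small
        assert np.mean(vals) == pytest.approx(0.25, abs=0.02)

    def test_missing_rate_applied(self):
        ped = make_pedigree("unrelated", 50)
        gm, _ = gene_drop(ped, SimConfig(n_loci=500, missing_rate=0.1, seed=7))
        frac = (gm.calls == MISSING).mean()
        assert frac == pytest.approx(0.1, abs=0.02)


class TestStudyFixture:
    def test_layout(self, study_fixture):
        gm, meta, truth = study_fixture
        assert gm.n_samples == 43
        sizes = {}
        for m in meta:
            sizes[m.population] = sizes.get(m.population, 0) + 1
        assert sizes == {"A": 11, "B": 20, "C": 12}
        kms = {m.population: m.river_km for m in meta}
        assert kms == {"A": 5.0, "B": 17.0, "C": 25.0}

    def test_missingness_capped_at_four(self, study_fixture):
        gm, _, _ = study_fixture
        assert (gm.calls == MISSING).sum(axis=0).max() <= 4

    def test_postfilter_locus_count_near_panel_size(self, study_fixture):
        gm, _, _ = study_fixture
        kept, _ = filter_loci(gm)
        assert abs(kept.n_loci - 15396) / 15396 < 0.10

    def test_truth_bookkeeping(self, study_fixture):
        _, meta, truth = study_fixture
        ids = {m.sample_id for m in meta}
        assert set(truth["F"]) <= ids
        assert sorted(truth["F"].values()) == sorted(
            [1 / 16] * 3 + [1 / 8] * 5
        )
        for (a, b), v in truth["related_pairs"].items():
            assert {a, b} <= ids
            assert v in (1 / 8, 1 / 16)

    def test_duplicate_embedding(self):
        gm, meta, truth = make_study_fixture(
            SimConfig(n_loci=400, missing_rate=0.0, seed=3, drift_fst=0.06),
            embed_duplicate=True,
        )
        i, j = gm.samples.index("B19"), gm.samples.index("B20")
        np.testing.assert_array_equal(gm.calls[i], gm.calls[j])
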