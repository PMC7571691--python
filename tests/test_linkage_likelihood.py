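import numpy as np
import pytest

from dcm_phenolink.linkage import Individual, LinkageModel, Pedigree, pedigree_likelihood, two_point_lod
from dcm_phenolink.synth.genedrop import PedigreeSimSpec, gene_drop, random_pedigree
from oracles import enumeration_likelihood


def make_trio(child_affection="affected"):
    return Pedigree(
        [
            Individual("F", affection="unknown", sex="male"),
            Individual("M", affection="unknown", sex="female"),
            Individual("C", "F", "M", "unknown", child_affection),
        ]
    )


class TestPedigreeLikelihood:
    def test_single_founder_marker_likelihood_is_hwe_probability(self):
        ped = Pedigree([Individual("X", affection="unknown")])
        model = LinkageModel(disease_allele_freq=0.01)
        freqs = {1: 0.7, 2: 0.3}
        # heterozygote: 2 p1 p2 (phenotype unknown sums penetrance factors out)
        L = pedigree_likelihood(ped, {"X": (1, 2)}, model, 0.1, marker_allele_freqs=freqs)
        assert L == pytest.approx(2 * 0.7 * 0.3, rel=1e-12)
        L_hom = pedigree_likelihood(ped, {"X": (2, 2)}, model, 0.1, marker_allele_freqs=freqs)
        assert L_hom == pytest.approx(0.3**2, rel=1e-12)

    def test_trio_with_affected_child_matches_hand_enumeration(self):
        # fully penetrant recessive, no marker information: the likelihood
        # of an affected child of untyped parents is q^2; the carrier x
        # carrier configuration contributes [2q(1-q)]^2 / 4 of it
        q = 0.2
        model = LinkageModel(disease_allele_freq=q, penetrance=(0.0, 0.0, 1.0))
        ped = make_trio()
        L = pedigree_likelihood(ped, {}, model, 0.1, marker_allele_freqs={1: 1.0})
        assert L == pytest.approx(q**2, rel=1e-12)
        carrier_term = (2 * q * (1 - q)) ** 2 * 0.25
        assert carrier_term < L  # one configuration among several

    def test_trio_with_unaffected_parents_matches_hand_enumeration(self):
        q, pen = 0.2, 0.99
        model = LinkageModel(disease_allele_freq=q, penetrance=(0.0, 0.0, pen))
        ped = Pedigree(
            [
                Individual("F", affection="unaffected", sex="male"),
                Individual("M", affection="unaffected", sex="female"),
                Individual("C", "F", "M", "unknown", "affected"),
            ]
        )
        # explicit sum over parental genotype classes (0, 1, 2 disease alleles)
        hwe = {0: (1 - q) ** 2, 1: 2 * q * (1 - q), 2: q**2}
        pen_unaff = {0: 1.0, 1: 1.0, 2: 1.0 - pen}
        p_d_transmit = {0: 0.0, 1: 0.5, 2: 1.0}
        expected = sum(
            hwe[gf] * pen_unaff[gf] * hwe[gm] * pen_unaff[gm] * p_d_transmit[gf] * p_d_transmit[gm] * pen
            for gf in range(3)
            for gm in range(3)
        )
        L = pedigree_likelihood(ped, {}, model, 0.3, marker_allele_freqs={1: 1.0})
        assert L == pytest.approx(expected, rel=1e-12)

    def test_peeling_equals_enumeration_on_random_pedigrees(self, rng):
        model = LinkageModel(disease_allele_freq=0.2, penetrance=(0.0, 0.0, 0.99))
        for _ in range(25):
            ped = random_pedigree(rng, 10)
            spec = PedigreeSimSpec(
                pedigree=ped,
                disease_allele_freq=0.2,
                penetrance=(0.0, 0.0, 0.99),
                theta=0.1,
                marker_allele_freqs=(0.4, 0.3, 0.2, 0.1),
                seed=int(rng.integers(2**31)),
            )
            rep = gene_drop(spec)[0]
            ped2 = ped.with_affections(rep.affections)
            geno = rep.genotypes.marker_genotypes("M1")
            theta = float(rng.uniform(0, 0.5))
            L_peel = pedigree_likelihood(ped2, geno, model, theta)
            L_enum = enumeration_likelihood(ped2, geno, model, theta)
            assert L_peel == pytest.approx(L_enum, rel=1e-9)

    def test_mendelian_inconsistency_gives_zero_likelihood(self):
        ped = make_trio(child_affection="unknown")
        model = LinkageModel()
        geno = {"F": (1, 1), "M": (2, 2), "C": (3, 3)}
        assert pedigree_likelihood(ped, geno, model, 0.1) == 0.0

    def test_state_bound_enforced(self):
        ped = make_trio()
        with pytest.raises(ValueError, match="bound"):
            pedigree_likelihood(ped, {"F": (1, 2), "M": (1, 2), "C": (1, 2)}, LinkageModel(), 0.1, state_bound=10)

    def test_invalid_inputs_rejected(self):
        ped = make_trio()
        with pytest.raises(ValueError, match="theta"):
            pedigree_likelihood(ped, {"C": (1, 1)}, LinkageModel(), 0.7)
        with pytest.raises(ValueError, match="sum to 1"):
            pedigree_likelihood(ped, {"C": (1, 1)}, LinkageModel(), 0.1, marker_allele_freqs={1: 0.5, 2: 0.4})


class TestTwoPointLod:
    def phase_known_pedigree(self):
        # grandparental genotypes force the father's phase; with full
        # penetrance the affected child's paternal gamete is known to be
        # nonrecombinant
        return (
            Pedigree(
                [
                    Individual("GF", affection="affected", sex="male"),
                    Individual("GM", affection="unaffected", sex="female"),
                    Individual("F", "GF", "GM", "male", "unaffected"),
                    Individual("M", affection="affected", sex="female"),
                    Individual("C", "F", "M", "unknown", "affected"),
                ]
            ),
            {"GF": (2, 2), "GM": (1, 1), "F": (1, 2), "M": (3, 3), "C": (2, 3)},
        )

    def test_lod_is_zero_at_free_recombination(self):
        ped, geno = self.phase_known_pedigree()
        model = LinkageModel(penetrance=(0, 0, 1.0), theta_grid=(0.0, 0.1, 0.3, 0.5))
        res = two_point_lod(ped, geno, model)
        assert res.lod[-1] == pytest.approx(0.0, abs=1e-12)

    def test_single_nonrecombinant_meiosis_gives_log10_two(self):
        ped, geno = self.phase_known_pedigree()
        model = LinkageModel(disease_allele_freq=0.05, penetrance=(0, 0, 1.0))
        res = two_point_lod(ped, geno, model)
        assert res.lod[0] == pytest.approx(np.log10(2), abs=1e-9)
        assert res.theta_hat == 0.0

    def test_lod_is_continuous_on_grid_refinement(self):
        ped, geno = self.phase_known_pedigree()
        grid = tuple(np.linspace(0.0, 0.5, 26))
        model = LinkageModel(penetrance=(0, 0, 1.0), theta_grid=grid)
        res = two_point_lod(ped, geno, model)
        steps = np.abs(np.diff(res.lod))
        assert steps.max() < 0.05  # Lod(theta) = log10(2(1-theta)) varies smoothly

    def test_theta_grid_recovery_from_simulation(self, multiplex_pedigree):
        # gene drops at theta = 0.05 on an ascertained multiplex family:
        # the grid argmax should track the simulated recombination fraction
        model = LinkageModel(disease_allele_freq=0.25, penetrance=(0, 0, 1.0))
        rng = np.random.default_rng(6)
        th_hats = []
        while len(th_hats) < 40:
            spec = PedigreeSimSpec(
                pedigree=multiplex_pedigree,
                disease_allele_freq=0.25,
                penetrance=(0, 0, 1.0),
                theta=0.05,
                marker_allele_freqs=(0.125,) * 8,
                seed=int(rng.integers(2**31)),
            )
            rep = gene_drop(spec)[0]
            if sum(a == "affected" for a in rep.affections.values()) < 4:
                continue
            res = two_point_lod(
                multiplex_pedigree.with_affections(rep.affections),
                rep.genotypes,
                model,
                marker_id="M1",
                marker_allele_freqs={i: 0.125 for i in range(1, 9)},
            )
            th_hats.append(res.theta_hat)
        assert abs(np.mean(th_hats) - 0.05) < 0.05  # coarse check; full run in acceptance

    def test_inconsistent_data_raises(self):
        ped = make_trio(child_affection="unknown")
        with pytest.raises(ValueError, match="inconsistent"):
            two_point_lod(ped, {"F": (1, 1), "M": (2, 2), "C": (3, 3)}, LinkageModel())


class TestPedigreeValidation:
    def test_ancestry_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            Pedigree(
                [
                    Individual("A", "B", "C"),
                    Individual("B", "A", "C"),
                    Individual("C"),
                ]
            )

    def test_unresolved_parent_rejected(self):
        with pytest.raises(ValueError, match="not in pedigree"):
            Pedigree([Individual("A", "missing", "also_missing")])

    def test_marriage_loop_allowed(self, cousin_loop_pedigree):
        assert len(cousin_loop_pedigree) == 9
        assert "I9" in cousin_loop_pedigree.members
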