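"""Kinship, member classification and transmission inference."""

from fractions import Fraction

import numpy as np
import pytest

from pedcnvseg.pedigree import AFFECTED, Individual, Pedigree, PedigreeError
from pedcnvseg.simulate import gene_drop, generate_pedigree

from oracles import random_pedigree


def trio():
    return Pedigree("T", [
        Individual("dad", sex="1"), Individual("mom", sex="2"),
        Individual("kid", father="dad", mother="mom"),
    ])


class TestKinship:
    def test_parent_child(self):
        assert trio().kinship("dad", "kid") == Fraction(1, 4)

    def test_first_cousins_share_one_eighth(self):
        ped, (p1, p2) = generate_pedigree("first_cousin_pair", "F")
        assert ped.kinship(p1, p2) == Fraction(1, 16)
        assert ped.expected_sharing(p1, p2) == Fraction(1, 8)  # 12.5%

    def test_second_cousins_share_one_thirtysecond(self):
        ped, (p1, p2) = generate_pedigree("second_cousin_pair", "F")
        assert ped.expected_sharing(p1, p2) == Fraction(1, 32)  # 3.125%

    def test_avuncular_pair_shares_one_quarter(self):
        ped, (uncle, nephew) = generate_pedigree("avuncular_pair", "F")
        assert ped.expected_sharing(uncle, nephew) == Fraction(1, 4)

    def test_full_siblings_share_half(self):
        ped, _ = generate_pedigree("first_cousin_pair", "F")
        assert ped.expected_sharing("F_b1", "F_b2") == Fraction(1, 2)

    def test_sharing_decreases_with_relationship_distance(self):
        ped, _ = generate_pedigree("second_cousin_pair", "F")
        chain = [
            ped.expected_sharing("F_b1", "F_b2"),    # sibs
            ped.expected_sharing("F_b1", "F_m2"),    # avuncular
            ped.expected_sharing("F_m1", "F_m2"),    # first cousins
            ped.expected_sharing("F_p1", "F_p2"),    # second cousins
        ]
        assert chain == [Fraction(1, 2), Fraction(1, 4), Fraction(1, 8), Fraction(1, 32)]
        assert chain == sorted(chain, reverse=True)

    def test_self_sharing_undefined(self):
        with pytest.raises(PedigreeError):
            trio().expected_sharing("kid", "kid")

    def test_unknown_individual_rejected(self):
        with pytest.raises(PedigreeError):
            trio().kinship("kid", "ghost")

    def test_agrees_with_path_counting_oracle_on_random_pedigrees(self):
        from oracles import assert_kinship_matches_path_counting

        # 50 pedigrees here; the full 200-pedigree sweep runs in the
        # acceptance suite
        assert_kinship_matches_path_counting(n_pedigrees=50, seed=7)


class TestStructure:
    def test_cycle_detected(self):
        with pytest.raises(PedigreeError, match="cycle"):
            Pedigree("C", [
                Individual("a", father="b", mother="m"),
                Individual("b", father="a", mother="m"),
                Individual("m"),
            ])

    def test_single_parent_completed_with_placeholder(self, caplog):
        with caplog.at_level("WARNING"):
            ped = Pedigree("S", [
                Individual("mom"),
                Individual("kid", mother="mom"),
            ])
        kid = ped.members["kid"]
        assert kid.father is not None and kid.father in ped.members

    def test_extended_family_validation_warns_without_distant_affecteds(self):
        ped = trio()
        ped.members["kid"].affection = AFFECTED
        assert ped.validate_extended_family()  # only one affected -> warning


class TestClassifyMembers:
    def test_canonical_family_partition(self):
        ped, _ = generate_pedigree("first_cousin_pair", "F")
        parts = ped.classify_members()
        assert parts["affected"] == ["F_p1", "F_p2"]
        # founding couple stays in the blood line
        assert {"F_f1", "F_f2", "F_b1", "F_b2"} <= set(parts["unaffected_blood"])
        assert parts["married_in"] == ["F_s1", "F_s2"]

    def test_affected_member_stays_affected_regardless_of_lineage(self):
        ped, _ = generate_pedigree("first_cousin_pair", "F")
        ped.members["F_s1"].affection = AFFECTED
        parts = ped.classify_members()
        assert "F_s1" in parts["affected"]
        assert "F_s1" not in parts["married_in"]


class TestInferTransmission:
    def maternal_family(self):
        return generate_pedigree("first_cousin_pair", "F", transmitting_sex="female")[0]

    def test_maternal_chain_single_introducer(self):
        ped = self.maternal_family()
        res = ped.infer_transmission({"F_p1", "F_p2", "F_b1", "F_b2"})
        assert res.consistent
        assert res.label == "maternal"
        assert res.introducers <= {"F_f1", "F_f2"}

    def test_mixed_routes_labelled_both(self):
        ped = generate_pedigree("first_cousin_pair", "F", transmitting_sex="mixed")[0]
        res = ped.infer_transmission({"F_p1", "F_p2", "F_b1", "F_b2"})
        assert res.consistent and res.label == "both"

    def test_untyped_transmitter_is_permissive(self):
        ped = self.maternal_family()
        ped.members["F_b2"].dna_available = False
        res = ped.infer_transmission({"F_p1", "F_p2", "F_b1"})
        assert res.consistent and res.label == "maternal"

    def test_carriers_split_by_typed_noncarriers_is_inconsistent(self):
        # both probands carry, but both their parents are typed non-carriers
        ped = self.maternal_family()
        res = ped.infer_transmission({"F_p1", "F_p2"})
        assert not res.consistent
        assert res.label == "undetermined"

    def test_identical_carrier_sets_give_identical_output(self):
        ped = generate_pedigree("first_cousin_pair", "F", transmitting_sex="mixed")[0]
        carriers = {"F_p1", "F_p2", "F_b1", "F_b2"}
        r1, r2 = ped.infer_transmission(set(carriers)), ped.infer_transmission(set(carriers))
        assert (r1.label, r1.introducers) == (r2.label, r2.introducers)

    def test_unknown_carrier_rejected(self):
        with pytest.raises(PedigreeError):
            self.maternal_family().infer_transmission({"ghost"})

    @pytest.mark.parametrize("template", [
        "avuncular_pair", "first_cousin_pair", "second_cousin_pair",
        "three_affected", "four_affected",
    ])
    def test_gene_drop_recovers_the_introducer(self, template):
        """The designated founder must always be among the feasible
        origins of the typed carrier set it generated."""
        rng = np.random.default_rng(11)
        ped, _ = generate_pedigree(template, "F")
        typed = set(ped.genotyped_ids())
        hits = 0
        for _ in range(100):
            drop = gene_drop(ped, rng, introducer="F_f1", penetrance=1.0)
            carriers = drop.carriers & typed
            if not carriers:
                continue
            res = ped.infer_transmission(carriers)
            assert res.consistent
            assert "F_f1" in res.diagnostics["feasible_origins"]
            hits += 1
        assert hits > 10
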