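"""Repair-type decision tree and cohort distributions."""

import pytest

from nhejoin.assay import AssayError, Junction, MalformedInputError
from nhejoin.explain import (
    TypeDistribution,
    classify,
    classify_cohort,
    classify_junction,
    enumerate_explanations,
    rank_explanations,
    repair_type,
)
from nhejoin.simulate import default_profile, simulate_junction


def winning(assay, top):
    j = Junction(id="t", top=top, assay=assay)
    return rank_explanations(enumerate_explanations(j)), j


class TestPartialSignatures:
    """The worked mechanistic signatures of the partially-complementary
    system, built literally from the configured ends."""

    def test_type_i_templated_fill(self, partial_assay):
        # intact overhangs, 2-nt terminal pairing, +CA templated top fill
        winner, j = winning(partial_assay,
                            partial_assay.left_top + "CA" + partial_assay.right_top)
        assert classify(winner, partial_assay).label == "I"

    def test_type_i_single_base_pairing_register(self, partial_assay):
        # 1-nt pairing leaves a 3-nt gap: +ACA templated fill
        winner, _ = winning(partial_assay,
                            partial_assay.left_top + "ACA" + partial_assay.right_top)
        assert classify(winner, partial_assay).label == "I"

    def test_type_iii_trim_and_mismatch_tolerant_pairing(self, partial_assay):
        lf = partial_assay.left_end.duplex_top
        rt = partial_assay.right_top
        # one terminal nucleotide removed from each protruding strand; the
        # 3-nt pairing carries a T:G mismatch whose MMR resolution gives
        # either allele at the junction
        for allele in ("ATA", "ACA"):
            winner, _ = winning(partial_assay, lf + allele + rt)
            assert classify(winner, partial_assay).label == "III"
            assert winner.insertion_top == ""
            assert winner.mismatches_in_pairing == 1

    def test_type_iv_end_bridging_both_sides(self, partial_assay):
        lf = partial_assay.left_end.duplex_top
        rt = partial_assay.right_top
        # right end blunted, synthesis across the intact left overhang
        winner, _ = winning(partial_assay, partial_assay.left_top + rt)
        assert classify(winner, partial_assay).label == "IV"
        # left end blunted, synthesis templated by the intact right overhang
        winner, _ = winning(partial_assay,
                            lf + partial_assay.right_end.virtual_top + rt)
        assert classify(winner, partial_assay).label == "IV"

    def test_type_ii_microhomology_with_deletion(self, partial_assay):
        rt = partial_assay.right_top
        d = rt.find("ATAA")
        top = partial_assay.left_top + rt[d + 4:]
        winner, _ = winning(partial_assay, top)
        assert classify(winner, partial_assay).label == "II"
        assert winner.mh_len >= 4

    def test_assay_mismatch_is_contract_error(self, partial_assay, noncomp_assay):
        winner, _ = winning(partial_assay,
                            partial_assay.left_top + "CA" + partial_assay.right_top)
        with pytest.raises(AssayError):
            classify(winner, noncomp_assay)


class TestNoncompSignatures:
    def test_type_i_two_strand_fill(self, noncomp_assay):
        v = noncomp_assay.right_end.virtual_top
        winner, _ = winning(noncomp_assay,
                            noncomp_assay.left_top + v + noncomp_assay.right_top)
        assert classify(winner, noncomp_assay).label == "I"
        assert winner.templated_top and winner.templated_bottom

    def test_type_ii_suffix_microhomology_one_strand_fill(self, noncomp_assay):
        rt = noncomp_assay.right_top
        d = rt.find("TAT")
        top = noncomp_assay.left_top + rt[d + 3:]
        winner, _ = winning(noncomp_assay, top)
        assert classify(winner, noncomp_assay).label == "II"

    def test_type_iii_microhomology_no_fill(self, noncomp_assay):
        lt = noncomp_assay.left_top
        q = noncomp_assay.left_end.duplex_top.find("AACA") + 4
        top = lt[:q] + noncomp_assay.right_top
        winner, _ = winning(noncomp_assay, top)
        assert classify(winner, noncomp_assay).label == "III"


@pytest.mark.parametrize("system,label", [
    ("partial", "I"), ("partial", "II"), ("partial", "III"), ("partial", "IV"),
    ("noncomp", "I"), ("noncomp", "II"), ("noncomp", "III"),
])
def test_simulated_mechanisms_classify_to_truth(system, label, request):
    """Noise-free round trip: every simulatable placement of every type is
    recovered exactly, in both assay systems."""
    assay = request.getfixturevalue(f"{system}_assay")
    profile = default_profile(system, "WT")
    for seed in range(40):
        sj = simulate_junction(label, assay, profile, seed=seed)
        cj = classify_junction(sj.junction)
        assert not cj.unclassifiable and not cj.ambiguous
        assert cj.repair_type == sj.truth


class TestCohort:
    def test_published_wt_cohort_shape(self, partial_assay):
        """A 24-junction cohort with 16/5/2/1 chosen explanations renders
        the published 67/21/8/4 percentages."""
        profile = default_profile("partial", "WT")
        junctions = []
        plan = [("I", 16), ("II", 5), ("III", 2), ("IV", 1)]
        i = 0
        for label, count in plan:
            for k in range(count):
                sj = simulate_junction(label, partial_assay, profile, seed=i,
                                       junction_id=f"wt-{i}")
                junctions.append(sj.junction)
                i += 1
        dist = classify_cohort(junctions)
        assert dist.n == 24
        assert dist.as_vector() == [16, 5, 2, 1]
        assert dist.percentages() == {"I": 67, "II": 21, "III": 8, "IV": 4}

    def test_empty_distribution_marks_percentages_undefined(self):
        dist = TypeDistribution(system="partial", counts={})
        assert dist.n == 0
        assert all(v is None for v in dist.percentages().values())

    def test_unknown_label_rejected(self):
        with pytest.raises(AssayError):
            TypeDistribution(system="noncomp", counts={"IV": 1})

    def test_mixed_assay_cohort_rejected(self, partial_assay, noncomp_assay):
        j1 = Junction(id="a", top=partial_assay.left_top + partial_assay.right_top,
                      assay=partial_assay)
        j2 = Junction(id="b", top=noncomp_assay.left_top + noncomp_assay.right_top,
                      assay=noncomp_assay)
        with pytest.raises(AssayError):
            classify_cohort([j1, j2])

    def test_empty_cohort_needs_explicit_distribution(self):
        with pytest.raises(MalformedInputError):
            classify_cohort([])

    def test_repair_type_registry_matches_table_headers(self):
        assert repair_type("partial", "I").description == "Gap-filling-mediated"
        assert repair_type("partial", "IV").description == "End-bridging"
        assert repair_type("noncomp", "II").description == \
            "MH-mediated and Gap-filling (1-strand)"
        with pytest.raises(AssayError):
            repair_type("noncomp", "IV")
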