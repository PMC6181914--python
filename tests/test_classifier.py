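import itertools

import pytest

from cpakit.classifier import (
    AMBIGUOUS_CLADE,
    COVERAGE_FAIL,
    GAPPED_MOTIF,
    MIXED_SIGNATURE,
    NHA_LIKE_E_TM3,
    POS7_NOT_ACIDIC,
    CladeReference,
    MotifAssignment,
    MotifSpec,
    assign_clade,
    classify,
    classify_assignment,
    classify_electrogenicity,
    classify_family,
    classify_selectivity,
    extract_motif,
    load_clade_reference,
)
from cpakit.hmm import build_profile, viterbi_align


@pytest.fixture(scope="module")
def reference():
    return load_clade_reference()


def motif(states: str, aux: str = "-") -> MotifAssignment:
    return MotifAssignment(tuple(states), aux=aux)


class TestMotifSpec:
    def test_exactly_eight_positions(self):
        spec = MotifSpec.ecnhaa_numbering()
        assert len(spec.columns) == 8
        assert spec.columns == (131, 132, 133, 134, 159, 163, 164, 300)
        assert spec.aux_column == 108
        assert spec.spacing_means == (23, 156)

    def test_wrong_cardinality_rejected(self):
        with pytest.raises(ValueError):
            MotifSpec((1, 2, 3), 9)

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError):
            MotifSpec((1, 2, 3, 4, 5, 6, 8, 7), 9)


class TestCladeReference:
    def test_six_cpa1_nine_cpa2(self, reference):
        assert len(reference.by_family("CPA1")) == 6
        assert len(reference.by_family("CPA2")) == 9
        assert len(reference) == 15

    def test_every_record_has_eight_states(self, reference):
        for rec in reference.records:
            assert len(rec.consensus) == 8
            assert rec.provenance in ("text-derived", "figure-derived")

    def test_expected_clade_names(self, reference):
        names = {r.name for r in reference.records}
        assert {"NhaA", "NapA-I", "NapA-II", "GerN", "CHX-like", "Kef-like",
                "KhaB", "animal-NHA-like", "uncharacterized-prokaryotic",
                "NhaP-I/NHE", "NHA", "NhaP-II K+-specific", "NhaP-III",
                "archaeal-NhaP-II Na+-specific",
                "bacterial-NhaP-II Na+-specific"} == names

    def test_electrogenic_rule_over_reference(self, reference):
        electrogenic = []
        for rec in reference.by_family("CPA2"):
            m = MotifAssignment(rec.consensus, aux=rec.aux)
            family, _ = classify_family(m)
            electro, _ = classify_electrogenicity(m, family)
            if electro == "electrogenic":
                electrogenic.append(rec.name)
        assert set(electrogenic) >= {"NhaA", "NapA-I", "NapA-II", "GerN"}


class TestFamilyRule:
    def test_e5_r8_is_cpa1(self):
        assert classify_family(motif("STDAENDR"))[0] == "CPA1"

    def test_ecnhaa_states_are_cpa2(self):
        assert classify_family(motif("ATDILDDK"))[0] == "CPA2"

    def test_half_signature_ambiguous_with_flag(self):
        family, flags = classify_family(motif("ATDIEDDK"))  # E5 but K8
        assert family == "ambiguous" and MIXED_SIGNATURE in flags

    def test_gapped_core_position_ambiguous(self):
        family, flags = classify_family(motif("ATDI-DDK"))
        assert family == "ambiguous" and GAPPED_MOTIF in flags


class TestElectrogenicityRule:
    def test_ecnhaa_electrogenic(self):
        assert classify_electrogenicity(motif("ATDILDDK"), "CPA2")[0] == "electrogenic"

    def test_d163n_mutant_electroneutral(self):
        assert classify_electrogenicity(motif("ATDILNDK"), "CPA2")[0] == "electroneutral"

    def test_atkea2_like_q6_electroneutral(self):
        assert classify_electrogenicity(motif("LSSTAQDK"), "CPA2")[0] == "electroneutral"

    def test_hsnha2_like_flagged_electroneutral(self):
        m = motif("ATDILDDR", aux="E")
        family, _ = classify_family(m)
        electro, flags = classify_electrogenicity(m, family)
        assert electro == "electroneutral" and NHA_LIKE_E_TM3 in flags

    def test_cpa1_always_electroneutral(self):
        assert classify_electrogenicity(motif("STDAEDDR"), "CPA1")[0] == "electroneutral"

    def test_nonacidic_position7_flagged(self):
        _, flags = classify_electrogenicity(motif("ATDILDNK"), "CPA2")
        assert POS7_NOT_ACIDIC in flags

    def test_gapped_inputs_unknown(self):
        assert classify_electrogenicity(motif("ATDIL-DK"), "CPA2")[0] == "unknown"


class TestSelectivityRule:
    @pytest.mark.parametrize("states,expected", [
        ("STDAENDR", "K"),    # serine at position 1
        ("LSSTAQDK", "K"),    # threonine at position 4
        ("ATDILDDK", "Na"),   # nonpolar 1 and 4
        ("PTDPENDR", "Na"),   # nonpolar 1 and 4
        ("NTDQENDR", "unknown"),
    ])
    def test_worked_examples(self, states, expected):
        assert classify_selectivity(motif(states))[0] == expected

    def test_both_gapped_unknown(self):
        assert classify_selectivity(motif("-TD-ENDR"))[0] == "unknown"


class TestRuleTotality:
    def test_exhaustive_class_representatives(self):
        """The cascade never raises, and CPA1 always implies electroneutral."""
        reps = {
            1: ["S", "A", "N", "-"], 4: ["T", "I", "Q", "-"],
            5: ["E", "L", "-"], 6: ["D", "N", "-"], 7: ["D", "N", "-"],
            8: ["R", "K", "H", "-"],
        }
        aux_states = ["E", "P"]
        count = 0
        for s1, s4, s5, s6, s7, s8, aux in itertools.product(
                reps[1], reps[4], reps[5], reps[6], reps[7], reps[8], aux_states):
            m = MotifAssignment((s1, "T", "D", s4, s5, s6, s7, s8), aux=aux)
            family, _ = classify_family(m)
            electro, _ = classify_electrogenicity(m, family)
            select, _ = classify_selectivity(m, family)
            assert family in ("CPA1", "CPA2", "ambiguous")
            assert electro in ("electrogenic", "electroneutral", "unknown")
            assert select in ("Na", "K", "unknown")
            if family == "CPA1":
                assert electro == "electroneutral"
            count += 1
        assert count == 4 * 4 * 3 * 3 * 3 * 4 * 2


class TestCladeAssignment:
    def test_reference_consensus_self_assigns(self, reference):
        for rec in reference.records:
            m = MotifAssignment(rec.consensus, aux=rec.aux)
            clade, margin, flags = assign_clade(m, reference)
            assert clade == rec.name, rec.name
            assert margin > 0

    def test_equidistant_tie_flagged_lexicographic(self):
        ref = CladeReference((
            _rec("beta", "ATDILDDK"), _rec("alpha", "ATDILDDR"),
        ))
        m = MotifAssignment(tuple("ATDILDDH"))
        clade, margin, flags = assign_clade(m, ref)
        assert clade == "alpha" and margin == 0 and AMBIGUOUS_CLADE in flags

    def test_unknown_consensus_state_matches_anything(self):
        ref = CladeReference((_rec("only", "XTDILDDK"),))
        m = MotifAssignment(tuple("WTDILDDK"))
        clade, _, _ = assign_clade(m, ref)
        assert clade == "only"


def _rec(name, states, family="CPA2", aux="-"):
    from cpakit.classifier import CladeRecord
    return CladeRecord(name, family, tuple(states), aux, "unknown", "unknown",
                       "figure-derived", ())


@pytest.fixture(scope="module")
def toy():
    # 11-column EcNhaA-like profile; motif at columns 1,2,3,4,6,7,8,9; aux 5
    seed = ["ATDIPLDDKWK"] * 6
    profile = build_profile(seed)
    spec = MotifSpec((1, 2, 3, 4, 6, 7, 8, 9), 5)
    return profile, spec


class TestExtractionAndClassify:

    def test_self_alignment_recovers_motif_and_positions(self, toy):
        profile, spec = toy
        query = "ATDIPLDDKWK"
        amap, _ = viterbi_align(profile, query)
        m = extract_motif(amap, query, spec)
        assert m.as_string == "ATDILDDK"
        assert m.aux == "P"
        assert m.query_positions == (1, 2, 3, 4, 6, 7, 8, 9)

    def test_deletion_at_position8_gap_and_flag(self, toy):
        profile, spec = toy
        query = "ATDIPLDDWK"  # K (column 9) deleted
        amap, _ = viterbi_align(profile, query)
        m = extract_motif(amap, query, spec)
        if m.state(8) == "-":
            family, flags = classify_family(m)
            assert family == "ambiguous" and GAPPED_MOTIF in flags

    def test_spec_column_outside_profile_rejected(self, toy):
        profile, _ = toy
        bad_spec = MotifSpec((1, 2, 3, 4, 6, 7, 8, 40), 5)
        query = "ATDIPLDDKWK"
        amap, _ = viterbi_align(profile, query)
        with pytest.raises(ValueError, match="outside profile"):
            extract_motif(amap, query, bad_spec)

    def test_classify_composition(self, toy, reference):
        profile, spec = toy
        result = classify("q1", "ATDIPLDDKWK", profile, spec, reference)
        assert (result.family, result.electrogenicity, result.selectivity) == \
               ("CPA2", "electrogenic", "Na")
        assert result.clade == "NhaA"

    def test_non_homologous_query_coverage_fail(self, toy, reference):
        profile, spec = toy
        result = classify("junk", "G", profile, spec, reference)
        assert result.family == "ambiguous"
        assert COVERAGE_FAIL in result.flags


class TestWorkedExampleSuite:
    """The published example transporters, end to end through the rules."""

    @pytest.mark.parametrize("name,states,aux,expected", [
        ("EcNhaA", "ATDILDDK", "P", ("CPA2", "electrogenic", "Na")),
        ("NhaP-II-K-like", "STDAENDR", "-", ("CPA1", "electroneutral", "K")),
        ("Kef-like", "LSSTAQDK", "-", ("CPA2", "electroneutral", "K")),
        ("NhaP-I/NHE-like", "PTDPENDR", "-", ("CPA1", "electroneutral", "Na")),
    ])
    def test_phenotype_triples(self, name, states, aux, expected, reference):
        result = classify_assignment(name, motif(states, aux), reference)
        assert (result.family, result.electrogenicity, result.selectivity) == expected

    def test_triple_mutant_conversion(self):
        wild_type = classify_assignment("WT", motif("ATDILDDK", "P"))
        mutant = classify_assignment("P108E_A160S_D163N", motif("ATDILNDK", "E"))
        assert wild_type.electrogenicity == "electrogenic"
        assert mutant.electrogenicity == "electroneutral"
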