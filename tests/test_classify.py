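import numpy as np
import pytest

from pksnrps import constants as C
from pksnrps._seqgen import mutate, random_protein
from pksnrps.bgc import CategoryHit, MeProfile
from pksnrps.classify import (DaaseAssignment, classify_daase,
                              level1_classify, level2_classify,
                              load_decision_table, predict_scaffold_parts,
                              reference_id_for_clade)
from pksnrps.errors import ValidationError
from pksnrps.io import ProteinRecord
from pksnrps.phylo import CladePlacement


def profile_with(present, bgc_id="bgc1"):
    cats = {c: CategoryHit(present=True, best_identity=95.0,
                           best_gene=f"g_{c}", best_query=f"q_{c}")
            for c in present}
    return MeProfile(bgc_id=bgc_id, categories=cats)


def daase(subclade):
    return [DaaseAssignment(gene_id="d1",
                            major_type=C.daase_type(subclade),
                            subclade=subclade,
                            sam_motif_present=subclade in ("Iα", "Iβ"),
                            nearest_reference="ref", best_identity=90.0)]


def placement(nearest_np="", distances=None):
    return CladePlacement(query_id="q", major_clade="Ia",
                          nearest_reference="REF", nearest_np_clade=nearest_np,
                          reference_distances=distances or {})


class TestDecisionTable:
    def test_cardinalities(self):
        table = load_decision_table()
        assert len(table.rules) == 18
        assert len(table.predicted_labels) == 11
        assert len(table.rules) + len(table.predicted_labels) == 29

    def test_all_known_clades_covered(self):
        table = load_decision_table()
        assert set(table.known_labels) == set(C.KNOWN_CLADES)
        assert set(table.predicted_labels) == set(C.PREDICTED_CLADES)

    def test_predicted_labels_carry_no_rule(self):
        table = load_decision_table()
        assert table.rule_for("Ia-δ") is None
        assert table.rule_for("Ia-D-1") is not None

    def test_undefined_category_rejected(self, tmp_path):
        bad = tmp_path / "table.tsv"
        text = ("np_clade\tlevel1_clade\tstatus\tkn_required\tter_required\t"
                "required_mes\tforbidden_mes\tscaffold\trepresentative_np\n"
                "Z-1\tIa\tknown\tabsent\tabsent\tP450-X\t\ttetramic_acid\tz\n")
        bad.write_text(text)
        with pytest.raises(ValidationError, match="P450-X"):
            load_decision_table(bad)

    def test_duplicate_label_rejected(self, tmp_path):
        bad = tmp_path / "table.tsv"
        row = ("Ia-A\tIa\tknown\tabsent\tabsent\tFMO\t\ttetramic_acid\tx\n")
        text = ("np_clade\tlevel1_clade\tstatus\tkn_required\tter_required\t"
                "required_mes\tforbidden_mes\tscaffold\trepresentative_np\n"
                + row + row)
        bad.write_text(text)
        with pytest.raises(ValidationError, match="duplicate"):
            load_decision_table(bad)


class TestClassifyDaase:
    def test_exact_type1_reference_typed_i_alpha(self, bundle):
        ref = bundle.daase_reference("LepI")
        out = classify_daase([("g1", ref.record)], bundle.daase_references,
                             bundle.motif_model)
        (a,) = out
        assert (a.major_type, a.subclade) == ("typeI", "Iα")
        assert a.sam_motif_present

    def test_exact_type2_macrocycle_reference(self, bundle):
        ref = bundle.daase_reference("CcsF")
        (a,) = classify_daase([("g1", ref.record)], bundle.daase_references,
                              bundle.motif_model)
        assert (a.major_type, a.subclade) == ("typeII", "IIβ-1")
        assert not a.sam_motif_present

    def test_mutated_references_keep_their_subclade(self, bundle):
        rng = np.random.default_rng(4)
        for name, expect in [("IccD", "Iβ"), ("Fsa2", "IIα"),
                             ("PoxQ", "IIβ-2"), ("MycB", "IIβ-2")]:
            ref = bundle.daase_reference(name)
            rec = ProteinRecord(id="m",
                                sequence=mutate(ref.record.sequence, 0.05,
                                                rng))
            (a,) = classify_daase([("g1", rec)], bundle.daase_references,
                                  bundle.motif_model)
            assert a.subclade == expect, name

    def test_random_sequence_unknown(self, bundle):
        rng = np.random.default_rng(5)
        rec = ProteinRecord(id="r", sequence=random_protein(rng, 400))
        (a,) = classify_daase([("g1", rec)], bundle.daase_references,
                              bundle.motif_model)
        assert (a.major_type, a.subclade) == ("unknown", "unknown")

    def test_motif_vs_reference_conflict_flagged(self, bundle):
        # a type-II backbone with the SAM motif spliced in: motif says
        # type I, homology says type II
        from pksnrps.bundle import SAM_MOTIF
        ref = bundle.daase_reference("Fsa2")
        seq = ref.record.sequence
        chimera = seq[:40] + SAM_MOTIF + seq[40 + len(SAM_MOTIF):]
        (a,) = classify_daase([("g1", ProteinRecord(id="x", sequence=chimera))],
                              bundle.daase_references, bundle.motif_model)
        assert a.major_type == "typeI"
        assert a.subclade == "unknown"
        assert a.conflict

    def test_empty_reference_set_rejected(self, bundle):
        with pytest.raises(ValidationError):
            classify_daase([], [], bundle.motif_model)


class TestLevel1:
    def test_core_i_clade_consistent_without_pkn(self):
        res = level1_classify(profile_with(set()), "Ia")
        assert (res.clade, res.consistent) == ("Ia", True)

    def test_clade_ii_without_pkn_warned_not_overridden(self):
        res = level1_classify(profile_with(set()), "II")
        assert res.clade == "II"
        assert not res.consistent

    def test_clade_iii_accepts_both_states(self):
        assert level1_classify(profile_with({"pKN"}), "III").consistent
        assert level1_classify(profile_with(set()), "III").consistent

    def test_unplaced_with_pkn_is_tentative_ii(self):
        res = level1_classify(profile_with({"pKN"}), "unplaced")
        assert (res.clade, res.tentative) == ("II", True)

    def test_unplaced_without_pkn_undetermined(self):
        res = level1_classify(profile_with(set()), "unplaced")
        assert res.clade == "undetermined"


@pytest.fixture(scope="module")
def table():
    return load_decision_table()


class TestLevel2:
    def test_tenellin_rule(self, table):
        profile = profile_with({"tER", "expandase_P450"})
        res = level2_classify(profile, [], level1_classify(profile, "Ia"),
                              table, placement())
        assert (res.np_clade, res.status) == ("Ia-D-1", "known")
        assert res.scaffold == "2-pyridone"

    def test_leporin_outranks_tenellin_by_specificity(self, table):
        profile = profile_with({"tER", "expandase_P450", "DAase"})
        res = level2_classify(profile, daase("Iα"),
                              level1_classify(profile, "Ia"), table,
                              placement())
        assert (res.np_clade, res.status) == ("Ia-D-2", "known")

    def test_sch210972_rule(self, table):
        profile = profile_with({"aldolase", "transaminase"})
        res = level2_classify(profile, [], level1_classify(profile, "Ib"),
                              table, placement())
        assert (res.np_clade, res.status) == ("Ib-B", "known")

    def test_oxaleimide_rule(self, table):
        profile = profile_with({"pKN", "tER", "DAase", "transaminase"})
        res = level2_classify(profile, daase("IIβ-2"),
                              level1_classify(profile, "III"), table,
                              placement())
        assert (res.np_clade, res.status) == ("III-C", "known")
        assert res.ring == "decalin"

    def test_chaetoglobosin_cytochalasin_tie_resolved_by_tree(self, table):
        profile = profile_with({"pKN", "tER", "DAase"})
        near_a = placement(distances={
            reference_id_for_clade("III-A"): 0.1,
            reference_id_for_clade("III-D"): 0.4})
        res = level2_classify(profile, daase("IIβ-1"),
                              level1_classify(profile, "III"), table, near_a)
        assert res.np_clade == "III-A"
        near_d = placement(distances={
            reference_id_for_clade("III-A"): 0.4,
            reference_id_for_clade("III-D"): 0.1})
        res = level2_classify(profile, daase("IIβ-1"),
                              level1_classify(profile, "III"), table, near_d)
        assert res.np_clade == "III-D"

    def test_ibd_requires_tree_neighborhood(self, table):
        profile = profile_with(set())
        lvl = level1_classify(profile, "Ib")
        sink = level2_classify(profile, [], lvl, table, placement())
        assert sink.status == "unclassified"
        ok = level2_classify(profile, [], lvl, table,
                             placement(nearest_np="Ib-D"))
        assert (ok.np_clade, ok.status) == ("Ib-D", "known")

    def test_predicted_neighborhood_fallback(self, table):
        profile = profile_with({"tER"})
        res = level2_classify(profile, [], level1_classify(profile, "Ia"),
                              table, placement(nearest_np="Ia-δ"))
        assert (res.np_clade, res.status) == ("Ia-δ", "predicted")

    def test_no_rule_no_neighborhood_unclassified(self, table):
        profile = profile_with({"glycosyltransferase"})
        res = level2_classify(profile, [], level1_classify(profile, "Ia"),
                              table, placement())
        assert (res.np_clade, res.status) == ("unclassified", "unclassified")

    def test_removing_an_me_never_increases_specificity(self, table):
        # dropping the DAase from a leporin profile falls back to the less
        # specific tenellin rule, never a more specific one
        full = profile_with({"tER", "expandase_P450", "DAase"})
        res_full = level2_classify(full, daase("Iα"),
                                   level1_classify(full, "Ia"), table,
                                   placement())
        reduced = profile_with({"tER", "expandase_P450"})
        res_red = level2_classify(reduced, [],
                                  level1_classify(reduced, "Ia"), table,
                                  placement())
        rule_full = table.rule_for(res_full.np_clade)
        rule_red = table.rule_for(res_red.np_clade)
        assert rule_red.specificity <= rule_full.specificity

    def test_exactly_one_status(self, table):
        for cats, clade in [({"tER", "expandase_P450"}, "Ia"),
                            ({"pKN", "MT", "P450_IIA"}, "II"),
                            ({"glycosyltransferase"}, "Ib")]:
            profile = profile_with(cats)
            res = level2_classify(profile, [],
                                  level1_classify(profile, clade), table,
                                  placement())
            assert res.status in ("known", "predicted", "unclassified")
            assert res.evidence


class TestScaffold:
    def test_expandase_gives_pyridone(self):
        sc, ring = predict_scaffold_parts(
            "Ia-D-1", None, profile_with({"expandase_P450", "tER"}), set())
        assert (sc, ring) == ("2-pyridone", "none")

    def test_decalin_tetramate(self):
        sc, ring = predict_scaffold_parts(
            "Ib-C", None, profile_with({"tER"}), {"IIα"})
        assert (sc, ring) == ("tetramic_acid", "decalin")

    def test_pyrrolinone_core(self):
        sc, ring = predict_scaffold_parts(
            "II-A", None, profile_with({"pKN", "MT", "P450_IIA"}), set())
        assert (sc, ring) == ("pyrrolinone", "none")

    def test_tetronic_acid_override(self):
        sc, _ = predict_scaffold_parts(
            "III-B", None, profile_with({"tER", "P450_III", "alphaKG"}),
            set())
        assert sc == "tetronic_acid"

    def test_polycycle_annotations(self):
        _, ring1 = predict_scaffold_parts(
            "Ia-D-2", None, profile_with({"expandase_P450"}), {"Iα"})
        assert ring1 == "pyridone_polycycle"
        _, ring2 = predict_scaffold_parts(
            "III-D", None, profile_with({"pKN"}), {"IIβ-1"})
        assert ring2 == "macrocycle"

    def test_pure_function_of_inputs(self):
        args = ("II-A", None, profile_with({"pKN"}), frozenset())
        assert predict_scaffold_parts(*args) == predict_scaffold_parts(*args)
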