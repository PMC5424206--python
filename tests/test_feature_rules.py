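"""Reference-anchored feature rules: indels, loop, residue classes, tRNA."""

import numpy as np
import pytest

from sepmine.feature_rules import (
    DomainModel,
    RuleSet,
    classify_sepcysE_homolog,
    classify_trna,
    evaluate_features,
    map_reference,
)
from sepmine.io_formats import SeqRecord
from sepmine.msa_phylo import MSA, build_msa
from sepmine.synthetic_data.families import (
    SEPCYSS_INDEL_POINT,
    SEPCYSS_LOOP_SPAN,
    SEPCYSS_PERSULFIDE_SITES,
    SEPRS_CTERM_SPAN,
    SEPRS_RES444,
    Indel,
    MemberPlan,
    default_family_configs,
    evolve_sequence,
    make_family_models,
    random_protein,
    sample_member,
)


@pytest.fixture(scope="module")
def models():
    return make_family_models(default_family_configs(), np.random.default_rng(21))


class TestMapReference:
    def test_gapless_reference_identity_map(self):
        msa = MSA(ids=["r", "m"], rows=["ACDE", "ACDF"])
        refmap = map_reference(msa, "r")
        assert refmap.pos_to_col == {1: 0, 2: 1, 3: 2, 4: 3}

    def test_gapped_reference_skips_columns(self):
        msa = MSA(ids=["r", "m"], rows=["A-CD", "AACD"])
        refmap = map_reference(msa, "r")
        assert refmap.pos_to_col == {1: 0, 2: 2, 3: 3}

    def test_absent_reference_rejected(self):
        msa = MSA(ids=["a", "b"], rows=["AC", "AC"])
        with pytest.raises(KeyError):
            map_reference(msa, "nope")


def _sepcyss_pair(models, plan):
    """Reference plus one planned variant, aligned."""
    ref = SeqRecord("ref", models["SepCysS"].reference)
    rng = np.random.default_rng(33)
    var = SeqRecord(
        "var", sample_member(models["SepCysS"], "cladeI", rng, plan=plan)
    )
    msa = build_msa([ref, var])
    return map_reference(msa, "ref")


class TestEvaluateFeatures:
    def test_reference_is_fixed_point(self, models):
        refmap = _sepcyss_pair(models, MemberPlan())
        report = evaluate_features(refmap, RuleSet())["ref"]
        assert report.loop_present
        assert report.indel_234_235 == 0
        assert report.persulfide_cys_count == 3
        assert report.plp_conserved

    def test_eight_residue_deletion_reads_minus_eight(self, models):
        """An 8-residue deletion adjacent to the 234/235 junction."""
        plan = MemberPlan(indels=(Indel("del", SEPCYSS_INDEL_POINT + 1, 8),))
        refmap = _sepcyss_pair(models, plan)
        report = evaluate_features(refmap, RuleSet())["var"]
        assert report.indel_234_235 == -8

    def test_eight_residue_insertion_reads_plus_eight(self, models):
        plan = MemberPlan(indels=(Indel("ins", SEPCYSS_INDEL_POINT, 8),))
        refmap = _sepcyss_pair(models, plan)
        report = evaluate_features(refmap, RuleSet())["var"]
        assert report.indel_234_235 == 8

    def test_loop_deletion_reads_absent(self, models):
        plan = MemberPlan(indels=(Indel("del", SEPCYSS_LOOP_SPAN[0], 4),))
        refmap = _sepcyss_pair(models, plan)
        report = evaluate_features(refmap, RuleSet())["var"]
        assert not report.loop_present

    def test_persulfide_zero_vs_three(self, models):
        plan = MemberPlan(
            features={p: "S" for p in SEPCYSS_PERSULFIDE_SITES}
        )
        refmap = _sepcyss_pair(models, plan)
        reports = evaluate_features(refmap, RuleSet())
        assert reports["var"].persulfide_cys_count == 0
        assert reports["ref"].persulfide_cys_count == 3

    def test_asp_at_444_is_hydrophilic(self, models):
        ref = SeqRecord("ref", models["SepRS"].reference)
        rng = np.random.default_rng(34)
        var = SeqRecord(
            "var",
            sample_member(
                models["SepRS"], "cladeIII", rng,
                plan=MemberPlan(features={SEPRS_RES444: "D"}),
            ),
        )
        msa = build_msa([ref, var])
        reports = evaluate_features(map_reference(msa, "ref"), RuleSet())
        assert reports["var"].res444_class == "hydrophilic"
        assert reports["ref"].res444_class == "hydrophobic"

    def test_indel_invariant_to_all_gap_columns(self, models):
        plan = MemberPlan(indels=(Indel("del", SEPCYSS_INDEL_POINT + 1, 8),))
        refmap = _sepcyss_pair(models, plan)
        before = evaluate_features(refmap, RuleSet())["var"].indel_234_235
        # splice an all-gap column pair far from the junction
        rows = [r[:30] + "--" + r[30:] for r in refmap.msa.rows]
        padded = MSA(ids=list(refmap.msa.ids), rows=rows)
        after = evaluate_features(
            map_reference(padded, "ref"), RuleSet()
        )["var"].indel_234_235
        assert before == after == -8

    def test_rule_position_outside_reference_rejected(self, models):
        refmap = _sepcyss_pair(models, MemberPlan())
        bad = RuleSet(plp_positions=(97, 175, 9999))
        with pytest.raises(ValueError, match="outside reference"):
            evaluate_features(refmap, bad)

    def test_rule_set_yaml_round_trip(self):
        rules = RuleSet()
        assert RuleSet.from_yaml(rules.to_yaml()) == rules


class TestSeprsTruncation:
    def _model(self, models):
        return DomainModel(
            reference=SeqRecord("SepRS_ref", models["SepRS"].reference),
            spans={"catalytic": (1, 390), "cterm": SEPRS_CTERM_SPAN},
        )

    def test_full_length_member(self, models):
        from sepmine.feature_rules import detect_seprs_truncation

        rng = np.random.default_rng(35)
        full = SeqRecord("p", sample_member(models["SepRS"], "cladeI", rng))
        assert detect_seprs_truncation(full, self._model(models)) == "full"

    def test_delta_c_variant(self, models):
        from sepmine.feature_rules import detect_seprs_truncation

        rng = np.random.default_rng(36)
        span_len = SEPRS_CTERM_SPAN[1] - SEPRS_CTERM_SPAN[0] + 1
        plan = MemberPlan(indels=(Indel("del", SEPRS_CTERM_SPAN[0], span_len),))
        trunc = SeqRecord(
            "p", sample_member(models["SepRS"], "cladeI", rng, plan=plan)
        )
        assert detect_seprs_truncation(trunc, self._model(models)) == "delta_C"

    def test_unrelated_protein_no_call(self, models):
        from sepmine.feature_rules import detect_seprs_truncation

        rng = np.random.default_rng(37)
        noise = SeqRecord("p", random_protein(300, rng))
        with pytest.warns(UserWarning, match="no confident"):
            assert detect_seprs_truncation(noise, self._model(models)) == "none"


class TestSepcysEClassification:
    @pytest.fixture()
    def refs(self, models):
        ref_e = models["SepCysE"].reference
        n_dom = SeqRecord("ndom", ref_e[:110])
        core = SeqRecord("core", models["SepCysS"].reference)
        return n_dom, core

    def test_full_length(self, models, refs):
        n_dom, core = refs
        rng = np.random.default_rng(38)
        full = SeqRecord("p", sample_member(models["SepCysE"], "main", rng))
        assert classify_sepcysE_homolog(full, n_dom, core) == "full"

    def test_fused_n_terminal(self, models, refs):
        n_dom, core = refs
        rng = np.random.default_rng(39)
        fused = SeqRecord(
            "p",
            sample_member(models["SepCysE"], "main", rng)[:105]
            + sample_member(models["SepCysS"], "cladeVI", rng),
        )
        assert classify_sepcysE_homolog(fused, n_dom, core) == "fused_N"

    def test_split_gene_preceding_sepcyss(self, models, refs):
        n_dom, core = refs
        rng = np.random.default_rng(40)
        frag = SeqRecord(
            "p", sample_member(models["SepCysE"], "main", rng)[:105]
        )
        assert (
            classify_sepcysE_homolog(frag, n_dom, core, precedes_sepcyss=True)
            == "split_n"
        )
        # the same fragment not adjacent to a SepCysS gene stays uncalled
        assert classify_sepcysE_homolog(frag, n_dom, core) == "none"

    def test_plain_sepcyss_is_none(self, models, refs):
        n_dom, core = refs
        rng = np.random.default_rng(41)
        plain = SeqRecord("p", sample_member(models["SepCysS"], "cladeI", rng))
        assert classify_sepcysE_homolog(plain, n_dom, core) == "none"


class TestClassifyTrna:
    def test_a37(self):
        seq = "G" * 33 + "GCA" + "A" + "G" * 35
        call = classify_trna(SeqRecord("t", seq), {"anticodon_start": "34"})
        assert call.anticodon == "GCA" and call.n37 == "A"
        assert call.isotype == "Cys"

    def test_g37_variant(self):
        seq = "A" * 33 + "GCA" + "G" + "A" * 35
        call = classify_trna(SeqRecord("t", seq), {"anticodon_start": "34"})
        assert call.n37 == "G"

    def test_missing_annotation_no_call(self):
        with pytest.warns(UserWarning, match="no anticodon"):
            assert classify_trna(SeqRecord("t", "ACGT" * 18), {}) is None

    def test_anticodon_at_sequence_end_no_call(self):
        seq = "A" * 69 + "GCA"  # no base left for N37
        with pytest.warns(UserWarning, match="N37"):
            assert (
                classify_trna(SeqRecord("t", seq), {"anticodon_start": "70"})
                is None
            )

    def test_pipeline_recovers_all_planted_n37(
        self, default_metagenome, pipeline_result
    ):
        mg, res = default_metagenome, pipeline_result
        assert len(res.trna_calls) == len(mg.truth.trnas)
        for call in res.trna_calls:
            truth = mg.truth.trnas[call.trna_id]
            assert (call.anticodon, call.n37, call.isotype) == (
                truth.anticodon, truth.n37, truth.isotype,
            )


def test_metagenome_feature_truth_recovered(default_metagenome):
    """Every planted SepCysS/SepRS feature flag is reproduced exactly from
    a fresh progressive alignment against the family reference."""
    mg = default_metagenome
    prot = {p.id: p for p in mg.proteins}

    cyss_ids = sorted(
        g.protein_id for g in mg.truth.genes.values()
        if g.family in ("SepCysS", "SepCysSN")
    )
    msa = build_msa([mg.references["SepCysS"]] + [prot[i] for i in cyss_ids])
    reports = evaluate_features(map_reference(msa, "SepCysS_ref"), RuleSet())
    for pid in cyss_ids:
        truth = mg.truth.features[pid]
        got = reports[pid]
        assert got.loop_present == truth.loop_present, pid
        assert got.indel_234_235 == truth.indel_234_235, pid
        assert got.persulfide_cys_count == truth.persulfide_count, pid
        assert got.plp_conserved == truth.plp_conserved, pid

    seprs_ids = sorted(
        g.protein_id for g in mg.truth.genes.values() if g.family == "SepRS"
    )
    msa2 = build_msa([mg.references["SepRS"]] + [prot[i] for i in seprs_ids])
    reports2 = evaluate_features(map_reference(msa2, "SepRS_ref"), RuleSet())
    for pid in seprs_ids:
        truth = mg.truth.features[pid]
        assert reports2[pid].res444_class == truth.res444_class, pid
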