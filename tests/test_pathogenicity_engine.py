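"""Rule engine: consensus, evidence codes, branch logic, oracle equivalence."""

import itertools

import pytest

from cardiotriage.pathogenicity_engine import (
    POSITIVE_BRANCHES,
    RuleBranch,
    TTNMapMissingError,
    classify_cohort,
    classify_variant,
    evidence_codes,
    predictor_consensus,
)
from cardiotriage.variant_model import (
    AnnotatedVariant,
    ClinVarClass,
    ConsequenceClass,
    ConservationProfile,
    DatabaseEvidence,
    MutationTasterCall,
    PolyPhenCall,
    PredictorProfile,
    ProveanCall,
    SiftCall,
    classify_consequence,
    parse_coding_change,
    parse_protein_change,
)

DAMAGING = PredictorProfile(
    sift=SiftCall.DAMAGING, provean=ProveanCall.DELETERIOUS,
    polyphen2=PolyPhenCall.PROBABLY_DAMAGING,
    mutation_taster=MutationTasterCall.DISEASE_CAUSING,
)


def make_variant(protein="A100V", cdna="c.300G>A", gene="MYH7",
                 transcript="NM_000257", predictors=DAMAGING,
                 conservation=ConservationProfile(),
                 evidence=DatabaseEvidence()):
    pc = parse_protein_change(protein) if protein else None
    cc = parse_coding_change(cdna)
    return AnnotatedVariant(
        gene=gene, transcript=transcript, chrom="14", genomic_pos=1000,
        coding=cc, protein=pc, consequence=classify_consequence(pc, cc),
        depth=50, predictors=predictors, conservation=conservation,
        evidence=evidence,
    )


@pytest.mark.parametrize(
    "profile, expected",
    [
        (DAMAGING, True),
        (PredictorProfile(SiftCall.DAMAGING, ProveanCall.DELETERIOUS,
                          PolyPhenCall.POSSIBLY_DAMAGING,
                          MutationTasterCall.DISEASE_CAUSING), True),
        (PredictorProfile(SiftCall.TOLERATED, ProveanCall.DELETERIOUS,
                          PolyPhenCall.PROBABLY_DAMAGING,
                          MutationTasterCall.DISEASE_CAUSING), False),
        (PredictorProfile(SiftCall.DAMAGING, ProveanCall.DELETERIOUS,
                          PolyPhenCall.ABSENT,
                          MutationTasterCall.DISEASE_CAUSING), False),
        (PredictorProfile(), False),
    ],
)
def test_predictor_consensus(profile, expected):
    assert predictor_consensus(profile) is expected


def test_evidence_codes_printed_rows(paper):
    """Code sets recomputed from annotations match the printed strings."""
    lamp2 = next(v for v in paper.variants if v.gene == "LAMP2")
    assert evidence_codes(lamp2) == {"PP2", "MT", "PC", "PP", "CV", "HG"}
    ryr2 = next(v for v in paper.variants if v.gene == "RYR2")
    assert evidence_codes(ryr2) == {"GS", "SI", "PR", "PP2", "MT", "PC", "PP"}


def test_evidence_codes_all_neutral_empty():
    v = make_variant(predictors=PredictorProfile(
        SiftCall.TOLERATED, ProveanCall.NEUTRAL, PolyPhenCall.BENIGN,
        MutationTasterCall.POLYMORPHISM))
    assert evidence_codes(v) == frozenset()


def test_grantham_code_is_missense_only():
    v = make_variant(protein="Q100X",
                     conservation=ConservationProfile(grantham=None))
    assert "GS" not in evidence_codes(v)


class TestClassifyVariant:
    def test_radical_nonsense_mt(self, ttn_map):
        call = classify_variant(make_variant(protein="R3435X", gene="AKAP9"),
                                ttn_map)
        assert call.potentially_pathogenic and call.branch is RuleBranch.RADICAL_MT

    def test_inframe_dup_rescued_by_published_data(self, ttn_map):
        v = make_variant(
            protein="L140_A146dup", cdna="c.667_687dup", gene="LMNA",
            predictors=PredictorProfile(
                mutation_taster=MutationTasterCall.POLYMORPHISM),
            evidence=DatabaseEvidence(published_support=True),
        )
        call = classify_variant(v, ttn_map)
        assert call.potentially_pathogenic
        assert call.branch is RuleBranch.DATABASE_OVERRIDE

    def test_ttn_missense_exempt_despite_consensus(self, ttn_map):
        v = make_variant(protein="A5000V", gene="TTN", transcript="NM_003319",
                         predictors=DAMAGING)
        call = classify_variant(v, ttn_map)
        assert not call.potentially_pathogenic
        assert call.branch is RuleBranch.TTN_MISSENSE_EXEMPT

    def test_clinvar_vus_demotes_despite_consensus(self, ttn_map):
        v = make_variant(gene="MYL2", protein="E134A", predictors=DAMAGING,
                         evidence=DatabaseEvidence(clinvar_class=ClinVarClass.VUS))
        call = classify_variant(v, ttn_map)
        assert not call.potentially_pathogenic
        assert call.branch is RuleBranch.DEMOTED_CLINVAR

    def test_demotion_dominance_benign_no_rescue(self, ttn_map):
        v = make_variant(predictors=DAMAGING,
                         evidence=DatabaseEvidence(clinvar_class=ClinVarClass.BENIGN))
        assert not classify_variant(v, ttn_map).potentially_pathogenic

    def test_demotion_overridden_by_hgmd(self, ttn_map):
        v = make_variant(predictors=DAMAGING,
                         evidence=DatabaseEvidence(
                             clinvar_class=ClinVarClass.VUS,
                             hgmd_same_phenotype=True))
        call = classify_variant(v, ttn_map)
        assert call.potentially_pathogenic
        assert call.branch is RuleBranch.DATABASE_OVERRIDE

    def test_radical_without_mt_verdict_negative_unless_override(self, ttn_map):
        v = make_variant(protein="Q100X", predictors=PredictorProfile())
        assert not classify_variant(v, ttn_map).potentially_pathogenic
        v2 = make_variant(protein="Q100X", predictors=PredictorProfile(),
                          evidence=DatabaseEvidence(
                              clinvar_class=ClinVarClass.PATHOGENIC,
                              clinvar_same_phenotype=True))
        assert classify_variant(v2, ttn_map).branch is RuleBranch.DATABASE_OVERRIDE

    def test_ttn_truncating_without_map_raises(self):
        v = make_variant(protein="V16477fs", gene="TTN",
                         transcript="NM_003319")
        with pytest.raises(TTNMapMissingError):
            classify_variant(v, None)


def test_ttn_missense_never_positive_any_profile(ttn_map):
    """The TTN missense exemption holds for every predictor/evidence combo."""
    sift_opts = list(SiftCall)
    ev_opts = [
        DatabaseEvidence(),
        DatabaseEvidence(clinvar_class=ClinVarClass.PATHOGENIC,
                         clinvar_same_phenotype=True),
        DatabaseEvidence(clinvar_class=ClinVarClass.VUS,
                         hgmd_same_phenotype=True),
        DatabaseEvidence(published_support=True),
    ]
    for sift, ev in itertools.product(sift_opts, ev_opts):
        v = make_variant(
            gene="TTN", transcript="NM_003319", protein="A5000V",
            predictors=PredictorProfile(
                sift=sift, provean=ProveanCall.DELETERIOUS,
                polyphen2=PolyPhenCall.PROBABLY_DAMAGING,
                mutation_taster=MutationTasterCall.DISEASE_CAUSING),
            evidence=ev,
        )
        assert not classify_variant(v, ttn_map).potentially_pathogenic


# --- brute-force truth-table oracle ----------------------------------------


def flowchart_oracle(consequence, is_ttn, band_a_shared, predictors, evidence):
    """Literal decision-flowchart evaluation, independent of the engine."""
    consensus = (
        predictors.sift is SiftCall.DAMAGING
        and predictors.provean is ProveanCall.DELETERIOUS
        and predictors.polyphen2 in (PolyPhenCall.PROBABLY_DAMAGING,
                                     PolyPhenCall.POSSIBLY_DAMAGING)
        and predictors.mutation_taster is MutationTasterCall.DISEASE_CAUSING
    )
    mt = predictors.mutation_taster is MutationTasterCall.DISEASE_CAUSING
    override = (
        (evidence.clinvar_class in (ClinVarClass.PATHOGENIC,
                                    ClinVarClass.LIKELY_PATHOGENIC)
         and evidence.clinvar_same_phenotype)
        or evidence.hgmd_same_phenotype
        or evidence.published_support
    )
    if is_ttn and consequence is ConsequenceClass.MISSENSE:
        return False
    if evidence.clinvar_class in (ClinVarClass.VUS, ClinVarClass.LIKELY_BENIGN,
                                  ClinVarClass.BENIGN):
        return evidence.hgmd_same_phenotype or evidence.published_support
    if is_ttn and consequence in (ConsequenceClass.NONSENSE,
                                  ConsequenceClass.STOPLOSS,
                                  ConsequenceClass.CANONICAL_SPLICE,
                                  ConsequenceClass.FRAMESHIFT_INDEL):
        return band_a_shared
    if consequence is ConsequenceClass.MISSENSE:
        return consensus or override
    return mt or override


def _variants_for(consequence, is_ttn, band_a_shared, predictors, evidence):
    token = {
        ConsequenceClass.MISSENSE: "A{p}V",
        ConsequenceClass.NONSENSE: "A{p}X",
        ConsequenceClass.STOPLOSS: "X{p}W",
        ConsequenceClass.FRAMESHIFT_INDEL: "A{p}fs",
        ConsequenceClass.INFRAME_INDEL: "A{p}del",
    }
    pos = 16000 if band_a_shared else 2000  # A-band vs I-band residue
    if consequence is ConsequenceClass.CANONICAL_SPLICE:
        protein, cdna = None, "c.100-2A>G"
        if is_ttn:
            # splice-site TTN truncations carry no residue; band untestable,
            # handled separately below
            return None
    else:
        protein, cdna = token[consequence].format(p=pos), "c.300G>A"
    return make_variant(
        protein=protein, cdna=cdna,
        gene="TTN" if is_ttn else "MYH7",
        transcript="NM_003319" if is_ttn else "NM_000257",
        predictors=predictors, evidence=evidence,
    )


def test_engine_matches_truth_table_oracle(ttn_map):
    """Exhaustive agreement over all boolean annotation combinations."""
    sift_opts = [SiftCall.DAMAGING, SiftCall.TOLERATED]
    provean_opts = [ProveanCall.DELETERIOUS, ProveanCall.NEUTRAL]
    pp2_opts = [PolyPhenCall.PROBABLY_DAMAGING, PolyPhenCall.POSSIBLY_DAMAGING,
                PolyPhenCall.BENIGN]
    mt_opts = [MutationTasterCall.DISEASE_CAUSING,
               MutationTasterCall.POLYMORPHISM]
    clinvar_opts = list(ClinVarClass)
    checked = 0
    for consequence in (ConsequenceClass.MISSENSE, ConsequenceClass.NONSENSE,
                        ConsequenceClass.STOPLOSS,
                        ConsequenceClass.CANONICAL_SPLICE,
                        ConsequenceClass.FRAMESHIFT_INDEL,
                        ConsequenceClass.INFRAME_INDEL):
        for is_ttn in (False, True):
            if is_ttn and consequence is ConsequenceClass.INFRAME_INDEL:
                continue  # TTN in-frame indels follow the plain radical rule
            for (sift, provean, pp2, mt, cln, same, hgmd, ref,
                 band) in itertools.product(
                    sift_opts, provean_opts, pp2_opts, mt_opts, clinvar_opts,
                    (False, True), (False, True), (False, True),
                    (False, True)):
                predictors = PredictorProfile(sift, provean, pp2, mt)
                evidence = DatabaseEvidence(cln, same, hgmd, ref)
                v = _variants_for(consequence, is_ttn, band, predictors,
                                  evidence)
                if v is None:
                    continue
                call = classify_variant(v, ttn_map)
                expected = flowchart_oracle(consequence, is_ttn, band,
                                            predictors, evidence)
                assert call.potentially_pathogenic == expected, (
                    consequence, is_ttn, band, predictors, evidence)
                # exactly one branch fires, consistent with the label
                assert (call.branch in POSITIVE_BRANCHES) == expected
                checked += 1
    assert checked > 5000


def test_classify_cohort_summary(paper):
    calls, summary = classify_cohort(list(paper.variants), paper.region_map)
    assert summary.n_variants == 28
    assert summary.n_positive == sum(c.potentially_pathogenic for c in calls)
    assert sum(summary.calls_by_branch.values()) == 28
    empty_calls, empty_summary = classify_cohort([], paper.region_map)
    assert empty_calls == [] and empty_summary.n_variants == 0
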