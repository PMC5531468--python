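"""Burden, tallies, phenotype overlap and novelty detection."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiotriage.cohort_analytics import (
    burden_summary,
    gene_tally,
    novel_associations,
    phenotype_overlap,
    render_reports,
)
from cardiotriage.pathogenicity_engine import classify_cohort
from cardiotriage.variant_model import (
    AnnotatedVariant,
    AssociationCatalog,
    Observation,
    Patient,
    Phenotype,
    classify_consequence,
    parse_protein_change,
)


def obs(pid, pheno, gene, token="A100V"):
    pc = parse_protein_change(token)
    v = AnnotatedVariant(gene=gene, transcript="NM_1", chrom="1",
                         genomic_pos=100, protein=pc,
                         consequence=classify_consequence(pc, None), depth=50)
    return Observation(Patient(pid, pheno), v)


def paper_calls(paper):
    obs_calls, _ = classify_cohort(list(paper.observations), paper.region_map)
    return obs_calls


def test_burden_on_printed_tables(paper):
    """3 patients carry two potentially pathogenic variants; 12 carry none."""
    calls = paper_calls(paper)
    summary = burden_summary(list(paper.roster), list(paper.observations), calls)
    pp = summary.pp_per_patient
    assert sum(1 for n in pp.values() if n == 2) == 3
    assert sum(1 for n in pp.values() if n == 0) == 12
    assert sum(1 for n in pp.values() if n == 1) == 23
    assert {p for p, n in pp.items() if n == 2} == {"76DCM", "1173HCM", "1776HCM"}


def test_burden_single_patient():
    roster = [Patient("P1DCM", Phenotype.DCM)]
    rows = [obs("P1DCM", Phenotype.DCM, "TTN") for _ in range(5)]
    s = burden_summary(roster, rows)
    assert s.mean == 5 and s.range == (5, 5)


def test_burden_unknown_carrier_is_error(paper):
    with pytest.raises(ValueError, match="not in roster"):
        burden_summary(list(paper.roster)[:1], list(paper.observations))


def test_burden_conservation_and_zero_carriers():
    roster = [Patient("A1DCM", Phenotype.DCM), Patient("B1HCM", Phenotype.HCM),
              Patient("C1ARVC", Phenotype.ARVC)]
    rows = [obs("A1DCM", Phenotype.DCM, "TTN"), obs("A1DCM", Phenotype.DCM, "LMNA")]
    s = burden_summary(roster, rows)
    assert sum(s.per_patient.values()) == len(rows)
    assert s.per_patient["C1ARVC"] == 0
    assert s.mean == pytest.approx(2 / 3)
    assert s.per_phenotype_mean[Phenotype.ARVC] == 0.0


def test_gene_tally_printed_table(paper):
    # tally the 28 distinct printed variants (first carrier each), since the
    # per-gene counts are variant-level, not carrier-level
    seen, distinct = set(), []
    for o in paper.observations:
        if o.variant.key not in seen:
            seen.add(o.variant.key)
            distinct.append(o)
    tally = gene_tally(distinct)
    assert tally["MYBPC3"].total == 4
    assert tally["OBSCN"].total == 4
    assert sum(t.total for t in tally.values()) == len(distinct) == 28
    # descending order
    totals = [t.total for t in tally.values()]
    assert totals == sorted(totals, reverse=True)
    assert gene_tally([]) == {}


def test_phenotype_overlap_toy():
    rows = [
        obs("A1DCM", Phenotype.DCM, "G1"),
        obs("B1HCM", Phenotype.HCM, "G2"),
        obs("A1DCM", Phenotype.DCM, "G2"),
        obs("C1ARVC", Phenotype.ARVC, "G3"),
        obs("A1DCM", Phenotype.DCM, "G3"),
        obs("B1HCM", Phenotype.HCM, "G3"),
    ]
    part = phenotype_overlap(rows)
    assert part.regions[frozenset({Phenotype.DCM})] == {"G1"}
    assert part.regions[frozenset({Phenotype.DCM, Phenotype.HCM})] == {"G2"}
    assert part.regions[frozenset({Phenotype.DCM, Phenotype.HCM,
                                   Phenotype.ARVC})] == {"G3"}


@settings(derandomize=True, max_examples=80)
@given(
    st.lists(
        st.tuples(st.sampled_from(["G%d" % i for i in range(8)]),
                  st.sampled_from(list(Phenotype))),
        min_size=0, max_size=60,
    )
)
def test_phenotype_overlap_disjoint_and_covering(pairs):
    """Fuzzed partition: regions disjoint, union = genes seen, sizes agree
    with a brute-force subset computation."""
    rows = [obs(f"P{i}{ph.value}", ph, g) for i, (g, ph) in enumerate(pairs)]
    part = phenotype_overlap(rows)
    seen_genes = {r.variant.gene for r in rows}
    assert part.all_genes() == seen_genes
    assert sum(len(g) for g in part.regions.values()) == len(seen_genes)
    # brute force: compute each gene's phenotype set directly
    for gene in seen_genes:
        phenos = frozenset(r.patient.phenotype for r in rows
                           if r.variant.gene == gene)
        assert gene in part.regions[phenos]


def test_novelty_printed_tables(paper):
    """Restricted to potentially pathogenic calls, the novel pairs are the
    five bold-row associations."""
    calls = paper_calls(paper)
    report = novel_associations(list(paper.observations), calls, paper.catalog)
    assert set(report.pp_novel_pairs) == {
        ("AKAP9", Phenotype.DCM), ("AKAP9", Phenotype.HCM),
        ("DLG1", Phenotype.HCM), ("OBSCN", Phenotype.ARVC),
        ("DMD", Phenotype.ARVC),
    }
    # known pairs are not flagged
    assert ("MYBPC3", Phenotype.HCM) not in report.novel_pairs
    assert ("OBSCN", Phenotype.DCM) not in report.novel_pairs
    # pp-restricted novelty is a subset of all-rare novelty
    assert report.pp_novel_pairs <= report.novel_pairs


def test_novelty_off_panel_gene_warns_and_is_configurable(paper, caplog):
    rows = [obs("P1DCM", Phenotype.DCM, "NOT_A_PANEL_GENE")]
    report = novel_associations(rows, None, paper.catalog)
    assert report.novel_pairs == frozenset()
    report2 = novel_associations(rows, None, paper.catalog,
                                 off_panel_is_novel=True)
    assert ("NOT_A_PANEL_GENE", Phenotype.DCM) in report2.novel_pairs


def test_tallies_invariant_under_permutation(paper):
    rows = list(paper.observations)
    rows_rev = rows[::-1]
    assert gene_tally(rows) == gene_tally(rows_rev)
    assert phenotype_overlap(rows).regions == phenotype_overlap(rows_rev).regions


def test_render_reports_round_trip(paper, tmp_path):
    import json
    calls = paper_calls(paper)
    bundle = render_reports(list(paper.roster), list(paper.observations),
                            calls, paper.catalog)
    out = tmp_path / "report.json"
    out.write_text(json.dumps(bundle, sort_keys=True))
    assert json.loads(out.read_text()) == json.loads(
        json.dumps(bundle, sort_keys=True))
    # evidence strings match the printed table row-for-row (variant order)
    by_key = {(r["gene"], r["protein"], r["nucleotide"]): r["supporting_evidences"]
              for r in bundle["variants"]}
    for v, expected in zip(paper.variants, paper.expected_codes):
        key = (v.gene, v.protein.raw if v.protein else ".", v.coding.raw)
        assert by_key[key] == expected


def test_render_reports_empty_cohort(paper):
    bundle = render_reports(list(paper.roster), [], [], paper.catalog)
    assert bundle["n_rare_variants"] == 0
    assert bundle["variants"] == []
    assert bundle["burden"]["mean"] == 0.0


def test_variant_type_tally_of_printed_table(paper):
    """The printed 28 split 15 missense / 5 nonsense / 4 frameshift /
    2 in-frame / 2 splice."""
    from collections import Counter
    types = Counter(v.consequence.value for v in paper.variants)
    assert types == {
        "missense": 15, "nonsense": 5, "frameshift_indel": 4,
        "inframe_indel": 2, "canonical_splice": 2,
    }
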