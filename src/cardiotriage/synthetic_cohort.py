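"""Synthetic cohorts with known ground truth, plus the printed-table fixtures.

Two sources of test data, neither requiring any download:

* :func:`make_paper_fixtures` rebuilds the published worked example — the 28
  potentially pathogenic variants with their supporting-evidence codes, the
  patient-to-variant mapping, and the 38-patient roster (16 DCM, 14 HCM,
  8 ARVC) — reconstructing each variant's annotation bundle from its printed
  evidence codes and notation.

* :func:`simulate_cohort` draws an annotated cohort emulating the study's
  structure (per-phenotype patient counts, ~85-92 candidate variants per
  patient collapsing to a few rare ones, a TTN-dominated gene distribution)
  while recording a ground-truth table at generation time: every variant's
  planted filter fate, pathogenicity label with rule branch, and novelty
  flag. With zero annotation noise the pipeline must recover the truth
  exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

import numpy as np

from .pathogenicity_engine import RuleBranch
from .rarity_filter import DEFAULT_THRESHOLDS
from .ttn_region_mapper import TTNRegionMap, load_default_map
from .variant_model import (
    AnnotatedVariant,
    AssociationCatalog,
    ClinVarClass,
    CodingChange,
    ConservationProfile,
    DatabaseEvidence,
    FrequencyRecord,
    GenePanel,
    MutationTasterCall,
    Observation,
    Patient,
    Phenotype,
    PolyPhenCall,
    PredictorProfile,
    ProveanCall,
    Sex,
    SiftCall,
    Zygosity,
    classify_consequence,
    parse_coding_change,
    parse_protein_change,
)

# --------------------------------------------------------------------------
# Published worked-example data: the 28 potentially pathogenic variants
# (gene, chrom, pos, transcript, cDNA, protein, rsID, gnomAD MAF, phenotype,
# supporting-evidence codes) and the carrier mapping.
# --------------------------------------------------------------------------

TABLE1_VARIANTS: tuple[tuple, ...] = (
    ("ACTC1", "15", 35084392, "NM_005159", "c.707C>T", "S236F", None, None, "HCM", "GS,SI,PR,PP2,MT,PC,PP"),
    ("AKAP9", "7", 91726576, "NM_005751", "c.10303C>T", "R3435X", None, None, "DCM", "MT"),
    ("AKAP9", "7", 91737871, "NM_005751", "c.11610C>G", "Y3870X", "rs757753258", 4.06e-6, "HCM", "MT"),
    ("DLG1", "3", 196812473, "NM_004087", "c.1915G>A", "G639R", "rs369412843", 8.12e-6, "HCM", "GS,SI,PR,PP2,MT,PC,PP"),
    ("DMD", "X", 32456458, "NM_004009", "c.3959G>A", "R1320H", "rs768990357", 2.24e-5, "ARVC", "SI,PR,PP2,MT,PC,PP"),
    ("DSP", "6", 7569522, "NM_004415", "c.1524dupG", "V508fs", None, None, "DCM", "MT"),
    ("DSP", "6", 7580243, "NM_004415", "c.3820G>C", "A1274P", None, None, "DCM", "SI,PR,PP2,MT,PP"),
    ("LAMP2", "X", 119576454, "NM_013995", "c.928G>A", "V310I", "rs104894858", None, "HCM", "PP2,MT,PC,PP,CV,HG"),
    ("LMNA", "1", 156100468, "NM_170708", "c.667_687dup", "L140_A146dup", None, None, "DCM", "REF"),
    ("LMNA", "1", 156106964, "NM_170708", "c.1549C>T", "Q517X", None, None, "DCM", "MT,PC,PP,HG"),
    ("MYBPC3", "11", 47371475, "NM_000256", "c.506-2A>C", None, "rs397516057", None, "HCM", "MT,PC,PP,CV"),
    ("MYBPC3", "11", 47369407, "NM_000256", "c.821+1G>A", None, "rs397516073", 2.98e-5, "HCM", "MT,PC,PP,CV,HG"),
    ("MYBPC3", "11", 47367758, "NM_000256", "c.1090G>A", "A364T", None, None, "HCM", "SI,PR,PP2,MT,PC,PP"),
    ("MYBPC3", "11", 47360197, "NM_000256", "c.2182G>T", "E728X", "rs397515954", None, "HCM", "MT,PC,PP,CV"),
    ("MYH7", "14", 23895233, "NM_000257", "c.2102G>A", "G701D", None, None, "HCM", "SI,PR,PP2,MT,PC,PP"),
    ("MYH7", "14", 23886383, "NM_000257", "c.4498C>T", "R1500W", "rs45544633", None, "DCM", "SI,PR,PP2,MT,CV,HG"),
    ("MYH7", "14", 23884353, "NM_000257", "c.5410G>A", "A1804T", "rs730880818", 4.06e-6, "DCM", "SI,PR,PP2,MT,PC,PP,CV"),
    ("NEXN", "1", 78401657, "NM_144573", "c.1398_1400delAAT", "I467del", None, None, "HCM", "MT,PC"),
    ("OBSCN", "1", 228400286, "NM_052843", "c.802G>T", "E268X", None, None, "HCM", "MT,PP"),
    ("OBSCN", "1", 228525823, "NM_001098623", "c.16979C>T", "A5660V", "rs191098985", 0.0006, "DCM", "GS,SI,PR,PP2,MT,PC,PP"),
    ("OBSCN", "1", 228527758, "NM_001098623", "c.17371G>C", "A5791P", "rs200362121", 0.0004, "ARVC", "SI,PR,PP2,MT,PC,PP"),
    ("OBSCN", "1", 228557681, "NM_001098623", "c.20006G>A", "R6669H", "rs373638525", 9.4e-5, "DCM", "SI,PR,PP2,MT,PP"),
    ("PKP2", "12", 33030842, "NM_004572", "c.962_972delTCGGCCAGGCG", "V321GfsX11", None, None, "ARVC", "MT"),
    ("PKP2", "12", 32974392, "NM_004572", "c.2043delT", "I681fs", None, None, "ARVC", "MT"),
    ("RAF1", "3", 12626632, "NM_002880", "c.1657A>C", "N553H", "rs745876012", 4.06e-6, "HCM", "SI,PR,PP2,MT,PC,PP"),
    ("RYR2", "1", 237802395, "NM_001035", "c.7009G>C", "G2337R", None, None, "ARVC", "GS,SI,PR,PP2,MT,PC,PP"),
    ("TNNT2", "1", 201334425, "NM_001276345", "c.305G>A", "R102Q", "rs121964856", None, "HCM", "SI,PR,PP2,MT,PC,PP,CV,HG"),
    ("TTN", "2", 179434235, "NM_003319", "c.49429delG", "V16477fs", None, None, "DCM", "MT,PC,PP"),
)

#: patient -> variant keys (gene, protein token or cDNA token for splice rows)
TABLE2_CARRIERS: tuple[tuple[str, tuple[tuple[str, str], ...]], ...] = (
    ("76DCM", (("AKAP9", "R3435X"), ("DSP", "V508fs"))),
    ("99DCM", (("TTN", "V16477fs"),)),
    ("682DCM", (("OBSCN", "R6669H"),)),
    ("737DCM", (("LMNA", "L140_A146dup"),)),
    ("1060DCM", (("DSP", "A1274P"),)),
    ("1329DCM", (("MYH7", "A1804T"),)),
    ("1718DCM", (("OBSCN", "A5660V"),)),
    ("1801DCM", (("MYH7", "R1500W"),)),
    ("1816DCM", (("LMNA", "Q517X"),)),
    ("1173HCM", (("MYBPC3", "E728X"), ("OBSCN", "E268X"))),
    ("1657HCM", (("MYBPC3", "c.506-2A>C"),)),
    ("1661HCM", (("MYBPC3", "c.506-2A>C"),)),
    ("1674HCM", (("NEXN", "I467del"),)),
    ("1699HCM", (("MYBPC3", "c.821+1G>A"),)),
    ("1721HCM", (("RAF1", "N553H"),)),
    ("1739HCM", (("TNNT2", "R102Q"),)),
    ("1740HCM", (("LAMP2", "V310I"),)),
    ("1741HCM", (("ACTC1", "S236F"),)),
    ("1776HCM", (("DLG1", "G639R"), ("MYBPC3", "A364T"))),
    ("1832HCM", (("MYH7", "G701D"),)),
    ("1833HCM", (("AKAP9", "Y3870X"),)),
    ("1662ARVC", (("OBSCN", "A5791P"),)),
    ("1666ARVC", (("PKP2", "I681fs"),)),
    ("1751ARVC", (("DMD", "R1320H"),)),
    ("1812ARVC", (("RYR2", "G2337R"),)),
    ("1825ARVC", (("PKP2", "V321GfsX11"),)),
)

#: patients of the roster carrying no potentially pathogenic variant
ZERO_PP_PATIENTS: tuple[str, ...] = (
    "310DCM", "365DCM", "968DCM", "1584DCM", "1669DCM", "1717DCM", "1838DCM",
    "1685HCM", "1798HCM", "1665ARVC", "1708ARVC", "1830ARVC",
)

# Per-patient sexes: chosen to reproduce the cohort tallies (DCM 14M/2F,
# HCM 7M/7F, ARVC 5M/3F) with the X-linked carriers male, so the printed
# hemizygous calls follow.
FEMALE_PATIENTS: frozenset[str] = frozenset(
    {
        "1669DCM", "1838DCM",
        "1721HCM", "1739HCM", "1741HCM", "1776HCM", "1798HCM", "1832HCM", "1833HCM",
        "1665ARVC", "1708ARVC", "1830ARVC",
    }
)

X_CHROM_GENES = frozenset({"DMD", "LAMP2", "EMD", "GLA", "TAZ", "FHL1"})


def _phenotype_of(patient_id: str) -> Phenotype:
    for ph in Phenotype:
        if patient_id.endswith(ph.value):
            return ph
    raise ValueError(f"cannot infer phenotype from id {patient_id!r}")


def load_default_catalog() -> AssociationCatalog:
    """The bundled best-effort 115-gene panel catalog."""
    ref = resources.files("cardiotriage.data").joinpath("panel_catalog.tsv")
    entries: set[tuple[str, str]] = set()
    for line in ref.read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        gene, tags = line.split("\t")
        for tag in tags.split(","):
            entries.add((gene, tag.strip()))
    return AssociationCatalog(entries=frozenset(entries))


def load_default_panel() -> GenePanel:
    catalog = load_default_catalog()
    return GenePanel(genes=catalog.genes(), catalog=catalog)


def _subst_ref_alt(cdna: str) -> tuple[Optional[str], Optional[str]]:
    if ">" in cdna:
        left, alt = cdna.rsplit(">", 1)
        return left[-1], alt
    return None, None


def _variant_from_table1_row(row: tuple, carrier_sex: Sex) -> AnnotatedVariant:
    """Reconstruct the annotation bundle of one printed variant from its
    supporting-evidence codes and notation."""
    (gene, chrom, pos, transcript, cdna, protein_raw, rsid, maf, _pheno,
     code_str) = row
    codes = {c.strip() for c in code_str.split(",") if c.strip()}
    protein = parse_protein_change(protein_raw) if protein_raw else None
    coding = parse_coding_change(cdna)
    consequence = classify_consequence(protein, coding)
    is_missense = consequence.value == "missense"
    predictors = PredictorProfile(
        sift=(SiftCall.DAMAGING if "SI" in codes
              else SiftCall.TOLERATED if is_missense else SiftCall.ABSENT),
        provean=(ProveanCall.DELETERIOUS if "PR" in codes
                 else ProveanCall.NEUTRAL if is_missense else ProveanCall.ABSENT),
        polyphen2=(PolyPhenCall.PROBABLY_DAMAGING if "PP2" in codes
                   else PolyPhenCall.BENIGN if is_missense else PolyPhenCall.ABSENT),
        mutation_taster=(MutationTasterCall.DISEASE_CAUSING if "MT" in codes
                         else MutationTasterCall.POLYMORPHISM),
    )
    conservation = ConservationProfile(
        phylop=2.5 if "PP" in codes else 0.1,
        phastcons=1.0 if "PC" in codes else 0.42,
        grantham=(101 if "GS" in codes else 45) if is_missense else None,
    )
    evidence = DatabaseEvidence(
        clinvar_class=ClinVarClass.PATHOGENIC if "CV" in codes else ClinVarClass.ABSENT,
        clinvar_same_phenotype="CV" in codes,
        hgmd_same_phenotype="HG" in codes,
        published_support="REF" in codes,
    )
    freqs: list[FrequencyRecord] = []
    if maf is not None:
        freqs.append(FrequencyRecord(source="gnomAD", maf=maf))
    if rsid is not None:
        freqs.append(FrequencyRecord(source="dbSNP", maf=None))
    ref, alt = _subst_ref_alt(cdna)
    zygosity = (
        Zygosity.HEMIZYGOUS
        if chrom == "X" and carrier_sex is Sex.M
        else Zygosity.HETEROZYGOUS
    )
    return AnnotatedVariant(
        gene=gene, transcript=transcript, chrom=chrom, genomic_pos=pos,
        coding=coding, protein=protein, consequence=consequence,
        ref=ref, alt=alt,
        depth=50,  # not printed; constant above threshold, never decisive
        frequencies=tuple(freqs), predictors=predictors,
        conservation=conservation, evidence=evidence, zygosity=zygosity,
    )


@dataclass(frozen=True)
class PaperFixtures:
    """The printed worked example as in-memory objects."""

    variants: tuple[AnnotatedVariant, ...]  # 28 distinct variants
    observations: tuple[Observation, ...]   # 29 patient x variant rows
    roster: tuple[Patient, ...]             # 38 patients
    expected_codes: tuple[str, ...]         # printed evidence strings, row order
    catalog: AssociationCatalog
    region_map: TTNRegionMap


def make_paper_fixtures() -> PaperFixtures:
    roster: list[Patient] = []
    carrier_map = dict(TABLE2_CARRIERS)
    for pid, _ in TABLE2_CARRIERS:
        roster.append(Patient(pid, _phenotype_of(pid),
                              Sex.F if pid in FEMALE_PATIENTS else Sex.M))
    for pid in ZERO_PP_PATIENTS:
        roster.append(Patient(pid, _phenotype_of(pid),
                              Sex.F if pid in FEMALE_PATIENTS else Sex.M))
    by_id = {p.patient_id: p for p in roster}

    # map each variant to its carriers to pick the zygosity-determining sex
    def carriers_of(gene: str, token: str) -> list[Patient]:
        found = []
        for pid, keys in carrier_map.items():
            if (gene, token) in keys:
                found.append(by_id[pid])
        return found

    variants: list[AnnotatedVariant] = []
    expected: list[str] = []
    observations: list[Observation] = []
    for row in TABLE1_VARIANTS:
        gene, token = row[0], (row[5] or row[4])
        carriers = carriers_of(gene, token)
        if not carriers:
            raise RuntimeError(f"no carrier recorded for {gene} {token}")
        variant = _variant_from_table1_row(row, carriers[0].sex)
        variants.append(variant)
        expected.append(", ".join(c.strip() for c in row[9].split(",")))
        for patient in carriers:
            observations.append(Observation(patient=patient, variant=variant))
    return PaperFixtures(
        variants=tuple(variants),
        observations=tuple(observations),
        roster=tuple(roster),
        expected_codes=tuple(expected),
        catalog=load_default_catalog(),
        region_map=load_default_map(),
    )


# --------------------------------------------------------------------------
# Simulator
# --------------------------------------------------------------------------

_AAS = "ACDEFGHIKLMNPQRSTVWY"
_BASES = "ACGT"

POSITIVE_BRANCH_NAMES = (
    "missense_consensus", "radical_mt", "ttn_truncating_a_band",
    "database_override",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped generator settings; the defaults are the study conditions.

    Per-phenotype patient counts, candidate-variant means and rare-variant
    means are the cohort's printed structure (16/14/8 patients; ~85/89/92
    candidates and 4.5/3.6/2.4 rare variants per DCM/HCM/ARVC patient).
    branch_rates give, per rare variant, the probability of planting each
    rule branch; the unassigned remainder is planted plainly not pathogenic.
    Rates mirror the observed composition of the rare-variant set (TTN
    missense heavy, ~1 in 5 potentially pathogenic).
    """

    n_patients: dict[Phenotype, int] = field(
        default_factory=lambda: {Phenotype.DCM: 16, Phenotype.HCM: 14,
                                 Phenotype.ARVC: 8}
    )
    candidate_mean: dict[Phenotype, float] = field(
        default_factory=lambda: {Phenotype.DCM: 85.0, Phenotype.HCM: 89.0,
                                 Phenotype.ARVC: 92.0}
    )
    rare_mean: dict[Phenotype, float] = field(
        default_factory=lambda: {Phenotype.DCM: 4.5, Phenotype.HCM: 3.6,
                                 Phenotype.ARVC: 2.4}
    )
    branch_rates: dict[str, float] = field(
        default_factory=lambda: {
            "missense_consensus": 0.10,
            "radical_mt": 0.08,
            "database_override": 0.014,
            "ttn_truncating_a_band": 0.007,
            "ttn_missense_exempt": 0.27,
            "demoted_clinvar": 0.014,
        }
    )
    absent_from_db_rate: float = 0.23
    predictor_noise: float = 0.0
    gene_skew: float = 1.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in self.branch_rates.items():
            if name not in {b.value for b in RuleBranch}:
                raise ValueError(f"unknown rule branch {name!r}")
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"branch rate {name} out of [0,1]")
        if sum(self.branch_rates.values()) > 1.0 + 1e-9:
            raise ValueError("branch rates must sum to <= 1")
        if not (0.0 <= self.absent_from_db_rate <= 1.0):
            raise ValueError("absent_from_db_rate out of [0,1]")
        if not (0.0 <= self.predictor_noise <= 1.0):
            raise ValueError("predictor_noise out of [0,1]")
        for ph in Phenotype:
            if self.n_patients.get(ph, 0) < 0 or self.candidate_mean.get(ph, 0) < 0:
                raise ValueError("counts must be >= 0")
            if self.rare_mean.get(ph, 0) < 0:
                raise ValueError("rates must be >= 0")
        plants_pathogenic = any(
            self.branch_rates.get(b, 0) > 0 for b in POSITIVE_BRANCH_NAMES
        )
        if plants_pathogenic and all(
            self.rare_mean.get(ph, 0) == 0 for ph in Phenotype
        ):
            raise ValueError(
                "infeasible config: pathogenic branches planted but the "
                "rare-variant rate is zero everywhere"
            )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one generated variant, frozen at generation time."""

    variant_id: str
    patient_id: str
    retained: bool
    failed_criteria: tuple[str, ...]
    label: Optional[bool]          # None when not retained
    branch: Optional[RuleBranch]   # None when not retained
    novel: Optional[bool]


@dataclass(frozen=True)
class SimulatedCohort:
    observations: tuple[Observation, ...]
    roster: tuple[Patient, ...]
    catalog: AssociationCatalog
    truth: dict[str, TruthRecord]  # keyed by variant_id = "<patient>:<idx>"

    def truth_in_order(self) -> list[TruthRecord]:
        counters: dict[str, int] = {}
        out: list[TruthRecord] = []
        for obs in self.observations:
            pid = obs.patient.patient_id
            i = counters.get(pid, 0)
            counters[pid] = i + 1
            out.append(self.truth[f"{pid}:{i}"])
        return out


def _gene_universe(catalog: AssociationCatalog) -> list[str]:
    genes = sorted(catalog.genes())
    # TTN first so the skewed sampler makes it dominate, as in real panels
    genes.remove("TTN")
    return ["TTN"] + genes


def _gene_coords(genes: list[str]) -> dict[str, tuple[str, int, str]]:
    """Deterministic synthetic (chromosome, base position, transcript) per
    gene; real X-linked panel genes keep chromosome X so zygosity typing is
    exercised. TTN keeps its real primary accession for the band rule."""
    coords = {}
    for i, g in enumerate(genes):
        chrom = "X" if g in X_CHROM_GENES else str((i % 22) + 1)
        transcript = "NM_003319" if g == "TTN" else f"NM_{900001 + i}"
        coords[g] = (chrom, 1_000_000 * (i + 1), transcript)
    return coords


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw a cohort; deterministic for a given config (seed included)."""
    rng = np.random.default_rng(config.seed)
    catalog = load_default_catalog()
    genes = _gene_universe(catalog)
    coords = _gene_coords(genes)
    non_ttn = [g for g in genes if g != "TTN"]
    weights = np.array([1.0 / (r + 1) ** config.gene_skew
                        for r in range(len(non_ttn))])
    weights /= weights.sum()

    branch_names = sorted(config.branch_rates)
    branch_p = np.array([config.branch_rates[b] for b in branch_names])
    p_rest = max(0.0, 1.0 - branch_p.sum())
    branch_names.append("not_pathogenic_plain")
    branch_p = np.append(branch_p, p_rest)
    branch_p /= branch_p.sum()

    roster: list[Patient] = []
    observations: list[Observation] = []
    truth: dict[str, TruthRecord] = {}

    idx = 0
    for ph in (Phenotype.DCM, Phenotype.HCM, Phenotype.ARVC):
        for k in range(config.n_patients.get(ph, 0)):
            idx += 1
            pid = f"{1000 + idx}{ph.value}"
            sex = Sex.M if rng.random() < 0.5 else Sex.F
            patient = Patient(pid, ph, sex)
            roster.append(patient)
            n_cand = int(rng.poisson(config.candidate_mean[ph]))
            n_rare = min(int(rng.poisson(config.rare_mean[ph])), n_cand)
            n_common = n_cand - n_rare
            var_i = 0
            for _ in range(n_rare):
                branch = branch_names[int(rng.choice(len(branch_names), p=branch_p))]
                variant, record = _make_rare_variant(
                    rng, config, catalog, coords, non_ttn, weights, patient,
                    branch, f"{pid}:{var_i}",
                )
                observations.append(Observation(patient=patient, variant=variant))
                truth[record.variant_id] = record
                var_i += 1
            for _ in range(n_common):
                variant, record = _make_failing_variant(
                    rng, config, coords, non_ttn, weights, patient,
                    f"{pid}:{var_i}",
                )
                observations.append(Observation(patient=patient, variant=variant))
                truth[record.variant_id] = record
                var_i += 1

    if config.predictor_noise > 0:
        observations = [
            Observation(o.patient,
                        _perturb_predictors(rng, o.variant, config.predictor_noise))
            for o in observations
        ]

    return SimulatedCohort(
        observations=tuple(observations), roster=tuple(roster),
        catalog=catalog, truth=truth,
    )


def _rare_maf_records(rng, config, threshold: float) -> tuple[FrequencyRecord, ...]:
    if rng.random() < config.absent_from_db_rate:
        return ()
    return (FrequencyRecord("gnomAD", maf=float(rng.uniform(0, 0.5) * threshold)),)


def _missense_parts(rng, position: int) -> tuple[str, str]:
    ref, alt = rng.choice(len(_AAS), size=2, replace=False)
    return f"{_AAS[ref]}{position}{_AAS[alt]}", _AAS[ref]


def _base_variant(rng, coords, gene: str, patient: Patient) -> dict:
    chrom, base, transcript = coords[gene]
    zyg = (Zygosity.HEMIZYGOUS if chrom == "X" and patient.sex is Sex.M
           else Zygosity.HETEROZYGOUS)
    return {
        "gene": gene,
        "chrom": chrom,
        "genomic_pos": int(base + rng.integers(1, 500_000)),
        "depth": int(rng.integers(12, 400)),
        "zygosity": zyg,
        "ref": _BASES[int(rng.integers(4))],
        "alt": _BASES[int(rng.integers(4))],
        "transcript": transcript,
    }


def _neutral_conservation(rng) -> ConservationProfile:
    return ConservationProfile(
        phylop=float(rng.uniform(-1, 3)),
        phastcons=float(rng.choice([1.0, round(float(rng.uniform(0, 0.99)), 3)])),
        grantham=None,
    )


def _damaging_profile() -> PredictorProfile:
    return PredictorProfile(
        sift=SiftCall.DAMAGING, provean=ProveanCall.DELETERIOUS,
        polyphen2=PolyPhenCall.PROBABLY_DAMAGING,
        mutation_taster=MutationTasterCall.DISEASE_CAUSING,
    )


def _dissenting_profile(rng) -> PredictorProfile:
    """Full consensus broken by exactly one dissent."""
    which = int(rng.integers(4))
    return PredictorProfile(
        sift=SiftCall.TOLERATED if which == 0 else SiftCall.DAMAGING,
        provean=ProveanCall.NEUTRAL if which == 1 else ProveanCall.DELETERIOUS,
        polyphen2=PolyPhenCall.BENIGN if which == 2 else PolyPhenCall.PROBABLY_DAMAGING,
        mutation_taster=(MutationTasterCall.POLYMORPHISM if which == 3
                         else MutationTasterCall.DISEASE_CAUSING),
    )


def _radical_token(rng, position: int) -> tuple[Optional[str], str, str]:
    """(protein token, cDNA token, consequence family) for a radical variant."""
    kind = int(rng.integers(4))
    aa = _AAS[int(rng.integers(len(_AAS)))]
    cpos = int(rng.integers(1, 5000))
    if kind == 0:
        return f"{aa}{position}X", f"c.{cpos}C>T", "nonsense"
    if kind == 1:
        return f"{aa}{position}fs", f"c.{cpos}delG", "frameshift_indel"
    if kind == 2:
        return None, f"c.{cpos}-2A>G", "canonical_splice"
    return f"{aa}{position}del", f"c.{cpos}_{cpos + 2}delAAT", "inframe_indel"


def _make_rare_variant(rng, config, catalog, coords, non_ttn, weights,
                       patient, branch: str, variant_id: str):
    threshold = DEFAULT_THRESHOLDS[patient.phenotype]
    ttn_branch = branch.startswith("ttn")
    gene = "TTN" if ttn_branch else non_ttn[int(rng.choice(len(non_ttn), p=weights))]
    base = _base_variant(rng, coords, gene, patient)
    freqs = _rare_maf_records(rng, config, threshold)
    evidence = DatabaseEvidence()
    conservation = _neutral_conservation(rng)
    position = int(rng.integers(50, 2000))

    if branch == "missense_consensus":
        token, _ = _missense_parts(rng, position)
        protein, coding = token, f"c.{3 * position}G>A"
        predictors = _damaging_profile()
        conservation = replace(conservation, grantham=int(rng.integers(5, 216)))
        label, rb = True, RuleBranch.MISSENSE_CONSENSUS
    elif branch == "demoted_clinvar":
        token, _ = _missense_parts(rng, position)
        protein, coding = token, f"c.{3 * position}G>A"
        predictors = _damaging_profile()
        conservation = replace(conservation, grantham=int(rng.integers(5, 216)))
        evidence = DatabaseEvidence(
            clinvar_class=ClinVarClass(
                str(rng.choice(["vus", "likely_benign", "benign"]))
            )
        )
        label, rb = False, RuleBranch.DEMOTED_CLINVAR
    elif branch == "database_override":
        token, _ = _missense_parts(rng, position)
        protein, coding = token, f"c.{3 * position}G>A"
        predictors = _dissenting_profile(rng)
        conservation = replace(conservation, grantham=int(rng.integers(5, 216)))
        kind = str(rng.choice(["cv", "hg", "ref"]))
        evidence = DatabaseEvidence(
            clinvar_class=(ClinVarClass.PATHOGENIC if kind == "cv"
                           else ClinVarClass.ABSENT),
            clinvar_same_phenotype=kind == "cv",
            hgmd_same_phenotype=kind == "hg",
            published_support=kind == "ref",
        )
        label, rb = True, RuleBranch.DATABASE_OVERRIDE
    elif branch == "radical_mt":
        protein, coding, _family = _radical_token(rng, position)
        predictors = PredictorProfile(
            mutation_taster=MutationTasterCall.DISEASE_CAUSING
        )
        label, rb = True, RuleBranch.RADICAL_MT
    elif branch == "ttn_missense_exempt":
        position = int(rng.integers(1, 26927))
        token, _ = _missense_parts(rng, position)
        protein, coding = token, f"c.{3 * position}G>A"
        predictors = _damaging_profile()  # exemption holds despite consensus
        conservation = replace(conservation, grantham=int(rng.integers(5, 216)))
        base["transcript"] = "NM_003319"
        label, rb = False, RuleBranch.TTN_MISSENSE_EXEMPT
    elif branch == "ttn_truncating_a_band":
        position = int(rng.integers(14901, 24201))  # shared A-band residues
        aa = _AAS[int(rng.integers(len(_AAS)))]
        protein = (f"{aa}{position}fs" if rng.random() < 0.5
                   else f"{aa}{position}X")
        coding = f"c.{3 * position}delG"
        predictors = PredictorProfile(
            mutation_taster=MutationTasterCall.DISEASE_CAUSING
        )
        base["transcript"] = "NM_003319"
        label, rb = True, RuleBranch.TTN_TRUNCATING_A_BAND
    else:  # not pathogenic, planted plainly
        if gene == "TTN" or rng.random() < 0.7:
            token, _ = _missense_parts(rng, position)
            protein, coding = token, f"c.{3 * position}G>A"
            predictors = _dissenting_profile(rng)
            if gene != "TTN":
                conservation = replace(
                    conservation, grantham=int(rng.integers(5, 216))
                )
            label = False
            rb = (RuleBranch.TTN_MISSENSE_EXEMPT if gene == "TTN"
                  else RuleBranch.NOT_PATHOGENIC)
        else:
            protein, coding, family = _radical_token(rng, position)
            predictors = PredictorProfile(
                mutation_taster=MutationTasterCall.POLYMORPHISM
            )
            label, rb = False, RuleBranch.NOT_PATHOGENIC
        if gene == "TTN":
            base["transcript"] = "NM_003319"
            # keep planted-negative TTN out of the truncating classes so the
            # not_pathogenic label is decided by predictors, not the band rule
            pos2 = int(rng.integers(1, 26927))
            token, _ = _missense_parts(rng, pos2)
            protein, coding = token, f"c.{3 * pos2}G>A"
            predictors = _dissenting_profile(rng)
            label, rb = False, RuleBranch.TTN_MISSENSE_EXEMPT

    transcript = base.pop("transcript")
    pc = parse_protein_change(protein) if protein else None
    cc = parse_coding_change(coding)
    variant = AnnotatedVariant(
        transcript=transcript,
        coding=cc, protein=pc,
        consequence=classify_consequence(pc, cc),
        frequencies=freqs, predictors=predictors,
        conservation=conservation, evidence=evidence,
        **base,
    )
    novel = not catalog.knows(gene, patient.phenotype)
    record = TruthRecord(
        variant_id=variant_id, patient_id=patient.patient_id,
        retained=True, failed_criteria=(), label=label, branch=rb, novel=novel,
    )
    return variant, record


def _make_failing_variant(rng, config, coords, non_ttn, weights, patient,
                          variant_id: str):
    """A candidate variant planted to fail exactly one inclusion criterion."""
    threshold = DEFAULT_THRESHOLDS[patient.phenotype]
    mode = str(rng.choice(["maf", "depth", "consequence"], p=[0.90, 0.05, 0.05]))
    gene = non_ttn[int(rng.choice(len(non_ttn), p=weights))]
    base = _base_variant(rng, coords, gene, patient)
    position = int(rng.integers(50, 2000))
    if mode == "consequence":
        aa = _AAS[int(rng.integers(len(_AAS)))]
        protein, coding = f"{aa}{position}{aa}", f"c.{3 * position}G>A"  # synonymous
        freqs = _rare_maf_records(rng, config, threshold)
    else:
        token, _ = _missense_parts(rng, position)
        protein, coding = token, f"c.{3 * position}G>A"
        if mode == "maf":
            maf = float(min(rng.uniform(2.0, 20.0) * threshold, 0.5))
            freqs = (FrequencyRecord("gnomAD", maf=maf),)
        else:
            freqs = _rare_maf_records(rng, config, threshold)
            base["depth"] = int(rng.integers(1, 10))
    pc = parse_protein_change(protein)
    cc = parse_coding_change(coding)
    variant = AnnotatedVariant(
        transcript=base.pop("transcript"),
        coding=cc, protein=pc,
        consequence=classify_consequence(pc, cc),
        frequencies=freqs,
        predictors=PredictorProfile(),
        conservation=_neutral_conservation(rng),
        evidence=DatabaseEvidence(),
        **base,
    )
    record = TruthRecord(
        variant_id=variant_id, patient_id=patient.patient_id,
        retained=False, failed_criteria=(mode,), label=None, branch=None,
        novel=None,
    )
    return variant, record


def _perturb_predictors(rng, variant: AnnotatedVariant, p: float) -> AnnotatedVariant:
    pr = variant.predictors
    flip = rng.random(4) < p

    def _sw(cond, cur, a, b):
        return (b if cur == a else a) if cond else cur

    noisy = PredictorProfile(
        sift=_sw(flip[0], pr.sift, SiftCall.DAMAGING, SiftCall.TOLERATED),
        provean=_sw(flip[1], pr.provean, ProveanCall.DELETERIOUS, ProveanCall.NEUTRAL),
        polyphen2=_sw(flip[2], pr.polyphen2, PolyPhenCall.PROBABLY_DAMAGING,
                      PolyPhenCall.BENIGN),
        mutation_taster=_sw(flip[3], pr.mutation_taster,
                            MutationTasterCall.DISEASE_CAUSING,
                            MutationTasterCall.POLYMORPHISM),
    )
    return replace(variant, predictors=noisy)
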