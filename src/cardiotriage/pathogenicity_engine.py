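"""Rule engine assigning the "potentially pathogenic" label to rare variants.

The decision tree, applied to every variant that survived rarity filtering:

1. TTN missense variants are never potentially pathogenic, whatever the
   predictors or databases say (their case/control frequencies do not differ
   and only segregation could establish causality).
2. A ClinVar assertion of VUS / Likely benign / Benign demotes the variant,
   unless HGMD-same-phenotype or published data independently assert
   pathogenicity (a pathogenic ClinVar entry cannot co-exist with a demoting
   one, so it cannot rescue).
3. TTN truncating variants are potentially pathogenic only if they hit the
   A-band in a region shared by all titin isoforms (see ttn_region_mapper).
4. Other missense variants require the full four-predictor consensus:
   SIFT damaging AND PROVEAN deleterious AND PolyPhen-2 possibly/probably
   damaging AND MutationTaster disease-causing.
5. Radical variants (stop-gain, stop-loss, canonical splice, frameshift and
   in-frame indels) require MutationTaster disease-causing.
6. A negative from (4)/(5) flips to positive when ClinVar-pathogenic-same-
   phenotype, HGMD-same-phenotype or published data support pathogenicity.

Every call records the single rule branch that fired and the Table-1-style
evidence codes (GS, SI, PR, PP2, MT, PC, PP, CV, HG, REF), which are
computed identically for positive and negative calls.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

from .ttn_region_mapper import TTNRegionMap, ttn_truncating_potentially_pathogenic
from .variant_model import (
    DEMOTING_CLINVAR,
    AnnotatedVariant,
    ClinVarClass,
    ConsequenceClass,
    MutationTasterCall,
    Observation,
    PolyPhenCall,
    PredictorProfile,
    ProveanCall,
    SiftCall,
)

TTN_GENE = "TTN"

#: Radical variant classes: classified by the MutationTaster-only rule.
RADICAL_CLASSES = frozenset(
    {
        ConsequenceClass.NONSENSE,
        ConsequenceClass.STOPLOSS,
        ConsequenceClass.CANONICAL_SPLICE,
        ConsequenceClass.FRAMESHIFT_INDEL,
        ConsequenceClass.INFRAME_INDEL,
    }
)

#: TTN consequence classes routed to the A-band rule.
TTN_TRUNCATING_CLASSES = frozenset(
    {
        ConsequenceClass.NONSENSE,
        ConsequenceClass.STOPLOSS,
        ConsequenceClass.CANONICAL_SPLICE,
        ConsequenceClass.FRAMESHIFT_INDEL,
    }
)


class RuleBranch(str, Enum):
    MISSENSE_CONSENSUS = "missense_consensus"
    RADICAL_MT = "radical_mt"
    TTN_TRUNCATING_A_BAND = "ttn_truncating_a_band"
    DATABASE_OVERRIDE = "database_override"
    DEMOTED_CLINVAR = "demoted_clinvar"
    TTN_MISSENSE_EXEMPT = "ttn_missense_exempt"
    NOT_PATHOGENIC = "not_pathogenic"


POSITIVE_BRANCHES = frozenset(
    {
        RuleBranch.MISSENSE_CONSENSUS,
        RuleBranch.RADICAL_MT,
        RuleBranch.TTN_TRUNCATING_A_BAND,
        RuleBranch.DATABASE_OVERRIDE,
    }
)

#: Canonical ordering of evidence codes, as printed in variant reports.
EVIDENCE_CODE_ORDER = ("GS", "SI", "PR", "PP2", "MT", "PC", "PP", "CV", "HG", "REF")


@dataclass(frozen=True)
class PathogenicityCall:
    variant: AnnotatedVariant
    potentially_pathogenic: bool
    branch: RuleBranch
    evidence_codes: frozenset[str]
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.potentially_pathogenic != (self.branch in POSITIVE_BRANCHES):
            raise ValueError("label inconsistent with fired branch")

    def evidence_string(self) -> str:
        return ", ".join(c for c in EVIDENCE_CODE_ORDER if c in self.evidence_codes)


def predictor_consensus(predictors: PredictorProfile) -> bool:
    """True iff all four predictors are simultaneously in their damaging
    categories; any unscored predictor breaks the consensus."""
    return (
        predictors.sift is SiftCall.DAMAGING
        and predictors.provean is ProveanCall.DELETERIOUS
        and predictors.polyphen2
        in (PolyPhenCall.PROBABLY_DAMAGING, PolyPhenCall.POSSIBLY_DAMAGING)
        and predictors.mutation_taster is MutationTasterCall.DISEASE_CAUSING
    )


def _clinvar_pathogenic_same_phenotype(variant: AnnotatedVariant) -> bool:
    return (
        variant.evidence.clinvar_class
        in (ClinVarClass.PATHOGENIC, ClinVarClass.LIKELY_PATHOGENIC)
        and variant.evidence.clinvar_same_phenotype
    )


def database_override(variant: AnnotatedVariant) -> bool:
    """Pathogenicity asserted by ClinVar (same phenotype), HGMD (same
    phenotype) or published data."""
    ev = variant.evidence
    return (
        _clinvar_pathogenic_same_phenotype(variant)
        or ev.hgmd_same_phenotype
        or ev.published_support
    )


def evidence_codes(variant: AnnotatedVariant) -> frozenset[str]:
    """Table-1-style supporting-evidence codes for one variant.

    Conservation codes (GS, PC, PP) are reported but never decisive.
    """
    codes: set[str] = set()
    p = variant.predictors
    c = variant.conservation
    if (
        variant.consequence is ConsequenceClass.MISSENSE
        and c.grantham is not None
        and c.grantham > 100
    ):
        codes.add("GS")
    if p.sift is SiftCall.DAMAGING:
        codes.add("SI")
    if p.provean is ProveanCall.DELETERIOUS:
        codes.add("PR")
    if p.polyphen2 in (PolyPhenCall.PROBABLY_DAMAGING, PolyPhenCall.POSSIBLY_DAMAGING):
        codes.add("PP2")
    if p.mutation_taster is MutationTasterCall.DISEASE_CAUSING:
        codes.add("MT")
    if c.phastcons is not None and c.phastcons == 1.0:
        codes.add("PC")
    if c.phylop is not None and c.phylop > 1.0:
        codes.add("PP")
    if _clinvar_pathogenic_same_phenotype(variant):
        codes.add("CV")
    if variant.evidence.hgmd_same_phenotype:
        codes.add("HG")
    if variant.evidence.published_support:
        codes.add("REF")
    return frozenset(codes)


class TTNMapMissingError(RuntimeError):
    """A TTN truncating variant cannot be ruled on without a region map."""


def classify_variant(
    variant: AnnotatedVariant, ttn_map: Optional[TTNRegionMap]
) -> PathogenicityCall:
    """Run the decision tree for one rare variant; exactly one branch fires."""
    codes = evidence_codes(variant)
    cons = variant.consequence

    if variant.gene == TTN_GENE and cons is ConsequenceClass.MISSENSE:
        return PathogenicityCall(
            variant, False, RuleBranch.TTN_MISSENSE_EXEMPT, codes,
            rationale="TTN missense: exempt independently of predictor results",
        )

    ev = variant.evidence
    if ev.clinvar_class in DEMOTING_CLINVAR:
        if ev.hgmd_same_phenotype or ev.published_support:
            return PathogenicityCall(
                variant, True, RuleBranch.DATABASE_OVERRIDE, codes,
                rationale=(
                    f"ClinVar {ev.clinvar_class.value} demotion overridden by "
                    "independent HGMD/published support (precedence decided here)"
                ),
            )
        return PathogenicityCall(
            variant, False, RuleBranch.DEMOTED_CLINVAR, codes,
            rationale=f"ClinVar class {ev.clinvar_class.value} demotes the variant",
        )

    if variant.gene == TTN_GENE and cons in TTN_TRUNCATING_CLASSES:
        if ttn_map is None:
            raise TTNMapMissingError(
                "TTN truncating variant requires a loaded TTN region map"
            )
        positive, why = ttn_truncating_potentially_pathogenic(variant, ttn_map)
        if positive:
            return PathogenicityCall(
                variant, True, RuleBranch.TTN_TRUNCATING_A_BAND, codes, rationale=why
            )
        return PathogenicityCall(
            variant, False, RuleBranch.NOT_PATHOGENIC, codes, rationale=why
        )

    if cons is ConsequenceClass.MISSENSE:
        if predictor_consensus(variant.predictors):
            return PathogenicityCall(
                variant, True, RuleBranch.MISSENSE_CONSENSUS, codes,
                rationale="four-predictor damaging consensus",
            )
        if database_override(variant):
            return PathogenicityCall(
                variant, True, RuleBranch.DATABASE_OVERRIDE, codes,
                rationale="predictors not decisive; ClinVar/HGMD/published support",
            )
        return PathogenicityCall(
            variant, False, RuleBranch.NOT_PATHOGENIC, codes,
            rationale="predictor consensus not met",
        )

    if cons in RADICAL_CLASSES:
        if variant.predictors.mutation_taster is MutationTasterCall.DISEASE_CAUSING:
            return PathogenicityCall(
                variant, True, RuleBranch.RADICAL_MT, codes,
                rationale="radical variant, MutationTaster disease-causing",
            )
        if database_override(variant):
            return PathogenicityCall(
                variant, True, RuleBranch.DATABASE_OVERRIDE, codes,
                rationale="MutationTaster not decisive; database/published support",
            )
        return PathogenicityCall(
            variant, False, RuleBranch.NOT_PATHOGENIC, codes,
            rationale="radical variant without MutationTaster support",
        )

    # Non protein-altering classes should not reach the engine; they are
    # never potentially pathogenic.
    return PathogenicityCall(
        variant, False, RuleBranch.NOT_PATHOGENIC, codes,
        rationale="consequence class outside the decision tree",
    )


@dataclass(frozen=True)
class ClassificationSummary:
    n_variants: int
    n_positive: int
    positives_by_consequence: dict[str, int]
    calls_by_branch: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "n_variants": self.n_variants,
            "n_positive": self.n_positive,
            "positives_by_consequence": dict(sorted(self.positives_by_consequence.items())),
            "calls_by_branch": dict(sorted(self.calls_by_branch.items())),
        }


def classify_cohort(
    rare: Sequence[AnnotatedVariant | Observation] | Iterable[AnnotatedVariant | Observation],
    ttn_map: Optional[TTNRegionMap],
) -> tuple[list[PathogenicityCall], ClassificationSummary]:
    """One call per rare variant (or observation), plus branch/type tallies."""
    calls: list[PathogenicityCall] = []
    by_cons: Counter = Counter()
    by_branch: Counter = Counter()
    for item in rare:
        variant = item.variant if isinstance(item, Observation) else item
        call = classify_variant(variant, ttn_map)
        calls.append(call)
        by_branch[call.branch.value] += 1
        if call.potentially_pathogenic:
            by_cons[variant.consequence.value] += 1
    summary = ClassificationSummary(
        n_variants=len(calls),
        n_positive=sum(1 for c in calls if c.potentially_pathogenic),
        positives_by_consequence=dict(by_cons),
        calls_by_branch=dict(by_branch),
    )
    return calls, summary
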