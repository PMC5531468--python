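"""Phenotype-specific rarity filtering.

A candidate call becomes a *rare variant* when it (i) alters the protein or a
canonical splice site, (ii) is supported by enough reads, and (iii) has a
minor allele frequency at or below a phenotype-specific ceiling chosen from
the population prevalence of each cardiomyopathy (DCM 0.4%, HCM 0.2%,
ARVC 0.05%). A variant absent from every population database counts as
frequency 0 and is retained.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .variant_model import (
    AnnotatedVariant,
    ConsequenceClass,
    Observation,
    Phenotype,
)

logger = logging.getLogger(__name__)

#: Consequence classes regarded as protein-altering for inclusion.
PROTEIN_ALTERING = frozenset(
    {
        ConsequenceClass.MISSENSE,
        ConsequenceClass.NONSENSE,
        ConsequenceClass.STOPLOSS,
        ConsequenceClass.CANONICAL_SPLICE,
        ConsequenceClass.FRAMESHIFT_INDEL,
        ConsequenceClass.INFRAME_INDEL,
    }
)


class MAFAggregation(str, Enum):
    """How per-database frequencies collapse to one number.

    max_across_sources: rare only if rare in *every* database (conservative,
    the default). min_across_sources: rare if rare in at least one.
    """

    MAX_ACROSS_SOURCES = "max_across_sources"
    MIN_ACROSS_SOURCES = "min_across_sources"


DEFAULT_THRESHOLDS = {
    Phenotype.DCM: 0.004,
    Phenotype.HCM: 0.002,
    Phenotype.ARVC: 0.0005,
}


@dataclass(frozen=True)
class MAFThresholdPolicy:
    per_phenotype: dict[Phenotype, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    min_depth: int = 10
    aggregation: MAFAggregation = MAFAggregation.MAX_ACROSS_SOURCES

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        for ph in Phenotype:
            thr = self.per_phenotype.get(ph)
            if thr is None:
                raise ValueError(f"no MAF threshold for phenotype {ph.value}")
            if not (0.0 < thr <= 1.0):
                raise ValueError(f"threshold for {ph.value} must be in (0,1]")

    def threshold(self, phenotype: Phenotype) -> float:
        return self.per_phenotype[phenotype]


@dataclass(frozen=True)
class FilterDecision:
    variant: AnnotatedVariant
    retained: bool
    failed_criteria: tuple[str, ...]  # subset of {"consequence","depth","maf"}

    def __post_init__(self) -> None:
        if self.retained != (len(self.failed_criteria) == 0):
            raise ValueError("retained iff failed_criteria empty")


def aggregated_maf(variant: AnnotatedVariant, aggregation: MAFAggregation) -> float:
    """Collapse per-source MAFs; absent from all databases counts as 0."""
    mafs = [f.maf for f in variant.frequencies if f.maf is not None]
    if not mafs:
        return 0.0
    if aggregation is MAFAggregation.MAX_ACROSS_SOURCES:
        return max(mafs)
    return min(mafs)


def passes_inclusion(
    variant: AnnotatedVariant,
    policy: MAFThresholdPolicy,
    phenotype: Optional[Phenotype],
) -> FilterDecision:
    """Evaluate the three inclusion criteria for one variant.

    The carrier phenotype is required because it fixes the MAF ceiling.
    """
    if phenotype is None:
        raise ValueError("carrier phenotype is required: MAF threshold undefined")
    failed: list[str] = []
    if variant.consequence not in PROTEIN_ALTERING:
        failed.append("consequence")
    if variant.depth < policy.min_depth:
        failed.append("depth")
    if aggregated_maf(variant, policy.aggregation) > policy.threshold(phenotype):
        failed.append("maf")
    return FilterDecision(variant=variant, retained=not failed,
                          failed_criteria=tuple(failed))


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_retained: int
    per_patient_input: dict[str, int]
    per_patient_retained: dict[str, int]
    failures_by_criterion: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "per_patient_input": dict(sorted(self.per_patient_input.items())),
            "per_patient_retained": dict(sorted(self.per_patient_retained.items())),
            "failures_by_criterion": dict(sorted(self.failures_by_criterion.items())),
        }


def filter_cohort(
    observations: Sequence[Observation] | Iterable[Observation],
    policy: MAFThresholdPolicy,
) -> tuple[list[Observation], FilterReport]:
    """Apply the inclusion criteria to a whole cohort.

    Returns the retained observations (the rare-variant set, input order
    preserved) plus a report whose counts partition the input exactly.
    """
    observations = list(observations)
    if not observations:
        logger.warning("filter_cohort called on an empty cohort")
    retained: list[Observation] = []
    per_in: Counter = Counter()
    per_kept: Counter = Counter()
    fail_counts: Counter = Counter()
    for obs in observations:
        per_in[obs.patient.patient_id] += 1
        decision = passes_inclusion(obs.variant, policy, obs.patient.phenotype)
        if decision.retained:
            retained.append(obs)
            per_kept[obs.patient.patient_id] += 1
        else:
            for crit in decision.failed_criteria:
                fail_counts[crit] += 1
    report = FilterReport(
        n_input=len(observations),
        n_retained=len(retained),
        per_patient_input=dict(per_in),
        per_patient_retained=dict(per_kept),
        failures_by_criterion=dict(fail_counts),
    )
    return retained, report
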