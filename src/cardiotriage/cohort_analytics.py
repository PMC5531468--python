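"""Cohort-level summaries over the rare-variant set and its classification.

Covers per-patient variant burden (zero-carriers included in denominators),
per-gene and per-type tallies, the seven-region phenotype-overlap partition
of genes (the count structure behind a three-set Venn diagram), and novel
gene-phenotype association detection against the panel's catalog of known
links.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .pathogenicity_engine import PathogenicityCall
from .variant_model import (
    AnnotatedVariant,
    AssociationCatalog,
    Observation,
    Patient,
    Phenotype,
)

logger = logging.getLogger(__name__)

#: The seven non-empty phenotype subsets, in report order.
OVERLAP_REGIONS: tuple[frozenset[Phenotype], ...] = (
    frozenset({Phenotype.DCM}),
    frozenset({Phenotype.HCM}),
    frozenset({Phenotype.ARVC}),
    frozenset({Phenotype.DCM, Phenotype.HCM}),
    frozenset({Phenotype.DCM, Phenotype.ARVC}),
    frozenset({Phenotype.HCM, Phenotype.ARVC}),
    frozenset({Phenotype.DCM, Phenotype.HCM, Phenotype.ARVC}),
)


def region_label(region: frozenset[Phenotype]) -> str:
    order = (Phenotype.DCM, Phenotype.HCM, Phenotype.ARVC)
    return "+".join(p.value for p in order if p in region)


@dataclass(frozen=True)
class BurdenSummary:
    per_patient: dict[str, int]
    mean: float
    range: tuple[int, int]
    per_phenotype_mean: dict[Phenotype, float]
    pp_per_patient: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "per_patient": dict(sorted(self.per_patient.items())),
            "mean": round(self.mean, 1),
            "range": list(self.range),
            "per_phenotype_mean": {
                ph.value: round(m, 1) for ph, m in sorted(
                    self.per_phenotype_mean.items(), key=lambda kv: kv[0].value
                )
            },
            "pp_per_patient": dict(sorted(self.pp_per_patient.items())),
        }


def burden_summary(
    roster: Sequence[Patient],
    rare_observations: Sequence[Observation],
    calls: Optional[Sequence[PathogenicityCall]] = None,
) -> BurdenSummary:
    """Rare-variant and potentially-pathogenic counts per patient.

    ``calls`` must align one-to-one with ``rare_observations`` when given.
    Patients with no rare variant contribute zeros (and stay in the mean's
    denominator). A carrier missing from the roster is an error.
    """
    if calls is not None and len(calls) != len(rare_observations):
        raise ValueError("calls must align one-to-one with rare observations")
    roster_ids = {p.patient_id for p in roster}
    if len(roster_ids) != len(roster):
        raise ValueError("duplicate patient_id in roster")
    per_patient = {p.patient_id: 0 for p in roster}
    pp_per_patient = {p.patient_id: 0 for p in roster}
    for i, obs in enumerate(rare_observations):
        pid = obs.patient.patient_id
        if pid not in roster_ids:
            raise ValueError(f"carrier {pid!r} not in roster")
        per_patient[pid] += 1
        if calls is not None and calls[i].potentially_pathogenic:
            pp_per_patient[pid] += 1
    n = len(roster)
    counts = list(per_patient.values())
    by_pheno: dict[Phenotype, list[int]] = defaultdict(list)
    for p in roster:
        by_pheno[p.phenotype].append(per_patient[p.patient_id])
    return BurdenSummary(
        per_patient=per_patient,
        mean=(sum(counts) / n) if n else 0.0,
        range=(min(counts), max(counts)) if counts else (0, 0),
        per_phenotype_mean={
            ph: sum(v) / len(v) for ph, v in by_pheno.items() if v
        },
        pp_per_patient=pp_per_patient,
    )


@dataclass(frozen=True)
class GeneTally:
    total: int
    per_phenotype: dict[Phenotype, int]
    per_type: dict[str, int]


def gene_tally(rare_observations: Iterable[Observation]) -> dict[str, GeneTally]:
    """Per-gene totals with phenotype and variant-type breakdowns, ordered by
    descending total (ties alphabetical) for direct use in reports."""
    totals: Counter = Counter()
    per_pheno: dict[str, Counter] = defaultdict(Counter)
    per_type: dict[str, Counter] = defaultdict(Counter)
    for obs in rare_observations:
        g = obs.variant.gene
        totals[g] += 1
        per_pheno[g][obs.patient.phenotype] += 1
        per_type[g][obs.variant.consequence.value] += 1
    ordered = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return {
        g: GeneTally(total=t, per_phenotype=dict(per_pheno[g]),
                     per_type=dict(per_type[g]))
        for g, t in ordered
    }


@dataclass(frozen=True)
class OverlapPartition:
    regions: dict[frozenset[Phenotype], frozenset[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for genes in self.regions.values():
            if seen & genes:
                raise ValueError("overlap regions must be pairwise disjoint")
            seen |= genes

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.regions.values():
            out |= genes
        return frozenset(out)

    def as_dict(self) -> dict:
        return {
            region_label(r): sorted(self.regions.get(r, frozenset()))
            for r in OVERLAP_REGIONS
        }


def phenotype_overlap(rare_observations: Iterable[Observation]) -> OverlapPartition:
    """Partition genes carrying rare variants by the exact set of phenotypes
    they were observed in."""
    pheno_sets: dict[str, set[Phenotype]] = defaultdict(set)
    for obs in rare_observations:
        pheno_sets[obs.variant.gene].add(obs.patient.phenotype)
    regions: dict[frozenset[Phenotype], set[str]] = {r: set() for r in OVERLAP_REGIONS}
    for gene, phenos in pheno_sets.items():
        regions[frozenset(phenos)].add(gene)
    return OverlapPartition(
        regions={r: frozenset(g) for r, g in regions.items()}
    )


@dataclass(frozen=True)
class NoveltyReport:
    novel_pairs: frozenset[tuple[str, Phenotype]]
    pp_novel_pairs: frozenset[tuple[str, Phenotype]]
    per_patient_novel: dict[str, bool]
    per_gene_novel_counts: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "novel_pairs": sorted((g, p.value) for g, p in self.novel_pairs),
            "pp_novel_pairs": sorted((g, p.value) for g, p in self.pp_novel_pairs),
            "per_patient_novel": dict(sorted(self.per_patient_novel.items())),
            "per_gene_novel_counts": dict(sorted(self.per_gene_novel_counts.items())),
            "n_patients_with_novel": sum(self.per_patient_novel.values()),
        }


def novel_associations(
    rare_observations: Sequence[Observation],
    calls: Optional[Sequence[PathogenicityCall]],
    catalog: AssociationCatalog,
    off_panel_is_novel: bool = False,
) -> NoveltyReport:
    """Gene-phenotype pairs observed in the rare set but absent from the
    catalog's cardiomyopathy tags.

    A channelopathy-only gene observed in any cardiomyopathy is by definition
    a novel pair. Genes outside the panel catalog trigger a warning and are
    counted novel only when ``off_panel_is_novel``. When ``calls`` is given
    (aligned with the observations), the report also restricts novelty to
    potentially pathogenic variants — always a subset of the full set.
    """
    if calls is not None and len(calls) != len(rare_observations):
        raise ValueError("calls must align one-to-one with rare observations")
    catalog_genes = catalog.genes()
    novel: set[tuple[str, Phenotype]] = set()
    pp_novel: set[tuple[str, Phenotype]] = set()
    per_patient: dict[str, bool] = {}
    per_gene: Counter = Counter()
    for i, obs in enumerate(rare_observations):
        gene, pheno = obs.variant.gene, obs.patient.phenotype
        pid = obs.patient.patient_id
        per_patient.setdefault(pid, False)
        if gene not in catalog_genes:
            logger.warning("gene %s absent from the panel catalog", gene)
            if not off_panel_is_novel:
                continue
            is_novel = True
        else:
            is_novel = not catalog.knows(gene, pheno)
        if is_novel:
            novel.add((gene, pheno))
            per_patient[pid] = True
            per_gene[gene] += 1
            if calls is not None and calls[i].potentially_pathogenic:
                pp_novel.add((gene, pheno))
    return NoveltyReport(
        novel_pairs=frozenset(novel),
        pp_novel_pairs=frozenset(pp_novel),
        per_patient_novel=per_patient,
        per_gene_novel_counts=dict(per_gene),
    )


def render_reports(
    roster: Sequence[Patient],
    rare_observations: Sequence[Observation],
    calls: Sequence[PathogenicityCall],
    catalog: Optional[AssociationCatalog] = None,
) -> dict:
    """Assemble the machine-readable report bundle (JSON-serialisable).

    The bundle mirrors the layouts of a per-variant evidence table, a
    per-patient genetic-profile table and the overlap/novelty count
    structure; an empty cohort yields an empty-but-valid bundle.
    """
    burden = burden_summary(roster, rare_observations, calls)
    tallies = gene_tally(rare_observations)
    overlap = phenotype_overlap(rare_observations)
    variant_rows = []
    for obs, call in zip(rare_observations, calls):
        v = obs.variant
        variant_rows.append(
            {
                "patient_id": obs.patient.patient_id,
                "phenotype": obs.patient.phenotype.value,
                "gene": v.gene,
                "genomic_position": f"chr{v.chrom}:{v.genomic_pos}",
                "transcript": v.transcript,
                "nucleotide": v.coding.raw if v.coding else ".",
                "protein": v.protein.raw if v.protein else ".",
                "potentially_pathogenic": call.potentially_pathogenic,
                "branch": call.branch.value,
                "supporting_evidences": call.evidence_string(),
            }
        )
    bundle = {
        "schema": "cardiotriage.report/1.0",
        "n_patients": len(roster),
        "n_rare_variants": len(rare_observations),
        "n_potentially_pathogenic": sum(
            1 for c in calls if c.potentially_pathogenic
        ),
        "variants": variant_rows,
        "burden": burden.as_dict(),
        "gene_tally": {
            g: {
                "total": t.total,
                "per_phenotype": {p.value: n for p, n in sorted(
                    t.per_phenotype.items(), key=lambda kv: kv[0].value)},
                "per_type": dict(sorted(t.per_type.items())),
            }
            for g, t in tallies.items()
        },
        "phenotype_overlap": overlap.as_dict(),
    }
    if catalog is not None:
        bundle["novel_associations"] = novel_associations(
            rare_observations, calls, catalog
        ).as_dict()
    return bundle
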