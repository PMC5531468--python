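"""Readers and writers for every file the pipeline touches.

One TSV dialect throughout: tab-separated, UTF-8, ``.`` for absent values,
``#``-prefixed header metadata (the first line embeds the schema name and
version). In MAF columns, ``NA`` means the database has a record for the
variant but reports no frequency (an rsID without a MAF), which is distinct
from ``.`` (no record at all). Outputs are byte-stable for a fixed input:
sorted keys, fixed float formatting, no timestamps.

VCF ingestion is a convenience adapter over the same in-memory model; the
TSV dialect is canonical.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import yaml

from .pathogenicity_engine import PathogenicityCall
from .rarity_filter import MAFAggregation, MAFThresholdPolicy
from .variant_model import (
    AnnotatedVariant,
    AssociationCatalog,
    ClinVarClass,
    ConservationProfile,
    DatabaseEvidence,
    FrequencyRecord,
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
    assign_zygosity,
    classify_consequence,
    parse_coding_change,
    parse_protein_change,
)

VARIANTS_SCHEMA = "cardiotriage.variants/1.0"
ROSTER_SCHEMA = "cardiotriage.roster/1.0"
CATALOG_SCHEMA = "cardiotriage.catalog/1.0"
CALLS_SCHEMA = "cardiotriage.calls/1.0"

_MAF_SOURCES = (("maf_gnomad", "gnomAD"), ("maf_1000g", "1000G"),
                ("maf_esp", "ESP"), ("maf_dbsnp", "dbSNP"))
_MAF_COLUMN_BY_SOURCE = {src: col for col, src in _MAF_SOURCES}

VARIANT_COLUMNS = (
    "patient_id", "phenotype", "sex", "gene", "transcript", "chrom", "pos",
    "ref", "alt", "cdna", "protein", "depth",
    "maf_gnomad", "maf_1000g", "maf_esp", "maf_dbsnp",
    "sift", "provean", "polyphen2", "mutation_taster",
    "phylop", "phastcons", "grantham",
    "clinvar_class", "clinvar_same_pheno", "hgmd_same_pheno",
    "published_support", "genotype",
)


class ValidationError(ValueError):
    """Input file fails schema or row validation."""


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return format(value, ".10g")
    return str(value)


def _parse_maf(text: str, column: str, line_no: int) -> Optional[float]:
    if "," in text:
        warnings.warn(
            f"line {line_no}: comma-decimal MAF {text!r} in {column} "
            "normalized to a dot",
            stacklevel=2,
        )
        text = text.replace(",", ".")
    try:
        return float(text)
    except ValueError as exc:
        raise ValidationError(
            f"line {line_no}: malformed MAF {text!r} in column {column}"
        ) from exc


def _parse_bool(text: str, column: str, line_no: int) -> bool:
    if text in ("1", "true", "True"):
        return True
    if text in ("0", "false", "False"):
        return False
    raise ValidationError(f"line {line_no}: bad boolean {text!r} in {column}")


def _genotype_for(zygosity: Zygosity) -> str:
    return {
        Zygosity.HETEROZYGOUS: "0/1",
        Zygosity.HOMOZYGOUS: "1/1",
        Zygosity.HEMIZYGOUS: "1",
        Zygosity.UNKNOWN: ".",
    }[zygosity]


def write_variant_table(path: Union[str, Path],
                        observations: Sequence[Observation]) -> None:
    lines = [f"# schema: {VARIANTS_SCHEMA}", "\t".join(VARIANT_COLUMNS)]
    for obs in observations:
        p, v = obs.patient, obs.variant
        mafs: dict[str, Optional[str]] = {col: "." for col, _ in _MAF_SOURCES}
        for rec in v.frequencies:
            col = _MAF_COLUMN_BY_SOURCE.get(rec.source)
            if col is None:
                raise ValidationError(f"no TSV column for MAF source {rec.source!r}")
            mafs[col] = "NA" if rec.maf is None else _fmt(rec.maf)
        row = [
            p.patient_id, p.phenotype.value, p.sex.value,
            v.gene, v.transcript, v.chrom, _fmt(v.genomic_pos),
            _fmt(v.ref), _fmt(v.alt),
            v.coding.raw if v.coding else ".",
            v.protein.raw if v.protein else ".",
            _fmt(v.depth),
            mafs["maf_gnomad"], mafs["maf_1000g"], mafs["maf_esp"],
            mafs["maf_dbsnp"],
            "." if v.predictors.sift is SiftCall.ABSENT else v.predictors.sift.value,
            "." if v.predictors.provean is ProveanCall.ABSENT
            else v.predictors.provean.value,
            "." if v.predictors.polyphen2 is PolyPhenCall.ABSENT
            else v.predictors.polyphen2.value,
            "." if v.predictors.mutation_taster is MutationTasterCall.ABSENT
            else v.predictors.mutation_taster.value,
            _fmt(v.conservation.phylop), _fmt(v.conservation.phastcons),
            _fmt(v.conservation.grantham),
            "." if v.evidence.clinvar_class is ClinVarClass.ABSENT
            else v.evidence.clinvar_class.value,
            _fmt(v.evidence.clinvar_same_phenotype),
            _fmt(v.evidence.hgmd_same_phenotype),
            _fmt(v.evidence.published_support),
            _genotype_for(v.zygosity),
        ]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _enum_or(enum_cls, text: str, absent, column: str, line_no: int):
    if text == ".":
        return absent
    try:
        return enum_cls(text)
    except ValueError as exc:
        raise ValidationError(
            f"line {line_no}: bad value {text!r} in column {column}"
        ) from exc


def read_variant_table(path: Union[str, Path]) -> list[Observation]:
    """Parse the canonical annotated-variant TSV; strict about columns."""
    text = Path(path).read_text(encoding="utf-8")
    header: Optional[list[str]] = None
    observations: list[Observation] = []
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            unknown = [c for c in header if c not in VARIANT_COLUMNS]
            if unknown:
                raise ValidationError(f"unknown column(s): {', '.join(unknown)}")
            missing = [c for c in VARIANT_COLUMNS if c not in header]
            if missing:
                raise ValidationError(f"missing column(s): {', '.join(missing)}")
            continue
        if len(fields) != len(header):
            raise ValidationError(
                f"line {line_no}: expected {len(header)} fields, got {len(fields)}"
            )
        row = dict(zip(header, fields))
        try:
            patient = Patient(
                patient_id=row["patient_id"],
                phenotype=Phenotype(row["phenotype"]),
                sex=_enum_or(Sex, row["sex"], Sex.UNKNOWN, "sex", line_no),
            )
        except ValueError as exc:
            raise ValidationError(f"line {line_no}: {exc}") from exc
        freqs: list[FrequencyRecord] = []
        for col, source in _MAF_SOURCES:
            cell = row[col]
            if cell == ".":
                continue
            if cell == "NA":
                freqs.append(FrequencyRecord(source=source, maf=None))
            else:
                freqs.append(
                    FrequencyRecord(source=source,
                                    maf=_parse_maf(cell, col, line_no))
                )
        protein = (parse_protein_change(row["protein"])
                   if row["protein"] != "." else None)
        coding = parse_coding_change(row["cdna"]) if row["cdna"] != "." else None
        try:
            variant = AnnotatedVariant(
                gene=row["gene"], transcript=row["transcript"],
                chrom=row["chrom"], genomic_pos=int(row["pos"]),
                coding=coding, protein=protein,
                consequence=classify_consequence(protein, coding),
                ref=None if row["ref"] == "." else row["ref"],
                alt=None if row["alt"] == "." else row["alt"],
                depth=int(row["depth"]),
                frequencies=tuple(freqs),
                predictors=PredictorProfile(
                    sift=_enum_or(SiftCall, row["sift"], SiftCall.ABSENT,
                                  "sift", line_no),
                    provean=_enum_or(ProveanCall, row["provean"],
                                     ProveanCall.ABSENT, "provean", line_no),
                    polyphen2=_enum_or(PolyPhenCall, row["polyphen2"],
                                       PolyPhenCall.ABSENT, "polyphen2", line_no),
                    mutation_taster=_enum_or(
                        MutationTasterCall, row["mutation_taster"],
                        MutationTasterCall.ABSENT, "mutation_taster", line_no),
                ),
                conservation=ConservationProfile(
                    phylop=None if row["phylop"] == "." else float(row["phylop"]),
                    phastcons=None if row["phastcons"] == "."
                    else float(row["phastcons"]),
                    grantham=None if row["grantham"] == "."
                    else int(float(row["grantham"])),
                ),
                evidence=DatabaseEvidence(
                    clinvar_class=_enum_or(
                        ClinVarClass, row["clinvar_class"], ClinVarClass.ABSENT,
                        "clinvar_class", line_no),
                    clinvar_same_phenotype=_parse_bool(
                        row["clinvar_same_pheno"], "clinvar_same_pheno", line_no),
                    hgmd_same_phenotype=_parse_bool(
                        row["hgmd_same_pheno"], "hgmd_same_pheno", line_no),
                    published_support=_parse_bool(
                        row["published_support"], "published_support", line_no),
                ),
                zygosity=assign_zygosity(row["chrom"], patient.sex,
                                         row["genotype"]),
            )
        except ValidationError:
            raise
        except (ValueError, KeyError) as exc:
            raise ValidationError(f"line {line_no}: {exc}") from exc
        observations.append(Observation(patient=patient, variant=variant))
    if header is None:
        raise ValidationError(f"{path}: no header row found")
    return observations


# --- roster / catalog -------------------------------------------------------


def write_roster(path: Union[str, Path], roster: Sequence[Patient]) -> None:
    lines = [f"# schema: {ROSTER_SCHEMA}", "patient_id\tphenotype\tsex"]
    for p in roster:
        lines.append(f"{p.patient_id}\t{p.phenotype.value}\t{p.sex.value}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_roster(path: Union[str, Path]) -> list[Patient]:
    roster: list[Patient] = []
    seen: set[str] = set()
    for line_no, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#") or line.startswith("patient_id"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValidationError(f"line {line_no}: roster rows need 3 fields")
        pid, pheno, sex = parts
        if pid in seen:
            raise ValidationError(f"line {line_no}: duplicate patient {pid!r}")
        seen.add(pid)
        try:
            roster.append(Patient(pid, Phenotype(pheno), Sex(sex)))
        except ValueError as exc:
            raise ValidationError(f"line {line_no}: {exc}") from exc
    return roster


def write_catalog(path: Union[str, Path], catalog: AssociationCatalog) -> None:
    lines = [f"# schema: {CATALOG_SCHEMA}"]
    by_gene: dict[str, list[str]] = {}
    for gene, tag in catalog.entries:
        by_gene.setdefault(gene, []).append(tag)
    for gene in sorted(by_gene):
        lines.append(f"{gene}\t{','.join(sorted(by_gene[gene]))}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_catalog(path: Union[str, Path]) -> AssociationCatalog:
    entries: set[tuple[str, str]] = set()
    for line_no, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"line {line_no}: catalog rows need 2 fields")
        gene, tags = parts
        for tag in tags.split(","):
            entries.add((gene, tag.strip()))
    try:
        return AssociationCatalog(entries=frozenset(entries))
    except ValueError as exc:
        raise ValidationError(str(exc)) from exc


# --- policy -----------------------------------------------------------------


def _parse_rate(value) -> float:
    """Accept 0.004, "0.004", "0.4%" and the decimal-comma form "0,4%"."""
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip().replace(",", ".")
    if text.endswith("%"):
        return float(text[:-1]) / 100.0
    return float(text)


def read_policy(path: Union[str, Path]) -> MAFThresholdPolicy:
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh) or {}
    thresholds = {
        Phenotype(ph): _parse_rate(v)
        for ph, v in (payload.get("maf_thresholds") or {}).items()
    }
    kwargs = {}
    if thresholds:
        kwargs["per_phenotype"] = thresholds
    if "min_depth" in payload:
        kwargs["min_depth"] = int(payload["min_depth"])
    if "aggregation" in payload:
        kwargs["aggregation"] = MAFAggregation(payload["aggregation"])
    try:
        return MAFThresholdPolicy(**kwargs)
    except ValueError as exc:
        raise ValidationError(str(exc)) from exc


def write_policy(path: Union[str, Path], policy: MAFThresholdPolicy) -> None:
    payload = {
        "maf_thresholds": {ph.value: float(thr)
                           for ph, thr in sorted(policy.per_phenotype.items(),
                                                 key=lambda kv: kv[0].value)},
        "min_depth": policy.min_depth,
        "aggregation": policy.aggregation.value,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


# --- calls / reports --------------------------------------------------------


def write_calls(path: Union[str, Path],
                observations: Sequence[Observation],
                calls: Sequence[PathogenicityCall]) -> None:
    if len(observations) != len(calls):
        raise ValueError("observations and calls must align")
    cols = ("patient_id", "phenotype", "gene", "chrom", "pos", "cdna",
            "protein", "potentially_pathogenic", "branch", "evidence_codes")
    lines = [f"# schema: {CALLS_SCHEMA}", "\t".join(cols)]
    for obs, call in zip(observations, calls):
        v = obs.variant
        lines.append("\t".join([
            obs.patient.patient_id, obs.patient.phenotype.value,
            v.gene, v.chrom, str(v.genomic_pos),
            v.coding.raw if v.coding else ".",
            v.protein.raw if v.protein else ".",
            "1" if call.potentially_pathogenic else "0",
            call.branch.value,
            call.evidence_string() or ".",
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_report_bundle(directory: Union[str, Path], bundle: dict) -> Path:
    """Write the JSON report; returns the report path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = directory / "report.json"
    with open(out, "w", encoding="utf-8") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def read_report_bundle(path: Union[str, Path]) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


# --- VCF ingestion ----------------------------------------------------------

DEFAULT_INFO_KEYS = {
    "gene": "GENE", "transcript": "TRANSCRIPT", "cdna": "CDNA",
    "protein": "PROTEIN", "sift": "SIFT", "provean": "PROVEAN",
    "polyphen2": "PP2", "mutation_taster": "MT",
    "phylop": "PHYLOP", "phastcons": "PHASTCONS", "grantham": "GRANTHAM",
    "clinvar_class": "CLNCLASS", "clinvar_same_pheno": "CLNSAMEPHENO",
    "hgmd_same_pheno": "HGMDSAMEPHENO", "published_support": "PUBLISHED",
    "maf_gnomad": "MAF_GNOMAD", "maf_1000g": "MAF_1000G",
    "maf_esp": "MAF_ESP", "maf_dbsnp": "MAF_DBSNP",
}


def _info_get(record, key: Optional[str], alt_index: int, n_alt: int):
    if key is None:
        return None
    value = record.INFO.get(key)
    if value is None:
        return None
    if isinstance(value, tuple):
        return value[alt_index] if len(value) == n_alt else value[0]
    if isinstance(value, str) and "," in value and n_alt > 1:
        parts = value.split(",")
        return parts[alt_index] if len(parts) == n_alt else value
    return value


def read_vcf(path: Union[str, Path], patient: Patient,
             info_key_map: Optional[dict] = None) -> list[Observation]:
    """Ingest a single-patient VCF 4.x with annotations in INFO keys.

    Multi-allelic records are split, each alternate allele becoming its own
    variant. A missing mapped INFO key yields an absent annotation, never an
    error; variants lacking predictor keys will later simply fail consensus.
    """
    from cyvcf2 import VCF  # deferred: only VCF users need the binding

    keys = dict(DEFAULT_INFO_KEYS)
    if info_key_map:
        keys.update(info_key_map)
    observations: list[Observation] = []
    vcf = VCF(str(path))
    for record in vcf:
        alts = record.ALT or []
        n_alt = len(alts)
        for i, alt in enumerate(alts):
            def g(field):  # noqa: B023 - bound per iteration below
                return _info_get(record, keys.get(field), i, n_alt)

            protein_raw = g("protein")
            cdna_raw = g("cdna")
            protein = parse_protein_change(str(protein_raw)) if protein_raw else None
            coding = parse_coding_change(str(cdna_raw)) if cdna_raw else None
            freqs: list[FrequencyRecord] = []
            for col, source in _MAF_SOURCES:
                val = g(col)
                if val is not None:
                    freqs.append(FrequencyRecord(source=source, maf=float(val)))
            depth = record.INFO.get("DP")
            gt = "0/1"
            if len(record.genotypes) == 1:
                alleles = record.genotypes[0][:-1]
                gt = "/".join(str(a) for a in alleles)

            def enum_of(enum_cls, field, absent):
                val = g(field)
                if val is None:
                    return absent
                try:
                    return enum_cls(str(val))
                except ValueError:
                    return absent

            variant = AnnotatedVariant(
                gene=str(g("gene") or "."),
                transcript=str(g("transcript") or "."),
                chrom=str(record.CHROM),
                genomic_pos=int(record.POS),
                coding=coding, protein=protein,
                consequence=classify_consequence(protein, coding),
                ref=str(record.REF), alt=str(alt),
                depth=int(depth) if depth is not None else 0,
                frequencies=tuple(freqs),
                predictors=PredictorProfile(
                    sift=enum_of(SiftCall, "sift", SiftCall.ABSENT),
                    provean=enum_of(ProveanCall, "provean", ProveanCall.ABSENT),
                    polyphen2=enum_of(PolyPhenCall, "polyphen2",
                                      PolyPhenCall.ABSENT),
                    mutation_taster=enum_of(MutationTasterCall, "mutation_taster",
                                            MutationTasterCall.ABSENT),
                ),
                conservation=ConservationProfile(
                    phylop=(float(g("phylop"))
                            if g("phylop") is not None else None),
                    phastcons=(float(g("phastcons"))
                               if g("phastcons") is not None else None),
                    grantham=(int(float(g("grantham")))
                              if g("grantham") is not None else None),
                ),
                evidence=DatabaseEvidence(
                    clinvar_class=enum_of(ClinVarClass, "clinvar_class",
                                          ClinVarClass.ABSENT),
                    clinvar_same_phenotype=bool(g("clinvar_same_pheno")),
                    hgmd_same_phenotype=bool(g("hgmd_same_pheno")),
                    published_support=bool(g("published_support")),
                ),
                zygosity=assign_zygosity(str(record.CHROM), patient.sex, gt),
            )
            observations.append(Observation(patient=patient, variant=variant))
    return observations
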