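"""Domain types for annotated variants, patients and gene panels.

The vocabulary follows targeted-resequencing practice for cardiomyopathy
panels: each observed variant carries short-form HGVS-like protein and cDNA
tokens (``S236F``, ``c.506-2A>C``), per-database minor allele frequencies,
in-silico predictor verdicts (SIFT, PROVEAN, PolyPhen-2, MutationTaster),
conservation scores (PhyloP, PhastCons, Grantham) and ClinVar/HGMD evidence.
Annotations are trusted inputs; nothing here re-annotates or validates
against reference sequences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Phenotype(str, Enum):
    """The three cardiomyopathy phenotypes of the cohort."""

    DCM = "DCM"
    HCM = "HCM"
    ARVC = "ARVC"


class Sex(str, Enum):
    M = "M"
    F = "F"
    UNKNOWN = "unknown"


class ProteinChangeKind(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    STOPLOSS = "stoploss"
    FRAMESHIFT = "frameshift"
    INFRAME_DEL = "inframe_del"
    INFRAME_INS = "inframe_ins"
    INFRAME_DUP = "inframe_dup"
    UNKNOWN = "unknown"


class ConsequenceClass(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    STOPLOSS = "stoploss"
    CANONICAL_SPLICE = "canonical_splice"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    OTHER = "other"


class Zygosity(str, Enum):
    HETEROZYGOUS = "heterozygous"
    HEMIZYGOUS = "hemizygous"
    HOMOZYGOUS = "homozygous"
    UNKNOWN = "unknown"


class SiftCall(str, Enum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    ABSENT = "absent"


class ProveanCall(str, Enum):
    DELETERIOUS = "deleterious"
    NEUTRAL = "neutral"
    ABSENT = "absent"


class PolyPhenCall(str, Enum):
    PROBABLY_DAMAGING = "probably_damaging"
    POSSIBLY_DAMAGING = "possibly_damaging"
    BENIGN = "benign"
    ABSENT = "absent"


class MutationTasterCall(str, Enum):
    DISEASE_CAUSING = "disease_causing"
    POLYMORPHISM = "polymorphism"
    ABSENT = "absent"


class ClinVarClass(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    ABSENT = "absent"


#: ClinVar classes that demote a variant out of the potentially-pathogenic label.
DEMOTING_CLINVAR = frozenset(
    {ClinVarClass.VUS, ClinVarClass.LIKELY_BENIGN, ClinVarClass.BENIGN}
)


@dataclass(frozen=True)
class Patient:
    patient_id: str
    phenotype: Phenotype
    sex: Sex = Sex.UNKNOWN


# --- protein / cDNA token parsing ------------------------------------------

_STOP = {"X", "*", "Ter"}

_RE_FS = re.compile(r"^([A-Z])(\d+)([A-Z]*)fs(?:[X*]\d*)?$")
_RE_RANGE = re.compile(r"^([A-Z])(\d+)_([A-Z])(\d+)(del|dup|ins)([A-Z]*)$")
_RE_SINGLE_INDEL = re.compile(r"^([A-Z])(\d+)(del|dup)$")
_RE_SUBST = re.compile(r"^([A-Z*])(\d+)([A-Z*]|Ter)$")


@dataclass(frozen=True)
class ProteinChange:
    """A parsed short-form protein-change token (``V508fs``, ``L140_A146dup``)."""

    raw: str
    kind: ProteinChangeKind
    position: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    end_aa: Optional[str] = None
    end_position: Optional[int] = None
    op: Optional[str] = None  # del / dup / ins for indels
    inserted: Optional[str] = None
    fs_suffix: Optional[str] = None  # e.g. "GfsX11" tail after the position

    def format(self) -> str:
        """Rebuild the canonical token from the parsed components."""
        k = self.kind
        if k in (ProteinChangeKind.MISSENSE, ProteinChangeKind.NONSENSE,
                 ProteinChangeKind.STOPLOSS):
            return f"{self.ref_aa}{self.position}{self.alt_aa}"
        if k is ProteinChangeKind.FRAMESHIFT:
            return f"{self.ref_aa}{self.position}{self.fs_suffix}"
        if k in (ProteinChangeKind.INFRAME_DEL, ProteinChangeKind.INFRAME_DUP,
                 ProteinChangeKind.INFRAME_INS):
            if self.end_position is not None:
                tail = self.inserted or ""
                return (f"{self.ref_aa}{self.position}_{self.end_aa}"
                        f"{self.end_position}{self.op}{tail}")
            return f"{self.ref_aa}{self.position}{self.op}"
        return self.raw


def parse_protein_change(raw: str) -> ProteinChange:
    """Parse a short-form protein token; unparseable input yields kind=unknown.

    A same-residue substitution (``A100A``, i.e. synonymous) is deliberately
    *unknown*: it is not an amino-acid change and is dropped downstream.
    """
    token = raw.strip()
    if not token:
        return ProteinChange(raw=raw, kind=ProteinChangeKind.UNKNOWN)

    m = _RE_FS.match(token)
    if m:
        ref, pos, _mid = m.groups()
        suffix = token[len(ref) + len(pos):]
        return ProteinChange(raw=token, kind=ProteinChangeKind.FRAMESHIFT,
                             position=int(pos), ref_aa=ref, fs_suffix=suffix)

    m = _RE_RANGE.match(token)
    if m:
        ref, pos, end_aa, end_pos, op, ins = m.groups()
        kind = {"del": ProteinChangeKind.INFRAME_DEL,
                "dup": ProteinChangeKind.INFRAME_DUP,
                "ins": ProteinChangeKind.INFRAME_INS}[op]
        return ProteinChange(raw=token, kind=kind, position=int(pos),
                             ref_aa=ref, end_aa=end_aa,
                             end_position=int(end_pos), op=op,
                             inserted=ins or None)

    m = _RE_SINGLE_INDEL.match(token)
    if m:
        ref, pos, op = m.groups()
        kind = {"del": ProteinChangeKind.INFRAME_DEL,
                "dup": ProteinChangeKind.INFRAME_DUP}[op]
        return ProteinChange(raw=token, kind=kind, position=int(pos),
                             ref_aa=ref, op=op)

    m = _RE_SUBST.match(token)
    if m:
        ref, pos, alt = m.groups()
        if alt in _STOP and ref not in _STOP:
            kind = ProteinChangeKind.NONSENSE
        elif ref in _STOP and alt not in _STOP:
            kind = ProteinChangeKind.STOPLOSS
        elif ref == alt or (ref in _STOP and alt in _STOP):
            kind = ProteinChangeKind.UNKNOWN
        else:
            kind = ProteinChangeKind.MISSENSE
        if kind is ProteinChangeKind.UNKNOWN:
            return ProteinChange(raw=token, kind=kind)
        return ProteinChange(raw=token, kind=kind, position=int(pos),
                             ref_aa=ref, alt_aa=alt)

    return ProteinChange(raw=token, kind=ProteinChangeKind.UNKNOWN)


_RE_SPLICE_OFFSET = re.compile(r"^c\.[\d_*]*?(\d+)([+-]\d+)")


@dataclass(frozen=True)
class CodingChange:
    """A cDNA-level token; splice_offset is the intronic offset, if any."""

    raw: str
    splice_offset: Optional[int] = None

    @property
    def is_canonical_splice(self) -> bool:
        return self.splice_offset is not None and abs(self.splice_offset) <= 2


def parse_coding_change(raw: str) -> CodingChange:
    token = raw.strip()
    m = _RE_SPLICE_OFFSET.match(token)
    offset = int(m.group(2)) if m else None
    return CodingChange(raw=token, splice_offset=offset)


_KIND_TO_CONSEQUENCE = {
    ProteinChangeKind.MISSENSE: ConsequenceClass.MISSENSE,
    ProteinChangeKind.NONSENSE: ConsequenceClass.NONSENSE,
    ProteinChangeKind.STOPLOSS: ConsequenceClass.STOPLOSS,
    ProteinChangeKind.FRAMESHIFT: ConsequenceClass.FRAMESHIFT_INDEL,
    ProteinChangeKind.INFRAME_DEL: ConsequenceClass.INFRAME_INDEL,
    ProteinChangeKind.INFRAME_INS: ConsequenceClass.INFRAME_INDEL,
    ProteinChangeKind.INFRAME_DUP: ConsequenceClass.INFRAME_INDEL,
}


def classify_consequence(
    protein: Optional[ProteinChange], coding: Optional[CodingChange]
) -> ConsequenceClass:
    """Total mapping to a single consequence class.

    The protein-level kind takes precedence when informative; otherwise a
    coding change within +-2 of an exon boundary is a canonical splice-site
    change; everything else (synonymous, deep intronic, UTR) is ``other``.
    Note a frameshift that ends in a stop ("V321GfsX11") stays
    frameshift_indel, not nonsense.
    """
    if protein is not None and protein.kind is not ProteinChangeKind.UNKNOWN:
        return _KIND_TO_CONSEQUENCE[protein.kind]
    if coding is not None and coding.is_canonical_splice:
        return ConsequenceClass.CANONICAL_SPLICE
    return ConsequenceClass.OTHER


def normalize_chrom(chrom: str) -> str:
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper()


def assign_zygosity(chrom: str, patient_sex: Sex, raw_genotype: str) -> Zygosity:
    """Zygosity from chromosome, carrier sex and a GT-like genotype string.

    X-chromosome variants in males are hemizygous; an X variant with unknown
    carrier sex is flagged unknown rather than raising.
    """
    c = normalize_chrom(chrom)
    alleles = [a for a in re.split(r"[/|]", raw_genotype.strip()) if a not in ("", ".")]
    alt_alleles = [a for a in alleles if a != "0"]
    if c == "X":
        if patient_sex is Sex.M:
            return Zygosity.HEMIZYGOUS
        if patient_sex is Sex.UNKNOWN:
            return Zygosity.UNKNOWN
    if len(alt_alleles) >= 2 and len(set(alt_alleles)) == 1:
        return Zygosity.HOMOZYGOUS
    if alt_alleles:
        return Zygosity.HETEROZYGOUS
    return Zygosity.UNKNOWN


# --- annotation bundles -----------------------------------------------------


@dataclass(frozen=True)
class FrequencyRecord:
    """MAF in one population database, on the 0-1 scale; None = record exists
    (e.g. an rsID) but no frequency is reported there."""

    source: str
    maf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"MAF out of [0,1]: {self.maf!r} ({self.source})")


@dataclass(frozen=True)
class PredictorProfile:
    sift: SiftCall = SiftCall.ABSENT
    provean: ProveanCall = ProveanCall.ABSENT
    polyphen2: PolyPhenCall = PolyPhenCall.ABSENT
    mutation_taster: MutationTasterCall = MutationTasterCall.ABSENT


@dataclass(frozen=True)
class ConservationProfile:
    phylop: Optional[float] = None
    phastcons: Optional[float] = None
    grantham: Optional[int] = None  # missense only

    def __post_init__(self) -> None:
        if self.phastcons is not None and not (0.0 <= self.phastcons <= 1.0):
            raise ValueError(f"PhastCons out of [0,1]: {self.phastcons!r}")
        if self.grantham is not None and self.grantham < 0:
            raise ValueError("Grantham score must be >= 0")


@dataclass(frozen=True)
class DatabaseEvidence:
    clinvar_class: ClinVarClass = ClinVarClass.ABSENT
    clinvar_same_phenotype: bool = False
    hgmd_same_phenotype: bool = False
    published_support: bool = False


@dataclass(frozen=True)
class AnnotatedVariant:
    """One observed variant with its full annotation bundle."""

    gene: str
    transcript: str
    chrom: str
    genomic_pos: int
    coding: Optional[CodingChange] = None
    protein: Optional[ProteinChange] = None
    consequence: ConsequenceClass = ConsequenceClass.OTHER
    ref: Optional[str] = None
    alt: Optional[str] = None
    depth: int = 0
    frequencies: tuple[FrequencyRecord, ...] = ()
    predictors: PredictorProfile = field(default_factory=PredictorProfile)
    conservation: ConservationProfile = field(default_factory=ConservationProfile)
    evidence: DatabaseEvidence = field(default_factory=DatabaseEvidence)
    zygosity: Zygosity = Zygosity.UNKNOWN

    def __post_init__(self) -> None:
        if self.genomic_pos < 1:
            raise ValueError("genomic_pos is 1-based (must be >= 1)")
        if self.depth < 0:
            raise ValueError("read depth is a count")

    @property
    def key(self) -> tuple[str, str, int, str]:
        cd = self.coding.raw if self.coding else "."
        return (self.gene, self.chrom, self.genomic_pos, cd)


@dataclass(frozen=True)
class Observation:
    """A variant observed in one carrier (one TSV row)."""

    patient: Patient
    variant: AnnotatedVariant


@dataclass(frozen=True)
class AssociationCatalog:
    """Known gene -> phenotype/channelopathy links (the panel's prior)."""

    entries: frozenset[tuple[str, str]]  # (gene, tag); tag in DCM/HCM/ARVC/channelopathy

    VALID_TAGS = frozenset({"DCM", "HCM", "ARVC", "channelopathy"})

    def __post_init__(self) -> None:
        bad = {t for _, t in self.entries if t not in self.VALID_TAGS}
        if bad:
            raise ValueError(f"unknown association tags: {sorted(bad)}")

    def genes(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.entries)

    def tags_for(self, gene: str) -> frozenset[str]:
        return frozenset(t for g, t in self.entries if g == gene)

    def knows(self, gene: str, phenotype: Phenotype) -> bool:
        return (gene, phenotype.value) in self.entries


@dataclass(frozen=True)
class GenePanel:
    genes: frozenset[str]
    catalog: AssociationCatalog

    def __post_init__(self) -> None:
        orphan = self.catalog.genes() - self.genes
        if orphan:
            raise ValueError(f"catalog genes outside the panel: {sorted(orphan)}")
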