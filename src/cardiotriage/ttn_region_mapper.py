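"""Sarcomeric band mapping for titin (TTN) truncating variants.

Titin spans half a sarcomere; its protein sequence is conventionally divided
into Z-disc, I-band, A-band and M-band regions, and truncating variants are
believed potentially pathogenic only when they fall in the A-band in a
region shared by all titin isoforms. Band boundaries differ per transcript:
the cardiac N2B isoform (NM_003319) contains all four bands, while the short
novex-3 isoform (NM_133379) terminates within the I-band and never reaches
the A-band.

The region map is data, not code: a versioned YAML file gives, per
transcript, an ordered gap-free list of 1-based inclusive residue intervals,
each labelled with a band and an ``shared_all_isoforms`` flag marking the
portion shared by every isoform considered. The rule logic is independent of
the particular boundary numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Union

import yaml

from .variant_model import AnnotatedVariant

BANDS = ("Z", "I", "A", "M")


@dataclass(frozen=True)
class BandInterval:
    band: str
    start: int
    end: int  # inclusive
    shared_all_isoforms: bool = False

    def __post_init__(self) -> None:
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}; expected one of {BANDS}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end}]")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class BandAssignment:
    transcript: str
    position: int
    band: str
    shared_all_isoforms: bool


@dataclass(frozen=True)
class TTNRegionMap:
    transcripts: dict[str, tuple[BandInterval, ...]]
    isoform_set: frozenset[str]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError("region map has no transcripts")
        for acc, intervals in self.transcripts.items():
            if not intervals:
                raise ValueError(f"{acc}: empty interval list")
            if intervals[0].start != 1:
                raise ValueError(f"{acc}: coverage must start at residue 1")
            for prev, cur in zip(intervals, intervals[1:]):
                if cur.start != prev.end + 1:
                    raise ValueError(
                        f"{acc}: intervals must be ascending and gap-free "
                        f"({prev.end} -> {cur.start})"
                    )
        missing = self.isoform_set - set(self.transcripts)
        if missing:
            raise ValueError(f"isoform_set accessions not in map: {sorted(missing)}")

    def length(self, transcript: str) -> int:
        return self.transcripts[transcript][-1].end


def band_of(
    position: int, transcript: str, region_map: TTNRegionMap
) -> BandAssignment:
    """Unique band for a residue of one transcript; out-of-range raises."""
    if transcript not in region_map.transcripts:
        raise KeyError(f"transcript {transcript} not in the region map")
    if position < 1:
        raise ValueError("protein positions are 1-based")
    for interval in region_map.transcripts[transcript]:
        if position in interval:
            return BandAssignment(
                transcript=transcript,
                position=position,
                band=interval.band,
                shared_all_isoforms=interval.shared_all_isoforms,
            )
    raise ValueError(
        f"residue {position} beyond {transcript} "
        f"(length {region_map.length(transcript)})"
    )


def ttn_truncating_potentially_pathogenic(
    variant: AnnotatedVariant, region_map: TTNRegionMap
) -> tuple[bool, str]:
    """A-band test for a TTN truncating variant.

    Positive iff the affected residue maps to the A-band of the variant's own
    transcript AND lies in the region marked as shared by every isoform in
    the map's isoform set. Which transcripts constitute "all isoforms" is a
    property of the map, not of the rule; the rationale spells out both
    sub-tests so the configured choice is visible in the trace.
    """
    if variant.gene != "TTN":
        raise ValueError("A-band rule applies to TTN variants only")
    if variant.protein is None or variant.protein.position is None:
        return False, "no protein position available; A-band test not evaluable"
    assignment = band_of(variant.protein.position, variant.transcript, region_map)
    in_a = assignment.band == "A"
    shared = assignment.shared_all_isoforms
    why = (
        f"residue {assignment.position} on {assignment.transcript}: "
        f"band={assignment.band} (A-band test {'passed' if in_a else 'failed'}); "
        f"shared-by-all-isoforms ({sorted(region_map.isoform_set)}) "
        f"{'passed' if shared else 'failed'}"
    )
    return in_a and shared, why


def region_map_from_dict(payload: dict) -> TTNRegionMap:
    try:
        raw_transcripts = payload["transcripts"]
        isoforms = payload.get("isoforms_considered_all", [])
    except (TypeError, KeyError) as exc:
        raise ValueError(f"malformed region map payload: {exc}") from exc
    transcripts = {
        acc: tuple(
            BandInterval(
                band=str(entry["band"]),
                start=int(entry["start"]),
                end=int(entry["end"]),
                shared_all_isoforms=bool(entry.get("shared_all_isoforms", False)),
            )
            for entry in entries
        )
        for acc, entries in raw_transcripts.items()
    }
    return TTNRegionMap(
        transcripts=transcripts, isoform_set=frozenset(str(a) for a in isoforms)
    )


def load_region_map(path: Union[str, "object"]) -> TTNRegionMap:
    """Load and validate a region-map YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    return region_map_from_dict(payload)


def load_default_map() -> TTNRegionMap:
    """The bundled study map (approximate public-annotation boundaries)."""
    ref = resources.files("cardiotriage.data").joinpath("ttn_regions.yaml")
    payload = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return region_map_from_dict(payload)
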