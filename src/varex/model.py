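"""Core domain objects shared across the package.

A multi-sample annotated VCF is decomposed into one :class:`VariantDocument`
per alternate allele.  Each document carries flat site-level attributes
(INFO / Annovar key=value pairs), a nested list of per-transcript annotation
maps (VEP CSQ), and a *sparse* list of per-sample genotype entries: samples
that are homozygous-reference are represented by absence, so a missing
genotype must be stored explicitly to remain distinguishable from hom-ref.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any


class GtClass(str, enum.Enum):
    """Genotype class of one sample with respect to one alternate allele."""

    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    MISSING = "MISSING"
    OTHER = "OTHER"


# Canonical contig ordering: numeric contigs first, then X, Y, MT, then
# anything else lexicographically.  "chr" prefixes are ignored for ranking.
_SPECIAL_CONTIGS = {"X": 23, "Y": 24, "MT": 25, "M": 25}


def contig_rank(chrom: str) -> tuple[int, str]:
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (int(name), "")
    if name.upper() in _SPECIAL_CONTIGS:
        return (_SPECIAL_CONTIGS[name.upper()], "")
    return (100, name)


@dataclass(frozen=True)
class VariantKey:
    """One alternate allele at one site, 1-based coordinates as in the VCF."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical: {self.ref}")

    def sort_token(self) -> tuple:
        return (*contig_rank(self.chrom), self.pos, self.ref, self.alt)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def from_string(cls, s: str) -> "VariantKey":
        chrom, pos, ref, alt = s.split(":")
        return cls(chrom, int(pos), ref, alt)


@dataclass
class SampleGenotypeEntry:
    """Sparse per-sample genotype record.

    ``gt_raw`` is the verbatim GT string from the VCF (phasing preserved);
    ``gt_class`` is computed against the document's alternate allele.
    By construction a stored entry is never HOM_REF.
    """

    sample_id: str
    gt_raw: str
    gt_class: GtClass
    format_values: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "gt_raw": self.gt_raw,
            "gt_class": self.gt_class.value,
            "format_values": self.format_values,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SampleGenotypeEntry":
        return cls(
            sample_id=d["sample_id"],
            gt_raw=d["gt_raw"],
            gt_class=GtClass(d["gt_class"]),
            format_values=dict(d.get("format_values", {})),
        )


@dataclass
class VariantDocument:
    """Nested document for one alternate allele at one site."""

    key: VariantKey
    qual: float | None = None
    filter_status: str = "."
    dbsnp_id: str | None = None
    flat_attributes: dict[str, Any] = field(default_factory=dict)
    transcript_annotations: list[dict[str, Any]] = field(default_factory=list)
    sample_entries: list[SampleGenotypeEntry] = field(default_factory=list)
    flag: str | None = None
    source_line: int = 0
    alt_index: int = 1  # 1-based index of this alt in the source ALT column

    def to_dict(self) -> dict:
        return {
            "chrom": self.key.chrom,
            "pos": self.key.pos,
            "ref": self.key.ref,
            "alt": self.key.alt,
            "qual": self.qual,
            "filter_status": self.filter_status,
            "dbsnp_id": self.dbsnp_id,
            "flat_attributes": self.flat_attributes,
            "transcript_annotations": self.transcript_annotations,
            "sample_entries": [e.to_dict() for e in self.sample_entries],
            "flag": self.flag,
            "source_line": self.source_line,
            "alt_index": self.alt_index,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariantDocument":
        return cls(
            key=VariantKey(d["chrom"], d["pos"], d["ref"], d["alt"]),
            qual=d.get("qual"),
            filter_status=d.get("filter_status", "."),
            dbsnp_id=d.get("dbsnp_id"),
            flat_attributes=dict(d.get("flat_attributes", {})),
            transcript_annotations=[dict(t) for t in d.get("transcript_annotations", [])],
            sample_entries=[SampleGenotypeEntry.from_dict(e) for e in d.get("sample_entries", [])],
            flag=d.get("flag"),
            source_line=d.get("source_line", 0),
            alt_index=d.get("alt_index", 1),
        )

    def entry_for(self, sample_id: str) -> SampleGenotypeEntry | None:
        for e in self.sample_entries:
            if e.sample_id == sample_id:
                return e
        return None


# --- annotation schema -----------------------------------------------------

FieldSource = str  # "core" | "info_flat" | "csq_nested" | "sample_format"
DataType = str  # "integer" | "float" | "categorical" | "text" | "flag"
Widget = str  # "range" | "dropdown" | "text_search" | "checkbox" | "excluded_toggle"

GROUP_VARIANT = "Variant Related Information"
GROUP_SAMPLE = "Sample Related Information"


@dataclass
class AnnotationFieldSpec:
    """Inferred description of one queryable field.

    The data type decides the filter widget: numeric fields get range
    filters, categorical fields a dropdown, flags a checkbox; optional
    identifier fields (dbsnp_id) get a present/absent toggle.
    """

    name: str
    source: FieldSource
    data_type: DataType
    cardinality: int = 0
    group: str = GROUP_VARIANT
    widget: Widget = "text_search"
    options: list[str] = field(default_factory=list)
    number: str | None = None  # VCF header Number (e.g. "A"), INFO/FORMAT only
    # raw key inside documents when the schema name was disambiguated
    # (e.g. FORMAT DP exposed as FMT_DP when INFO DP exists)
    storage_name: str | None = None

    @property
    def is_numeric(self) -> bool:
        return self.data_type in ("integer", "float")

    @property
    def lookup_name(self) -> str:
        return self.storage_name or self.name

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "source": self.source,
            "data_type": self.data_type,
            "cardinality": self.cardinality,
            "group": self.group,
            "widget": self.widget,
            "options": self.options,
            "number": self.number,
            "storage_name": self.storage_name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotationFieldSpec":
        return cls(**d)


@dataclass
class AnnotationSchema:
    """Ordered field catalogue inferred from one annotated VCF."""

    fields: list[AnnotationFieldSpec] = field(default_factory=list)
    csq_format: list[str] = field(default_factory=list)
    samples: list[str] = field(default_factory=list)
    annotation_style: str = "generic"  # "vep" | "annovar" | "generic"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [f.name for f in self.fields]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate field names in schema: {dupes}")
        if self.annotation_style == "vep" and not self.csq_format:
            raise ValueError("vep-style schema requires a non-empty csq_format")
        if self.annotation_style != "vep" and self.csq_format:
            raise ValueError("csq_format must be empty unless annotation_style is vep")

    def field_spec(self, name: str) -> AnnotationFieldSpec | None:
        for f in self.fields:
            if f.name == name:
                return f
        return None

    def names(self) -> list[str]:
        return [f.name for f in self.fields]

    def by_source(self, *sources: str) -> list[AnnotationFieldSpec]:
        return [f for f in self.fields if f.source in sources]

    def to_dict(self) -> dict:
        return {
            "fields": [f.to_dict() for f in self.fields],
            "csq_format": self.csq_format,
            "samples": self.samples,
            "annotation_style": self.annotation_style,
            "warnings": self.warnings,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotationSchema":
        return cls(
            fields=[AnnotationFieldSpec.from_dict(f) for f in d["fields"]],
            csq_format=list(d.get("csq_format", [])),
            samples=list(d.get("samples", [])),
            annotation_style=d.get("annotation_style", "generic"),
            warnings=list(d.get("warnings", [])),
        )
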