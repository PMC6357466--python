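"""Scoped include/exclude filter queries with attribute projection.

A query is a conjunction of filters over three scopes:

* ``variant`` — core columns (CHROM, POS, dbsnp_id, REF, ALT, QUAL,
  FILTER, flag) and flat INFO/Annovar attributes;
* ``transcript`` — nested VEP CSQ fields, with same-entry semantics: a
  variant matches when at least one transcript annotation satisfies *all*
  transcript-scoped include filters jointly;
* ``sample`` — nested per-sample genotype fields (Sample_ID, GT, DP, ...),
  also with same-entry semantics.

A variant matches when all include filters are satisfied and no exclude
filter is satisfied.  Projection emits one row per variant, or one row per
variant x matching nested entry when a selected attribute is nested (only
the entries that satisfied their scope's include filters are projected).
Display mode truncates at a configurable cap (default 400, matching the
interactive result-page limit); export always writes the full row set.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timezone
from typing import Any

import yaml

from .model import AnnotationFieldSpec, AnnotationSchema, VariantDocument, VariantKey

DISPLAY_CAP = 400

OPERATORS = ("eq", "in", "lt", "le", "gt", "ge", "exists", "not_exists")
SCOPES = ("variant", "transcript", "sample")

_SCOPE_SOURCES = {
    "variant": ("core", "info_flat"),
    "transcript": ("csq_nested",),
    "sample": ("sample_format",),
}


class QueryError(ValueError):
    pass


@dataclass
class FilterSpec:
    field: str
    scope: str
    operator: str
    values: list = dc_field(default_factory=list)
    polarity: str = "include"

    def to_dict(self) -> dict:
        return {
            "field": self.field,
            "scope": self.scope,
            "operator": self.operator,
            "values": self.values,
            "polarity": self.polarity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FilterSpec":
        return cls(
            field=d["field"],
            scope=d.get("scope", "variant"),
            operator=d["operator"],
            values=list(d.get("values", [])),
            polarity=d.get("polarity", "include"),
        )


@dataclass
class Query:
    dataset: str = ""
    analysis_type: str = "exploration"
    filters: list[FilterSpec] = dc_field(default_factory=list)
    attributes: list[str] = dc_field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset,
            "analysis_type": self.analysis_type,
            "filters": [f.to_dict() for f in self.filters],
            "attributes": list(self.attributes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Query":
        return cls(
            dataset=d.get("dataset", ""),
            analysis_type=d.get("analysis_type", "exploration"),
            filters=[FilterSpec.from_dict(f) for f in d.get("filters", [])],
            attributes=list(d.get("attributes", [])),
        )


@dataclass
class QueryResult:
    rows: list[tuple]
    total_matched: int
    truncated: bool


@dataclass
class CompiledFilter:
    spec: FilterSpec
    field_spec: AnnotationFieldSpec
    values: list


@dataclass
class CompiledQuery:
    query: Query
    filters: list[CompiledFilter]
    attributes: list[AnnotationFieldSpec]
    schema: AnnotationSchema


def load_query_file(path: str) -> Query:
    """Read a query from a YAML/JSON file listing filters and attributes."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise QueryError(f"{path}: query file must contain a mapping")
    return Query.from_dict(data)


def validate_query(query: Query, schema: AnnotationSchema) -> CompiledQuery:
    """Check every filter against the schema and compile typed values.

    Verifies field existence, scope/source agreement and operator/type
    compatibility; range-operator values are parsed to numbers.
    """
    if not query.attributes:
        raise QueryError("attribute list is empty; select at least one attribute")
    compiled: list[CompiledFilter] = []
    for f in query.filters:
        fs = schema.field_spec(f.field)
        if fs is None:
            raise QueryError(f"unknown field {f.field!r}")
        if f.scope not in SCOPES:
            raise QueryError(f"filter on {f.field!r}: unknown scope {f.scope!r}")
        if fs.source not in _SCOPE_SOURCES[f.scope]:
            raise QueryError(
                f"filter on {f.field!r}: scope {f.scope!r} does not match "
                f"the field's source {fs.source!r}"
            )
        if f.operator not in OPERATORS:
            raise QueryError(f"filter on {f.field!r}: unknown operator {f.operator!r}")
        if f.polarity not in ("include", "exclude"):
            raise QueryError(f"filter on {f.field!r}: unknown polarity {f.polarity!r}")
        values = list(f.values)
        if f.operator in ("lt", "le", "gt", "ge"):
            if not fs.is_numeric:
                raise QueryError(
                    f"operator {f.operator!r} requires a numeric field; "
                    f"{f.field!r} is {fs.data_type}"
                )
            if len(values) != 1:
                raise QueryError(f"operator {f.operator!r} on {f.field!r} needs exactly one value")
            try:
                values = [float(values[0])]
            except (TypeError, ValueError):
                raise QueryError(
                    f"filter on {f.field!r}: cannot parse {values[0]!r} as a number"
                ) from None
        elif f.operator == "eq":
            if len(values) != 1:
                raise QueryError(f"operator 'eq' on {f.field!r} needs exactly one value")
        elif f.operator == "in":
            if len(values) < 1:
                raise QueryError(f"operator 'in' on {f.field!r} needs at least one value")
        else:  # exists / not_exists
            values = []
        compiled.append(CompiledFilter(f, fs, values))
    attrs: list[AnnotationFieldSpec] = []
    for name in query.attributes:
        fs = schema.field_spec(name)
        if fs is None:
            raise QueryError(f"unknown attribute {name!r}")
        attrs.append(fs)
    return CompiledQuery(query, compiled, attrs, schema)


# --------------------------------------------------------------------------
# evaluation

def _variant_value(doc: VariantDocument, name: str) -> Any:
    if name == "CHROM":
        return doc.key.chrom
    if name == "POS":
        return doc.key.pos
    if name == "REF":
        return doc.key.ref
    if name == "ALT":
        return doc.key.alt
    if name == "QUAL":
        return doc.qual
    if name == "FILTER":
        return doc.filter_status
    if name == "dbsnp_id":
        return doc.dbsnp_id
    if name == "flag":
        return doc.flag
    return doc.flat_attributes.get(name)


def _entry_value(entry: Any, name: str, scope: str) -> Any:
    if scope == "transcript":
        return entry.get(name)
    if name == "Sample_ID":
        return entry.sample_id
    if name == "GT":
        return entry.gt_raw
    return entry.format_values.get(name)


def _predicate(cf: CompiledFilter, value: Any) -> bool:
    op = cf.spec.operator
    if op == "exists":
        return value is not None and value is not False
    if op == "not_exists":
        return value is None or value is False
    if value is None:
        return False
    if op == "eq":
        return _eq(value, cf.values[0])
    if op == "in":
        return any(_eq(value, v) for v in cf.values)
    try:
        num = float(value)
    except (TypeError, ValueError):
        return False
    bound = cf.values[0]
    return {
        "lt": num < bound,
        "le": num <= bound,
        "gt": num > bound,
        "ge": num >= bound,
    }[op]


def _eq(value: Any, target: Any) -> bool:
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        try:
            return float(value) == float(target)
        except (TypeError, ValueError):
            return False
    return str(value) == str(target)


def _matching_entries(doc: VariantDocument, scope: str, includes: list[CompiledFilter]) -> list:
    entries = doc.transcript_annotations if scope == "transcript" else doc.sample_entries
    if not includes:
        return list(entries)
    return [
        e
        for e in entries
        if all(_predicate(cf, _entry_value(e, cf.field_spec.lookup_name, scope)) for cf in includes)
    ]


def match_document(doc: VariantDocument, cq: CompiledQuery) -> tuple[bool, list, list]:
    """Evaluate one document; returns (matched, matching transcripts, matching samples)."""
    inc = {s: [cf for cf in cq.filters if cf.spec.polarity == "include" and cf.spec.scope == s]
           for s in SCOPES}
    exc = [cf for cf in cq.filters if cf.spec.polarity == "exclude"]

    for cf in inc["variant"]:
        if not _predicate(cf, _variant_value(doc, cf.field_spec.lookup_name)):
            return False, [], []
    t_match = _matching_entries(doc, "transcript", inc["transcript"])
    if inc["transcript"] and not t_match:
        return False, [], []
    s_match = _matching_entries(doc, "sample", inc["sample"])
    if inc["sample"] and not s_match:
        return False, [], []
    for cf in exc:
        if cf.spec.scope == "variant":
            if _predicate(cf, _variant_value(doc, cf.field_spec.lookup_name)):
                return False, [], []
        else:
            entries = (doc.transcript_annotations if cf.spec.scope == "transcript"
                       else doc.sample_entries)
            if any(_predicate(cf, _entry_value(e, cf.field_spec.lookup_name, cf.spec.scope))
                   for e in entries):
                return False, [], []
    return True, t_match, s_match


def _project(doc: VariantDocument, cq: CompiledQuery, t_match: list, s_match: list) -> list[tuple]:
    t_needed = any(a.source == "csq_nested" for a in cq.attributes)
    s_needed = any(a.source == "sample_format" for a in cq.attributes)
    t_entries = t_match if t_needed else [None]
    s_entries = s_match if s_needed else [None]
    rows = []
    for t in t_entries:
        for s in s_entries:
            row = []
            for a in cq.attributes:
                if a.source == "csq_nested":
                    row.append(_entry_value(t, a.lookup_name, "transcript") if t is not None else None)
                elif a.source == "sample_format":
                    row.append(_entry_value(s, a.lookup_name, "sample") if s is not None else None)
                else:
                    row.append(_variant_value(doc, a.lookup_name))
            rows.append(tuple(row))
    return rows


def execute(
    cq: CompiledQuery,
    store,
    mode: str = "display",
    display_cap: int = DISPLAY_CAP,
) -> QueryResult:
    """Run a compiled query against a store.

    ``display`` mode returns at most ``display_cap`` rows in store order
    (the interactive result page); ``full`` mode returns every row.
    ``total_matched`` always counts the full row set.
    """
    if not isinstance(cq, CompiledQuery):
        raise QueryError("query must be validated with validate_query before execution")
    if mode not in ("display", "full"):
        raise QueryError(f"unknown mode {mode!r}")
    rows: list[tuple] = []
    for doc in store.documents():
        ok, t_match, s_match = match_document(doc, cq)
        if ok:
            rows.extend(_project(doc, cq, t_match, s_match))
    total = len(rows)
    if mode == "display" and total > display_cap:
        return QueryResult(rows[:display_cap], total, True)
    return QueryResult(rows, total, False)


def export_csv(cq: CompiledQuery, store, path: str) -> int:
    """Export the full (uncapped) result set as RFC-4180 CSV; returns row count.

    The header row lists the attributes in the user-specified order.  On an
    I/O failure the partial file is removed.
    """
    result = execute(cq, store, mode="full")
    try:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow([a.name for a in cq.attributes])
            for row in result.rows:
                writer.writerow(["" if v is None else v for v in row])
    except OSError:
        if os.path.exists(path):
            os.remove(path)
        raise
    return len(result.rows)


# --------------------------------------------------------------------------
# saved queries

@dataclass
class SavedQuery:
    name: str
    query: Query
    created: str


def _load_registry(registry_path: str) -> dict:
    if os.path.exists(registry_path):
        with open(registry_path) as fh:
            return json.load(fh)
    return {}


def save_query(name: str, query: Query, registry_path: str, overwrite: bool = False) -> SavedQuery:
    """Persist a named query in a local registry file."""
    if not name:
        raise QueryError("saved-query name must be non-empty")
    registry = _load_registry(registry_path)
    if name in registry and not overwrite:
        raise QueryError(f"saved query {name!r} already exists (use overwrite)")
    created = datetime.now(timezone.utc).isoformat()
    registry[name] = {"query": query.to_dict(), "created": created}
    with open(registry_path, "w") as fh:
        json.dump(registry, fh, indent=1, sort_keys=True)
    return SavedQuery(name, query, created)


def recall_query(name: str, registry_path: str) -> Query:
    registry = _load_registry(registry_path)
    if name not in registry:
        raise QueryError(f"no saved query named {name!r}")
    return Query.from_dict(registry[name]["query"])


def set_flag(store, key: VariantKey, flag: str | None) -> VariantDocument:
    """Flag a reviewed variant Approved/Rejected, or clear with None.

    A subsequent exclude filter ``{flag eq Rejected}`` removes rejected
    variants from result sets.
    """
    if flag == "clear":
        flag = None
    return store.set_flag(key, flag)


# --------------------------------------------------------------------------
# external resource links

DEFAULT_LINK_TEMPLATES = {
    "ucsc": (
        "https://genome.ucsc.edu/cgi-bin/hgTracks?db=hg19&position="
        "chr{chrom}:{start}-{end}"
    ),
    "decipher": "https://www.deciphergenomics.org/search/patients/results?q={chrom}:{pos}",
    "genemania": "https://genemania.org/search/homo-sapiens/{genes}",
}

UCSC_WINDOW = 25  # bases shown either side of the variant


def build_external_links(
    doc: VariantDocument,
    templates: dict | None = None,
    gene_field: str = "SYMBOL",
) -> dict[str, str]:
    """Deterministic external-resource URLs for one variant document.

    UCSC browser window around the position, DECIPHER position search, and
    GeneMANIA over the gene symbols found in the transcript annotations
    (omitted when no symbol is present).
    """
    templates = dict(DEFAULT_LINK_TEMPLATES, **(templates or {}))
    chrom = doc.key.chrom
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    links = {
        "ucsc": templates["ucsc"].format(
            chrom=chrom,
            pos=doc.key.pos,
            start=max(1, doc.key.pos - UCSC_WINDOW),
            end=doc.key.pos + UCSC_WINDOW,
        ),
        "decipher": templates["decipher"].format(chrom=chrom, pos=doc.key.pos),
    }
    genes = sorted({
        str(ann[gene_field]) for ann in doc.transcript_annotations if ann.get(gene_field)
    })
    if genes:
        links["genemania"] = templates["genemania"].format(genes="/".join(genes))
    return links
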