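"""Annotated-VCF ingestion.

Parses multi-sample VCF 4.x files carrying VEP ``CSQ`` annotations, Annovar
key=value annotations, or generic semicolon-separated attribute pairs into
:class:`~varex.model.VariantDocument` objects plus an inferred
:class:`~varex.model.AnnotationSchema`.

Conventions implemented here:

* **Per-allele decomposition** — a multi-allelic line yields one document
  per ALT allele; ``Number=A`` INFO values are split positionally and CSQ
  entries are routed to the document whose alt matches their ``Allele``
  field.  Genotype classes are computed against that allele.
* **Sparsity** — per-sample entries are stored only for calls that are not
  homozygous-reference.  Missing calls (any ``.`` allele) *are* stored, so
  absence of an entry always means hom-ref.
* **Chunked parallel parsing** — the data lines are split into balanced
  line ranges (sizes differing by at most one) and each range can be parsed
  by a separate worker process; the resulting document multiset is
  independent of the worker count.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from multiprocessing import get_context
from typing import Any, Iterator

from .model import (
    GROUP_SAMPLE,
    GROUP_VARIANT,
    AnnotationFieldSpec,
    AnnotationSchema,
    GtClass,
    SampleGenotypeEntry,
    VariantDocument,
    VariantKey,
)


class IngestError(ValueError):
    """Raised on malformed VCF content; messages name the line and token."""


# --------------------------------------------------------------------------
# low-level file access

def open_text(path: str):
    """Open a plain or gzip/bgzip-compressed text file for reading."""
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass
class VcfHeader:
    info_defs: dict[str, dict]  # ID -> {number, type, description}
    format_defs: dict[str, dict]
    csq_format: list[str]
    samples: list[str]
    n_header_lines: int


_META_RE = re.compile(
    r'ID=(?P<id>[^,>]+)(?:,Number=(?P<number>[^,>]+))?(?:,Type=(?P<type>[^,>]+))?'
    r'(?:,Description="(?P<desc>[^"]*)")?'
)


def read_header(path: str) -> VcfHeader:
    """Parse meta lines and the #CHROM column header.

    Raises :class:`IngestError` when the mandatory #CHROM line is absent.
    The CSQ transcript-annotation format is read verbatim from the CSQ
    Description line (``"... Format: Allele|Consequence|..."``).
    """
    info_defs: dict[str, dict] = {}
    format_defs: dict[str, dict] = {}
    csq_format: list[str] = []
    samples: list[str] = []
    n = 0
    found_chrom = False
    with open_text(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            line = line.rstrip("\n")
            if line.startswith("##INFO=<") or line.startswith("##FORMAT=<"):
                m = _META_RE.search(line)
                if m is None:
                    continue
                entry = {
                    "number": m.group("number") or ".",
                    "type": m.group("type") or "String",
                    "description": m.group("desc") or "",
                }
                if line.startswith("##INFO=<"):
                    info_defs[m.group("id")] = entry
                    if m.group("id") == "CSQ" and "Format: " in entry["description"]:
                        fmt = entry["description"].split("Format: ", 1)[1]
                        csq_format = [t for t in fmt.strip().split("|") if t]
                else:
                    format_defs[m.group("id")] = entry
            elif line.startswith("#CHROM"):
                found_chrom = True
                cols = line.split("\t")
                if len(cols) > 9:
                    samples = cols[9:]
    if not found_chrom:
        raise IngestError(f"{path}: missing #CHROM header line")
    return VcfHeader(info_defs, format_defs, csq_format, samples, n)


def iter_data_lines(path: str) -> Iterator[tuple[int, str]]:
    """Yield (0-based data-line index, stripped line) for every data line."""
    i = 0
    with open_text(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            line = line.rstrip("\n")
            if line:
                yield i, line
                i += 1


def count_data_lines(path: str) -> int:
    n = 0
    for _ in iter_data_lines(path):
        n += 1
    return n


# --------------------------------------------------------------------------
# genotype classification

_GT_SEP_RE = re.compile(r"([/|])")


def classify_genotype(gt_raw: str) -> GtClass:
    """Classify a raw GT string against alternate allele 1.

    ``0/0`` and ``0|0`` are HOM_REF; one 0 plus one non-zero allele is HET;
    two identical non-zero alleles are HOM_ALT; any ``.`` allele is MISSING;
    everything else (haploid calls, 1/2, malformed tokens) is OTHER.  The
    phasing separator never changes the class.
    """
    if gt_raw == "":
        raise IngestError("empty genotype string")
    alleles = [t for t in _GT_SEP_RE.split(gt_raw) if t not in ("/", "|")]
    if any(a == "." for a in alleles):
        return GtClass.MISSING
    if len(alleles) != 2 or not all(a.isdigit() for a in alleles):
        return GtClass.OTHER
    a, b = alleles
    if a == "0" and b == "0":
        return GtClass.HOM_REF
    if (a == "0") != (b == "0"):
        return GtClass.HET
    if a == b:
        return GtClass.HOM_ALT
    return GtClass.OTHER


def remap_gt(gt_raw: str, alt_index: int) -> str:
    """Recode a GT string so that allele ``alt_index`` becomes 1.

    Used when decomposing multi-allelic sites: the reference allele stays 0,
    the allele of interest becomes 1 and every other non-reference allele
    becomes 2, preserving separators and missing markers.
    """
    out = []
    for tok in _GT_SEP_RE.split(gt_raw):
        if tok in ("/", "|", "."):
            out.append(tok)
        elif tok == "0":
            out.append("0")
        elif tok == str(alt_index):
            out.append("1")
        elif tok.isdigit():
            out.append("2")
        else:
            out.append(tok)
    return "".join(out)


def classify_genotype_for_alt(gt_raw: str, alt_index: int) -> GtClass:
    """Class of a genotype with respect to one specific alt allele.

    Recodes the allele of interest to 1 first; a call carrying some *other*
    non-reference allele (recoded 2) is OTHER for this allele, so a het for
    a sibling alt never masquerades as HET of this document.
    """
    remapped = remap_gt(gt_raw, alt_index)
    cls = classify_genotype(remapped)
    if cls in (GtClass.HET, GtClass.HOM_ALT) and "2" in remapped:
        return GtClass.OTHER
    return cls


def haploid_alt_class(gt_raw: str, alt_index: int) -> GtClass | None:
    """Class of a single-allele (hemizygous) call, or None if not haploid.

    Male X genotypes may be written ``0`` / ``1``; these normalise to
    HOM_REF / HOM_ALT for inheritance analysis.
    """
    alleles = [t for t in _GT_SEP_RE.split(gt_raw) if t not in ("/", "|")]
    if len(alleles) != 1:
        return None
    a = alleles[0]
    if a == ".":
        return GtClass.MISSING
    if a == "0":
        return GtClass.HOM_REF
    if a == str(alt_index):
        return GtClass.HOM_ALT
    return GtClass.OTHER


# --------------------------------------------------------------------------
# value coercion

def _coerce_scalar(token: str) -> Any:
    try:
        return int(token)
    except ValueError:
        pass
    try:
        return float(token)
    except ValueError:
        return token


def _coerce_typed(token: str, data_type: str | None) -> Any:
    if token == "." or token == "":
        return None
    if data_type == "integer":
        try:
            return int(token)
        except ValueError:
            return _coerce_scalar(token)
    if data_type == "float":
        try:
            return float(token)
        except ValueError:
            return _coerce_scalar(token)
    if data_type in ("categorical", "text"):
        return token
    return _coerce_scalar(token)


# --------------------------------------------------------------------------
# INFO / CSQ / sample-column parsing

def parse_info_pairs(
    info_string: str,
    schema: AnnotationSchema | None = None,
    line_no: int | None = None,
) -> dict[str, Any]:
    """Parse a raw INFO column into a typed attribute map.

    ``key=value`` pairs become typed entries (comma-separated values become
    lists); bare keys become flag entries with value ``True``.  The ``CSQ``
    key is *not* included here — its block is routed to
    :func:`parse_csq_block` by the caller.  ``"."`` yields an empty map.
    """
    if info_string in (".", ""):
        return {}
    out: dict[str, Any] = {}
    where = f" on line {line_no}" if line_no is not None else ""
    for token in info_string.split(";"):
        if not token:
            continue
        if "=" in token:
            key, _, value = token.partition("=")
            if not key:
                raise IngestError(f"malformed INFO pair {token!r}{where}: empty key")
            if key == "CSQ":
                continue
            if value == "":
                continue  # empty values are never stored
            spec = schema.field_spec(key) if schema is not None else None
            dtype = spec.data_type if spec is not None else None
            if "," in value:
                out[key] = [_coerce_typed(v, dtype) for v in value.split(",")]
            else:
                out[key] = _coerce_typed(value, dtype)
        else:
            out[token] = True
    return out


def parse_csq_block(csq_value: str, csq_format: list[str]) -> list[dict[str, Any]]:
    """Parse a VEP CSQ block into per-transcript annotation maps.

    One map per comma-separated entry; within an entry, pipe-separated
    values are matched positionally to ``csq_format``.  Empty positions are
    omitted, so the stored map carries no empty-string values.
    """
    if not csq_format:
        raise IngestError("csq_format is empty; cannot parse CSQ block")
    annotations: list[dict[str, Any]] = []
    for idx, entry in enumerate(csq_value.split(",")):
        values = entry.split("|")
        if len(values) > len(csq_format):
            raise IngestError(
                f"CSQ entry {idx} has {len(values)} fields but the declared "
                f"format has only {len(csq_format)}"
            )
        ann = {}
        for name, value in zip(csq_format, values):
            if value != "":
                ann[name] = _coerce_scalar(value)
        annotations.append(ann)
    return annotations


def parse_sample_entries(
    format_keys: list[str],
    sample_columns: list[str],
    sample_ids: list[str],
    schema: AnnotationSchema | None = None,
    alt_index: int = 1,
) -> list[SampleGenotypeEntry]:
    """Build sparse genotype entries for one decomposed allele.

    Entries are produced only for samples whose class against ``alt_index``
    is not HOM_REF; MISSING calls are stored so that absence always means
    hom-ref.  Trailing FORMAT fields may be dropped in a sample column (VCF
    allows this); *extra* fields are a parse error naming the sample.
    """
    if len(sample_columns) != len(sample_ids):
        raise IngestError(
            f"sample column count {len(sample_columns)} != sample id count {len(sample_ids)}"
        )
    try:
        gt_idx = format_keys.index("GT")
    except ValueError:
        gt_idx = None
    entries: list[SampleGenotypeEntry] = []
    for sample_id, col in zip(sample_ids, sample_columns):
        fields = col.split(":")
        if len(fields) > len(format_keys):
            raise IngestError(
                f"sample {sample_id}: {len(fields)} FORMAT values for "
                f"{len(format_keys)} declared keys"
            )
        gt_raw = fields[gt_idx] if gt_idx is not None and gt_idx < len(fields) else "."
        gt_class = classify_genotype_for_alt(gt_raw, alt_index)
        if gt_class is GtClass.HOM_REF:
            continue
        fmt_values: dict[str, Any] = {}
        for key, value in zip(format_keys, fields):
            if key == "GT" or value in (".", ""):
                continue
            spec = schema.field_spec(key) if schema is not None else None
            dtype = spec.data_type if spec is not None else None
            fmt_values[key] = (
                value if "," in value else _coerce_typed(value, dtype)
            )
        entries.append(SampleGenotypeEntry(sample_id, gt_raw, gt_class, fmt_values))
    return entries


# --------------------------------------------------------------------------
# record decomposition

def decompose_record(
    vcf_data_line: str,
    schema: AnnotationSchema,
    source_line: int = 0,
    warnings: list[str] | None = None,
) -> list[VariantDocument]:
    """Decompose one data line into one document per ALT allele.

    Number=A INFO values are split positionally across the alt documents;
    CSQ annotations go to the document whose alt equals their ``Allele``
    value (to every document when the format has no Allele field); sample
    genotype classes are computed against each allele.  Monomorphic lines
    (ALT ``.``) are skipped with a warning.
    """
    cols = vcf_data_line.rstrip("\n").split("\t")
    if len(cols) < 8:
        raise IngestError(f"line {source_line}: expected >= 8 columns, got {len(cols)}")
    chrom, pos_s, vid, ref, alt_col, qual_s, filt, info = cols[:8]
    if alt_col in (".", ""):
        if warnings is not None:
            warnings.append(f"line {source_line}: monomorphic ALT '.' skipped")
        return []
    alts = alt_col.split(",")
    try:
        pos = int(pos_s)
    except ValueError:
        raise IngestError(f"line {source_line}: non-integer POS {pos_s!r}") from None
    qual = None if qual_s in (".", "") else float(qual_s)
    dbsnp_id = None if vid in (".", "") else vid

    flat = parse_info_pairs(info, schema, line_no=source_line)

    csq_raw = None
    for token in info.split(";"):
        if token.startswith("CSQ="):
            csq_raw = token[4:]
            break
    csq_annotations: list[dict] = []
    if csq_raw is not None and schema.csq_format:
        csq_annotations = parse_csq_block(csq_raw, schema.csq_format)

    format_keys: list[str] = []
    sample_cols: list[str] = []
    if len(cols) > 9:
        format_keys = cols[8].split(":")
        sample_cols = cols[9:]

    numbers = {
        f.name: f.number for f in schema.fields if f.source == "info_flat" and f.number
    }

    docs: list[VariantDocument] = []
    for i, alt in enumerate(alts, start=1):
        attrs: dict[str, Any] = {}
        for k, v in flat.items():
            if isinstance(v, list):
                if numbers.get(k) == "A":
                    attrs[k] = v[i - 1] if i - 1 < len(v) else None
                else:
                    attrs[k] = ",".join("" if x is None else str(x) for x in v)
            else:
                attrs[k] = v
        attrs = {k: v for k, v in attrs.items() if v is not None}

        anns = csq_annotations
        if csq_annotations and "Allele" in schema.csq_format:
            anns = [a for a in csq_annotations if a.get("Allele") == alt]

        entries = (
            parse_sample_entries(format_keys, sample_cols, schema.samples, schema, i)
            if sample_cols
            else []
        )
        docs.append(
            VariantDocument(
                key=VariantKey(chrom, pos, ref, alt),
                qual=qual,
                filter_status=filt,
                dbsnp_id=dbsnp_id,
                flat_attributes=attrs,
                transcript_annotations=anns,
                sample_entries=entries,
                source_line=source_line,
                alt_index=i,
            )
        )
    return docs


# --------------------------------------------------------------------------
# schema inference

_HEADER_TYPE_MAP = {"Integer": "integer", "Float": "float", "Flag": "flag"}


def _widget_for(data_type: str) -> str:
    return {
        "integer": "range",
        "float": "range",
        "categorical": "dropdown",
        "flag": "checkbox",
    }.get(data_type, "text_search")


def _observed_type(values: set[str], threshold: int) -> tuple[str, int]:
    """Infer (data_type, cardinality) from observed string values."""
    card = len(values)
    if values and all(_is_int(v) for v in values):
        return "integer", card
    if values and all(_is_number(v) for v in values):
        return "float", card
    if 0 < card <= threshold:
        return "categorical", card
    return "text", card


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def infer_schema(
    vcf_path: str,
    k: int = 5000,
    dropdown_threshold: int = 50,
    annotation_style: str | None = None,
) -> AnnotationSchema:
    """Infer the annotation schema from the header and the first *k* records.

    Field types come from header Type declarations where present, otherwise
    from the observed values (all-numeric becomes integer/float; at most
    ``dropdown_threshold`` distinct strings becomes categorical; else text).
    Header declarations win over conflicting observations, with a warning.
    Core, INFO and CSQ fields are grouped under "Variant Related
    Information"; FORMAT fields under "Sample Related Information".
    """
    header = read_header(vcf_path)
    warnings: list[str] = []
    if annotation_style is None:
        annotation_style = "vep" if header.csq_format else "generic"
    if annotation_style == "vep" and not header.csq_format:
        raise IngestError(f"{vcf_path}: vep style requested but no CSQ format in header")
    if annotation_style != "vep" and header.csq_format:
        warnings.append(
            f"CSQ format present in header but style={annotation_style}; CSQ nesting disabled"
        )

    csq_format = header.csq_format if annotation_style == "vep" else []

    # observation pass over the first k data lines
    chrom_vals: set[str] = set()
    filter_vals: set[str] = set()
    info_vals: dict[str, set[str]] = {}
    csq_vals: dict[str, set[str]] = {name: set() for name in csq_format}
    fmt_vals: dict[str, set[str]] = {}
    for idx, line in iter_data_lines(vcf_path):
        if idx >= k:
            break
        cols = line.split("\t")
        if len(cols) < 8:
            continue
        chrom_vals.add(cols[0])
        filter_vals.add(cols[6])
        for token in cols[7].split(";"):
            if not token or token == ".":
                continue
            key, sep, value = token.partition("=")
            if key == "CSQ":
                if csq_format and sep:
                    for entry in value.split(","):
                        for name, v in zip(csq_format, entry.split("|")):
                            if v != "":
                                csq_vals[name].add(v)
                continue
            if sep and value != "":
                for v in value.split(","):
                    info_vals.setdefault(key, set()).add(v)
            elif not sep:
                info_vals.setdefault(key, set())
        if len(cols) > 9:
            fkeys = cols[8].split(":")
            for col in cols[9:]:
                for fk, v in zip(fkeys, col.split(":")):
                    if v not in (".", ""):
                        fmt_vals.setdefault(fk, set()).add(v)

    fields: list[AnnotationFieldSpec] = []
    seen: set[str] = set()

    def add(spec: AnnotationFieldSpec, prefix: str = "") -> None:
        if spec.name in seen:
            if prefix:
                # routine disambiguation (e.g. FORMAT DP vs INFO DP); the
                # raw document key is preserved in storage_name
                spec.storage_name = spec.name
                spec.name = prefix + spec.name
            else:
                raise IngestError(f"duplicate schema field {spec.name}")
        seen.add(spec.name)
        fields.append(spec)

    # core fields
    add(AnnotationFieldSpec("CHROM", "core", "categorical", len(chrom_vals),
                            GROUP_VARIANT, "dropdown", sorted(chrom_vals)))
    add(AnnotationFieldSpec("POS", "core", "integer", 0, GROUP_VARIANT, "range"))
    add(AnnotationFieldSpec("dbsnp_id", "core", "text", 0, GROUP_VARIANT, "excluded_toggle"))
    add(AnnotationFieldSpec("REF", "core", "text", 0, GROUP_VARIANT, "text_search"))
    add(AnnotationFieldSpec("ALT", "core", "text", 0, GROUP_VARIANT, "text_search"))
    add(AnnotationFieldSpec("QUAL", "core", "float", 0, GROUP_VARIANT, "range"))
    add(AnnotationFieldSpec("FILTER", "core", "categorical", len(filter_vals),
                            GROUP_VARIANT, "dropdown", sorted(filter_vals)))
    add(AnnotationFieldSpec("flag", "core", "categorical", 2, GROUP_VARIANT,
                            "dropdown", ["Approved", "Rejected"]))

    # INFO fields (header order, then any seen only in records)
    info_names = [n for n in header.info_defs if n != "CSQ"]
    for n in info_vals:
        if n not in info_names and n != "CSQ":
            info_names.append(n)
    for name in info_names:
        observed = info_vals.get(name, set())
        hdr = header.info_defs.get(name)
        number = hdr["number"] if hdr else None
        if hdr and hdr["type"] in _HEADER_TYPE_MAP:
            dtype = _HEADER_TYPE_MAP[hdr["type"]]
            obs_dtype, card = _observed_type(observed, dropdown_threshold)
            if observed and dtype in ("integer", "float") and obs_dtype not in ("integer", "float"):
                warnings.append(
                    f"INFO {name}: header declares {hdr['type']} but observed "
                    f"values are not numeric; keeping header type"
                )
            if dtype == "integer" and obs_dtype == "float":
                dtype = "float"  # header Integer with float observations stays numeric
        elif hdr and hdr["number"] == "0":
            dtype, card = "flag", 0
        else:
            dtype, card = _observed_type(observed, dropdown_threshold)
        card = len(observed)
        options = sorted(observed) if dtype == "categorical" else []
        add(AnnotationFieldSpec(name, "info_flat", dtype, card, GROUP_VARIANT,
                                _widget_for(dtype), options, number))

    # CSQ fields
    for name in csq_format:
        observed = csq_vals.get(name, set())
        dtype, card = _observed_type(observed, dropdown_threshold)
        options = sorted(observed) if dtype == "categorical" else []
        spec = AnnotationFieldSpec(name, "csq_nested", dtype, card, GROUP_VARIANT,
                                   _widget_for(dtype), options)
        add(spec, prefix="CSQ_")

    # sample fields
    if header.samples:
        add(AnnotationFieldSpec("Sample_ID", "sample_format", "categorical",
                                len(header.samples), GROUP_SAMPLE, "dropdown",
                                sorted(header.samples)))
        for name, hdr in header.format_defs.items():
            observed = fmt_vals.get(name, set())
            if name == "GT":
                dtype, card = "categorical", len(observed)
            elif hdr["type"] in _HEADER_TYPE_MAP:
                dtype = _HEADER_TYPE_MAP[hdr["type"]]
                card = len(observed)
                if hdr["number"] not in ("1", "0"):
                    # multi-valued FORMAT fields (e.g. AD) are kept verbatim
                    dtype, card = _observed_type(observed, dropdown_threshold)
            else:
                dtype, card = _observed_type(observed, dropdown_threshold)
            options = sorted(observed) if dtype == "categorical" else []
            spec = AnnotationFieldSpec(name, "sample_format", dtype, card,
                                       GROUP_SAMPLE, _widget_for(dtype), options,
                                       hdr["number"])
            add(spec, prefix="FMT_")

    return AnnotationSchema(
        fields=fields,
        csq_format=csq_format,
        samples=header.samples,
        annotation_style=annotation_style,
        warnings=warnings,
    )


# --------------------------------------------------------------------------
# chunk planning and parallel ingest

@dataclass(frozen=True)
class GenomicChunk:
    """A balanced range of data lines of one VCF."""

    path: str
    first_data_line: int  # 0-based among data lines
    n_lines: int


@dataclass
class IngestReport:
    n_data_lines: int
    n_documents: int
    n_chunks: int
    per_chunk_document_counts: list[int] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_data_lines": self.n_data_lines,
            "n_documents": self.n_documents,
            "n_chunks": self.n_chunks,
            "per_chunk_document_counts": self.per_chunk_document_counts,
            "warnings": self.warnings,
        }


def plan_chunks(vcf_path: str, n_workers: int, warnings: list[str] | None = None) -> list[GenomicChunk]:
    """Split the data lines into min(n_workers, n_lines) balanced chunks.

    Chunk sizes differ by at most one line and their in-order concatenation
    reproduces the data lines exactly.  An empty VCF yields an empty plan
    with a warning.
    """
    if n_workers < 1:
        raise ValueError(f"n_workers must be >= 1, got {n_workers}")
    n_lines = count_data_lines(vcf_path)
    if n_lines == 0:
        if warnings is not None:
            warnings.append(f"{vcf_path}: no data lines; empty chunk plan")
        return []
    n_chunks = min(n_workers, n_lines)
    base, rem = divmod(n_lines, n_chunks)
    chunks = []
    start = 0
    for i in range(n_chunks):
        size = base + (1 if i < rem else 0)
        chunks.append(GenomicChunk(vcf_path, start, size))
        start += size
    return chunks


def parse_chunk(chunk: GenomicChunk, schema: AnnotationSchema) -> tuple[list[VariantDocument], list[str]]:
    """Parse one chunk's line range into documents."""
    docs: list[VariantDocument] = []
    warnings: list[str] = []
    end = chunk.first_data_line + chunk.n_lines
    for idx, line in iter_data_lines(chunk.path):
        if idx < chunk.first_data_line:
            continue
        if idx >= end:
            break
        docs.extend(decompose_record(line, schema, source_line=idx, warnings=warnings))
    return docs, warnings


def _parse_chunk_worker(args: tuple) -> tuple[list[dict], list[str]]:
    chunk_tuple, schema_dict = args
    chunk = GenomicChunk(*chunk_tuple)
    schema = AnnotationSchema.from_dict(schema_dict)
    docs, warnings = parse_chunk(chunk, schema)
    return [d.to_dict() for d in docs], warnings


def ingest_vcf(
    vcf_path: str,
    store,
    n_workers: int = 1,
    k: int = 5000,
    dropdown_threshold: int = 50,
    annotation_style: str | None = None,
    batch_size: int = 512,
) -> IngestReport:
    """Ingest an annotated VCF into a document store.

    The schema is inferred first, the store index is created from it, then
    the data lines are parsed (in parallel worker processes when
    ``n_workers > 1``) and bulk-loaded.  The document multiset in the store
    is independent of ``n_workers``.  A worker failure aborts the ingest
    and marks the partially loaded store invalid.
    """
    schema = infer_schema(vcf_path, k=k, dropdown_threshold=dropdown_threshold,
                          annotation_style=annotation_style)
    store.create(schema)
    warnings = list(schema.warnings)
    chunks = plan_chunks(vcf_path, n_workers, warnings=warnings)
    per_chunk_counts: list[int] = []
    all_docs: list[VariantDocument] = []
    if n_workers <= 1 or len(chunks) <= 1:
        for chunk in chunks:
            docs, w = parse_chunk(chunk, schema)
            per_chunk_counts.append(len(docs))
            warnings.extend(w)
            all_docs.extend(docs)
    else:
        schema_dict = schema.to_dict()
        args = [((c.path, c.first_data_line, c.n_lines), schema_dict) for c in chunks]
        ctx = get_context("fork")
        try:
            with ctx.Pool(processes=min(n_workers, len(chunks))) as pool:
                results = pool.map(_parse_chunk_worker, args)
        except Exception as exc:
            store.mark_invalid()
            raise IngestError(f"chunk worker failed: {exc}") from exc
        for i, (doc_dicts, w) in enumerate(results):
            docs = [VariantDocument.from_dict(d) for d in doc_dicts]
            per_chunk_counts.append(len(docs))
            warnings.extend(w)
            all_docs.extend(docs)
    store.bulk_load(all_docs, batch_size=batch_size)
    n_lines = sum(c.n_lines for c in chunks)
    return IngestReport(
        n_data_lines=n_lines,
        n_documents=len(all_docs),
        n_chunks=len(chunks),
        per_chunk_document_counts=per_chunk_counts,
        warnings=warnings,
    )
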