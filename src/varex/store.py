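"""Embedded document store.

The store is a contract — create an index from a schema, bulk-load
documents, scan with nested-scope filter semantics — with one complete
embedded reference backend.  Documents live as JSON lines under a single
index directory together with the field mapping and the UI-configuration
artifact, both written with stable key order so two runs over the same VCF
produce byte-identical files.

Two nested blocks mirror the document structure: ``transcript_annotations``
(per-transcript VEP CSQ fields) and ``sample_entries`` (per-sample FORMAT
fields).  Filters inside a nested block use same-entry conjunction: all
block-scoped predicates must hold for one and the same nested entry.
"""

from __future__ import annotations

import json
import os
from typing import Iterable

from .model import (
    GROUP_SAMPLE,
    GROUP_VARIANT,
    AnnotationSchema,
    VariantDocument,
    VariantKey,
)


class StoreError(RuntimeError):
    pass


NESTED_BLOCKS = ("transcript_annotations", "sample_entries")

_SOURCE_BLOCK = {
    "core": "root",
    "info_flat": "root",
    "csq_nested": "transcript_annotations",
    "sample_format": "sample_entries",
}


def create_index(schema: AnnotationSchema) -> dict:
    """Build the field mapping for a schema.

    Every field gets exactly one entry: numeric fields are range-capable,
    categorical/text/flag fields support term retrieval; CSQ fields live in
    the transcript nested block and FORMAT fields in the sample block.
    """
    mapping: dict = {"nested_blocks": list(NESTED_BLOCKS), "fields": {}}
    for f in schema.fields:
        if f.name in mapping["fields"]:
            raise StoreError(f"duplicate field name in schema: {f.name}")
        mapping["fields"][f.name] = {
            "kind": "numeric" if f.is_numeric else "keyword",
            "block": _SOURCE_BLOCK[f.source],
        }
    return mapping


def generate_ui_config(schema: AnnotationSchema) -> dict:
    """Derive the UI configuration deterministically from a schema.

    Panels appear in fixed order: variant-level fields, the transcript
    annotation panel (when the VCF carries VEP CSQ), then sample-level
    fields.  Dropdown options are the observed categorical values, sorted.
    """
    def item(f):
        entry = {"field": f.name, "widget": f.widget}
        if f.widget == "dropdown":
            entry["options"] = list(f.options)
        return entry

    panels = []
    variant_fields = [f for f in schema.fields if f.source in ("core", "info_flat")]
    if variant_fields:
        panels.append({"label": GROUP_VARIANT, "items": [item(f) for f in variant_fields]})
    csq_fields = [f for f in schema.fields if f.source == "csq_nested"]
    if csq_fields:
        panels.append({"label": "Transcript Annotations", "items": [item(f) for f in csq_fields]})
    sample_fields = [f for f in schema.fields if f.source == "sample_format"]
    if sample_fields:
        panels.append({"label": GROUP_SAMPLE, "items": [item(f) for f in sample_fields]})
    return {"panels": panels}


class EmbeddedStore:
    """Reference store backend persisting to one index directory.

    Layout: ``schema.json``, ``mapping.json``, ``ui_config.json``,
    ``documents.jsonl`` and ``flags.json``.  Documents are held in memory
    in canonical order (source line, then alt index), which makes query
    results independent of bulk-load order.
    """

    SCHEMA_FILE = "schema.json"
    MAPPING_FILE = "mapping.json"
    UI_FILE = "ui_config.json"
    DOCS_FILE = "documents.jsonl"
    FLAGS_FILE = "flags.json"
    INVALID_FILE = "INVALID"

    def __init__(self, index_dir: str):
        self.index_dir = str(index_dir)
        self.schema: AnnotationSchema | None = None
        self.mapping: dict | None = None
        self._docs: list[VariantDocument] = []
        self._by_key: dict[str, VariantDocument] = {}
        self._flags: dict[str, str] = {}

    # -- lifecycle ---------------------------------------------------------

    def _path(self, name: str) -> str:
        return os.path.join(self.index_dir, name)

    def create(self, schema: AnnotationSchema) -> dict:
        os.makedirs(self.index_dir, exist_ok=True)
        self.schema = schema
        self.mapping = create_index(schema)
        with open(self._path(self.SCHEMA_FILE), "w") as fh:
            json.dump(schema.to_dict(), fh, indent=1)
        with open(self._path(self.MAPPING_FILE), "w") as fh:
            json.dump(self.mapping, fh, indent=1)
        with open(self._path(self.UI_FILE), "w") as fh:
            json.dump(generate_ui_config(schema), fh, indent=1)
        # reset any previous content
        open(self._path(self.DOCS_FILE), "w").close()
        with open(self._path(self.FLAGS_FILE), "w") as fh:
            json.dump({}, fh)
        if os.path.exists(self._path(self.INVALID_FILE)):
            os.remove(self._path(self.INVALID_FILE))
        self._docs = []
        self._by_key = {}
        self._flags = {}
        return self.mapping

    @classmethod
    def open(cls, index_dir: str) -> "EmbeddedStore":
        store = cls(index_dir)
        if os.path.exists(store._path(cls.INVALID_FILE)):
            raise StoreError(f"{index_dir}: store marked invalid by an aborted ingest")
        schema_path = store._path(cls.SCHEMA_FILE)
        if not os.path.exists(schema_path):
            raise StoreError(f"{index_dir}: no schema.json; not a store directory")
        with open(schema_path) as fh:
            store.schema = AnnotationSchema.from_dict(json.load(fh))
        with open(store._path(cls.MAPPING_FILE)) as fh:
            store.mapping = json.load(fh)
        docs_path = store._path(cls.DOCS_FILE)
        if os.path.exists(docs_path):
            with open(docs_path) as fh:
                for line in fh:
                    line = line.strip()
                    if line:
                        store._admit(VariantDocument.from_dict(json.loads(line)))
        flags_path = store._path(cls.FLAGS_FILE)
        if os.path.exists(flags_path):
            with open(flags_path) as fh:
                store._flags = json.load(fh)
        store._sort()
        store._apply_flags()
        return store

    def mark_invalid(self) -> None:
        os.makedirs(self.index_dir, exist_ok=True)
        open(self._path(self.INVALID_FILE), "w").close()

    # -- loading -----------------------------------------------------------

    def _admit(self, doc: VariantDocument) -> None:
        self._docs.append(doc)
        self._by_key[str(doc.key)] = doc

    def _sort(self) -> None:
        self._docs.sort(key=lambda d: (d.source_line, d.alt_index))

    def _validate(self, doc: VariantDocument) -> None:
        assert self.schema is not None
        known = set(self.schema.names())
        for name in doc.flat_attributes:
            if name not in known:
                raise StoreError(
                    f"document at source line {doc.source_line}: "
                    f"attribute {name!r} not in mapping"
                )
        csq_ok = set(self.schema.csq_format)
        for ann in doc.transcript_annotations:
            for name in ann:
                if name not in csq_ok:
                    raise StoreError(
                        f"document at source line {doc.source_line}: "
                        f"transcript field {name!r} not in mapping"
                    )

    def bulk_load(self, documents: Iterable[VariantDocument], batch_size: int = 512) -> int:
        """Load documents in batches; returns the loaded count.

        Loading is order-independent: documents are re-sorted canonically,
        so query results do not depend on the order batches arrive in.
        """
        if self.schema is None:
            raise StoreError("index not created; call create(schema) first")
        if batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        docs = list(documents)
        for d in docs:
            self._validate(d)
        n = 0
        with open(self._path(self.DOCS_FILE), "a") as fh:
            for i in range(0, len(docs), batch_size):
                batch = docs[i : i + batch_size]
                for d in batch:
                    fh.write(json.dumps(d.to_dict()) + "\n")
                    self._admit(d)
                n += len(batch)
        self._sort()
        return n

    # -- retrieval ---------------------------------------------------------

    def documents(self) -> list[VariantDocument]:
        """All documents in canonical (source line, alt index) order."""
        return list(self._docs)

    def __len__(self) -> int:
        return len(self._docs)

    def get(self, key: VariantKey) -> VariantDocument | None:
        return self._by_key.get(str(key))

    # -- flags -------------------------------------------------------------

    def set_flag(self, key: VariantKey, flag: str | None) -> VariantDocument:
        """Persist an Approved/Rejected flag (or clear it) on one document."""
        doc = self.get(key)
        if doc is None:
            raise StoreError(f"unknown variant key {key}")
        if flag not in (None, "Approved", "Rejected"):
            raise ValueError(f"flag must be Approved, Rejected or None, got {flag!r}")
        doc.flag = flag
        if flag is None:
            self._flags.pop(str(key), None)
        else:
            self._flags[str(key)] = flag
        with open(self._path(self.FLAGS_FILE), "w") as fh:
            json.dump(self._flags, fh, indent=1, sort_keys=True)
        return doc

    def _apply_flags(self) -> None:
        for key_s, flag in self._flags.items():
            doc = self._by_key.get(key_s)
            if doc is not None:
                doc.flag = flag
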