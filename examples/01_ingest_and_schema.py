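"""Ingest an annotated multi-sample VCF and inspect the inferred schema.

Generates a small VEP-annotated cohort, parses it into the document store
in two parallel chunks, and prints the ingest report plus a few inferred
field specifications that drive filter widgets.
"""

import tempfile
import os

from varex import EmbeddedStore, ingest_vcf, simulate_multisample_vcf

workdir = tempfile.mkdtemp(prefix="varex_example_")
vcf, truth = simulate_multisample_vcf(workdir, n_variants=500, n_samples=8,
                                      annotation_style="vep", seed=11)

store = EmbeddedStore(os.path.join(workdir, "index"))
report = ingest_vcf(vcf, store, n_workers=2)

print(f"data lines        : {report.n_data_lines}")
print(f"documents         : {report.n_documents}  (one per alt allele; "
      f"multi-allelic sites decompose)")
print(f"chunks            : {report.n_chunks} -> {report.per_chunk_document_counts}")
entries = sum(len(d.sample_entries) for d in store.documents())
print(f"sparse GT entries : {entries}  (hom-ref calls stored by absence)")

print("\ninferred fields (name, source, type -> widget):")
for name in ("POS", "AF", "FILTER", "IMPACT", "SYMBOL", "GT", "dbsnp_id"):
    f = store.schema.field_spec(name)
    print(f"  {f.name:10s} {f.source:14s} {f.data_type:12s} -> {f.widget}")
# Numeric fields become range filters, categorical fields dropdowns; the
# dbsnp identifier gets a present/absent toggle for novel-variant queries.
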