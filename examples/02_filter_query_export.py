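"""Scoped filter queries: novel high-impact variants, display cap, CSV export.

Builds a cohort store, then runs the classic candidate-variant filter set —
no dbSNP id, transcript IMPACT HIGH, FILTER PASS — and shows how display
mode caps rows at 400 while export returns everything.
"""

import os
import tempfile

from varex import (
    EmbeddedStore, FilterSpec, Query, execute, export_csv, ingest_vcf,
    simulate_multisample_vcf, validate_query,
)

workdir = tempfile.mkdtemp(prefix="varex_example_")
vcf, _ = simulate_multisample_vcf(workdir, n_variants=1000, n_samples=6,
                                  seed=12, multiallelic_fraction=0.0)
store = EmbeddedStore(os.path.join(workdir, "index"))
ingest_vcf(vcf, store)

novel_detrimental = Query(
    filters=[
        FilterSpec("dbsnp_id", "variant", "not_exists"),
        FilterSpec("IMPACT", "transcript", "in", ["HIGH"]),
        FilterSpec("FILTER", "variant", "eq", ["PASS"]),
    ],
    attributes=["CHROM", "POS", "REF", "ALT", "IMPACT", "QUAL", "FILTER"],
)
cq = validate_query(novel_detrimental, store.schema)
result = execute(cq, store, mode="display")
print(f"novel HIGH-impact PASS variants: {result.total_matched} matched, "
      f"{len(result.rows)} displayed (cap 400), truncated={result.truncated}")
print("first row:", result.rows[0])

# a match-all query to demonstrate the cap/export law
match_all = validate_query(Query(attributes=["CHROM", "POS", "REF", "ALT"]),
                           store.schema)
display = execute(match_all, store, mode="display")
n_csv = export_csv(match_all, store, os.path.join(workdir, "all.csv"))
print(f"\nmatch-all: {display.total_matched} total, {len(display.rows)} shown, "
      f"{n_csv} rows exported to CSV — export is never capped")
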