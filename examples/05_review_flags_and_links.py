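"""Post-query review: flag variants, exclude the rejected, link out.

Flags one variant Rejected (as after inspecting its alignments), shows how
an exclude filter drops it from subsequent result sets, saves the query
for later re-use, and builds external browser links for a hit.
"""

import os
import tempfile

from varex import (
    EmbeddedStore, FilterSpec, Query, build_external_links, execute,
    ingest_vcf, recall_query, save_query, set_flag, simulate_multisample_vcf,
    validate_query,
)

workdir = tempfile.mkdtemp(prefix="varex_example_")
vcf, _ = simulate_multisample_vcf(workdir, n_variants=50, n_samples=4, seed=15)
store = EmbeddedStore(os.path.join(workdir, "index"))
ingest_vcf(vcf, store)

suspect = store.documents()[0]
set_flag(store, suspect.key, "Rejected")
print(f"flagged {suspect.key} as Rejected")

clean = Query(
    filters=[FilterSpec("flag", "variant", "eq", ["Rejected"], polarity="exclude")],
    attributes=["CHROM", "POS", "REF", "ALT"],
)
result = execute(validate_query(clean, store.schema), store, mode="full")
print(f"clean result set: {result.total_matched} of {len(store)} variants "
      f"(the rejected one is gone)")

registry = os.path.join(workdir, "queries.json")
save_query("without_rejected", clean, registry)
recalled = recall_query("without_rejected", registry)
print(f"saved query recalled intact: {recalled.to_dict() == clean.to_dict()}")

links = build_external_links(store.documents()[1])
print("\nexternal resources for the next variant:")
for resource, url in links.items():
    print(f"  {resource:9s} {url}")
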