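"""Case/control allele-distribution comparison with a planted shift.

Simulates paired cohorts (60 + 60 samples, 300 shared sites) in which 10
sites carry a +0.3 allele-frequency shift in the cases, then compares the
cohorts and lists the strongest frequency gaps with Fisher exact p-values.
"""

import os
import tempfile

from varex import (
    EmbeddedStore, compare_case_control, ingest_vcf, simulate_case_control,
)

workdir = tempfile.mkdtemp(prefix="varex_example_")
case_vcf, control_vcf, truth = simulate_case_control(
    workdir, n_variants=300, n_case=60, n_control=60,
    delta_sites=10, delta=0.3, seed=14)

store = EmbeddedStore(os.path.join(workdir, "index"))
ingest_vcf(case_vcf, store)

records = compare_case_control(store, control_vcf, fisher=True)
records.sort(key=lambda r: abs(r.case_af - r.control_af), reverse=True)

planted = {(s["chrom"], s["pos"]) for s in truth["sites"] if s["is_delta_site"]}
print("top 10 frequency gaps (case_af - control_af, Fisher p, planted?):")
hits = 0
for r in records[:10]:
    was_planted = (r.key.chrom, r.key.pos) in planted
    hits += was_planted
    print(f"  {r.key}  {r.case_af:.3f} vs {r.control_af:.3f}  "
          f"p={r.fisher_p:.2e}  planted={was_planted}")
print(f"\n{hits}/10 of the largest gaps are planted shift sites; the rest "
      f"of the 300 sites differ only by binomial sampling noise.")
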