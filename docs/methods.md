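# Methods

## Data model

A VCF data line with *k* alternate alleles becomes *k* variant documents.
Decomposition is per-allele because the quantities users filter on
(allele frequencies such as `EUR_AF`, per-allele `AC`) and the Mendelian
genotype logic are allele-specific:

* `Number=A` INFO values are split positionally across the alt documents;
  scalar INFO values are shared; other multi-valued INFO fields are kept
  verbatim as comma-joined strings.
* VEP `CSQ` entries are routed to the document whose alt equals the
  entry's `Allele` value; when the declared CSQ format has no `Allele`
  field every document receives all entries.
* A sample's genotype class is computed against the document's allele by
  recoding: the allele of interest becomes 1, every other non-reference
  allele becomes 2. A recoded call containing a 2 is classed OTHER — a
  het for a sibling alt never counts as HET of this document.

Genotype entries are sparse: hom-ref calls are represented by absence.
Missing calls (any `.` allele) are stored as MISSING entries, which makes
absence unambiguous — the inheritance rules must distinguish an untyped
parent from a hom-ref parent, and the original system's behaviour here is
unpublished, so explicit storage is the safe choice. Coordinates are
1-based fully closed, exactly as printed in the VCF POS column.

Annovar and generic annotation dialects are parsed identically (flat
key=value INFO pairs); the VEP dialect additionally nests CSQ. Field
types come from header `Type` declarations where present, otherwise from
observed values over the first 5,000 records (all-integer → integer,
all-numeric → float, ≤ 50 distinct strings → categorical, else text; the
dropdown threshold is configurable). Header declarations win over
conflicting observations, with a warning. Name collisions between
sources — FORMAT `DP` vs INFO `DP` is routine in real VCFs — are
disambiguated with `FMT_`/`CSQ_` prefixes while the raw document key is
retained on the field spec, so renamed fields stay queryable.

## Chunked parallel ingestion

The data lines are split into `min(workers, lines)` contiguous ranges
whose sizes differ by at most one line (remainder lines go to the
earliest chunks, so 10 lines over 4 workers gives 3/3/2/2). Ranges are by
line count rather than by contig because contigs are badly unbalanced.
Each range is parsed in a separate worker process; documents are then
sorted canonically by (source line, alt index) before loading, which
makes the store content independent of both worker count and bulk-load
order. A worker failure aborts the ingest and marks the index directory
invalid so a partial store cannot be opened silently.

## Store and query semantics

The store is a contract — create an index from a schema, bulk-load in
batches (default 512), scan with nested-scope semantics — with one
embedded reference backend that persists JSON-lines documents plus the
mapping and UI-configuration artifacts under a single index directory,
written with stable key order so identical inputs give byte-identical
artifacts. The engine evaluates queries by full scan over the in-memory
document list; the contract, not the storage engine, is the load-bearing
part, and an external search-server backend could implement the same
surface.

A variant matches a query when all include filters hold and no exclude
filter holds. Transcript- and sample-scoped include filters use
same-entry conjunction: some single nested entry must satisfy all of the
scope's include filters jointly. A nested exclude filter rejects the
variant when any entry satisfies it. Numeric comparisons (`lt/le/gt/ge`)
are only accepted on numeric fields and their operands are parsed at
validation time; `eq`/`in` compare numerically for numeric values and as
strings otherwise; `exists`/`not_exists` treat absent values and unset
flags alike.

Projection emits one row per variant, except when a selected attribute is
nested, in which case one row is emitted per variant × matching nested
entry (transcript × sample combinations when both kinds are selected) —
only the entries that satisfied their scope's include filters are
projected. Display mode truncates at 400 rows (configurable) in store
order, which is source-line order since no ranking is defined; CSV export
is never truncated. Review flags (`Approved`/`Rejected`) persist in the
index directory and are exposed as an ordinary categorical variant field
named `flag`, so rejected variants are removed with an ordinary exclude
filter.

## Mendelian rule tables

The seven models are data: per model, the set of allowed (child, father,
mother) genotype-class triples, with X-linked tables keyed by child sex.
Revising a rule is an edit to a table, not to code. The defaults are the
standard clinical-genetics interpretations:

| model | child | father | mother |
|---|---|---|---|
| autosomal de novo | HET | HOM_REF | HOM_REF |
| autosomal dominant | HET | one parent HET, the other HOM_REF | |
| autosomal recessive | HOM_ALT | HET | HET |
| compound het (per variant) | HET | exactly one carrier parent, other HOM_REF | |
| X de novo | HET (f) / HOM_ALT (m) | HOM_REF | HOM_REF |
| X dominant, female child | HET | HOM_ALT, mother HOM_REF — or HOM_REF, mother HET | |
| X dominant, male child | HOM_ALT | HOM_REF | HET |
| X recessive, male child | HOM_ALT | HOM_REF | HET |
| X recessive, female child | HOM_ALT | HOM_ALT | HET |

Affected-status requirements sit on top of the genotype tables and are
applied only when the pedigree states the statuses: the child must be
affected; a dominant model's carrier parent must be affected and the
non-carrier parent unaffected; a hemizygous father under X-linked
recessive is affected; recessive carrier parents are unaffected. The
X-dominant and X-recessive tables coincide for a male child
(HOM_ALT / HOM_REF / HET) — the mother's affected status is what
separates them, which is why the trio simulator refuses to plant both in
one fixture.

Genotype reconstruction maps entry absence to HOM_REF; optional quality
gates (`min_dp`, `min_gq`) demote entries below threshold to MISSING.
On X, male genotypes written haploid (`0`, `1`) normalise to
HOM_REF/HOM_ALT, and a diploid-coded male HET on X is treated as a
carrier call. Strict mode (default) fails any rule involving a MISSING
member; permissive mode treats MISSING as a wildcard over concrete
classes and flags such hits. With unknown child sex an X-linked rule
accepts the union of the male and female tables. Compound-het pairing
combines one maternal-origin and one paternal-origin candidate per gene
(gene symbol field configurable, default `SYMBOL`); the origin
definitions guarantee neither parent carries both variants. Unaffected
siblings present in the pedigree veto autosomal-recessive hits at which
they are HOM_ALT.

## Case/control comparison

Cohorts are matched by exact (chrom, pos, ref, alt) after decomposition;
the control VCF must be position-sorted and is parsed with the same
ingest machinery. Allele counts follow the sparse convention: an absent
sample contributes 0 alternate over 2 called alleles, a MISSING entry
removes both alleles from the called total (diploid convention), an OTHER
call contributes the count of alleles matching the document's alt index.
A site absent from one cohort is reported as hom-ref in that cohort
(0 over 2N) — safe for jointly-called cohorts, not for independently
called ones, which is why `present_in` flags one-sided sites. The method
reports counts and frequencies; a two-sided Fisher exact p-value on the
2×2 allele table is available behind a flag as a convenience, not as an
association-testing framework.

## Synthetic fixtures

The generators emulate the three annotation dialects, trio genotype
structure and paired cohorts; they deliberately model *no* population
genetics — sites are independent (no linkage disequilibrium), background
allele frequencies are uniform draws, annotations are vocabulary samples
and contigs are populated evenly. Passing tests therefore demonstrate the
rule logic, parsing contracts and accounting identities, not robustness
to realistic allele-frequency spectra or annotation pathologies.

Defaults: cohort sites are non-reference per sample with probability 0.3,
missing with 0.02, multi-allelic with 0.05; trio fixtures use 2,000
background variants whose genotype triples are drawn from pools verified
(by an importable test) to satisfy no model, with ~10% of background on X
when X-linked models are planted; case/control fixtures use 100 samples
per cohort at 500 fully-called shared sites, so every called-allele total
is exactly 2N and the truth file records exact realised counts. A single
integer seed drives all randomness through deterministic numpy
substreams (`default_rng([seed, stream])`); identical arguments give
byte-identical files.

## Numerical and testing choices

* The query engine is cross-checked against an independently written
  naive full-scan evaluator on hundreds of randomly generated queries;
  the INFO parser is cross-checked against cyvcf2 on a fixture.
* The inheritance rules are cross-checked against an independently coded
  predicate-style reference over all 5³ genotype-class triples ×
  {autosome, X} × child sex.
* The null-model case/control check asks that realised frequency gaps at
  equal-frequency sites stay within the 99% binomial acceptance region at
  ≥ 99% of sites. The region is computed with the exact test on the 2×2
  allele table (Fisher, two-sided, p ≥ 0.01) rather than a normal
  approximation: at 2 × 100 alleles per cohort the exact test's true
  exceedance is ≈ 0.7%, so the check is stable, whereas the
  normal-approximation bound sits exactly at its nominal 1% and flickers
  with the seed.
* Ties and degenerate inputs: `eq` on floats compares numerically
  (`0.50` matches `0.5`); empty INFO (`.`) and empty CSQ positions store
  nothing; monomorphic lines (ALT `.`) are skipped with a counted
  warning; an empty VCF yields an empty chunk plan and an empty store.

## Known limitations

* One trio (plus siblings) per pedigree; multi-family batches are out of
  scope.
* The embedded backend holds documents in memory and scans linearly —
  appropriate for the fixture-to-exome scale it targets, not for
  population-scale stores; the store contract is the extension point.
* Structural variants, re-annotation, and genotype-likelihood fields are
  not interpreted.
* Case/control absence-as-hom-ref is a convention, not an inference; use
  jointly-called cohorts.
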