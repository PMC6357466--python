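# varex — variant exploration warehouse

`varex` is a library and command-line tool for storing, filtering and
prioritising genetic variants from high-throughput sequencing projects.
It targets the everyday task that follows variant calling and annotation:
out of the millions of variants in an annotated multi-sample VCF, produce
a short reviewed list of candidates for a Mendelian or complex-disease
study — without writing ad-hoc VCF-parsing scripts.

It is aimed at bioinformaticians supporting family-based and cohort
studies: the library is the primary interface, the `varex` CLI wraps it
for shell pipelines, and `examples/` walks through each capability.

## What it does

**Sparse nested document store.** An annotated VCF (VEP `CSQ`, Annovar
key=value, or any generic semicolon-separated INFO dialect) is decomposed
into one document per alternate allele. Each document nests its
per-transcript annotations and its per-sample genotype entries. Genotype
storage exploits the sparsity of cohort VCFs: homozygous-reference calls
are represented by absence, and missing calls (`./.`) are stored
explicitly so that absence always means hom-ref. Ingestion splits the
file into balanced line chunks parsed by parallel workers; the resulting
store is byte-identical for any worker count. Schema inference types every
field (numeric → range filter, categorical → dropdown, flag → checkbox)
and emits a deterministic index mapping and UI-configuration artifact.

**Scoped include/exclude queries.** Filters apply at three scopes —
variant, transcript, sample — and combine conjunctively, with include or
exclude polarity. Nested scopes use same-entry semantics: `Sample_ID in
{HG003, HG004}` and `GT in {0|1, 1|0}` must hold for *one and the same*
sample entry. Display mode returns the first 400 records; CSV export
always returns the full result set with user-ordered columns. Queries can
be saved and recalled by name, and reviewed variants can be flagged
`Approved`/`Rejected` and excluded from later result sets.

**Mendelian inheritance analyses.** Given a PLINK-style PED file, seven
models run over the store: autosomal de novo / dominant / recessive,
compound heterozygous, and X-linked de novo / dominant / recessive. Rules
are data (tables of allowed child/father/mother genotype-class triples),
e.g. autosomal de novo is child HET with both parents HOM_REF; a
compound-het pair is two hets in one gene with opposite parental origins.
Hemizygous male X calls (`1` or `1/1`) are normalised, and missing
genotypes fail rules in strict mode or act as flagged wildcards in
permissive mode.

**Case/control comparison.** A second cohort VCF is matched site-by-site
(chrom, pos, ref, alt after decomposition) and per-cohort alternate-allele
counts and frequencies are reported, with `present_in` marking one-sided
sites and an optional two-sided Fisher exact p-value per record.

**Deterministic fixtures.** `varex.fixtures` generates annotated cohort
VCFs in all three dialects, trio VCF+PED pairs with planted inheritance
patterns over a background that satisfies no model, and paired
case/control cohorts with a planted frequency shift — each with a JSON
truth file sufficient to score analysis output.

## Worked example

```python
import varex

vcf, truth = varex.simulate_multisample_vcf("work", n_variants=1000,
                                            n_samples=6, seed=12,
                                            multiallelic_fraction=0.0)
store = varex.EmbeddedStore("work/index")
varex.ingest_vcf(vcf, store, n_workers=2)

query = varex.Query(
    filters=[
        varex.FilterSpec("dbsnp_id", "variant", "not_exists"),
        varex.FilterSpec("IMPACT", "transcript", "in", ["HIGH"]),
        varex.FilterSpec("FILTER", "variant", "eq", ["PASS"]),
    ],
    attributes=["CHROM", "POS", "REF", "ALT", "IMPACT", "QUAL", "FILTER"],
)
cq = varex.validate_query(query, store.schema)
result = varex.execute(cq, store, mode="display")
print(result.total_matched, len(result.rows), result.rows[0])
```

Output:

```
313 313 ('1', 1042, 'A', 'T', 'HIGH', 1241.68, 'PASS')
```

313 variants are novel (no dbSNP id), carry a HIGH-impact transcript
consequence and passed the caller's filters; all are shown because the
count is under the 400-row display cap. The same filter set through the
CLI:

```bash
varex simulate cohort --seed 12 --out work --variants 1000 --samples 6
varex load --vcf work/cohort.vcf --index-dir work/index --workers 2
varex query --index-dir work/index --query query.yaml --export hits.csv
```

The trio workflow (`examples/03_mendelian_trio.py`) plants 5 de novo
sites and 2 compound-het pairs among 1,000 background variants and
recovers exactly those:

```
de novo hits: 5 (planted 5)
  1:33319:G:T  child=HET father=HOM_REF mother=HOM_REF ...
compound-het pairs: 2 (planted 2)
```

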