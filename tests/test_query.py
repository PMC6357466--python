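"""Query-engine tests: validation, scoped matching semantics, caps, export,
saved queries, flags and external links — with a brute-force scan oracle."""

import csv
import os
import random

import pytest

from varex import (
    EmbeddedStore,
    FilterSpec,
    Query,
    QueryError,
    VariantKey,
    build_external_links,
    execute,
    export_csv,
    ingest_vcf,
    recall_query,
    save_query,
    set_flag,
    validate_query,
)
from varex.fixtures import simulate_multisample_vcf

from conftest import make_store


def q(filters=None, attributes=None):
    return Query(filters=filters or [],
                 attributes=attributes or ["CHROM", "POS", "REF", "ALT"])


# --------------------------------------------------------------------------
# validation

class TestValidateQuery:
    def test_novel_detrimental_filterset_is_valid(self, mini_store):
        query = q(filters=[
            FilterSpec("dbsnp_id", "variant", "not_exists"),
            FilterSpec("IMPACT", "transcript", "in", ["HIGH"]),
            FilterSpec("FILTER", "variant", "eq", ["PASS"]),
        ])
        assert validate_query(query, mini_store.schema)

    def test_region_consequence_filterset_is_valid(self, mini_store):
        query = q(filters=[
            FilterSpec("CHROM", "variant", "eq", ["6"]),
            FilterSpec("POS", "variant", "ge", [28477797]),
            FilterSpec("POS", "variant", "le", [33448354]),
            FilterSpec("Consequence", "transcript", "in", ["missense_variant"]),
        ])
        cq = validate_query(query, mini_store.schema)
        assert cq.filters[1].values == [28477797.0]

    def test_range_operator_on_categorical_is_error(self, mini_store):
        with pytest.raises(QueryError, match="numeric"):
            validate_query(q(filters=[FilterSpec("IMPACT", "transcript", "lt", [1])]),
                           mini_store.schema)

    def test_unknown_field_and_scope_mismatch(self, mini_store):
        with pytest.raises(QueryError, match="unknown field"):
            validate_query(q(filters=[FilterSpec("NOPE", "variant", "eq", [1])]),
                           mini_store.schema)
        with pytest.raises(QueryError, match="scope"):
            validate_query(q(filters=[FilterSpec("IMPACT", "variant", "eq", ["HIGH"])]),
                           mini_store.schema)

    def test_empty_attribute_list_is_error(self, mini_store):
        with pytest.raises(QueryError, match="attribute"):
            validate_query(Query(attributes=[]), mini_store.schema)

    def test_in_requires_values(self, mini_store):
        with pytest.raises(QueryError, match="at least one"):
            validate_query(q(filters=[FilterSpec("IMPACT", "transcript", "in", [])]),
                           mini_store.schema)


# --------------------------------------------------------------------------
# execution semantics

class TestExecute:
    def test_match_all_returns_every_document(self, mini_store):
        result = execute(validate_query(q(), mini_store.schema), mini_store, "full")
        assert result.total_matched == len(mini_store)
        assert not result.truncated

    def test_sample_scope_same_entry_conjunction(self, mini_store):
        """Sample_ID and GT must hold for one and the same sample entry:
        HG002 is het at 1:100 but only HG003/HG004 are het at 6:28480000."""
        query = q(filters=[
            FilterSpec("Sample_ID", "sample", "in", ["HG003", "HG004"]),
            FilterSpec("GT", "sample", "in", ["0|1", "1|0"]),
        ])
        rows = execute(validate_query(query, mini_store.schema), mini_store, "full").rows
        assert rows == [("6", 28480000, "G", "A")]

    def test_transcript_scope_same_entry_conjunction(self, mini_store):
        # GENE1 has a MODERATE missense and a MODIFIER intron entry; requiring
        # missense+MODIFIER jointly must not match across entries.
        query = q(filters=[
            FilterSpec("Consequence", "transcript", "eq", ["missense_variant"]),
            FilterSpec("IMPACT", "transcript", "eq", ["MODIFIER"]),
        ])
        result = execute(validate_query(query, mini_store.schema), mini_store, "full")
        assert result.total_matched == 0

    def test_nested_attribute_projects_only_matching_entries(self, mini_store):
        query = Query(
            filters=[FilterSpec("Consequence", "transcript", "eq", ["missense_variant"])],
            attributes=["CHROM", "POS", "Consequence", "IMPACT"],
        )
        rows = execute(validate_query(query, mini_store.schema), mini_store, "full").rows
        assert all(r[2] == "missense_variant" for r in rows)
        assert len(rows) == 3  # one matching transcript entry per matching doc

    def test_exclude_polarity_complements_include(self, mini_store):
        inc = q(filters=[FilterSpec("FILTER", "variant", "eq", ["PASS"])])
        exc = q(filters=[FilterSpec("FILTER", "variant", "eq", ["PASS"],
                                    polarity="exclude")])
        inc_rows = set(execute(validate_query(inc, mini_store.schema), mini_store, "full").rows)
        exc_rows = set(execute(validate_query(exc, mini_store.schema), mini_store, "full").rows)
        all_rows = set(execute(validate_query(q(), mini_store.schema), mini_store, "full").rows)
        assert inc_rows | exc_rows == all_rows
        assert inc_rows & exc_rows == set()

    def test_dbsnp_not_exists(self, mini_store):
        query = q(filters=[FilterSpec("dbsnp_id", "variant", "not_exists")])
        rows = execute(validate_query(query, mini_store.schema), mini_store, "full").rows
        assert ("1", 100, "A", "G") not in rows
        assert len(rows) == len(mini_store) - 1

    def test_unvalidated_query_rejected(self, mini_store):
        with pytest.raises(QueryError, match="validated"):
            execute(q(), mini_store)


class TestDisplayCap:
    def test_cap_law(self, tmp_path):
        vcf, _ = simulate_multisample_vcf(tmp_path, 500, 2, seed=21,
                                          multiallelic_fraction=0.0)
        store, _ = make_store(tmp_path, vcf)
        cq = validate_query(q(), store.schema)
        display = execute(cq, store, "display", display_cap=100)
        full = execute(cq, store, "full")
        assert len(display.rows) == 100 and display.truncated
        assert display.total_matched == full.total_matched == 500
        assert display.rows == full.rows[:100]

    def test_no_truncation_below_cap(self, mini_store):
        result = execute(validate_query(q(), mini_store.schema), mini_store, "display")
        assert not result.truncated
        assert len(result.rows) == result.total_matched


class TestExportCsv:
    def test_zero_matches_writes_header_only(self, mini_store, tmp_path):
        query = q(filters=[FilterSpec("CHROM", "variant", "eq", ["22"])])
        out = os.path.join(tmp_path, "empty.csv")
        assert export_csv(validate_query(query, mini_store.schema), mini_store, out) == 0
        with open(out) as fh:
            assert fh.read().strip() == "CHROM,POS,REF,ALT"

    def test_export_uncapped_while_display_capped(self, tmp_path):
        vcf, _ = simulate_multisample_vcf(tmp_path, 450, 2, seed=22,
                                          multiallelic_fraction=0.0)
        store, _ = make_store(tmp_path, vcf)
        cq = validate_query(q(), store.schema)
        out = os.path.join(tmp_path, "full.csv")
        n = export_csv(cq, store, out)
        display = execute(cq, store, "display")
        assert n == 450 and len(display.rows) == 400

    def test_attribute_reordering_permutes_columns(self, mini_store, tmp_path):
        a = validate_query(q(attributes=["CHROM", "POS", "REF", "ALT"]), mini_store.schema)
        b = validate_query(q(attributes=["ALT", "CHROM", "REF", "POS"]), mini_store.schema)
        pa, pb = os.path.join(tmp_path, "a.csv"), os.path.join(tmp_path, "b.csv")
        export_csv(a, mini_store, pa)
        export_csv(b, mini_store, pb)
        with open(pa) as fh:
            rows_a = list(csv.reader(fh))
        with open(pb) as fh:
            rows_b = list(csv.reader(fh))
        assert rows_b[0] == ["ALT", "CHROM", "REF", "POS"]
        perm = [rows_a[0].index(c) for c in rows_b[0]]
        assert all(rb == [ra[i] for i in perm] for ra, rb in zip(rows_a, rows_b))


# --------------------------------------------------------------------------
# saved queries and flags

class TestSavedQueries:
    def test_round_trip_structural_equality(self, tmp_path):
        reg = os.path.join(tmp_path, "registry.json")
        query = q(filters=[FilterSpec("IMPACT", "transcript", "in", ["HIGH"])])
        save_query("novel", query, reg)
        assert recall_query("novel", reg).to_dict() == query.to_dict()

    def test_unknown_name_and_duplicate(self, tmp_path):
        reg = os.path.join(tmp_path, "registry.json")
        with pytest.raises(QueryError, match="no saved query"):
            recall_query("missing", reg)
        save_query("a", q(), reg)
        with pytest.raises(QueryError, match="exists"):
            save_query("a", q(), reg)
        save_query("a", q(), reg, overwrite=True)

    def test_recalled_query_re_executes_identically(self, tmp_path, mini_vcf):
        reg = os.path.join(tmp_path, "registry.json")
        query = q(filters=[FilterSpec("FILTER", "variant", "eq", ["PASS"])])
        store1 = EmbeddedStore(os.path.join(tmp_path, "s1"))
        ingest_vcf(mini_vcf, store1)
        rows1 = execute(validate_query(query, store1.schema), store1, "full").rows
        save_query("pass_only", query, reg)
        store2 = EmbeddedStore(os.path.join(tmp_path, "s2"))
        ingest_vcf(mini_vcf, store2)
        recalled = recall_query("pass_only", reg)
        rows2 = execute(validate_query(recalled, store2.schema), store2, "full").rows
        assert rows1 == rows2


class TestFlags:
    def test_rejected_variant_excluded_by_flag_filter(self, mini_store):
        key = mini_store.documents()[0].key
        set_flag(mini_store, key, "Rejected")
        query = q(filters=[FilterSpec("flag", "variant", "eq", ["Rejected"],
                                      polarity="exclude")])
        rows = execute(validate_query(query, mini_store.schema), mini_store, "full").rows
        assert (key.chrom, key.pos, key.ref, key.alt) not in rows
        assert len(rows) == len(mini_store) - 1

    def test_set_then_clear(self, mini_store):
        key = mini_store.documents()[0].key
        set_flag(mini_store, key, "Approved")
        assert mini_store.get(key).flag == "Approved"
        set_flag(mini_store, key, "clear")
        assert mini_store.get(key).flag is None


class TestExternalLinks:
    def test_ucsc_window_and_determinism(self, mini_store):
        doc = [d for d in mini_store.documents() if d.key.chrom == "6"][0]
        links = build_external_links(doc)
        assert "chr6" in links["ucsc"]
        assert str(28480000 - 25) in links["ucsc"] and str(28480000 + 25) in links["ucsc"]
        assert links == build_external_links(doc)

    def test_genemania_from_symbols_or_omitted(self, mini_store):
        doc = mini_store.documents()[0]
        assert "GENE1" in build_external_links(doc)["genemania"]
        bare = type(doc)(key=doc.key)
        assert "genemania" not in build_external_links(bare)


# --------------------------------------------------------------------------
# randomized brute-force oracle equivalence

def naive_match(doc, filters, schema=None):
    """Independent full-scan evaluator over raw document dicts."""
    d = doc.to_dict()

    def raw(field):
        if schema is not None:
            fs = schema.field_spec(field)
            if fs is not None and fs.storage_name:
                return fs.storage_name
        return field

    def value_at(scope, field, entry=None):
        field = raw(field)
        if scope == "variant":
            if field in ("CHROM", "POS", "REF", "ALT"):
                return d[field.lower() if field != "CHROM" else "chrom"] \
                    if field != "POS" else d["pos"]
            if field == "QUAL":
                return d["qual"]
            if field == "FILTER":
                return d["filter_status"]
            if field in ("dbsnp_id", "flag"):
                return d[field]
            return d["flat_attributes"].get(field)
        if scope == "transcript":
            return entry.get(field)
        if field == "Sample_ID":
            return entry["sample_id"]
        if field == "GT":
            return entry["gt_raw"]
        return entry["format_values"].get(field)

    def holds(f, v):
        op = f.operator
        if op == "exists":
            return v is not None and v is not False
        if op == "not_exists":
            return v is None or v is False
        if v is None:
            return False
        if op == "eq":
            return str(v) == str(f.values[0]) or (
                isinstance(v, (int, float)) and float(v) == float(f.values[0]))
        if op == "in":
            return any(str(v) == str(x) or (
                isinstance(v, (int, float)) and float(v) == float(x))
                for x in f.values)
        try:
            v = float(v)
        except (TypeError, ValueError):
            return False
        t = float(f.values[0])
        return {"lt": v < t, "le": v <= t, "gt": v > t, "ge": v >= t}[op]

    for scope, entries in (("transcript", d["transcript_annotations"]),
                           ("sample", d["sample_entries"])):
        group = [f for f in filters if f.scope == scope and f.polarity == "include"]
        if group and not any(
            all(holds(f, value_at(scope, f.field, e)) for f in group) for e in entries
        ):
            return False
    for f in filters:
        if f.polarity == "include" and f.scope == "variant":
            if not holds(f, value_at("variant", f.field)):
                return False
        elif f.polarity == "exclude":
            if f.scope == "variant":
                if holds(f, value_at("variant", f.field)):
                    return False
            else:
                entries = (d["transcript_annotations"] if f.scope == "transcript"
                           else d["sample_entries"])
                if any(holds(f, value_at(f.scope, f.field, e)) for e in entries):
                    return False
    return True


def random_filters(rng, schema):
    """Draw 1-3 random validated filters across scopes and polarities."""
    choices = [
        lambda: FilterSpec("CHROM", "variant", "in",
                           rng.sample(schema.field_spec("CHROM").options,
                                      k=min(3, len(schema.field_spec("CHROM").options)))),
        lambda: FilterSpec("POS", "variant", rng.choice(["ge", "le"]),
                           [rng.randint(100, 50000)]),
        lambda: FilterSpec("QUAL", "variant", rng.choice(["gt", "lt"]),
                           [rng.uniform(100, 2500)]),
        lambda: FilterSpec("FILTER", "variant", "eq", ["PASS"]),
        lambda: FilterSpec("AF", "variant", "lt", [rng.uniform(0.05, 0.4)]),
        lambda: FilterSpec("EUR_AF", "variant", "lt", [0.01 + rng.random() * 0.3]),
        lambda: FilterSpec("DB", "variant", rng.choice(["exists", "not_exists"])),
        lambda: FilterSpec("dbsnp_id", "variant", rng.choice(["exists", "not_exists"])),
        lambda: FilterSpec("IMPACT", "transcript", "in",
                           rng.sample(["HIGH", "MODERATE", "LOW", "MODIFIER"],
                                      k=rng.randint(1, 3))),
        lambda: FilterSpec("Consequence", "transcript", "in",
                           rng.sample(schema.field_spec("Consequence").options,
                                      k=rng.randint(1, 3))),
        lambda: FilterSpec("Sample_ID", "sample", "in",
                           rng.sample(schema.samples, k=rng.randint(1, 2))),
        lambda: FilterSpec("GT", "sample", "in",
                           rng.sample(["0/1", "0|1", "1|0", "1/1"], k=rng.randint(1, 3))),
        # FORMAT DP collides with INFO DP and is renamed on inference
        lambda: FilterSpec("FMT_DP", "sample", "ge", [rng.randint(10, 50)]),
        lambda: FilterSpec("GQ", "sample", "ge", [rng.randint(30, 90)]),
    ]
    filters = [rng.choice(choices)() for _ in range(rng.randint(1, 3))]
    for f in filters:
        if rng.random() < 0.3 and f.operator not in ("not_exists",):
            f.polarity = "exclude"
    return filters


def test_random_queries_match_brute_force_oracle(tmp_path):
    """Randomly generated scoped queries agree with a naive full scan."""
    vcf, _ = simulate_multisample_vcf(tmp_path, 600, 6, seed=31)
    store, _ = make_store(tmp_path, vcf)
    rng = random.Random(31)
    for _ in range(60):
        filters = random_filters(rng, store.schema)
        cq = validate_query(q(filters=filters), store.schema)
        rows = execute(cq, store, "full").rows
        expected = [
            (doc.key.chrom, doc.key.pos, doc.key.ref, doc.key.alt)
            for doc in store.documents()
            if naive_match(doc, filters, store.schema)
        ]
        assert rows == expected, f"divergence for {[f.to_dict() for f in filters]}"
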