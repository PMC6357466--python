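"""Pedigree-driven Mendelian inheritance analyses.

Seven inheritance models are supported for a trio (optionally plus
siblings): autosomal de novo / dominant / recessive, compound
heterozygous, and X-linked de novo / dominant / recessive.

The genotype rule tables are *data*: each model maps to the set of allowed
(child, father, mother) genotype-class triples, so revising a rule is an
edit to a table, not to code.  Genotype classes are reconstructed from the
sparse store entries (absence of an entry means hom-ref); hemizygous male
X calls written ``1`` or ``1/1`` both normalise to HOM_ALT.

Affected-status requirements that go beyond genotypes (a dominant model
needs the carrier parent to be affected) are applied on top of the tables
when the pedigree states the statuses; unknown statuses skip those gates.
In strict mode (default) a MISSING genotype in any trio member fails every
rule; permissive mode treats MISSING as a wildcard and flags such hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from .model import GtClass, VariantDocument, VariantKey
from .ingest import haploid_alt_class


class PedigreeError(ValueError):
    pass


MODELS = (
    "autosomal_de_novo",
    "autosomal_dominant",
    "autosomal_recessive",
    "compound_heterozygous",
    "x_linked_de_novo",
    "x_linked_dominant",
    "x_linked_recessive",
)

X_CONTIGS = {"X", "chrX", "x", "chrx"}

_HR, _HET, _HA = "HOM_REF", "HET", "HOM_ALT"
_CLASSES = ("HOM_REF", "HET", "HOM_ALT", "MISSING", "OTHER")

# --- normative rule tables -------------------------------------------------
# Allowed (child, father, mother) genotype-class triples per model.
# Autosomal tables apply to non-X contigs only; X tables are keyed by the
# child's sex (a father on X can only be HOM_REF or HOM_ALT after
# hemizygous normalisation).  compound_heterozygous lists the per-variant
# candidacy condition: child het with exactly one carrier parent; pairing
# of opposite parental origins happens in find_compound_het.

AUTOSOMAL_TABLES: dict[str, frozenset[tuple[str, str, str]]] = {
    "autosomal_de_novo": frozenset({(_HET, _HR, _HR)}),
    "autosomal_dominant": frozenset({(_HET, _HET, _HR), (_HET, _HR, _HET)}),
    "autosomal_recessive": frozenset({(_HA, _HET, _HET)}),
    "compound_heterozygous": frozenset({
        (_HET, _HET, _HR), (_HET, _HA, _HR),  # paternal origin
        (_HET, _HR, _HET), (_HET, _HR, _HA),  # maternal origin
    }),
}

X_TABLES: dict[tuple[str, str], frozenset[tuple[str, str, str]]] = {
    ("x_linked_de_novo", "female"): frozenset({(_HET, _HR, _HR)}),
    ("x_linked_de_novo", "male"): frozenset({(_HA, _HR, _HR)}),
    # carrier parent transmits; a father cannot transmit X to a son
    ("x_linked_dominant", "female"): frozenset({(_HET, _HA, _HR), (_HET, _HR, _HET)}),
    ("x_linked_dominant", "male"): frozenset({(_HA, _HR, _HET)}),
    ("x_linked_recessive", "male"): frozenset({(_HA, _HR, _HET)}),
    ("x_linked_recessive", "female"): frozenset({(_HA, _HA, _HET)}),
}


# --- pedigree --------------------------------------------------------------

@dataclass
class PedigreeRecord:
    family_id: str
    sample_id: str
    father_id: str  # "0" = unknown
    mother_id: str
    sex: str  # male | female | unknown
    affected: str  # affected | unaffected | unknown


@dataclass
class TrioStructure:
    child: str
    father: str
    mother: str
    child_sex: str
    child_affected: str
    father_affected: str
    mother_affected: str
    siblings: list[PedigreeRecord] = field(default_factory=list)


_SEX_CODES = {"1": "male", "2": "female"}
_PHENO_CODES = {"2": "affected", "1": "unaffected"}


def load_pedigree(ped_path: str) -> list[PedigreeRecord]:
    """Read a PLINK-style 6-column PED file (FID IID PAT MAT SEX PHENO)."""
    records: list[PedigreeRecord] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise PedigreeError(
                    f"{ped_path} line {lineno}: expected 6 columns, got {len(cols)}"
                )
            fid, iid, pat, mat, sex, pheno = cols[:6]
            records.append(PedigreeRecord(
                family_id=fid,
                sample_id=iid,
                father_id=pat,
                mother_id=mat,
                sex=_SEX_CODES.get(sex, "unknown"),
                affected=_PHENO_CODES.get(pheno, "unknown"),
            ))
    ids = {r.sample_id for r in records}
    for lineno, r in enumerate(records, start=1):
        for parent in (r.father_id, r.mother_id):
            if parent != "0" and parent not in ids:
                raise PedigreeError(
                    f"{ped_path}: sample {r.sample_id} references unknown parent {parent!r}"
                )
    seen: set[tuple[str, str]] = set()
    for r in records:
        if (r.family_id, r.sample_id) in seen:
            raise PedigreeError(f"{ped_path}: duplicate sample id {r.sample_id}")
        seen.add((r.family_id, r.sample_id))
    return records


def derive_trio(records: list[PedigreeRecord], vcf_samples: list[str] | None = None) -> TrioStructure:
    """Find the trio (child with both parents) in a pedigree.

    When several children have both parents, an affected child is
    preferred; the remaining full siblings are attached to the trio.
    Raises when no trio exists or when trio members are absent from the
    VCF sample list.
    """
    by_id = {r.sample_id: r for r in records}
    candidates = [r for r in records if r.father_id != "0" and r.mother_id != "0"]
    if not candidates:
        raise PedigreeError("no trio in pedigree: no sample lists both parents")
    child = next((c for c in candidates if c.affected == "affected"), candidates[0])
    father = by_id[child.father_id]
    mother = by_id[child.mother_id]
    if father.sex == "male" and mother.sex == "female":
        pass
    elif father.sex == "female" and mother.sex == "male":
        father, mother = mother, father
    siblings = [
        c for c in candidates
        if c.sample_id != child.sample_id
        and c.father_id == father.sample_id and c.mother_id == mother.sample_id
    ]
    if vcf_samples is not None:
        missing = [s for s in (child.sample_id, father.sample_id, mother.sample_id)
                   if s not in vcf_samples]
        if missing:
            raise PedigreeError(
                f"pedigree samples absent from the VCF: {', '.join(missing)}"
            )
    return TrioStructure(
        child=child.sample_id,
        father=father.sample_id,
        mother=mother.sample_id,
        child_sex=child.sex,
        child_affected=child.affected,
        father_affected=father.affected,
        mother_affected=mother.affected,
        siblings=siblings,
    )


# --- rule evaluation -------------------------------------------------------

def _as_name(c) -> str:
    return c.value if isinstance(c, GtClass) else str(c)


def _table_for(model: str, chrom_is_X: bool, child_sex: str) -> frozenset | None:
    if model in AUTOSOMAL_TABLES:
        return None if chrom_is_X else AUTOSOMAL_TABLES[model]
    if model not in {m for m, _ in X_TABLES}:
        raise ValueError(f"unknown model {model!r}")
    if not chrom_is_X:
        return None
    if child_sex in ("male", "female"):
        return X_TABLES[(model, child_sex)]
    # unknown child sex: either sex's table may apply
    return X_TABLES[(model, "male")] | X_TABLES[(model, "female")]


def evaluate_inheritance(
    model: str,
    child_gt_class,
    father_gt_class,
    mother_gt_class,
    chrom_is_X: bool = False,
    child_sex: str = "unknown",
    strict: bool = True,
) -> bool:
    """Rule-table verdict for one genotype-class trio.

    Autosomal models never fire on X and X-linked models never fire off X.
    Under strict mode (default) any MISSING member fails; permissive mode
    treats MISSING as a wildcard over the concrete classes.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    table = _table_for(model, chrom_is_X, child_sex)
    if table is None:
        return False
    trio = tuple(_as_name(c) for c in (child_gt_class, father_gt_class, mother_gt_class))
    if "MISSING" in trio:
        if strict:
            return False
        concrete = ("HOM_REF", "HET", "HOM_ALT", "OTHER")
        slots = [concrete if c == "MISSING" else (c,) for c in trio]
        return any(t in table for t in product(*slots))
    return trio in table


@dataclass
class MendelianHit:
    model: str
    key: VariantKey
    child_gt: str
    father_gt: str
    mother_gt: str
    gene: str | None = None
    permissive_wildcard: bool = False


@dataclass
class CompoundHetPair:
    gene: str
    key_maternal: VariantKey
    key_paternal: VariantKey
    child_gt_maternal: str
    child_gt_paternal: str


def _member_class(
    doc: VariantDocument,
    sample_id: str,
    sex: str,
    on_x: bool,
    min_dp: int | None,
    min_gq: int | None,
) -> str:
    """Reconstruct one member's genotype class; absence means hom-ref."""
    entry = doc.entry_for(sample_id)
    if entry is None:
        return "HOM_REF"
    if min_dp is not None:
        dp = entry.format_values.get("DP")
        if dp is None or (isinstance(dp, (int, float)) and dp < min_dp):
            return "MISSING"
    if min_gq is not None:
        gq = entry.format_values.get("GQ")
        if gq is None or (isinstance(gq, (int, float)) and gq < min_gq):
            return "MISSING"
    cls = entry.gt_class.value
    if on_x and sex == "male":
        hap = haploid_alt_class(entry.gt_raw, doc.alt_index)
        if hap is not None:
            cls = hap.value
        elif cls == "HET":
            # diploid-coded het on male X is treated as a carrier call
            cls = "HOM_ALT"
    return cls


def _status_gates(model: str, trio: TrioStructure, classes: tuple[str, str, str]) -> bool:
    """Affected-status requirements beyond the genotype tables."""
    child_c, father_c, mother_c = classes
    if trio.child_affected == "unaffected":
        return False  # every model looks for the affected child's variant
    if model == "autosomal_dominant":
        # the carrier parent must be affected, the non-carrier unaffected
        carrier, other = (
            (trio.father_affected, trio.mother_affected)
            if father_c == "HET"
            else (trio.mother_affected, trio.father_affected)
        )
        if carrier == "unaffected" or other == "affected":
            return False
        if trio.father_affected == "unaffected" and trio.mother_affected == "unaffected":
            return False  # dominant requires an affected parent
    elif model == "x_linked_dominant":
        carrier = trio.father_affected if father_c == "HOM_ALT" else trio.mother_affected
        if carrier == "unaffected":
            return False
    elif model == "x_linked_recessive":
        if father_c == "HOM_ALT" and trio.father_affected == "unaffected":
            return False  # a hemizygous father is affected
    elif model == "autosomal_recessive":
        if trio.father_affected == "affected" or trio.mother_affected == "affected":
            return False  # carrier parents are unaffected
    return True


def _doc_gene(doc: VariantDocument, gene_field: str) -> str | None:
    for ann in doc.transcript_annotations:
        g = ann.get(gene_field)
        if g:
            return str(g)
    return None


def run_mendelian(
    store,
    pedigree: list[PedigreeRecord],
    model: str,
    min_dp: int | None = None,
    min_gq: int | None = None,
    permissive: bool = False,
    gene_field: str = "SYMBOL",
) -> list[MendelianHit]:
    """Evaluate every variant document in the store under one model.

    X-linked models are restricted to contigs named X/chrX; autosomal
    models to autosomes.  Quality gates demote entries below min DP/GQ to
    MISSING.  Sibling records, when present, act as additional constraints:
    an unaffected sibling must not satisfy the child slot of the rule.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    trio = derive_trio(pedigree, store.schema.samples if store.schema else None)
    if model == "compound_heterozygous":
        pairs = find_compound_het(store, pedigree, gene_field=gene_field,
                                  min_dp=min_dp, min_gq=min_gq, permissive=permissive)
        hits: list[MendelianHit] = []
        seen: set[str] = set()
        for p in pairs:
            for key, gt in ((p.key_maternal, p.child_gt_maternal),
                            (p.key_paternal, p.child_gt_paternal)):
                if str(key) not in seen:
                    seen.add(str(key))
                    hits.append(MendelianHit(model, key, gt, "", "", p.gene))
        return hits

    is_x_model = model.startswith("x_linked")
    strict = not permissive
    hits = []
    for doc in store.documents():
        on_x = doc.key.chrom in X_CONTIGS
        if is_x_model != on_x:
            continue
        classes = (
            _member_class(doc, trio.child, trio.child_sex, on_x, min_dp, min_gq),
            _member_class(doc, trio.father, "male", on_x, min_dp, min_gq),
            _member_class(doc, trio.mother, "female", on_x, min_dp, min_gq),
        )
        if not evaluate_inheritance(model, *classes, chrom_is_X=on_x,
                                    child_sex=trio.child_sex, strict=strict):
            continue
        if not _status_gates(model, trio, classes):
            continue
        if model == "autosomal_recessive" and trio.siblings:
            bad = False
            for sib in trio.siblings:
                if sib.affected == "unaffected":
                    sc = _member_class(doc, sib.sample_id, sib.sex, on_x, min_dp, min_gq)
                    if sc == "HOM_ALT":
                        bad = True
                        break
            if bad:
                continue
        hits.append(MendelianHit(
            model,
            doc.key,
            *classes,
            gene=_doc_gene(doc, gene_field),
            permissive_wildcard=permissive and "MISSING" in classes,
        ))
    return hits


def find_compound_het(
    store,
    pedigree: list[PedigreeRecord],
    gene_field: str = "SYMBOL",
    min_dp: int | None = None,
    min_gq: int | None = None,
    permissive: bool = False,
) -> list[CompoundHetPair]:
    """Compound-heterozygote pairs: two hets in one gene, opposite origins.

    A candidate variant has the child HET with exactly one carrier parent
    (the other hom-ref); a pair combines one maternal-origin and one
    paternal-origin candidate on the same gene, so neither parent carries
    both.  Pairs are reported once, ordered by position within the pair.
    """
    schema = store.schema
    if schema is None or schema.field_spec(gene_field) is None:
        raise PedigreeError(f"gene field {gene_field!r} is not in the schema")
    trio = derive_trio(pedigree, schema.samples)
    maternal: dict[str, list[tuple[VariantDocument, str]]] = {}
    paternal: dict[str, list[tuple[VariantDocument, str]]] = {}
    carrier = ("HET", "HOM_ALT")
    for doc in store.documents():
        on_x = doc.key.chrom in X_CONTIGS
        child_c = _member_class(doc, trio.child, trio.child_sex, on_x, min_dp, min_gq)
        if child_c != "HET":
            continue
        father_c = _member_class(doc, trio.father, "male", on_x, min_dp, min_gq)
        mother_c = _member_class(doc, trio.mother, "female", on_x, min_dp, min_gq)
        genes = {str(a[gene_field]) for a in doc.transcript_annotations if a.get(gene_field)}
        if not genes:
            continue
        if mother_c in carrier and father_c == "HOM_REF":
            for g in genes:
                maternal.setdefault(g, []).append((doc, child_c))
        elif father_c in carrier and mother_c == "HOM_REF":
            for g in genes:
                paternal.setdefault(g, []).append((doc, child_c))
    pairs: list[CompoundHetPair] = []
    for gene in sorted(set(maternal) & set(paternal)):
        for m_doc, m_gt in maternal[gene]:
            for p_doc, p_gt in paternal[gene]:
                if m_doc.key == p_doc.key:
                    continue
                pairs.append(CompoundHetPair(gene, m_doc.key, p_doc.key, m_gt, p_gt))
    pairs.sort(key=lambda p: (p.gene, min(p.key_maternal.sort_token(),
                                          p.key_paternal.sort_token())))
    return pairs
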