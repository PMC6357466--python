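"""Case/control allele-distribution comparison.

The case cohort is an ingested store; the control cohort is a second
annotated VCF parsed on the fly.  Variants are matched on (chrom, pos,
ref, alt) after per-allele decomposition, and per-cohort alternate-allele
counts and frequencies are reported for every key present in either
cohort.

A site absent from one cohort's VCF is counted as homozygous-reference in
that cohort (0 alternate alleles over 2N called) — a convention that is
safe for jointly-called cohorts but not for independently-called ones, so
each record carries ``present_in`` to make one-sided sites visible.  An
optional two-sided Fisher exact p-value on the 2x2 allele-count table can
be requested per record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .ingest import (
    IngestError,
    decompose_record,
    infer_schema,
    iter_data_lines,
)
from .model import GtClass, SampleGenotypeEntry, VariantDocument, VariantKey
from .query import CompiledQuery, match_document
from .model import contig_rank


class CaseControlError(ValueError):
    pass


@dataclass
class CaseControlRecord:
    key: VariantKey
    case_alt_alleles: int
    case_called_alleles: int
    case_af: float
    control_alt_alleles: int
    control_called_alleles: int
    control_af: float
    present_in: str  # both | case_only | control_only
    fisher_p: float | None = None

    def to_row(self) -> list:
        return [
            self.key.chrom, self.key.pos, self.key.ref, self.key.alt,
            self.case_alt_alleles, self.case_called_alleles, round(self.case_af, 6),
            self.control_alt_alleles, self.control_called_alleles, round(self.control_af, 6),
            self.present_in,
        ] + ([self.fisher_p] if self.fisher_p is not None else [])


_GT_SEPS = ("|", "/")


def _alt_dosage(gt_raw: str, alt_index: int) -> int:
    alleles = gt_raw.replace("|", "/").split("/")
    return sum(1 for a in alleles if a == str(alt_index))


def allele_distribution(
    sample_entries: list[SampleGenotypeEntry],
    n_cohort_samples: int,
    alt_index: int = 1,
) -> tuple[int, int, float]:
    """(alt alleles, called alleles, frequency) for one variant document.

    Sparse entries cover only non-hom-ref calls, so absent samples
    contribute 0 alternate over 2 called alleles.  MISSING entries remove
    both alleles from the called total (diploid convention).  OTHER calls
    contribute the count of alleles matching the document's alt index.
    """
    if n_cohort_samples < len(sample_entries):
        raise CaseControlError(
            f"cohort of {n_cohort_samples} samples cannot hold "
            f"{len(sample_entries)} genotype entries"
        )
    n_missing = sum(1 for e in sample_entries if e.gt_class is GtClass.MISSING)
    alt = sum(
        _alt_dosage(e.gt_raw, alt_index)
        for e in sample_entries
        if e.gt_class is not GtClass.MISSING
    )
    called = 2 * (n_cohort_samples - n_missing)
    af = alt / called if called > 0 else 0.0
    return alt, called, af


def _check_sorted(path: str) -> None:
    last: dict[str, int] = {}
    order: list[str] = []
    for idx, line in iter_data_lines(path):
        cols = line.split("\t", 2)
        chrom, pos = cols[0], int(cols[1])
        if chrom in last:
            if order[-1] != chrom:
                raise CaseControlError(
                    f"{path}: contig {chrom} appears in two blocks; VCF must be position-sorted"
                )
            if pos < last[chrom]:
                raise CaseControlError(
                    f"{path}: position {chrom}:{pos} out of order; VCF must be position-sorted"
                )
        else:
            order.append(chrom)
        last[chrom] = pos


def load_control_cohort(control_vcf_path: str) -> tuple[dict[str, VariantDocument], int]:
    """Parse the control VCF into a key-indexed document map.

    Returns (documents by key string, control sample count).  Raises when
    the VCF is not position-sorted or declares no samples.
    """
    _check_sorted(control_vcf_path)
    schema = infer_schema(control_vcf_path)
    if not schema.samples:
        raise CaseControlError(f"{control_vcf_path}: control VCF declares no samples")
    docs: dict[str, VariantDocument] = {}
    warnings: list[str] = []
    for idx, line in iter_data_lines(control_vcf_path):
        for doc in decompose_record(line, schema, source_line=idx, warnings=warnings):
            docs[str(doc.key)] = doc
    return docs, len(schema.samples)


def match_cohorts(
    case_store, control_vcf_path: str
) -> Iterator[tuple[VariantDocument | None, VariantDocument | None]]:
    """Outer join of case and control documents on (chrom, pos, ref, alt).

    Every key present in either cohort yields exactly one pair; one side is
    None for cohort-exclusive variants.  Pairs arrive in genomic order.
    """
    control_docs, _ = load_control_cohort(control_vcf_path)
    case_by_key = {str(d.key): d for d in case_store.documents()}
    keys = set(case_by_key) | set(control_docs)
    for key_s in sorted(keys, key=lambda s: VariantKey.from_string(s).sort_token()):
        yield case_by_key.get(key_s), control_docs.get(key_s)


def compare_case_control(
    case_store,
    control_vcf_path: str,
    filters: CompiledQuery | None = None,
    fisher: bool = False,
) -> list[CaseControlRecord]:
    """Per-variant allele counts and frequencies in the two cohorts.

    ``filters`` is a compiled query validated against the case schema; it
    is applied to the case document when present, otherwise to the control
    document.  With ``fisher=True`` a two-sided Fisher exact p-value over
    the 2x2 alt/ref allele-count table is attached to each record.
    """
    control_docs, n_control = load_control_cohort(control_vcf_path)
    if case_store.schema is None or not case_store.schema.samples:
        raise CaseControlError("case store has no samples")
    n_case = len(case_store.schema.samples)
    if fisher:
        from scipy.stats import fisher_exact

    case_by_key = {str(d.key): d for d in case_store.documents()}
    keys = set(case_by_key) | set(control_docs)
    records: list[CaseControlRecord] = []
    for key_s in sorted(keys, key=lambda s: VariantKey.from_string(s).sort_token()):
        case_doc = case_by_key.get(key_s)
        control_doc = control_docs.get(key_s)
        if filters is not None:
            target = case_doc if case_doc is not None else control_doc
            ok, _, _ = match_document(target, filters)
            if not ok:
                continue
        if case_doc is not None:
            c_alt, c_called, c_af = allele_distribution(
                case_doc.sample_entries, n_case, case_doc.alt_index
            )
        else:
            c_alt, c_called, c_af = 0, 2 * n_case, 0.0
        if control_doc is not None:
            k_alt, k_called, k_af = allele_distribution(
                control_doc.sample_entries, n_control, control_doc.alt_index
            )
        else:
            k_alt, k_called, k_af = 0, 2 * n_control, 0.0
        present_in = (
            "both" if case_doc is not None and control_doc is not None
            else "case_only" if case_doc is not None
            else "control_only"
        )
        p = None
        if fisher:
            table = [[c_alt, c_called - c_alt], [k_alt, k_called - k_alt]]
            p = float(fisher_exact(table, alternative="two-sided")[1])
        records.append(CaseControlRecord(
            VariantKey.from_string(key_s),
            c_alt, c_called, c_af,
            k_alt, k_called, k_af,
            present_in, p,
        ))
    return records
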