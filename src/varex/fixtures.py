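"""Deterministic synthetic-data generators with machine-readable truth.

Three generators emulate the inputs the engine consumes:

* :func:`simulate_multisample_vcf` — an annotated multi-sample cohort VCF
  in any of the three annotation dialects (VEP CSQ, Annovar-style
  key=value, generic key=value);
* :func:`simulate_trio` — a trio VCF + PED pair with inheritance patterns
  planted against a background that satisfies no model;
* :func:`simulate_case_control` — paired case/control cohort VCFs sharing
  a site list, with a planted frequency shift at chosen sites.

Every generator is driven by a single integer seed through per-component
numpy substreams, writes a JSON truth file sufficient to score analysis
output without re-reading the VCF, and produces byte-identical files for
identical inputs.  The fixtures target rule logic, not population-genetic
realism: sites are independent (no linkage), frequencies are uniform draws
and annotations are vocabulary samples.
"""

from __future__ import annotations

import json
import os

import numpy as np

AUTOSOMES = tuple(str(c) for c in range(1, 23))

_CONSEQUENCES = (
    "missense_variant", "synonymous_variant", "intron_variant",
    "stop_gained", "splice_donor_variant", "frameshift_variant",
    "5_prime_UTR_variant", "downstream_gene_variant",
)
_IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
_BIOTYPES = ("protein_coding", "lincRNA", "processed_transcript")
_FUNC_REGIONS = ("exonic", "intronic", "splicing", "UTR3", "UTR5", "intergenic")
_EXONIC_FUNC = ("nonsynonymous_SNV", "synonymous_SNV", "stopgain", "frameshift_deletion")
_BASES = ("A", "C", "G", "T")

CSQ_FORMAT = ["Allele", "Consequence", "IMPACT", "SYMBOL", "BIOTYPE"]


class FixtureError(ValueError):
    pass


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


def _header_lines(
    samples: list[str],
    contigs: list[str],
    annotation_style: str,
    info_extra: list[str] = (),
    format_keys: list[str] = ("GT", "DP", "GQ"),
) -> list[str]:
    lines = ["##fileformat=VCFv4.2", "##source=varex-fixtures"]
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    lines += [
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        '##INFO=<ID=AC,Number=A,Type=Integer,Description="Alt allele count">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Alt allele frequency">',
        '##INFO=<ID=EUR_AF,Number=A,Type=Float,Description="European allele frequency">',
        '##INFO=<ID=DB,Number=0,Type=Flag,Description="dbSNP membership">',
    ]
    if annotation_style == "vep":
        fmt = "|".join(CSQ_FORMAT)
        lines.append(
            f'##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence '
            f'annotations from VEP. Format: {fmt}">'
        )
    elif annotation_style == "annovar":
        lines += [
            '##INFO=<ID=Func_refGene,Number=1,Type=String,Description="Region">',
            '##INFO=<ID=ExonicFunc_refGene,Number=1,Type=String,Description="Exonic function">',
            '##INFO=<ID=Gene_refGene,Number=1,Type=String,Description="Gene">',
            '##INFO=<ID=SIFT_score,Number=1,Type=Float,Description="SIFT score">',
        ]
    elif annotation_style == "generic":
        lines += [
            '##INFO=<ID=REGION,Number=1,Type=String,Description="Region class">',
            '##INFO=<ID=SCORE,Number=1,Type=Float,Description="Generic score">',
        ]
    else:
        raise FixtureError(f"unknown annotation style {annotation_style!r}")
    lines += list(info_extra)
    fmt_defs = {
        "GT": '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "DP": '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "GQ": '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    }
    for k in format_keys:
        lines.append(fmt_defs[k])
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    return lines


def _site_positions(rng: np.random.Generator, n: int) -> list[int]:
    steps = rng.integers(1, 1000, size=n)
    return list(np.cumsum(steps) + 100)


def _split_over_contigs(n: int, contigs: list[str]) -> list[tuple[str, int]]:
    """(contig, count) blocks covering n sites, balanced in contig order."""
    k = min(len(contigs), n) or 1
    base, rem = divmod(n, k)
    return [(contigs[i], base + (1 if i < rem else 0)) for i in range(k)]


# --------------------------------------------------------------------------
# cohort fixture

def simulate_multisample_vcf(
    out_dir: str,
    n_variants: int,
    n_samples: int,
    annotation_style: str = "vep",
    alt_fraction: float = 0.3,
    missing_fraction: float = 0.02,
    multiallelic_fraction: float = 0.05,
    seed: int = 0,
    contigs: tuple = AUTOSOMES,
    prefix: str = "cohort",
) -> tuple[str, dict]:
    """Write an annotated multi-sample VCF plus its truth file.

    Each sample at each site is non-hom-ref with probability
    ``alt_fraction`` and missing with probability ``missing_fraction``
    (missing counts as non-hom-ref for sparsity).  VEP style emits a CSQ
    block with 1-4 transcript entries per alt allele; Annovar/generic
    styles emit flat key=value pairs.  Identical arguments produce
    byte-identical files.
    """
    if n_variants < 1 or n_samples < 1:
        raise FixtureError("n_variants and n_samples must be >= 1")
    if not (0 < alt_fraction <= 1):
        raise FixtureError("alt_fraction must be in (0, 1]")
    if not (0 <= missing_fraction < 1) or alt_fraction + missing_fraction > 1:
        raise FixtureError("missing_fraction invalid or alt+missing > 1")
    os.makedirs(out_dir, exist_ok=True)
    rng = _rng(seed, 1)
    samples = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    lines = _header_lines(samples, list(contigs), annotation_style)
    per_line = []
    gene_no = 0
    for contig, count in _split_over_contigs(n_variants, list(contigs)):
        positions = _site_positions(rng, count)
        for pos in positions:
            gene_no += 1
            ref = _BASES[rng.integers(0, 4)]
            n_alts = 2 if rng.random() < multiallelic_fraction else 1
            alt_pool = [b for b in _BASES if b != ref]
            alts = list(rng.choice(alt_pool, size=n_alts, replace=False))
            vid = f"rs{int(rng.integers(10_000, 99_999_999))}" if rng.random() < 0.5 else "."
            qual = round(float(rng.uniform(20, 3000)), 2)
            filt = "PASS" if rng.random() < 0.9 else "q10"

            gts = []
            n_nonref = 0
            for _ in samples:
                u = rng.random()
                if u < missing_fraction:
                    gt = "./."
                elif u < missing_fraction + alt_fraction:
                    ai = str(1 + int(rng.integers(0, n_alts)))
                    r = rng.random()
                    if r < 0.55:
                        gt = f"0/{ai}"
                    elif r < 0.70:
                        gt = f"0|{ai}" if rng.random() < 0.5 else f"{ai}|0"
                    else:
                        gt = f"{ai}/{ai}"
                else:
                    gt = "0/0"
                if gt not in ("0/0", "0|0"):
                    n_nonref += 1
                dp = max(1, int(rng.poisson(30)))
                gq = int(rng.integers(20, 100))
                gts.append(f"{gt}:{dp}:{gq}")

            afs = [round(float(rng.uniform(0.001, 0.5)), 4) for _ in alts]
            eur = [round(float(rng.uniform(0.001, 0.5)), 4) for _ in alts]
            acs = [int(rng.integers(1, 2 * n_samples + 1)) for _ in alts]
            info_parts = [
                f"DP={int(rng.integers(100, 10000))}",
                "AC=" + ",".join(str(a) for a in acs),
                "AF=" + ",".join(str(a) for a in afs),
                "EUR_AF=" + ",".join(str(a) for a in eur),
            ]
            if vid != ".":
                info_parts.append("DB")
            n_csq = 0
            if annotation_style == "vep":
                entries = []
                for alt in alts:
                    for _ in range(int(rng.integers(1, 5))):
                        entries.append("|".join([
                            alt,
                            _CONSEQUENCES[rng.integers(0, len(_CONSEQUENCES))],
                            _IMPACTS[rng.integers(0, len(_IMPACTS))],
                            f"GENE{gene_no:05d}",
                            _BIOTYPES[rng.integers(0, len(_BIOTYPES))],
                        ]))
                n_csq = len(entries)
                info_parts.append("CSQ=" + ",".join(entries))
            elif annotation_style == "annovar":
                info_parts += [
                    f"Func_refGene={_FUNC_REGIONS[rng.integers(0, len(_FUNC_REGIONS))]}",
                    f"ExonicFunc_refGene={_EXONIC_FUNC[rng.integers(0, len(_EXONIC_FUNC))]}",
                    f"Gene_refGene=GENE{gene_no:05d}",
                    f"SIFT_score={round(float(rng.uniform(0, 1)), 3)}",
                ]
            else:
                info_parts += [
                    f"REGION={_FUNC_REGIONS[rng.integers(0, len(_FUNC_REGIONS))]}",
                    f"SCORE={round(float(rng.uniform(0, 100)), 3)}",
                ]
            lines.append("\t".join([
                contig, str(int(pos)), vid, ref, ",".join(alts), str(qual),
                filt, ";".join(info_parts), "GT:DP:GQ", *gts,
            ]))
            per_line.append({
                "chrom": contig, "pos": int(pos), "ref": ref, "alts": alts,
                "n_csq": n_csq, "n_nonref_samples": n_nonref,
            })

    vcf_path = os.path.join(out_dir, f"{prefix}.vcf")
    with open(vcf_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    truth = {
        "seed": seed,
        "params": {
            "n_variants": n_variants, "n_samples": n_samples,
            "annotation_style": annotation_style, "alt_fraction": alt_fraction,
            "missing_fraction": missing_fraction,
            "multiallelic_fraction": multiallelic_fraction,
        },
        "samples": samples,
        "per_line": per_line,
        "n_documents_expected": sum(len(r["alts"]) for r in per_line),
        # one entry per (document, non-hom-ref sample): a raw non-ref call
        # stays non-ref under every per-allele recoding
        "n_sparse_entries_expected": sum(
            len(r["alts"]) * r["n_nonref_samples"] for r in per_line
        ),
    }
    truth_path = os.path.join(out_dir, f"{prefix}.truth.json")
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1)
    return vcf_path, truth


# --------------------------------------------------------------------------
# trio fixture

_HR, _HET, _HA = "HOM_REF", "HET", "HOM_ALT"

# genotype-class trios that satisfy no inheritance rule (child, father, mother)
_BG_AUTO = [
    (_HR, _HR, _HR), (_HET, _HET, _HET), (_HR, _HET, _HR),
    (_HR, _HR, _HET), (_HR, _HET, _HET), (_HET, _HA, _HET),
]
_BG_X_MALE = [
    (_HR, _HR, _HR), (_HR, _HR, _HET), (_HA, _HA, _HET),
    (_HR, _HA, _HR), (_HA, _HR, _HA),
]
_BG_X_FEMALE = [
    (_HR, _HR, _HR), (_HR, _HR, _HET), (_HET, _HA, _HET),
    (_HA, _HA, _HA), (_HR, _HA, _HR),
]

# planted genotype-class trios per model, keyed by child sex where it matters
_PLANT_AUTO = {
    "autosomal_de_novo": (_HET, _HR, _HR),
    "autosomal_dominant": (_HET, _HET, _HR),  # affected father is the carrier
    "autosomal_recessive": (_HA, _HET, _HET),
}
_PLANT_X = {
    ("x_linked_de_novo", "male"): (_HA, _HR, _HR),
    ("x_linked_de_novo", "female"): (_HET, _HR, _HR),
    ("x_linked_dominant", "male"): (_HA, _HR, _HET),  # affected carrier mother
    ("x_linked_dominant", "female"): (_HET, _HR, _HET),
    ("x_linked_recessive", "male"): (_HA, _HR, _HET),
    ("x_linked_recessive", "female"): (_HA, _HA, _HET),
}

# plant sets whose affected-status requirements cannot coexist in one trio,
# or whose genotype patterns would cross-match another planted model
_CONFLICTS = [
    {"autosomal_dominant", "x_linked_dominant"},
    {"autosomal_dominant", "compound_heterozygous"},
    {"x_linked_dominant", "x_linked_recessive"},
]

TRIO_SAMPLES = ("PROBAND", "FATHER", "MOTHER")


def _gt_string(cls: str, rng: np.random.Generator, male_on_x: bool = False) -> str:
    if male_on_x:
        # hemizygous calls are written haploid or diploid-coded at random
        if cls == _HR:
            return "0" if rng.random() < 0.5 else "0/0"
        if cls == _HA:
            return "1" if rng.random() < 0.5 else "1/1"
        if cls == _HET:  # not used for males on X
            return "0/1"
    if cls == _HR:
        return "0/0"
    if cls == _HA:
        return "1/1"
    if cls == _HET:
        r = rng.random()
        return "0/1" if r < 0.6 else ("0|1" if r < 0.8 else "1|0")
    raise FixtureError(f"no GT encoding for class {cls}")


def simulate_trio(
    out_dir: str,
    n_background: int = 2000,
    planted: dict | None = None,
    seed: int = 0,
    child_sex: str = "male",
    include_x: bool | None = None,
    prefix: str = "trio",
) -> tuple[str, str, dict]:
    """Write a trio VCF + PED with planted inheritance patterns.

    ``planted`` maps model name to the number of sites to plant (for
    compound_heterozygous, the number of *pairs*).  Background variants
    satisfy no model; each planted variant satisfies exactly its model's
    genotype rule, with X placement for X-linked models and gene sharing
    for compound-het pairs.  The PED encodes an affected child with
    unaffected parents unless a planted model requires an affected carrier
    parent.  Contradictory plant sets raise :class:`FixtureError`.
    """
    planted = dict(planted or {})
    from .mendelian import MODELS  # local import avoids a cycle at import time

    for m, c in planted.items():
        if m not in MODELS:
            raise FixtureError(f"unknown model {m!r}")
        if c < 0:
            raise FixtureError(f"planted count for {m} must be >= 0")
    planted = {m: c for m, c in planted.items() if c > 0}
    for conflict in _CONFLICTS:
        if conflict <= set(planted):
            raise FixtureError(
                f"contradictory plant request: {sorted(conflict)} cannot "
                f"coexist in one trio fixture"
            )
    if child_sex not in ("male", "female"):
        raise FixtureError("child_sex must be 'male' or 'female'")

    x_models = [m for m in planted if m.startswith("x_linked")]
    if include_x is None:
        include_x = bool(x_models)
    if x_models and not include_x:
        raise FixtureError("X-linked plants require the X contig")

    father_affected = "autosomal_dominant" in planted or (
        "x_linked_recessive" in planted and child_sex == "female"
    )
    mother_affected = "x_linked_dominant" in planted

    os.makedirs(out_dir, exist_ok=True)
    rng = _rng(seed, 2)
    auto_contigs = list(AUTOSOMES[:6])
    contigs = auto_contigs + (["X"] if include_x else [])

    n_bg_x = max(1, n_background // 10) if include_x and n_background else 0
    n_bg_auto = n_background - n_bg_x

    # build per-contig slot label lists: "bg" or (model, pair_id, side)
    slots: dict[str, list] = {c: [] for c in contigs}
    for contig, count in _split_over_contigs(n_bg_auto, auto_contigs):
        slots[contig] += ["bg"] * count
    if include_x:
        slots["X"] += ["bg"] * n_bg_x
    ci = 0
    for model, count in sorted(planted.items()):
        for j in range(count):
            if model == "compound_heterozygous":
                contig = auto_contigs[ci % len(auto_contigs)]
                ci += 1
                slots[contig] += [(model, j, "maternal"), (model, j, "paternal")]
            elif model.startswith("x_linked"):
                slots["X"].append((model, j, None))
            else:
                contig = auto_contigs[ci % len(auto_contigs)]
                ci += 1
                slots[contig].append((model, j, None))

    lines = _header_lines(list(TRIO_SAMPLES), contigs, "vep")
    truth_sites = []
    bg_no = 0
    for contig in contigs:
        labels = slots[contig]
        labels = [labels[i] for i in rng.permutation(len(labels))]
        positions = _site_positions(rng, len(labels))
        on_x = contig == "X"
        bg_pool = (_BG_X_MALE if child_sex == "male" else _BG_X_FEMALE) if on_x else _BG_AUTO
        for label, pos in zip(labels, positions):
            ref = _BASES[rng.integers(0, 4)]
            alt = [b for b in _BASES if b != ref][rng.integers(0, 3)]
            if label == "bg":
                bg_no += 1
                trio_cls = bg_pool[rng.integers(0, len(bg_pool))]
                gene = f"BGENE{bg_no:05d}"
                model = None
            else:
                model, pair_id, side = label
                if model == "compound_heterozygous":
                    trio_cls = (_HET, _HR, _HET) if side == "maternal" else (_HET, _HET, _HR)
                    gene = f"CHGENE{pair_id:03d}"
                elif model.startswith("x_linked"):
                    trio_cls = _PLANT_X[(model, child_sex)]
                    gene = f"PGENE{model[:12]}{pair_id:03d}"
                else:
                    trio_cls = _PLANT_AUTO[model]
                    gene = f"PGENE{model[:12]}{pair_id:03d}"
            child_gt = _gt_string(trio_cls[0], rng, on_x and child_sex == "male")
            father_gt = _gt_string(trio_cls[1], rng, on_x)
            mother_gt = _gt_string(trio_cls[2], rng, False)
            gts = []
            for gt in (child_gt, father_gt, mother_gt):
                dp = 20 + int(rng.integers(0, 40))
                gq = int(rng.integers(60, 100))
                gts.append(f"{gt}:{dp}:{gq}")
            csq = "|".join([alt, _CONSEQUENCES[rng.integers(0, len(_CONSEQUENCES))],
                            _IMPACTS[rng.integers(0, len(_IMPACTS))], gene,
                            _BIOTYPES[0]])
            info = f"DP={60 + int(rng.integers(0, 100))};AC=1;AF=0.01;EUR_AF=0.01;CSQ={csq}"
            lines.append("\t".join([
                contig, str(int(pos)), ".", ref, alt, "1000.0", "PASS",
                info, "GT:DP:GQ", *gts,
            ]))
            truth_sites.append({
                "chrom": contig, "pos": int(pos), "ref": ref, "alt": alt,
                "model": model,
                "pair_id": label[1] if label != "bg" and label[0] == "compound_heterozygous" else None,
                "gene": gene,
                "classes": list(trio_cls),
            })

    vcf_path = os.path.join(out_dir, f"{prefix}.vcf")
    with open(vcf_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    ped_path = os.path.join(out_dir, f"{prefix}.ped")
    child_sex_code = "1" if child_sex == "male" else "2"
    with open(ped_path, "w") as fh:
        fh.write(f"FAM1 PROBAND FATHER MOTHER {child_sex_code} 2\n")
        fh.write(f"FAM1 FATHER 0 0 1 {'2' if father_affected else '1'}\n")
        fh.write(f"FAM1 MOTHER 0 0 2 {'2' if mother_affected else '1'}\n")
    truth = {
        "seed": seed,
        "params": {
            "n_background": n_background, "planted": planted,
            "child_sex": child_sex, "include_x": include_x,
        },
        "samples": list(TRIO_SAMPLES),
        "sites": truth_sites,
    }
    truth_path = os.path.join(out_dir, f"{prefix}.truth.json")
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1)
    return vcf_path, ped_path, truth


# --------------------------------------------------------------------------
# case/control fixture

def simulate_case_control(
    out_dir: str,
    n_variants: int = 500,
    n_case: int = 100,
    n_control: int = 100,
    delta_sites: int = 0,
    delta: float = 0.0,
    seed: int = 0,
    prefix: str = "cc",
) -> tuple[str, str, dict]:
    """Write paired case/control VCFs over a shared site list.

    Allele frequencies are equal in expectation across cohorts except at
    ``delta_sites`` randomly chosen sites, where the case frequency is
    shifted by ``delta``.  All genotypes are fully called, so every site's
    called-allele total is exactly twice the cohort size.  The truth file
    records the exact realised allele counts per cohort.
    """
    if not (0 <= delta <= 1):
        raise FixtureError("delta must be in [0, 1]")
    if delta_sites > n_variants or delta_sites < 0:
        raise FixtureError("delta_sites must be in [0, n_variants]")
    if n_variants < 1 or n_case < 1 or n_control < 1:
        raise FixtureError("n_variants and cohort sizes must be >= 1")
    os.makedirs(out_dir, exist_ok=True)
    rng = _rng(seed, 3)
    case_samples = [f"CASE{i:04d}" for i in range(1, n_case + 1)]
    control_samples = [f"CTRL{i:04d}" for i in range(1, n_control + 1)]

    p_base = rng.uniform(0.05, 0.45, size=n_variants)
    delta_idx = set(
        int(i) for i in rng.choice(n_variants, size=delta_sites, replace=False)
    ) if delta_sites else set()

    sites = []
    i = 0
    for contig, count in _split_over_contigs(n_variants, list(AUTOSOMES)):
        for pos in _site_positions(rng, count):
            sites.append((contig, int(pos), i))
            i += 1

    def gt(g: int) -> str:
        return ("0/0", "0/1", "1/1")[g]

    case_lines = _header_lines(case_samples, list(AUTOSOMES), "generic",
                               format_keys=("GT", "DP"))
    control_lines = _header_lines(control_samples, list(AUTOSOMES), "generic",
                                  format_keys=("GT", "DP"))
    truth_sites = []
    for contig, pos, idx in sites:
        ref = _BASES[rng.integers(0, 4)]
        alt = [b for b in _BASES if b != ref][rng.integers(0, 3)]
        p_ctrl = float(p_base[idx])
        p_case = min(0.99, p_ctrl + delta) if idx in delta_idx else p_ctrl
        g_case = rng.binomial(2, p_case, size=n_case)
        g_ctrl = rng.binomial(2, p_ctrl, size=n_control)
        case_cols = [f"{gt(int(g))}:{20 + int(rng.integers(0, 30))}" for g in g_case]
        ctrl_cols = [f"{gt(int(g))}:{20 + int(rng.integers(0, 30))}" for g in g_ctrl]
        region = _FUNC_REGIONS[rng.integers(0, len(_FUNC_REGIONS))]
        score = round(float(rng.uniform(0, 100)), 3)
        info = f"DP=500;AC=1;AF={round(p_ctrl, 4)};EUR_AF={round(p_ctrl, 4)};REGION={region};SCORE={score}"
        base = [contig, str(pos), ".", ref, alt, "999.0", "PASS", info, "GT:DP"]
        case_lines.append("\t".join(base + case_cols))
        control_lines.append("\t".join(base + ctrl_cols))
        truth_sites.append({
            "chrom": contig, "pos": pos, "ref": ref, "alt": alt,
            "is_delta_site": idx in delta_idx,
            "p_case": round(p_case, 6), "p_control": round(p_ctrl, 6),
            "case_alt": int(g_case.sum()), "case_called": 2 * n_case,
            "control_alt": int(g_ctrl.sum()), "control_called": 2 * n_control,
        })

    case_path = os.path.join(out_dir, f"{prefix}_case.vcf")
    control_path = os.path.join(out_dir, f"{prefix}_control.vcf")
    with open(case_path, "w") as fh:
        fh.write("\n".join(case_lines) + "\n")
    with open(control_path, "w") as fh:
        fh.write("\n".join(control_lines) + "\n")
    truth = {
        "seed": seed,
        "params": {
            "n_variants": n_variants, "n_case": n_case, "n_control": n_control,
            "delta_sites": delta_sites, "delta": delta,
        },
        "sites": truth_sites,
    }
    truth_path = os.path.join(out_dir, f"{prefix}.truth.json")
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1)
    return case_path, control_path, truth
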