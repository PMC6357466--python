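import os
import textwrap

import pytest

from varex import EmbeddedStore, ingest_vcf

# Three-sample VEP-annotated mini VCF exercising multi-allelic decomposition,
# per-allele INFO splitting, CSQ routing, flags, phasing and missing calls.
MINI_VEP_VCF = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=1>
    ##contig=<ID=6>
    ##INFO=<ID=AC,Number=A,Type=Integer,Description="Alt allele count">
    ##INFO=<ID=AN,Number=1,Type=Integer,Description="Total alleles">
    ##INFO=<ID=AF,Number=A,Type=Float,Description="Alt allele frequency">
    ##INFO=<ID=DB,Number=0,Type=Flag,Description="dbSNP membership">
    ##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations from VEP. Format: Allele|Consequence|IMPACT|SYMBOL">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
    ##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tHG002\tHG003\tHG004
    1\t100\trs123\tA\tG\t50\tPASS\tAC=2;AN=6;AF=0.5;DB;CSQ=G|missense_variant|MODERATE|GENE1,G|intron_variant|MODIFIER|GENE1\tGT:DP:GQ\t0/1:30:99\t0|0:25:80\t./.:10:3
    1\t200\t.\tC\tT,G\t99\tPASS\tAC=1,1;AN=6;AF=0.25,0.125;CSQ=T|missense_variant|HIGH|GENE2,G|synonymous_variant|LOW|GENE2\tGT:DP:GQ\t0/1:20:50\t1/2:30:60\t0/0:10:20
    6\t28480000\t.\tG\tA\t80\tq10\tAC=2;AN=6;AF=0.1;CSQ=A|missense_variant|MODERATE|HLA1\tGT:DP:GQ\t0/0:30:90\t0|1:32:95\t1|0:28:88
    """)


def write_text(path, content):
    with open(path, "w") as fh:
        fh.write(content)
    return str(path)


@pytest.fixture
def mini_vcf(tmp_path):
    return write_text(tmp_path / "mini.vcf", MINI_VEP_VCF)


@pytest.fixture
def mini_store(tmp_path, mini_vcf):
    store = EmbeddedStore(os.path.join(tmp_path, "mini_idx"))
    ingest_vcf(mini_vcf, store)
    return store


def make_store(tmp_path, vcf_path, name="idx", **kwargs):
    store = EmbeddedStore(os.path.join(tmp_path, name))
    report = ingest_vcf(vcf_path, store, **kwargs)
    return store, report
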