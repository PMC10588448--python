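import textwrap

import pytest

from varburden.cohort_io import (
    AnnotatedVariant,
    AnnotationRecord,
    ControlFrequencyRecord,
    GenotypeCall,
    VariantKey,
)
from varburden.classify import ConsequenceClass


VCF_BODY = """\
##fileformat=VCFv4.2
##contig=<ID=17,length=83257441>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
17\t100\t.\tC\tT\t.\t.\t.\tGT:AD:GQ\t0/1:10,10:99\t0/0:20,0:99\t./.:.:.\t0/0:18,0:95
17\t200\t.\tG\tA,T\t.\t.\t.\tGT:AD:GQ\t1/2:2,8,9:80\t0/1:10,10,0:99\t0/0:30,0,0:99\t0/0:25,0,0:99
17\t300\t.\tCT\tC\t.\t.\t.\tGT:AD:GQ\t0/1:9,7:40\t0/0:22,0:99\t0/0:25,0:99\t0/1:10,6:50
"""


@pytest.fixture
def small_vcf(tmp_path):
    """Four-sample VCF with a multi-allelic site, a missing genotype and an indel."""
    path = tmp_path / "cases.vcf"
    path.write_text(VCF_BODY)
    return path


def make_variant(
    gene="RPA1",
    chrom="17",
    pos=100,
    ref="C",
    alt="T",
    consequence=ConsequenceClass.MISSENSE,
    cadd=25.0,
    control_ac=None,
    control_an=267908,
    carriers=(),
    missing=(),
    n_samples=4,
    ddg=None,
):
    """Assemble an AnnotatedVariant without touching files."""
    key = VariantKey(chrom, pos, ref, alt)
    control = (
        ControlFrequencyRecord(key, control_ac, control_an, control_ac / control_an)
        if control_ac is not None
        else None
    )
    ann = AnnotationRecord(
        key=key, gene=gene, consequence=consequence, cadd_phred=cadd, ddg_fold=ddg
    )
    return AnnotatedVariant(
        key=key, gene=gene, annotation=ann, control=control,
        carriers=tuple(carriers), missing_samples=frozenset(missing),
        n_samples=n_samples,
    )


def het(sample, ref_reads=10, alt_reads=10, gq=99):
    return GenotypeCall(sample, "het", ref_reads, alt_reads, gq)
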